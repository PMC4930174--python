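"""Stage game, payoff accounting, and per-period random matching.

The stage game is a symmetric two-player Prisoner's Dilemma with payoffs
T > R > P > S.  In every period each of the ``n`` actors in a group is
matched with exactly ``m`` partners, i.e. the period's interaction graph is
an m-regular graph on ``n`` labeled vertices drawn uniformly at random.
Unmatched potential relations pay a fixed non-interaction amount ``Q`` per
period, so a period's income is the sum of the actor's m dyad payoffs plus
``(n - 1 - m) * Q``.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Action",
    "Condition",
    "PDPayoffs",
    "GroupConfig",
    "Matching",
    "sample_matching",
    "enumerate_regular_graphs",
    "dyad_payoff",
    "period_payoff",
    "interaction_probability",
]


class Action(str, enum.Enum):
    """Cooperate or defect.  Lab color labels are accepted as aliases."""

    C = "C"
    D = "D"

    @classmethod
    def parse(cls, value: "Action | str") -> "Action":
        if isinstance(value, Action):
            return value
        key = str(value).strip().upper()
        # ORANGE/BLUE are the on-screen labels subjects saw for C/D.
        aliases = {"C": cls.C, "D": cls.D, "ORANGE": cls.C, "BLUE": cls.D}
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown action {value!r}; expected C, D, ORANGE or BLUE") from None


class Condition(str, enum.Enum):
    """Information regime: what actors observe about others' interactions."""

    ATOMIZED = "atomized"
    EMBEDDED = "embedded"

    @classmethod
    def parse(cls, value: "Condition | str") -> "Condition":
        if isinstance(value, Condition):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(f"unknown condition {value!r}; expected 'atomized' or 'embedded'") from None


@dataclass(frozen=True)
class PDPayoffs:
    """Stage-game payoffs plus the per-relation non-interaction payoff Q.

    Parameters
    ----------
    T, R, P, S
        Temptation, reward, punishment and sucker payoffs, in points,
        with T > R > P > S.
    Q
        Points received per unmatched potential partner per period.  Q does
        not depend on anyone's choice and provably does not move the
        equilibrium thresholds; it only shifts income levels.
    """

    T: float = 60.0
    R: float = 40.0
    P: float = 20.0
    S: float = 0.0
    Q: float = 30.0

    def __post_init__(self) -> None:
        vals = (self.T, self.R, self.P, self.S, self.Q)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all payoffs must be finite")
        if not (self.T > self.R > self.P > self.S):
            raise ValueError(
                f"Prisoner's Dilemma requires T > R > P > S, got "
                f"T={self.T}, R={self.R}, P={self.P}, S={self.S}"
            )


@dataclass(frozen=True)
class GroupConfig:
    """Group size, per-period degree, horizon and information condition."""

    n: int = 6
    m: int = 2
    periods: int = 40
    condition: Condition = Condition.ATOMIZED

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need at least two actors, got n={self.n}")
        if not (1 <= self.m <= self.n - 1):
            raise ValueError(f"degree m must satisfy 1 <= m <= n-1, got n={self.n}, m={self.m}")
        if (self.n * self.m) % 2 != 0:
            raise ValueError(f"no m-regular graph exists for odd n*m (n={self.n}, m={self.m})")
        if self.periods < 1:
            raise ValueError("periods must be positive")
        object.__setattr__(self, "condition", Condition.parse(self.condition))


class Matching:
    """One period's interaction graph: an m-regular graph on actors 0..n-1."""

    __slots__ = ("edges", "_neighbors")

    def __init__(self, edges: Iterable[tuple[int, int]]):
        norm = tuple(sorted((min(a, b), max(a, b)) for a, b in edges))
        self.edges: tuple[tuple[int, int], ...] = norm
        nbrs: dict[int, list[int]] = {}
        for a, b in norm:
            if a == b:
                raise ValueError(f"self-pair ({a},{b}) in matching")
            nbrs.setdefault(a, []).append(b)
            nbrs.setdefault(b, []).append(a)
        if len(set(norm)) != len(norm):
            raise ValueError("duplicate edge in matching")
        self._neighbors = nbrs

    def neighbors(self, actor: int) -> tuple[int, ...]:
        return tuple(self._neighbors.get(actor, ()))

    def degree(self, actor: int) -> int:
        return len(self._neighbors.get(actor, ()))

    def validate(self, n: int, m: int) -> None:
        """Raise if this is not an m-regular graph on vertices 0..n-1."""
        for a, b in self.edges:
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"edge ({a},{b}) out of range for n={n}")
        for actor in range(n):
            d = self.degree(actor)
            if d != m:
                raise ValueError(f"actor {actor} has degree {d}, expected {m}")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Matching) and self.edges == other.edges

    def __hash__(self) -> int:
        return hash(self.edges)

    def __repr__(self) -> str:
        return f"Matching({list(self.edges)!r})"


# Cache of fully enumerated labeled m-regular graphs, keyed by (n, m).
# Value None means the count exceeded the cap and rejection sampling is used.
_ENUM_CACHE: dict[tuple[int, int], list[tuple[tuple[int, int], ...]] | None] = {}
_ENUM_CAP = 200_000


def enumerate_regular_graphs(n: int, m: int, cap: int = _ENUM_CAP) -> list[tuple[tuple[int, int], ...]] | None:
    """All labeled m-regular graphs on n vertices, as sorted edge tuples.

    Returns None if there are more than ``cap`` such graphs (the sampler then
    falls back to configuration-model rejection, which is also exactly
    uniform).  For the experimental default (n=6, m=2) there are 70 graphs:
    60 labeled 6-cycles and 10 disjoint triangle pairs.
    """
    key = (n, m)
    if cap == _ENUM_CAP and key in _ENUM_CACHE:
        return _ENUM_CACHE[key]

    results: list[tuple[tuple[int, int], ...]] = []
    deg = [m] * n
    edges: list[tuple[int, int]] = []
    adj = [set() for _ in range(n)]
    overflow = False

    def backtrack() -> None:
        nonlocal overflow
        if overflow:
            return
        u = next((v for v in range(n) if deg[v] > 0), None)
        if u is None:
            results.append(tuple(sorted(edges)))
            if len(results) > cap:
                overflow = True
            return
        candidates = [v for v in range(u + 1, n) if deg[v] > 0 and v not in adj[u]]
        need = deg[u]
        if len(candidates) < need:
            return
        for combo in itertools.combinations(candidates, need):
            deg[u] = 0
            for v in combo:
                deg[v] -= 1
                adj[u].add(v)
                adj[v].add(u)
                edges.append((u, v))
            backtrack()
            for v in combo:
                deg[v] += 1
                adj[u].discard(v)
                adj[v].discard(u)
                edges.pop()
            deg[u] = need
            if overflow:
                return

    backtrack()
    out = None if overflow else results
    if cap == _ENUM_CAP:
        _ENUM_CACHE[key] = out
    return out


def _rejection_sample_regular(n: int, m: int, rng: np.random.Generator) -> Matching:
    # Configuration model conditioned on simplicity: every simple m-regular
    # graph corresponds to exactly (m!)^n stub pairings, so resampling until
    # the pairing has no loops or multi-edges is exactly uniform.
    stubs = np.repeat(np.arange(n), m)
    while True:
        perm = rng.permutation(stubs)
        pairs = perm.reshape(-1, 2)
        if np.any(pairs[:, 0] == pairs[:, 1]):
            continue
        canon = {(min(a, b), max(a, b)) for a, b in pairs.tolist()}
        if len(canon) == n * m // 2:
            return Matching(canon)


def sample_matching(n: int, m: int, rng: np.random.Generator) -> Matching:
    """Draw one m-regular interaction graph uniformly over all labeled ones.

    Every potential relation has the same marginal probability m/(n-1) of
    being used, as the model requires.
    """
    if not (1 <= m <= n - 1) or (n * m) % 2 != 0 or n < 2:
        raise ValueError(f"no m-regular graph exists for n={n}, m={m}")
    graphs = enumerate_regular_graphs(n, m) if n <= 10 else None
    if graphs is not None:
        if not graphs:
            raise ValueError(f"no m-regular graph exists for n={n}, m={m}")
        idx = int(rng.integers(len(graphs)))
        return Matching(graphs[idx])
    return _rejection_sample_regular(n, m, rng)


def dyad_payoff(action_i: Action | str, action_j: Action | str, payoffs: PDPayoffs) -> tuple[float, float]:
    """Stage-game payoffs for one matched dyad: (points_i, points_j)."""
    ai, aj = Action.parse(action_i), Action.parse(action_j)
    table = {
        (Action.C, Action.C): (payoffs.R, payoffs.R),
        (Action.C, Action.D): (payoffs.S, payoffs.T),
        (Action.D, Action.C): (payoffs.T, payoffs.S),
        (Action.D, Action.D): (payoffs.P, payoffs.P),
    }
    return table[(ai, aj)]


def period_payoff(
    actor: int,
    matching: Matching,
    actions: Mapping[tuple[int, int], Action | str],
    payoffs: PDPayoffs,
    config: GroupConfig,
) -> float:
    """One actor's total income for a period.

    ``actions`` maps ordered pairs (i, j) to the action i played against j
    and must cover both directions of every matched dyad.  The total is the
    sum over the actor's m dyads plus the fixed (n-1-m)*Q baseline for the
    unmatched relations (3*30 = 90 points under the experimental defaults).
    """
    if not (0 <= actor < config.n):
        raise ValueError(f"actor index {actor} out of range for n={config.n}")
    total = 0.0
    for partner in matching.neighbors(actor):
        try:
            own = actions[(actor, partner)]
            theirs = actions[(partner, actor)]
        except KeyError as exc:
            raise ValueError(f"missing action for matched dyad {exc.args[0]}") from None
        total += dyad_payoff(own, theirs, payoffs)[0]
    return total + (config.n - 1 - config.m) * payoffs.Q


def interaction_probability(n: int, m: int) -> float:
    """Per-period probability pi = m/(n-1) that a given relation is matched."""
    if n < 2 or not (1 <= m <= n - 1):
        raise ValueError(f"need 1 <= m <= n-1, got n={n}, m={m}")
    return m / (n - 1)
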