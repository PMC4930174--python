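"""Agent-based engine for the networked repeated Prisoner's Dilemma.

Plays the exact lab game: in each of ``periods`` periods a uniform m-regular
matching is drawn, all matched actors choose simultaneously (using only
information from previous periods), per-decision trembles are applied, and
everyone's information state is updated according to the group's condition
(atomized: own dyads only; embedded: all dyads; matching structure is public
in both).

Strategies
----------
ALL_C / ALL_D
    Unconditional.
TRIGGER
    Cooperate with a partner until that partner is *observed* playing D
    against anyone within the actor's information scope, then defect against
    that partner forever.  Non-discriminating by default: a partner's D
    counts even when it is itself retaliation; an optional ``discriminating``
    flag ignores Ds aimed at actors already known (to the observer) to have
    defected.
STRONG_TRIGGER
    Defect against everyone forever after observing any D by anyone.
LEARNING
    Bush-Mosteller aspiration-based reinforcement per dyad: the propensity to
    cooperate with a given partner moves up when the realized payoff beats
    the aspiration level and down otherwise, at a configurable rate.  A
    backward-looking interpretation of learning accounts of cooperation; the
    functional form is this package's choice.

Trembles flip the intended action with a fixed per-decision probability;
records keep both intended and realized actions so analyses can condition on
error events.  An optional per-period extra-defection probability (used for
endgame ramps in synthetic data) forces realized actions to D and is likewise
visible through the intended/realized distinction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .game_core import (
    Action,
    Condition,
    GroupConfig,
    Matching,
    PDPayoffs,
    dyad_payoff,
    sample_matching,
)

__all__ = [
    "StrategyKind",
    "LearningParams",
    "StrategySpec",
    "ForcedDefection",
    "SimulationRecord",
    "InformationState",
    "decide",
    "apply_tremble",
    "run_group",
    "cooperation_trajectory",
    "cooperation_rate",
]


class StrategyKind(str, enum.Enum):
    ALL_C = "ALL_C"
    ALL_D = "ALL_D"
    TRIGGER = "TRIGGER"
    STRONG_TRIGGER = "STRONG_TRIGGER"
    LEARNING = "LEARNING"

    @classmethod
    def parse(cls, value: "StrategyKind | str") -> "StrategyKind":
        if isinstance(value, StrategyKind):
            return value
        try:
            return cls(str(value).strip().upper())
        except ValueError:
            raise ValueError(
                f"unknown strategy {value!r}; expected one of {[k.value for k in cls]}"
            ) from None


@dataclass(frozen=True)
class LearningParams:
    """Bush-Mosteller parameters.

    aspiration : points against which a realized payoff counts as reward or
        punishment (default Q = 30, the income of an unmatched relation).
    rate : learning rate in [0, 1].
    initial_propensity : starting probability of cooperating with a fresh
        partner.
    """

    aspiration: float = 30.0
    rate: float = 0.5
    initial_propensity: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"learning rate must lie in [0,1], got {self.rate}")
        if not 0.0 <= self.initial_propensity <= 1.0:
            raise ValueError(f"initial propensity must lie in [0,1], got {self.initial_propensity}")


@dataclass(frozen=True)
class StrategySpec:
    kind: StrategyKind = StrategyKind.TRIGGER
    tremble: float = 0.0
    learning: LearningParams | None = None
    discriminating: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", StrategyKind.parse(self.kind))
        if not 0.0 <= self.tremble < 1.0:
            raise ValueError(f"tremble must lie in [0,1), got {self.tremble}")
        if self.kind is StrategyKind.LEARNING and self.learning is None:
            object.__setattr__(self, "learning", LearningParams())


@dataclass(frozen=True)
class ForcedDefection:
    """Test fixture: force one realized D in one dyad.

    Fires in the first period >= ``period`` in which the dyad {actor,
    partner} is matched (the dyad need not be matched in the requested
    period, since matchings are random).
    """

    actor: int = 0
    partner: int = 1
    period: int = 1


@dataclass(frozen=True)
class SimulationRecord:
    """One dyad-period outcome, including pre-tremble intentions."""

    period: int
    actor_a: int
    actor_b: int
    intended_a: Action
    intended_b: Action
    action_a: Action
    action_b: Action
    payoff_a: float
    payoff_b: float


@dataclass
class InformationState:
    """What each actor has observed so far, per the information condition.

    ``seen_defect[i]`` is the set of actors that actor i has observed playing
    D (within i's scope); ``any_defect[i]`` flags whether i has observed any
    D at all (for STRONG_TRIGGER).  ``history[i]`` is i's cumulative log of
    visible dyad outcomes as (period, a, b, action_a, action_b) tuples, and
    ``matchings`` the public record of who was matched with whom.
    Observations accumulate and are never forgotten.
    """

    n: int
    condition: Condition
    seen_defect: list[set[int]] = field(default_factory=list)
    any_defect: list[bool] = field(default_factory=list)
    history: list[list[tuple[int, int, int, Action, Action]]] = field(default_factory=list)
    matchings: list[Matching] = field(default_factory=list)
    propensity: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.condition = Condition.parse(self.condition)
        if not self.seen_defect:
            self.seen_defect = [set() for _ in range(self.n)]
        if not self.any_defect:
            self.any_defect = [False] * self.n
        if not self.history:
            self.history = [[] for _ in range(self.n)]

    def observers_of(self, a: int, b: int) -> range | tuple[int, int]:
        if self.condition is Condition.EMBEDDED:
            return range(self.n)
        return (a, b)

    def update(
        self,
        period: int,
        matching: Matching,
        records: Sequence[SimulationRecord],
        strategies: Sequence[StrategySpec],
    ) -> None:
        """Fold one period's outcomes into every actor's information set.

        Uses a snapshot of pre-period knowledge for the discriminating-trigger
        exemption, so simultaneous retaliations are classified consistently.
        """
        self.matchings.append(matching)
        snapshot = [frozenset(s) for s in self.seen_defect]
        for rec in records:
            for obs in self.observers_of(rec.actor_a, rec.actor_b):
                self.history[obs].append(
                    (period, rec.actor_a, rec.actor_b, rec.action_a, rec.action_b)
                )
                for who, target, act in (
                    (rec.actor_a, rec.actor_b, rec.action_a),
                    (rec.actor_b, rec.actor_a, rec.action_b),
                ):
                    if act is Action.D and who != obs:
                        if strategies[obs].discriminating and target in snapshot[obs]:
                            continue  # retaliation against a known defector
                        self.seen_defect[obs].add(who)
                        self.any_defect[obs] = True
            # Bush-Mosteller update for learners, from their own realized
            # action and payoff.
            for who, partner, act, pay in (
                (rec.actor_a, rec.actor_b, rec.action_a, rec.payoff_a),
                (rec.actor_b, rec.actor_a, rec.action_b, rec.payoff_b),
            ):
                spec = strategies[who]
                if spec.kind is not StrategyKind.LEARNING:
                    continue
                lp = spec.learning
                self._bm_update(who, partner, act, pay, lp)

    def _bm_update(
        self, actor: int, partner: int, act: Action, payoff: float, lp: LearningParams
    ) -> None:
        key = (actor, partner)
        p = self.propensity.get(key, lp.initial_propensity)
        scale = max(abs(payoff - lp.aspiration), 1e-12)
        # stimulus in [-1, 1]; scale is set per-update so only the sign and
        # the rate matter, which keeps the rule payoff-scale free
        s = (payoff - lp.aspiration) / scale
        if act is Action.C:
            p = p + lp.rate * s * (1.0 - p) if s >= 0 else p + lp.rate * s * p
        else:
            p = p - lp.rate * s * p if s >= 0 else p - lp.rate * s * (1.0 - p)
        self.propensity[key] = min(1.0, max(0.0, p))


def decide(
    actor: int,
    partner: int,
    strategy: StrategySpec,
    info: InformationState,
    rng: np.random.Generator,
) -> Action:
    """Intended action of ``actor`` toward ``partner`` given current knowledge."""
    kind = strategy.kind
    if kind is StrategyKind.ALL_C:
        return Action.C
    if kind is StrategyKind.ALL_D:
        return Action.D
    if kind is StrategyKind.TRIGGER:
        return Action.D if partner in info.seen_defect[actor] else Action.C
    if kind is StrategyKind.STRONG_TRIGGER:
        return Action.D if info.any_defect[actor] else Action.C
    # LEARNING
    p = info.propensity.get((actor, partner), strategy.learning.initial_propensity)
    return Action.C if rng.random() < p else Action.D


def apply_tremble(intended: Action, tremble: float, rng: np.random.Generator) -> Action:
    """Flip the intended action with probability ``tremble`` (symmetric)."""
    if tremble and rng.random() < tremble:
        return Action.D if intended is Action.C else Action.C
    return intended


def run_group(
    config: GroupConfig,
    payoffs: PDPayoffs,
    strategies: Sequence[StrategySpec],
    seed: int | np.random.Generator | np.random.SeedSequence,
    *,
    inject: ForcedDefection | None = None,
    extra_defect_prob: Sequence[float] | None = None,
) -> list[SimulationRecord]:
    """Simulate one group for ``config.periods`` periods.

    Decisions within a period are simultaneous: every actor decides from the
    information state as of the end of the previous period.  Fully
    reproducible from ``seed``.

    ``extra_defect_prob`` gives, per period, an additional probability that a
    realized action is forced to D (independent per decision) — used to
    superimpose endgame defection ramps on synthetic data.
    """
    if len(strategies) != config.n:
        raise ValueError(f"need one strategy per actor: got {len(strategies)} for n={config.n}")
    if extra_defect_prob is not None and len(extra_defect_prob) != config.periods:
        raise ValueError("extra_defect_prob must have one entry per period")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    info = InformationState(n=config.n, condition=config.condition)
    records: list[SimulationRecord] = []
    injected = inject is None  # flips True once the forced D has fired

    for t in range(1, config.periods + 1):
        matching = sample_matching(config.n, config.m, rng)
        extra = extra_defect_prob[t - 1] if extra_defect_prob is not None else 0.0
        period_records: list[SimulationRecord] = []
        for a, b in matching.edges:
            ia = decide(a, b, strategies[a], info, rng)
            ib = decide(b, a, strategies[b], info, rng)
            ra = apply_tremble(ia, strategies[a].tremble, rng)
            rb = apply_tremble(ib, strategies[b].tremble, rng)
            if extra > 0.0:
                if ra is Action.C and rng.random() < extra:
                    ra = Action.D
                if rb is Action.C and rng.random() < extra:
                    rb = Action.D
            if not injected and t >= inject.period and {a, b} == {inject.actor, inject.partner}:
                if a == inject.actor:
                    ra = Action.D
                else:
                    rb = Action.D
                injected = True
            pa, pb = dyad_payoff(ra, rb, payoffs)
            period_records.append(
                SimulationRecord(
                    period=t, actor_a=a, actor_b=b,
                    intended_a=ia, intended_b=ib,
                    action_a=ra, action_b=rb,
                    payoff_a=pa, payoff_b=pb,
                )
            )
        info.update(t, matching, period_records, strategies)
        records.extend(period_records)
    return records


def cooperation_trajectory(records: Sequence[SimulationRecord]) -> np.ndarray:
    """Per-period proportion of realized C actions, ordered by period."""
    if not records:
        raise ValueError("empty record sequence")
    counts: dict[int, list[int]] = {}
    for rec in records:
        c, tot = counts.setdefault(rec.period, [0, 0])
        counts[rec.period][0] = c + (rec.action_a is Action.C) + (rec.action_b is Action.C)
        counts[rec.period][1] = tot + 2
    return np.array([counts[t][0] / counts[t][1] for t in sorted(counts)])


def cooperation_rate(
    records: Sequence[SimulationRecord], period_lo: int = 1, period_hi: int | None = None
) -> float:
    """Overall proportion of realized C actions over a period window."""
    c = tot = 0
    for rec in records:
        if rec.period < period_lo or (period_hi is not None and rec.period > period_hi):
            continue
        c += (rec.action_a is Action.C) + (rec.action_b is Action.C)
        tot += 2
    if tot == 0:
        raise ValueError("empty period window")
    return c / tot
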