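"""Closed-form expected utilities and discount-factor thresholds.

Conditional cooperation (everyone playing the trigger strategy) is a Nash
equilibrium of the infinitely repeated networked Prisoner's Dilemma exactly
when the discount factor beta exceeds a threshold that depends on the
information regime.  Playing ALL-C against triggers earns m*R + (n-1-m)*Q
per period forever.  A deviant playing ALL-D earns the temptation payoff T
once per relation before that relation turns to permanent mutual punishment
P; how fast relations turn depends on how fast the information travels:

* embedded — every relation learns of the first defection immediately, so
  the deviant collects m*T once and m*P from then on.  Indifference gives
  the classic dyadic threshold  beta_emb = (T - R) / (T - P).
* atomized — a relation only learns when it is itself matched, which happens
  with probability pi = m/(n-1) per period, so per relation the deviant
  collects T with probability pi*(1-pi)^(t-1) in period t (first activation)
  and P on later activations.  Indifference gives
  beta_ato = (T - R) / (T - P - (R - P)*(1 - pi))  >=  beta_emb,
  with equality exactly at pi = 1 (full round-robin).

The non-interaction payoff Q cancels from both sides of each comparison and
has no effect on either threshold.

All expected utilities here are infinite-horizon discounted sums, matching
the equilibrium analysis; :func:`finite_horizon_eu` truncates them for
diagnostic use only and carries no equilibrium meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .game_core import Condition, PDPayoffs, interaction_probability

__all__ = [
    "ThresholdResult",
    "eu_all_c",
    "eu_all_d_embedded",
    "eu_all_d_atomized",
    "beta_threshold_embedded",
    "beta_threshold_atomized",
    "indifference_check",
    "threshold_analysis",
    "finite_horizon_eu",
]


def _check_beta(beta: float) -> float:
    beta = float(beta)
    if not 0.0 < beta < 1.0:
        raise ValueError(f"discount factor beta must lie strictly in (0,1), got {beta}")
    return beta


def eu_all_c(payoffs: PDPayoffs, n: int, m: int, beta: float) -> float:
    """Discounted value of playing ALL-C against a group of triggers.

    Same in both information conditions: m*R + (n-1-m)*Q per period,
    discounted, = (m*R + (n-1-m)*Q) / (1 - beta).
    """
    beta = _check_beta(beta)
    interaction_probability(n, m)  # validates (n, m)
    return (m * payoffs.R + (n - 1 - m) * payoffs.Q) / (1.0 - beta)


def eu_all_d_embedded(payoffs: PDPayoffs, n: int, m: int, beta: float) -> float:
    """Discounted value of ALL-D against triggers under embedded information.

    The deviation is profitable for one period only (m*T), after which every
    relation punishes: m*T + beta*m*P/(1-beta) + (n-1-m)*Q/(1-beta).
    """
    beta = _check_beta(beta)
    interaction_probability(n, m)
    return (
        m * payoffs.T
        + beta * m * payoffs.P / (1.0 - beta)
        + (n - 1 - m) * payoffs.Q / (1.0 - beta)
    )


def eu_all_d_atomized(payoffs: PDPayoffs, n: int, m: int, beta: float) -> float:
    """Discounted value of ALL-D against triggers under atomized information.

    Each of the n-1 relations activates independently with probability
    pi = m/(n-1) per period and yields T on its first activation, P on later
    ones, Q when inactive.  Summing the geometric series gives
    m*P/(1-beta) + m*(T-P)/(1 - beta*(1-pi)) + (n-1-m)*Q/(1-beta).
    """
    beta = _check_beta(beta)
    pi = interaction_probability(n, m)
    return (
        m * payoffs.P / (1.0 - beta)
        + m * (payoffs.T - payoffs.P) / (1.0 - beta * (1.0 - pi))
        + (n - 1 - m) * payoffs.Q / (1.0 - beta)
    )


def beta_threshold_embedded(payoffs: PDPayoffs) -> float:
    """Minimal discount factor sustaining conditional cooperation, embedded.

    (T - R) / (T - P): the classic dyadic repeated-PD condition.  Does not
    depend on Q, n or m.
    """
    return (payoffs.T - payoffs.R) / (payoffs.T - payoffs.P)


def beta_threshold_atomized(payoffs: PDPayoffs, n: int, m: int) -> float:
    """Minimal discount factor sustaining conditional cooperation, atomized.

    (T - R) / (T - P - (R - P)*(1 - pi)) with pi = m/(n-1).  Always at least
    the embedded threshold; equal exactly when pi = 1.
    """
    pi = interaction_probability(n, m)
    return (payoffs.T - payoffs.R) / (payoffs.T - payoffs.P - (payoffs.R - payoffs.P) * (1.0 - pi))


def indifference_check(
    payoffs: PDPayoffs, n: int, m: int, beta: float, condition: Condition | str
) -> float:
    """Signed gap EU(ALL-C) - EU(ALL-D | condition), in discounted points.

    Positive exactly when beta exceeds the condition's threshold; zero at it.
    """
    condition = Condition.parse(condition)
    if condition is Condition.EMBEDDED:
        return eu_all_c(payoffs, n, m, beta) - eu_all_d_embedded(payoffs, n, m, beta)
    return eu_all_c(payoffs, n, m, beta) - eu_all_d_atomized(payoffs, n, m, beta)


@dataclass(frozen=True)
class ThresholdResult:
    """Threshold discount factors plus EU components at a stated beta."""

    beta_emb: float
    beta_ato: float
    pi: float
    beta: float
    eu_all_c: float
    eu_all_d_embedded: float
    eu_all_d_atomized: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def threshold_analysis(payoffs: PDPayoffs, n: int, m: int, beta: float = 0.8) -> ThresholdResult:
    """Full equilibrium summary for one parameterization.

    ``beta`` only anchors the expected-utility columns; the thresholds do not
    depend on it.  The default 0.8 lies above both thresholds for the
    experimental payoffs.
    """
    return ThresholdResult(
        beta_emb=beta_threshold_embedded(payoffs),
        beta_ato=beta_threshold_atomized(payoffs, n, m),
        pi=interaction_probability(n, m),
        beta=_check_beta(beta),
        eu_all_c=eu_all_c(payoffs, n, m, beta),
        eu_all_d_embedded=eu_all_d_embedded(payoffs, n, m, beta),
        eu_all_d_atomized=eu_all_d_atomized(payoffs, n, m, beta),
    )


def finite_horizon_eu(
    payoffs: PDPayoffs,
    n: int,
    m: int,
    beta: float,
    horizon: int,
    strategy: str = "all_c",
    condition: Condition | str = Condition.EMBEDDED,
) -> float:
    """Truncated (finite-horizon) discounted expected utility — diagnostic only.

    Sums the same per-period expectations as the closed forms over periods
    1..horizon.  This is NOT an equilibrium object: the thresholds above are
    derived for the infinite-horizon game, and the finite lab game is only an
    approximation to it.
    """
    beta = _check_beta(beta)
    pi = interaction_probability(n, m)
    base = (n - 1 - m) * payoffs.Q
    total = 0.0
    disc = 1.0
    surv = 1.0  # (1-pi)^(t-1), probability a given relation was never active
    condition = Condition.parse(condition)
    for t in range(1, horizon + 1):
        if strategy == "all_c":
            per = m * payoffs.R + base
        elif strategy == "all_d":
            if condition is Condition.EMBEDDED:
                per = (m * payoffs.T if t == 1 else m * payoffs.P) + base
            else:
                per = (n - 1) * pi * (surv * payoffs.T + (1.0 - surv) * payoffs.P) + base
        else:
            raise ValueError(f"unknown strategy {strategy!r}; expected 'all_c' or 'all_d'")
        total += disc * per
        disc *= beta
        surv *= 1.0 - pi
    return total
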