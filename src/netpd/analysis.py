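"""Group-level statistical pipeline.

The group is the unit of analysis throughout.  For every group three
cooperation summaries are computed: the main-window rate (periods 1-35,
excluding the last five periods where endgame effects bias behavior), the
first-interaction rate (each dyad's first matched period only), and the
late-window rate (periods 30-35) used for the variance comparison.

Hypothesis tests:

* H1 — average cooperation higher under embedded than atomized information:
  Mann-Whitney on main-window group rates (exact permutation p-value with
  midranks for combined N <= 20, normal approximation with tie correction
  above that; two-sided by default).
* H2 — the same contrast on first-interaction rates.
* Variance comparison — across-group SD of late-window cooperation larger
  under embeddedness: one-sided F test by default, with a seeded
  label-permutation variant as a robustness option.
* Power — exact noncentral-t power of the two-sample t test, used to ask
  whether a handful of groups per arm suffices to detect an effect of a
  given size (one-sided by default, since the hypotheses are directional).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import validate_dataset

__all__ = [
    "GroupStats",
    "TestResult",
    "group_cooperation_rate",
    "first_interaction_cooperation",
    "summarize_groups",
    "mann_whitney",
    "variance_comparison",
    "t_test_power",
    "run_hypothesis_suite",
]

_ALTERNATIVES = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class GroupStats:
    """Per-group cooperation summaries feeding the hypothesis tests."""

    group_id: str
    experiment_id: str
    condition: str
    coop_rate_main: float
    coop_rate_first: float
    coop_rate_endwindow: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    alternative: str
    method: str
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def _check_alternative(alternative: str) -> str:
    alt = alternative.replace("-", "_")
    if alt not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}, got {alternative!r}")
    return alt


def _group_slice(dataset: pd.DataFrame, group_id: str) -> pd.DataFrame:
    grp = dataset[dataset["group_id"] == group_id]
    if grp.empty:
        raise ValueError(f"group {group_id!r} not present in dataset")
    return grp


def group_cooperation_rate(
    dataset: pd.DataFrame, group_id: str, period_lo: int = 1, period_hi: int = 35
) -> float:
    """Proportion of C actions by the group's members in a period window."""
    grp = _group_slice(dataset, group_id)
    win = grp[(grp["period"] >= period_lo) & (grp["period"] <= period_hi)]
    if win.empty:
        raise ValueError(
            f"group {group_id!r}: no interactions in periods {period_lo}..{period_hi}"
        )
    c = (win["action_a"] == "C").sum() + (win["action_b"] == "C").sum()
    return float(c) / (2 * len(win))


def first_interaction_cooperation(
    dataset: pd.DataFrame, group_id: str, level: str = "action"
) -> float:
    """Cooperation rate over each dyad's first matched period.

    ``level='action'`` (default) counts the two first-interaction actions per
    dyad; ``level='dyad'`` counts the dyad as cooperative only if both first
    actions are C.  Dyads that never match are excluded.
    """
    if level not in ("action", "dyad"):
        raise ValueError(f"level must be 'action' or 'dyad', got {level!r}")
    grp = _group_slice(dataset, group_id)
    lo = grp.assign(
        _d1=np.minimum(grp["actor_a"], grp["actor_b"]),
        _d2=np.maximum(grp["actor_a"], grp["actor_b"]),
    )
    firsts = lo.loc[lo.groupby(["_d1", "_d2"])["period"].idxmin()]
    if level == "action":
        c = (firsts["action_a"] == "C").sum() + (firsts["action_b"] == "C").sum()
        return float(c) / (2 * len(firsts))
    both = ((firsts["action_a"] == "C") & (firsts["action_b"] == "C")).sum()
    return float(both) / len(firsts)


def summarize_groups(
    dataset: pd.DataFrame,
    main_window: tuple[int, int] = (1, 35),
    end_window: tuple[int, int] = (30, 35),
    first_level: str = "action",
) -> pd.DataFrame:
    """One row of :class:`GroupStats` per group, as a DataFrame."""
    rows = []
    for gid, grp in dataset.groupby("group_id", sort=True):
        rows.append(
            GroupStats(
                group_id=str(gid),
                experiment_id=str(grp["experiment_id"].iloc[0]),
                condition=str(grp["condition"].iloc[0]),
                coop_rate_main=group_cooperation_rate(dataset, gid, *main_window),
                coop_rate_first=first_interaction_cooperation(dataset, gid, first_level),
                coop_rate_endwindow=group_cooperation_rate(dataset, gid, *end_window),
            )
        )
    return pd.DataFrame([asdict(r) for r in rows])


# ---------------------------------------------------------------------------
# Mann-Whitney

def _exact_mw_pvalues(ranks2: np.ndarray, n_a: int, u_obs2: int) -> tuple[float, float]:
    """Exact tail probabilities of 2*U over all rank splits.

    ``ranks2`` are midranks doubled to integers (midranks are multiples of
    one half), ``u_obs2`` the doubled observed U of sample a.  Enumerates all
    C(N, n_a) equally likely assignments of ranks to sample a.
    """
    offset = n_a * (n_a + 1)  # 2 * n_a(n_a+1)/2
    ge = le = total = 0
    for combo in combinations(ranks2.tolist(), n_a):
        u2 = sum(combo) - offset
        ge += u2 >= u_obs2
        le += u2 <= u_obs2
        total += 1
    return ge / total, le / total


def mann_whitney(
    rates_a: Sequence[float],
    rates_b: Sequence[float],
    alternative: str = "two_sided",
    exact_max_n: int = 20,
) -> TestResult:
    """Mann-Whitney U test on two independent samples of group rates.

    Reports the U statistic of sample a.  For combined N <= ``exact_max_n``
    the p-value is the exact permutation probability over all C(N, n_a) rank
    assignments (midranks under ties); beyond that, the normal approximation
    with tie correction.  ``alternative='greater'`` means sample a tends to
    exceed sample b.
    """
    alt = _check_alternative(alternative)
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
    degenerate = np.unique(combined).size == 1

    if n_a + n_b <= exact_max_n:
        ranks2 = np.rint(2 * ranks).astype(int)
        u_obs2 = int(round(2 * u_a))
        p_ge, p_le = _exact_mw_pvalues(ranks2, n_a, u_obs2)
        if alt == "greater":
            p = p_ge
        elif alt == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        method = "exact"
    else:
        scipy_alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alt]
        res = stats.mannwhitneyu(a, b, alternative=scipy_alt, method="asymptotic")
        p = float(res.pvalue)
        method = "normal_approx"
    return TestResult(u_a, float(p), n_a, n_b, alt, f"mann_whitney_{method}", degenerate)


# ---------------------------------------------------------------------------
# Variance comparison

def variance_comparison(
    rates_a: Sequence[float],
    rates_b: Sequence[float],
    alternative: str = "greater",
    method: str = "f",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Compare the across-group variances of two arms.

    Statistic is the variance ratio F = s^2_a / s^2_b (unbiased sample
    variances).  ``alternative='greater'`` tests H1: var_a > var_b (the
    default, matching the directional embeddedness-variance claim).
    ``method='permutation'`` replaces the F reference distribution with a
    seeded label permutation, as a guard against non-normality.
    """
    alt = _check_alternative(alternative)
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two groups per arm to compare variances")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0.0 or (alt != "greater" and va == 0.0):
        raise ValueError("zero variance in a comparison arm; variance ratio undefined")
    f_obs = va / vb
    dfa, dfb = a.size - 1, b.size - 1

    if method == "f":
        if alt == "greater":
            p = stats.f.sf(f_obs, dfa, dfb)
        elif alt == "less":
            p = stats.f.cdf(f_obs, dfa, dfb)
        else:
            p = min(1.0, 2.0 * min(stats.f.sf(f_obs, dfa, dfb), stats.f.cdf(f_obs, dfa, dfb)))
        return TestResult(float(f_obs), float(p), a.size, b.size, alt, "variance_ratio_f")
    if method != "permutation":
        raise ValueError(f"method must be 'f' or 'permutation', got {method!r}")

    rng = np.random.default_rng(seed)
    combined = np.concatenate([a, b])
    ge = le = 0
    eps = 1e-12
    for _ in range(n_permutations):
        perm = rng.permutation(combined)
        va_p = perm[: a.size].var(ddof=1)
        vb_p = perm[a.size :].var(ddof=1)
        f_p = va_p / max(vb_p, eps)
        ge += f_p >= f_obs - eps
        le += f_p <= f_obs + eps
    p_ge = (1 + ge) / (1 + n_permutations)
    p_le = (1 + le) / (1 + n_permutations)
    if alt == "greater":
        p = p_ge
    elif alt == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(float(f_obs), float(p), a.size, b.size, alt, "variance_ratio_permutation")


# ---------------------------------------------------------------------------
# Power

def t_test_power(
    delta: float,
    sd: float,
    n_per_group: int,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> float:
    """Exact noncentral-t power of the two-sample t test.

    For a true mean difference ``delta`` (proportion units) and common
    per-group SD ``sd``, with ``n_per_group`` groups per arm, the t statistic
    is noncentral t with df = 2n - 2 and noncentrality delta/sd * sqrt(n/2).
    One-sided by default (the hypotheses are directional).
    """
    alt = _check_alternative(alternative)
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n_per_group < 2:
        raise ValueError("need at least two groups per arm")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    df = 2 * n_per_group - 2
    ncp = delta / sd * math.sqrt(n_per_group / 2.0)
    if alt == "two_sided":
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    tcrit = stats.t.ppf(1 - alpha, df)
    if alt == "less":
        ncp = -ncp
        return float(stats.nct.cdf(-tcrit, df, ncp))
    return float(stats.nct.sf(tcrit, df, ncp))


# ---------------------------------------------------------------------------
# Full suite

def _contrast_block(
    stats_df: pd.DataFrame, column: str, alternative: str
) -> dict:
    emb = stats_df.loc[stats_df["condition"] == "embedded", column].to_numpy()
    ato = stats_df.loc[stats_df["condition"] == "atomized", column].to_numpy()
    if emb.size == 0 or ato.size == 0:
        raise ValueError("both condition arms must be present in the dataset")
    test = mann_whitney(emb, ato, alternative=alternative)
    return {
        "mean_embedded": float(emb.mean()),
        "mean_atomized": float(ato.mean()),
        "test": test.to_dict(),
    }


def _end_window_block(
    stats_df: pd.DataFrame, variance_method: str, seed: int
) -> dict:
    emb = stats_df.loc[stats_df["condition"] == "embedded", "coop_rate_endwindow"].to_numpy()
    ato = stats_df.loc[stats_df["condition"] == "atomized", "coop_rate_endwindow"].to_numpy()
    block = {
        "mean_embedded": float(emb.mean()),
        "mean_atomized": float(ato.mean()),
        "sd_embedded": float(emb.std(ddof=1)) if emb.size > 1 else None,
        "sd_atomized": float(ato.std(ddof=1)) if ato.size > 1 else None,
    }
    try:
        vtest = variance_comparison(
            emb, ato, alternative="greater", method=variance_method, seed=seed
        )
        block["variance_test"] = vtest.to_dict()
    except ValueError as exc:
        block["variance_test"] = {"degenerate": True, "reason": str(exc)}
    return block


def run_hypothesis_suite(
    dataset: pd.DataFrame,
    alternative: str = "two_sided",
    main_window: tuple[int, int] = (1, 35),
    end_window: tuple[int, int] = (30, 35),
    first_level: str = "action",
    variance_method: str = "f",
    variance_seed: int = 0,
    validate: bool = True,
) -> dict:
    """The full reporting pipeline, per experiment and pooled.

    For each experiment in the dataset and for the pooled data: the H1
    contrast (main-window rates, embedded vs atomized), the H2 contrast
    (first-interaction rates), and the late-window means/SDs with the
    directional variance comparison.  P-values are reported raw (no
    multiple-testing correction).  The returned dict is JSON-serializable and
    deterministic for a given dataset.
    """
    if validate:
        validate_dataset(dataset)
    stats_df = summarize_groups(dataset, main_window, end_window, first_level)

    def block(sub: pd.DataFrame) -> dict:
        return {
            "n_groups": {
                "atomized": int((sub["condition"] == "atomized").sum()),
                "embedded": int((sub["condition"] == "embedded").sum()),
            },
            "h1_main_window": _contrast_block(sub, "coop_rate_main", alternative),
            "h2_first_interaction": _contrast_block(sub, "coop_rate_first", alternative),
            "end_window": _end_window_block(sub, variance_method, variance_seed),
        }

    experiments = {
        str(eid): block(sub)
        for eid, sub in stats_df.groupby("experiment_id", sort=True)
    }
    report = {
        "options": {
            "alternative": alternative,
            "main_window": list(main_window),
            "end_window": list(end_window),
            "first_interaction_level": first_level,
            "variance_method": variance_method,
            "note": (
                "Mann-Whitney tests are two-sided by default; the variance "
                "comparison and power analyses are one-sided because those "
                "hypotheses are directional."
            ),
        },
        "experiments": experiments,
        "pooled": block(stats_df),
        "groups": stats_df.to_dict(orient="records"),
    }
    return report
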