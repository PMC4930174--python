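"""Lab-shaped synthetic datasets for the two experiments.

The human-subject data behind the original experiments were never deposited,
so the analysis pipeline is exercised on synthetic datasets with exactly the
lab's structure: 6-person groups, 40 scored periods, each subject matched
with exactly 2 partners per period, groups split between the atomized and
embedded information conditions (7 + 7 groups in the Experiment-1 layout,
6 + 6 in the Experiment-2 layout).  Strategy compositions are *scenario
inputs*, not estimates of the lab population.

Datasets are flat tables, one row per dyad-period:

    experiment_id, group_id, condition, period,
    actor_a, actor_b, action_a, action_b, payoff_a, payoff_b

Actors are numbered 1..n as on the lab screens; actions are C/D (the lab
labels ORANGE/BLUE are normalized on read).  An optional endgame ramp adds
extra defection probability over the last five periods to mimic the endgame
effects human subjects show in finitely repeated games; it is off in all
theory-facing tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .game_core import Action, Condition, GroupConfig, PDPayoffs, dyad_payoff
from .simulator import StrategyKind, StrategySpec, run_group

__all__ = [
    "DATASET_COLUMNS",
    "ExperimentDesign",
    "experiment1_design",
    "experiment2_design",
    "generate_experiment",
    "records_to_rows",
    "write_dataset",
    "read_dataset",
    "validate_dataset",
    "DatasetValidationError",
]

DATASET_COLUMNS = [
    "experiment_id",
    "group_id",
    "condition",
    "period",
    "actor_a",
    "actor_b",
    "action_a",
    "action_b",
    "payoff_a",
    "payoff_b",
]

#: Default scenario mixture: a majority of conditional cooperators with a
#: small decision-error rate, some unconditional cooperators, and a minority
#: of unconditional defectors.  Chosen once as a plausible behavioral-lab
#: composition producing intermediate, declining cooperation; see the methods
#: note.  It is a scenario, not an estimate.
DEFAULT_MIXTURE: tuple[tuple[StrategySpec, float], ...] = (
    (StrategySpec(kind=StrategyKind.TRIGGER, tremble=0.05), 0.6),
    (StrategySpec(kind=StrategyKind.ALL_C, tremble=0.05), 0.2),
    (StrategySpec(kind=StrategyKind.ALL_D), 0.2),
)


class DatasetValidationError(ValueError):
    """A dataset violates the lab's structural invariants."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of one synthetic experiment.

    groups_per_condition groups are generated independently for each of the
    two conditions.  Each actor's strategy is an independent draw from
    ``strategy_mixture`` (pairs of StrategySpec and probability, summing
    to 1).  ``endgame_ramp_max`` is the extra defection probability reached
    in the final period; it ramps linearly from 0 over the last five periods.
    """

    experiment_id: str = "exp1"
    groups_per_condition: int = 7
    group_config: GroupConfig = field(default_factory=GroupConfig)
    payoffs: PDPayoffs = field(default_factory=PDPayoffs)
    strategy_mixture: tuple[tuple[StrategySpec, float], ...] = DEFAULT_MIXTURE
    endgame_ramp_max: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        weights = [w for _, w in self.strategy_mixture]
        if not weights or any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"mixture probabilities must be nonnegative and sum to 1, got {weights}")
        if not 0.0 <= self.endgame_ramp_max < 1.0:
            raise ValueError("endgame_ramp_max must lie in [0,1)")


def experiment1_design(**overrides) -> ExperimentDesign:
    """Experiment-1 layout: 7 atomized + 7 embedded 6-person groups."""
    return ExperimentDesign(experiment_id="exp1", groups_per_condition=7, **overrides)


def experiment2_design(**overrides) -> ExperimentDesign:
    """Experiment-2 layout: 6 atomized + 6 embedded 6-person groups."""
    return ExperimentDesign(experiment_id="exp2", groups_per_condition=6, **overrides)


def _ramp(periods: int, ramp_max: float) -> list[float] | None:
    if ramp_max <= 0.0:
        return None
    extra = [0.0] * periods
    window = min(5, periods)
    # linear ramp over the last `window` periods, 0 at the first of them
    for k in range(window):
        t = periods - window + k
        extra[t] = ramp_max * k / max(window - 1, 1)
    return extra


def records_to_rows(
    records: Sequence,
    experiment_id: str,
    group_id: str,
    condition: Condition | str,
    cols: dict[str, list] | None = None,
) -> dict[str, list]:
    """Append simulator records to columnar dataset storage (1-based actors)."""
    condition = Condition.parse(condition)
    if cols is None:
        cols = {c: [] for c in DATASET_COLUMNS}
    for rec in records:
        cols["experiment_id"].append(experiment_id)
        cols["group_id"].append(group_id)
        cols["condition"].append(condition.value)
        cols["period"].append(rec.period)
        cols["actor_a"].append(rec.actor_a + 1)
        cols["actor_b"].append(rec.actor_b + 1)
        cols["action_a"].append(rec.action_a.value)
        cols["action_b"].append(rec.action_b.value)
        cols["payoff_a"].append(rec.payoff_a)
        cols["payoff_b"].append(rec.payoff_b)
    return cols


def generate_experiment(design: ExperimentDesign) -> pd.DataFrame:
    """Run one independent simulated group per design slot and tabulate.

    Per-group seeds derive from ``design.seed`` with a splittable spawn-key
    scheme indexed by (condition, group), so adding groups never perturbs
    existing ones.  Returns a DataFrame with :data:`DATASET_COLUMNS`; actors
    are 1-based.
    """
    cols: dict[str, list] = {c: [] for c in DATASET_COLUMNS}
    specs, weights = zip(*design.strategy_mixture)
    weights = np.asarray(weights, dtype=float)

    for ci, condition in enumerate((Condition.ATOMIZED, Condition.EMBEDDED)):
        cfg = replace(design.group_config, condition=condition)
        for g in range(design.groups_per_condition):
            gid = f"{design.experiment_id}-{condition.value[:3]}-{g + 1:02d}"
            ss = np.random.SeedSequence(entropy=design.seed, spawn_key=(ci, g))
            rng = np.random.default_rng(ss)
            idx = rng.choice(len(specs), size=cfg.n, p=weights)
            strategies = [specs[i] for i in idx]
            records = run_group(
                cfg,
                design.payoffs,
                strategies,
                rng,
                extra_defect_prob=_ramp(cfg.periods, design.endgame_ramp_max),
            )
            records_to_rows(records, design.experiment_id, gid, condition, cols)
    return pd.DataFrame(cols)


def write_dataset(dataset: pd.DataFrame, path: str | Path) -> None:
    """Write a dataset as UTF-8 CSV with the canonical header."""
    missing = [c for c in DATASET_COLUMNS if c not in dataset.columns]
    if missing:
        raise DatasetValidationError(f"dataset missing columns {missing}")
    dataset.loc[:, DATASET_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_dataset(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read a dataset CSV, normalize action aliases, and validate structure."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"file {path} missing columns {missing}")
    df = df.loc[:, DATASET_COLUMNS].copy()
    for col in ("action_a", "action_b"):
        try:
            df[col] = [Action.parse(v).value for v in df[col]]
        except ValueError as exc:
            raise DatasetValidationError(f"column {col}: {exc}") from None
    for col in ("period", "actor_a", "actor_b"):
        df[col] = df[col].astype(int)
    if validate:
        validate_dataset(df)
    return df


def validate_dataset(dataset: pd.DataFrame) -> None:
    """Check the lab's structural invariants, with row-level diagnostics.

    Per group: condition constant and valid; periods complete 1..max; every
    actor appears in the same number of dyads (the group's degree m) in every
    period; no self-pairs or duplicate dyads within a period.
    """
    if dataset.empty:
        raise DatasetValidationError("dataset is empty")
    for gid, grp in dataset.groupby("group_id", sort=False):
        conds = grp["condition"].unique()
        if len(conds) != 1:
            raise DatasetValidationError(f"group {gid}: mixed conditions {sorted(conds)}")
        Condition.parse(conds[0])
        periods = np.sort(grp["period"].unique())
        expected = np.arange(1, periods.max() + 1)
        if len(periods) != len(expected) or not np.array_equal(periods, expected):
            missing = sorted(set(expected) - set(periods))
            raise DatasetValidationError(f"group {gid}: incomplete periods, missing {missing}")
        actors = sorted(set(grp["actor_a"]) | set(grp["actor_b"]))
        rows_per_period = grp.groupby("period").size()
        if rows_per_period.nunique() != 1:
            raise DatasetValidationError(f"group {gid}: unequal dyad counts across periods")
        m = 2 * int(rows_per_period.iloc[0]) // len(actors)
        for period, sub in grp.groupby("period"):
            pairs = list(zip(sub["actor_a"], sub["actor_b"]))
            canon = [(min(a, b), max(a, b)) for a, b in pairs]
            if any(a == b for a, b in canon):
                raise DatasetValidationError(f"group {gid}, period {period}: self-paired actor")
            if len(set(canon)) != len(canon):
                raise DatasetValidationError(f"group {gid}, period {period}: duplicate dyad")
            deg: dict[int, int] = {}
            for a, b in canon:
                deg[a] = deg.get(a, 0) + 1
                deg[b] = deg.get(b, 0) + 1
            for actor in actors:
                d = deg.get(actor, 0)
                if d != m:
                    raise DatasetValidationError(
                        f"group {gid}, period {period}: actor {actor} appears in "
                        f"{d} dyads, expected {m}"
                    )


def recompute_payoffs(dataset: pd.DataFrame, payoffs: PDPayoffs) -> pd.DataFrame:
    """Return a copy with dyad payoffs recomputed from the actions.

    Useful when hand-building fixtures; the stored payoffs are the dyad
    payoffs only (the per-period (n-1-m)*Q baseline is constant and omitted
    from the table).
    """
    out = dataset.copy()
    pa, pb = [], []
    for a, b in zip(out["action_a"], out["action_b"]):
        x, y = dyad_payoff(a, b, payoffs)
        pa.append(x)
        pb.append(y)
    out["payoff_a"] = pa
    out["payoff_b"] = pb
    return out
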