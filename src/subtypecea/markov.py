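"""Health states, treatment arms, strategy trees and the yearly Markov engine.

The cohort model has three health states — alive after radical cystectomy
(RC), dead of bladder cancer, dead of other causes — with both death states
absorbing. A cohort enters at cycle 0 (the treatment year: RC with or
without perioperative chemotherapy) fully alive, then transitions once per
model year according to an arm-specific schedule of cause-specific yearly
death probabilities. A treatment *strategy* is a decision tree collapsed to
its terminal arms: a probability mixture over (arm, subtype, prognosis)
branches.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    ScheduleLengthError,
    SchemaError,
    ValidationError,
)
from .params import ParameterSet

_SUM_TOL = 1e-9


class HealthState(Enum):
    """The model's three health states; the two death states are absorbing."""

    ALIVE_POST_RC = 0
    DEAD_BLADDER_CANCER = 1
    DEAD_OTHER_CAUSE = 2


class ArmLabel(str, Enum):
    NAC_RC = "NAC_RC"
    RC_ONLY = "RC_ONLY"
    RC_AC = "RC_AC"


class Strategy(str, Enum):
    CURRENT_PRACTICE = "CURRENT_PRACTICE"
    SUBTYPE_BASED = "SUBTYPE_BASED"


class Subtype(str, Enum):
    URO_GU = "URO_GU"
    BA_SQ = "BA_SQ"
    UNKNOWN = "UNKNOWN"


class Prognosis(str, Enum):
    GOOD = "GOOD"
    POOR = "POOR"


# Schedule keys are strategy-scoped where needed: the NAC+RC arm carries a
# population-wide survival schedule under current practice but a Uro/GU-
# specific one under subtype-based triage; upfront-RC schedules are shared.
SCHEDULE_NAC_RC_CURRENT = "nac_rc_current"
SCHEDULE_NAC_RC_URO_GU = "nac_rc_uro_gu"
SCHEDULE_RC_ONLY = "rc_only"
SCHEDULE_RC_AC = "rc_ac"

SCHEDULE_KEYS = (
    SCHEDULE_NAC_RC_CURRENT,
    SCHEDULE_NAC_RC_URO_GU,
    SCHEDULE_RC_ONLY,
    SCHEDULE_RC_AC,
)

_SCHEDULE_CSV_HEADER = ["arm", "year", "p_death_bc", "p_death_other"]


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-arm yearly cause-specific death probabilities, year 1-based.

    ``p_death_bc[t-1]`` / ``p_death_other[t-1]`` are the probabilities that
    a patient alive at the start of model year ``t`` dies of bladder cancer
    / another cause during that year. Entries may be NaN only when the
    schedule was estimated from data with an empty risk set in that year
    (``allow_missing=True``); such a schedule cannot drive the Markov
    engine until the missing years are supplied or pooled.
    """

    arm_label: str
    p_death_bc: tuple[float, ...]
    p_death_other: tuple[float, ...]
    allow_missing: bool = False

    def __post_init__(self) -> None:
        bc = np.asarray(self.p_death_bc, dtype=float)
        oth = np.asarray(self.p_death_other, dtype=float)
        object.__setattr__(self, "p_death_bc", tuple(bc.tolist()))
        object.__setattr__(self, "p_death_other", tuple(oth.tolist()))
        if bc.shape != oth.shape or bc.ndim != 1 or bc.size == 0:
            raise ValidationError(
                f"schedule {self.arm_label!r}: cause-specific sequences must be "
                "1-D, non-empty and equal-length"
            )
        missing = np.isnan(bc) | np.isnan(oth)
        if missing.any() and not self.allow_missing:
            raise ValidationError(
                f"schedule {self.arm_label!r}: NaN probabilities in years "
                f"{(np.flatnonzero(missing) + 1).tolist()}"
            )
        ok = ~missing
        if (bc[ok] < 0).any() or (oth[ok] < 0).any():
            raise ValidationError(
                f"schedule {self.arm_label!r}: negative probabilities"
            )
        if (bc[ok] + oth[ok] > 1.0 + 1e-12).any():
            bad = np.flatnonzero(ok)[(bc[ok] + oth[ok]) > 1.0 + 1e-12] + 1
            raise ValidationError(
                f"schedule {self.arm_label!r}: p_death_bc + p_death_other > 1 "
                f"in years {bad.tolist()}"
            )

    @property
    def years(self) -> int:
        return len(self.p_death_bc)

    @property
    def missing_years(self) -> tuple[int, ...]:
        bc = np.asarray(self.p_death_bc)
        oth = np.asarray(self.p_death_other)
        return tuple((np.flatnonzero(np.isnan(bc) | np.isnan(oth)) + 1).tolist())

    def require(self, horizon: int) -> None:
        """Raise unless this schedule can drive ``horizon`` model years."""
        if self.years < horizon:
            raise ScheduleLengthError(
                f"schedule {self.arm_label!r} covers {self.years} years but "
                f"horizon {horizon} requested; schedules are not extrapolated"
            )
        missing = [y for y in self.missing_years if y <= horizon]
        if missing:
            raise ValidationError(
                f"schedule {self.arm_label!r}: missing estimates for years "
                f"{missing} within horizon {horizon}"
            )


def schedules_to_csv(
    schedules: Mapping[str, TransitionSchedule],
    path: str | Path | io.TextIOBase,
) -> None:
    rows = [
        (key, t + 1, s.p_death_bc[t], s.p_death_other[t])
        for key, s in schedules.items()
        for t in range(s.years)
    ]
    pd.DataFrame(rows, columns=_SCHEDULE_CSV_HEADER).to_csv(path, index=False)


def schedules_from_csv(
    path: str | Path | io.TextIOBase,
) -> dict[str, TransitionSchedule]:
    """Read per-arm schedules from CSV with columns (arm, year, p_death_bc,
    p_death_other); years must be contiguous from 1 within each arm."""
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != _SCHEDULE_CSV_HEADER:
        raise SchemaError(
            f"schedule CSV header must be {_SCHEDULE_CSV_HEADER}, "
            f"got {list(df.columns)}"
        )
    out: dict[str, TransitionSchedule] = {}
    for arm, g in df.groupby("arm", sort=False):
        g = g.sort_values("year")
        years = g["year"].to_numpy()
        if not np.array_equal(years, np.arange(1, len(years) + 1)):
            raise SchemaError(
                f"schedule CSV: arm {arm!r} years must run 1..{len(years)} "
                f"without gaps, got {years.tolist()}"
            )
        out[str(arm)] = TransitionSchedule(
            str(arm),
            tuple(g["p_death_bc"].astype(float)),
            tuple(g["p_death_other"].astype(float)),
        )
    return out


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state-occupancy fractions; row 0 is the treatment year."""

    occupancy: np.ndarray  # shape (cycles, 3), rows sum to 1

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if occ.ndim != 2 or occ.shape[1] != len(HealthState) or occ.shape[0] < 1:
            raise ValidationError("trace must be (cycles, 3) with >= 1 row")
        if (occ < -1e-12).any():
            raise ValidationError("negative occupancy")
        if np.abs(occ.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValidationError("trace rows must sum to 1")

    @property
    def n_cycles(self) -> int:
        """Number of rows (horizon + 1)."""
        return self.occupancy.shape[0]

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:, HealthState.ALIVE_POST_RC.value]

    @property
    def dead_bc(self) -> np.ndarray:
        return self.occupancy[:, HealthState.DEAD_BLADDER_CANCER.value]

    @property
    def dead_other(self) -> np.ndarray:
        return self.occupancy[:, HealthState.DEAD_OTHER_CAUSE.value]


def run_cohort(schedule: TransitionSchedule, horizon: int) -> CohortTrace:
    """Run the yearly-cycle cohort recursion for ``horizon`` model years.

    Returns a trace with ``horizon + 1`` rows: cycle 0 (everyone alive,
    the treatment year) plus one row after each yearly transition. At each
    step the alive mass is multiplied by ``1 - p_bc - p_other`` and the
    absorbing death states are incremented accordingly.
    """
    if horizon < 1:
        raise ValidationError(f"horizon must be >= 1, got {horizon}")
    schedule.require(horizon)
    p_bc = np.asarray(schedule.p_death_bc[:horizon])
    p_oth = np.asarray(schedule.p_death_other[:horizon])
    # Alive fraction is a running product of yearly survival probabilities;
    # cumulative deaths follow from alive-at-entry mass times each hazard.
    surv = np.concatenate([[1.0], np.cumprod(1.0 - p_bc - p_oth)])
    alive_at_entry = surv[:-1]
    occ = np.empty((horizon + 1, 3))
    occ[:, 0] = surv
    occ[:, 1] = np.concatenate([[0.0], np.cumsum(alive_at_entry * p_bc)])
    occ[:, 2] = np.concatenate([[0.0], np.cumsum(alive_at_entry * p_oth)])
    return CohortTrace(occ)


def trace_to_csv(
    traces: Mapping[str, CohortTrace], path: str | Path | io.TextIOBase
) -> None:
    """Write one or more traces as (strategy, cycle, alive, dead_bc, dead_other)."""
    rows = [
        (name, c, tr.alive[c], tr.dead_bc[c], tr.dead_other[c])
        for name, tr in traces.items()
        for c in range(tr.n_cycles)
    ]
    pd.DataFrame(
        rows, columns=["strategy", "cycle", "alive", "dead_bc", "dead_other"]
    ).to_csv(path, index=False)


def mix_branches(branch_values: Sequence[tuple[float, float]]) -> float:
    """Probability-weighted mean over decision-tree terminal branches."""
    if len(branch_values) == 0:
        raise ValidationError("mix_branches: empty branch list")
    probs = np.array([p for p, _ in branch_values], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValidationError(
            f"mix_branches: branch probabilities sum to {probs.sum():.8f}, not 1"
        )
    values = np.array([v for _, v in branch_values], dtype=float)
    return float(probs @ values)


@dataclass(frozen=True)
class TreatmentArm:
    """A terminal treatment arm: its one-off costs, chemo toll and schedule."""

    label: ArmLabel
    one_off_costs: tuple[tuple[str, float], ...]
    chemo_disutility: float  # QALY-weight decrement magnitude, >= 0
    toll_duration: float  # fraction of a year in (0, 1]; 0 only when no toll
    schedule_key: str

    def __post_init__(self) -> None:
        if any(amount < 0 for _, amount in self.one_off_costs):
            raise ValidationError(f"arm {self.label}: negative one-off cost")
        if self.chemo_disutility < 0:
            raise ValidationError(f"arm {self.label}: negative disutility magnitude")
        if self.chemo_disutility > 0 and not (0.0 < self.toll_duration <= 1.0):
            raise ValidationError(
                f"arm {self.label}: toll duration must be in (0, 1]"
            )

    @property
    def toll(self) -> float:
        """One-time cycle-0 QALY decrement: disutility x toll duration."""
        return self.chemo_disutility * self.toll_duration


class Branch(NamedTuple):
    probability: float
    arm: TreatmentArm
    subtype: Subtype
    prognosis: Optional[Prognosis]


@dataclass(frozen=True)
class StrategySpec:
    """A named mixture of treatment arms (the collapsed decision tree)."""

    name: Strategy
    branches: tuple[Branch, ...]
    subtype_test_cost: float = 0.0

    def __post_init__(self) -> None:
        total = sum(b.probability for b in self.branches)
        if abs(total - 1.0) > _SUM_TOL:
            raise ValidationError(
                f"strategy {self.name}: branch probabilities sum to {total}"
            )


def _make_arm(label: ArmLabel, params: ParameterSet, schedule_key: str) -> TreatmentArm:
    cost_rc = ("cost_rc", params.value("cost_rc"))
    if label is ArmLabel.NAC_RC:
        return TreatmentArm(
            label,
            (("cost_nac", params.value("cost_nac")), cost_rc),
            params.value("disutility_chemo"),
            params.value("toll_duration_nac"),
            schedule_key,
        )
    if label is ArmLabel.RC_AC:
        return TreatmentArm(
            label,
            (cost_rc, ("cost_ac", params.value("cost_ac"))),
            params.value("disutility_chemo"),
            params.value("toll_duration_ac"),
            schedule_key,
        )
    return TreatmentArm(label, (cost_rc,), 0.0, 0.0, schedule_key)


def build_strategy(params: ParameterSet, which: Strategy | str) -> StrategySpec:
    """Collapse one strategy's decision tree to its terminal-arm mixture.

    CURRENT_PRACTICE: NAC+RC for a fraction of patients, the rest upfront
    RC with the poor-prognosis minority continuing to adjuvant chemo.
    SUBTYPE_BASED: Uro/GU tumours get NAC+RC; Ba/Sq tumours get upfront RC
    with the (much larger) poor-prognosis fraction continuing to AC, and
    every patient is charged the subtype identification cost.

    Branch probabilities are renormalized proportionally: the printed
    subtype prevalences and prognosis splits sum to 0.999 due to rounding.
    """
    which = Strategy(which)

    def prop(name: str) -> float:
        try:
            v = params.value(name)
        except KeyError:
            raise ConfigurationError(
                f"build_strategy({which.value}): missing parameter {name!r}"
            ) from None
        if not (0.0 <= v <= 1.0):
            raise ValidationError(
                f"build_strategy({which.value}): {name}={v} outside [0, 1]"
            )
        return v

    if which is Strategy.CURRENT_PRACTICE:
        p_rc = prop("p_rc_only_current")
        raw = [
            Branch(
                prop("p_nac_rc_current"),
                _make_arm(ArmLabel.NAC_RC, params, SCHEDULE_NAC_RC_CURRENT),
                Subtype.UNKNOWN,
                None,
            ),
            Branch(
                p_rc * prop("p_good_current"),
                _make_arm(ArmLabel.RC_ONLY, params, SCHEDULE_RC_ONLY),
                Subtype.UNKNOWN,
                Prognosis.GOOD,
            ),
            Branch(
                p_rc * prop("p_poor_current"),
                _make_arm(ArmLabel.RC_AC, params, SCHEDULE_RC_AC),
                Subtype.UNKNOWN,
                Prognosis.POOR,
            ),
        ]
        test_cost = 0.0
    else:
        p_basq = prop("p_basq")
        raw = [
            Branch(
                prop("p_uro_gu"),
                _make_arm(ArmLabel.NAC_RC, params, SCHEDULE_NAC_RC_URO_GU),
                Subtype.URO_GU,
                None,
            ),
            Branch(
                p_basq * prop("p_good_basq"),
                _make_arm(ArmLabel.RC_ONLY, params, SCHEDULE_RC_ONLY),
                Subtype.BA_SQ,
                Prognosis.GOOD,
            ),
            Branch(
                p_basq * prop("p_poor_basq"),
                _make_arm(ArmLabel.RC_AC, params, SCHEDULE_RC_AC),
                Subtype.BA_SQ,
                Prognosis.POOR,
            ),
        ]
        test_cost = params.value("cost_subtype_id")

    total = sum(b.probability for b in raw)
    if total <= 0:
        raise ValidationError(
            f"build_strategy({which.value}): branch probabilities sum to {total}"
        )
    branches = tuple(b._replace(probability=b.probability / total) for b in raw)
    return StrategySpec(which, branches, subtype_test_cost=test_cost)
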