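"""Synthetic registry cohorts and discrete-time transition estimation.

The real analysis drew yearly cause-specific death probabilities from a
national registry-linked database that cannot be redistributed. This
module closes that loop synthetically: it simulates a cisplatin-eligible
post-cystectomy cohort — strategy/branch mixtures from the parameter
table, yearly competing-risks death times from per-arm hazard schedules,
administrative censoring at a fixed horizon — and re-estimates the yearly
transition probabilities from the simulated patient records with a
cause-specific life-table estimator (deaths over risk set per year,
censoring at year-end).

The default generating hazards are synthetic: plausibility-shaped for
muscle-invasive bladder cancer after radical cystectomy (bladder-cancer
hazard peaking in years 1-2 then declining; other-cause hazard slowly
rising; roughly a 5-point absolute 5-year survival benefit for NAC), not
values from any registry.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import EstimationError, SchemaError, ValidationError
from .markov import (
    ArmLabel,
    Branch,
    Prognosis,
    SCHEDULE_KEYS,
    SCHEDULE_NAC_RC_CURRENT,
    SCHEDULE_NAC_RC_URO_GU,
    SCHEDULE_RC_AC,
    SCHEDULE_RC_ONLY,
    Strategy,
    Subtype,
    TransitionSchedule,
    build_strategy,
)
from .params import ParameterSet

CAUSE_BLADDER_CANCER = "BLADDER_CANCER"
CAUSE_OTHER = "OTHER"
CAUSE_CENSORED = "CENSORED"
CAUSES = (CAUSE_BLADDER_CANCER, CAUSE_OTHER, CAUSE_CENSORED)

_REGISTRY_COLUMNS = [
    "id", "strategy", "arm", "subtype", "prognosis", "event_year", "cause",
]

# Other-cause mortality shared across arms (ages <= 76 at surgery, slowly
# rising with follow-up year).
_P_OTHER = (0.020, 0.020, 0.025, 0.030, 0.030, 0.035, 0.040, 0.045, 0.050, 0.055)

#: Synthetic per-arm yearly bladder-cancer death probabilities, years 1-10.
_P_BC = {
    SCHEDULE_RC_ONLY: (0.100, 0.120, 0.090, 0.060, 0.040,
                       0.030, 0.025, 0.020, 0.020, 0.015),
    SCHEDULE_NAC_RC_CURRENT: (0.085, 0.100, 0.075, 0.050, 0.035,
                              0.027, 0.022, 0.018, 0.018, 0.013),
    SCHEDULE_NAC_RC_URO_GU: (0.070, 0.085, 0.065, 0.045, 0.030,
                             0.024, 0.020, 0.016, 0.016, 0.012),
    SCHEDULE_RC_AC: (0.180, 0.160, 0.110, 0.070, 0.050,
                     0.038, 0.030, 0.025, 0.025, 0.020),
}


def default_schedules(horizon: int = 10) -> dict[str, TransitionSchedule]:
    """Synthetic default transition schedules for the four arm/population
    combinations, covering up to 10 model years."""
    if not (1 <= horizon <= len(_P_OTHER)):
        raise ValidationError(f"default schedules cover 1..{len(_P_OTHER)} years")
    return {
        key: TransitionSchedule(key, _P_BC[key][:horizon], _P_OTHER[:horizon])
        for key in SCHEDULE_KEYS
    }


@dataclass(frozen=True)
class SyntheticPatient:
    """One simulated registry record."""

    id: int
    strategy: Strategy
    arm: ArmLabel
    subtype: Subtype
    prognosis: Prognosis
    event_year: int  # year of death, or censoring year (= horizon)
    cause: str  # CAUSE_BLADDER_CANCER | CAUSE_OTHER | CAUSE_CENSORED

    def __post_init__(self) -> None:
        if self.event_year < 1:
            raise ValidationError("event_year must be >= 1")
        if self.cause not in CAUSES:
            raise ValidationError(f"cause {self.cause!r} not in {CAUSES}")


@dataclass(frozen=True)
class TrueGeneratingModel:
    """Ground truth for cohort simulation: hazards, mixtures, censoring.

    ``n`` patients are generated per strategy; every patient is assigned a
    terminal branch of their strategy's decision tree by the mixture
    proportions, then a yearly death time by sequential Bernoulli draws
    from the branch arm's cause-specific hazards, censored administratively
    at ``horizon`` years. No patient ever receives both neoadjuvant and
    adjuvant chemotherapy (the arms are mutually exclusive by design).
    """

    schedules: Mapping[str, TransitionSchedule]
    params: ParameterSet
    n: int
    horizon: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError(f"cohort size must be > 0, got {self.n}")
        if self.horizon < 1:
            raise ValidationError("censoring horizon must be >= 1")
        for key in SCHEDULE_KEYS:
            if key not in self.schedules:
                raise ValidationError(f"generating model lacks schedule {key!r}")
            self.schedules[key].require(self.horizon)

    @classmethod
    def default(
        cls, n: int = 10_000, horizon: int = 10, seed: int = 0
    ) -> "TrueGeneratingModel":
        return cls(
            schedules=default_schedules(horizon),
            params=ParameterSet.default(),
            n=n,
            horizon=horizon,
            seed=seed,
        )


def schedule_key_for(strategy: Strategy | str, arm: ArmLabel | str) -> str:
    """Estimation/simulation grouping: upfront-RC schedules are shared
    across strategies; the NAC+RC schedule is strategy-scoped."""
    strategy = Strategy(strategy)
    arm = ArmLabel(arm)
    if arm is ArmLabel.RC_ONLY:
        return SCHEDULE_RC_ONLY
    if arm is ArmLabel.RC_AC:
        return SCHEDULE_RC_AC
    return (
        SCHEDULE_NAC_RC_URO_GU
        if strategy is Strategy.SUBTYPE_BASED
        else SCHEDULE_NAC_RC_CURRENT
    )


def _simulate_events(
    schedule: TransitionSchedule, m: int, horizon: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized competing-risks event times for m patients.

    Returns (event_year, cause_code) with cause_code 0=bc, 1=other,
    2=censored; censored records carry event_year == horizon.
    """
    year = np.full(m, horizon, dtype=int)
    cause = np.full(m, 2, dtype=int)
    at_risk = np.ones(m, dtype=bool)
    for t in range(1, horizon + 1):
        p_bc = schedule.p_death_bc[t - 1]
        p_oth = schedule.p_death_other[t - 1]
        u = rng.random(m)
        dies_bc = at_risk & (u < p_bc)
        dies_oth = at_risk & ~dies_bc & (u < p_bc + p_oth)
        year[dies_bc | dies_oth] = t
        cause[dies_bc] = 0
        cause[dies_oth] = 1
        at_risk &= ~(dies_bc | dies_oth)
    return year, cause


def generate_cohort(model: TrueGeneratingModel) -> list[SyntheticPatient]:
    """Simulate ``model.n`` patients per strategy; reproducible from seed."""
    rng = np.random.default_rng(model.seed)
    patients: list[SyntheticPatient] = []
    pid = 0
    p_poor = model.params.value("p_poor_current")
    cause_names = (CAUSE_BLADDER_CANCER, CAUSE_OTHER, CAUSE_CENSORED)
    for strategy in (Strategy.CURRENT_PRACTICE, Strategy.SUBTYPE_BASED):
        spec = build_strategy(model.params, strategy)
        probs = np.array([b.probability for b in spec.branches])
        assignment = rng.choice(len(spec.branches), size=model.n, p=probs)
        for b_idx, branch in enumerate(spec.branches):
            idx = np.flatnonzero(assignment == b_idx)
            m = idx.size
            if m == 0:
                continue
            sched = model.schedules[branch.arm.schedule_key]
            year, cause = _simulate_events(sched, m, model.horizon, rng)
            if branch.prognosis is None:
                # NAC+RC patients: the tree never branches on their
                # pathology, so the label is drawn from the overall split.
                poor = rng.random(m) < p_poor
            else:
                poor = np.full(m, branch.prognosis is Prognosis.POOR)
            for j in range(m):
                patients.append(
                    SyntheticPatient(
                        id=pid + int(idx[j]),
                        strategy=strategy,
                        arm=branch.arm.label,
                        subtype=branch.subtype,
                        prognosis=Prognosis.POOR if poor[j] else Prognosis.GOOD,
                        event_year=int(year[j]),
                        cause=cause_names[cause[j]],
                    )
                )
        pid += model.n
    patients.sort(key=lambda p: p.id)
    return patients


def cohort_to_frame(cohort: Sequence[SyntheticPatient]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                p.id, p.strategy.value, p.arm.value, p.subtype.value,
                p.prognosis.value, p.event_year, p.cause,
            )
            for p in cohort
        ],
        columns=_REGISTRY_COLUMNS,
    )


def cohort_to_csv(
    cohort: Sequence[SyntheticPatient], path: str | Path | io.TextIOBase
) -> None:
    """Write a registry-style CSV with the strict 7-column schema."""
    cohort_to_frame(cohort).to_csv(path, index=False)


def csv_to_cohort(path: str | Path | io.TextIOBase) -> list[SyntheticPatient]:
    """Parse a registry CSV back into patients; schema violations report
    the offending row number (1-based, excluding the header)."""
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != _REGISTRY_COLUMNS:
        raise SchemaError(
            f"registry CSV header must be {_REGISTRY_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    cohort = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            cohort.append(
                SyntheticPatient(
                    id=int(row.id),
                    strategy=Strategy(row.strategy),
                    arm=ArmLabel(row.arm),
                    subtype=Subtype(row.subtype),
                    prognosis=Prognosis(row.prognosis),
                    event_year=int(row.event_year),
                    cause=str(row.cause),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise SchemaError(f"registry CSV row {i}: {exc}") from exc
    return cohort


def estimate_transitions(
    cohort: Sequence[SyntheticPatient],
    horizon: int,
    allow_missing: bool = False,
) -> dict[str, TransitionSchedule]:
    """Cause-specific life-table estimates of yearly death probabilities.

    For each schedule group and model year ``t``, the estimate is deaths of
    each cause during year ``t`` divided by patients at risk entering year
    ``t``; patients censored during year ``t`` remain in that year's risk
    set (censoring at year-end). A year with an empty risk set has no
    estimate: with ``allow_missing`` it is returned as NaN (flagged on the
    schedule), otherwise an :class:`EstimationError` is raised.
    """
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    if len(cohort) == 0:
        raise EstimationError("cannot estimate transitions from an empty cohort")
    df = cohort_to_frame(cohort)
    df["key"] = [
        schedule_key_for(s, a) for s, a in zip(df["strategy"], df["arm"])
    ]
    out: dict[str, TransitionSchedule] = {}
    empty: list[tuple[str, int]] = []
    for key, g in df.groupby("key", sort=True):
        event_year = g["event_year"].to_numpy()
        cause = g["cause"].to_numpy()
        p_bc = np.empty(horizon)
        p_oth = np.empty(horizon)
        for t in range(1, horizon + 1):
            at_risk = int((event_year >= t).sum())
            if at_risk == 0:
                p_bc[t - 1] = np.nan
                p_oth[t - 1] = np.nan
                empty.append((str(key), t))
                continue
            d_bc = int(((cause == CAUSE_BLADDER_CANCER) & (event_year == t)).sum())
            d_oth = int(((cause == CAUSE_OTHER) & (event_year == t)).sum())
            p_bc[t - 1] = d_bc / at_risk
            p_oth[t - 1] = d_oth / at_risk
        out[str(key)] = TransitionSchedule(
            str(key), tuple(p_bc), tuple(p_oth), allow_missing=True
        )
    if empty and not allow_missing:
        raise EstimationError(
            "empty risk set (no estimate possible) for "
            + ", ".join(f"{k} year {t}" for k, t in empty)
            + "; supply or pool these years, or pass allow_missing=True"
        )
    return out
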