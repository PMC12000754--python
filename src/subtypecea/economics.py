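"""Discounted cost and QALY accrual along a cohort trace, and incremental
cost-effectiveness measures (ICER, NMB, dominance classification).

Accounting conventions
----------------------
* Cycle 0 is the treatment year: one-off costs (surgery, chemotherapy
  courses, subtype identification) accrue undiscounted, and the alive
  cohort accrues the cystectomy utility minus a one-time chemotherapy
  disutility toll (disutility magnitude x toll duration in years).
* Every later cycle ``t >= 1`` the alive fraction accrues the yearly
  surveillance cost and the surveillance utility, discounted by
  ``1 / (1 + rate)^t``. Death states accrue nothing.
* QALYs are the discrete area under the utility-weighted survival curve.
* An optional half-cycle correction replaces the end-of-cycle alive
  fraction in the recurring accruals with the mean of the cycle's start
  and end occupancy (off by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .exceptions import ValidationError
from .markov import CohortTrace, StrategySpec, TreatmentArm, mix_branches, run_cohort
from .markov import TransitionSchedule
from .params import ParameterSet

logger = logging.getLogger(__name__)

#: Dominance / degeneracy flags attached to a comparison.
DOMINANT = "dominant"
DOMINATED = "dominated"
COST_SAVING_LESS_EFFECTIVE = "cost_saving_less_effective"
ICER_UNDEFINED = "undefined"


@dataclass(frozen=True)
class EconomicOutcome:
    """Discounted totals for one strategy at one horizon."""

    strategy: str
    total_cost: float
    total_qaly: float
    horizon: int

    def __post_init__(self) -> None:
        if self.total_cost < 0:
            raise ValidationError("total_cost must be >= 0")


@dataclass(frozen=True)
class CEResult:
    """Incremental outcomes of intervention vs comparator at one horizon.

    ``icer`` is None whenever a dominance flag applies or the QALY
    difference is zero; ``nmb_delta = wtp * delta_qaly - delta_cost`` is
    always defined and positive iff the intervention is cost-effective at
    the stated willingness-to-pay.
    """

    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    flag: Optional[str]
    wtp: float
    nmb_delta: float
    horizon: int


def discount_factor(year: int, rate: float) -> float:
    """Present-value multiplier ``1 / (1 + rate)^year``; year 0 -> 1."""
    if year < 0:
        raise ValidationError(f"year must be >= 0, got {year}")
    if rate < 0:
        raise ValidationError(f"discount rate must be >= 0, got {rate}")
    return 1.0 / (1.0 + rate) ** year


def _recurring_alive_pv(
    trace: CohortTrace, rate: float, half_cycle_correction: bool
) -> float:
    """Present value of one EUR (or one utility unit) accrued per alive
    person-year in cycles 1..H."""
    alive = trace.alive
    occ = alive[1:]
    if half_cycle_correction:
        occ = 0.5 * (alive[:-1] + alive[1:])
    t = np.arange(1, trace.n_cycles)
    return float(occ @ (1.0 + rate) ** (-t.astype(float)))


def accrue_costs(
    trace: CohortTrace,
    arm: TreatmentArm,
    params: ParameterSet,
    strategy_level_costs: float = 0.0,
    half_cycle_correction: bool = False,
) -> float:
    """Discounted total cost per patient entering this arm.

    One-off costs (and any strategy-level cost such as the subtype test)
    hit at cycle 0 undiscounted; surveillance accrues per alive cycle.
    """
    if strategy_level_costs < 0:
        raise ValidationError("strategy-level cost must be >= 0")
    c_surv = params.value("cost_surveillance")
    if c_surv < 0:
        raise ValidationError("cost_surveillance must be >= 0")
    one_off = sum(amount for _, amount in arm.one_off_costs) + strategy_level_costs
    rate = params.value("discount_rate")
    return one_off + c_surv * _recurring_alive_pv(trace, rate, half_cycle_correction)


def accrue_qalys(
    trace: CohortTrace,
    arm: TreatmentArm,
    params: ParameterSet,
    half_cycle_correction: bool = False,
) -> float:
    """Discounted QALYs per patient entering this arm (discrete AUC)."""
    u0 = params.value("u_cystectomy") - arm.toll
    if u0 < 0:
        logger.warning(
            "arm %s: cycle-0 utility %.4f negative after chemo toll; clamped to 0",
            arm.label.value,
            u0,
        )
        u0 = 0.0
    rate = params.value("discount_rate")
    u_surv = params.value("u_surveillance")
    return float(trace.alive[0]) * u0 + u_surv * _recurring_alive_pv(
        trace, rate, half_cycle_correction
    )


def evaluate_strategy(
    strategy: StrategySpec,
    schedules: Mapping[str, TransitionSchedule],
    horizon: int,
    params: ParameterSet,
    half_cycle_correction: bool = False,
    traces: Optional[Mapping[str, CohortTrace]] = None,
) -> EconomicOutcome:
    """Expected discounted cost and QALYs for one strategy at one horizon.

    Each branch's arm is simulated with its own transition schedule; branch
    outcomes are combined by the tree's probability mixture. ``traces`` may
    supply pre-computed cohort traces keyed by schedule key (used to avoid
    re-running identical traces inside the PSA loop).
    """
    cost_branches = []
    qaly_branches = []
    for branch in strategy.branches:
        key = branch.arm.schedule_key
        if traces is not None and key in traces:
            trace = traces[key]
        else:
            if key not in schedules:
                raise ValidationError(
                    f"no transition schedule for key {key!r}; available: "
                    f"{sorted(schedules)}"
                )
            trace = run_cohort(schedules[key], horizon)
        cost_branches.append(
            (
                branch.probability,
                accrue_costs(
                    trace,
                    branch.arm,
                    params,
                    strategy_level_costs=strategy.subtype_test_cost,
                    half_cycle_correction=half_cycle_correction,
                ),
            )
        )
        qaly_branches.append(
            (
                branch.probability,
                accrue_qalys(
                    trace, branch.arm, params,
                    half_cycle_correction=half_cycle_correction,
                ),
            )
        )
    return EconomicOutcome(
        strategy=strategy.name.value,
        total_cost=mix_branches(cost_branches),
        total_qaly=mix_branches(qaly_branches),
        horizon=horizon,
    )


def compare_strategies(
    a: EconomicOutcome, b: EconomicOutcome, wtp: float
) -> CEResult:
    """Incremental analysis of intervention ``b`` against comparator ``a``.

    Sign conventions: ``delta = b - a``. A finite ICER is reported only in
    the more-costly/more-effective quadrant (and as 0 at equal cost);
    otherwise a dominance flag is set. With zero QALY difference the ICER
    is undefined and flagged.
    """
    if a.horizon != b.horizon:
        raise ValidationError(
            f"horizon mismatch: {a.horizon} vs {b.horizon}"
        )
    dc = b.total_cost - a.total_cost
    dq = b.total_qaly - a.total_qaly
    icer: Optional[float] = None
    flag: Optional[str] = None
    if dq > 0:
        if dc > 0:
            icer = dc / dq
        elif dc < 0:
            flag = DOMINANT
        else:
            icer = 0.0
    elif dq < 0:
        flag = DOMINATED if dc > 0 else COST_SAVING_LESS_EFFECTIVE
    else:
        flag = ICER_UNDEFINED
    return CEResult(
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer,
        flag=flag,
        wtp=wtp,
        nmb_delta=wtp * dq - dc,
        horizon=a.horizon,
    )


def convert_currency(amount_sek: float, sek_per_eur: float) -> float:
    """SEK -> EUR via a purchasing-power-parity factor (configuration)."""
    if sek_per_eur <= 0:
        raise ValidationError(f"sek_per_eur must be > 0, got {sek_per_eur}")
    return amount_sek / sek_per_eur
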