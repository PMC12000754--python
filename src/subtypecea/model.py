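"""The model / results objects tying the pipeline together.

:class:`CostEffectivenessModel` is built from a parameter table and a set
of per-arm transition schedules; :meth:`~CostEffectivenessModel.fit`
evaluates both treatment strategies deterministically at each configured
horizon and returns a :class:`CEAResults` carrying the per-strategy
discounted totals, the incremental comparisons and a printable summary
table. Sensitivity analyses (``tornado``, ``psa``, ``scenario``) hang off
the model object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .economics import (
    CEResult,
    EconomicOutcome,
    compare_strategies,
    evaluate_strategy,
)
from .exceptions import ConfigurationError, ValidationError
from .markov import (
    CohortTrace,
    Strategy,
    TransitionSchedule,
    build_strategy,
    run_cohort,
    schedules_from_csv,
)
from .params import ParameterSet
from .sensitivity import (
    CEACPoint,
    PSAResult,
    TornadoEntry,
    default_wtp_grid,
    one_way_tornado,
    run_psa,
    run_scenario,
)


class CostEffectivenessModel:
    """Markov cohort cost-effectiveness model of subtype-based NAC triage.

    Parameters
    ----------
    schedules
        Mapping of schedule key -> :class:`TransitionSchedule` covering the
        four arm/population combinations. Must span the largest horizon.
    params
        The parameter table; defaults to the base case.
    horizons
        Evaluation horizons in follow-up years (default from ``params``).
        An "N-year" horizon runs N yearly transitions after the treatment
        year, i.e. N + 1 accrual cycles.
    half_cycle_correction
        Apply a half-cycle correction to recurring accruals (default off).
    """

    def __init__(
        self,
        schedules: Mapping[str, TransitionSchedule],
        params: Optional[ParameterSet] = None,
        horizons: Optional[Sequence[int]] = None,
        half_cycle_correction: bool = False,
    ) -> None:
        self.params = params if params is not None else ParameterSet.default()
        self.schedules = dict(schedules)
        self.horizons = tuple(horizons) if horizons is not None else self.params.horizons
        if not self.horizons or any(h < 1 for h in self.horizons):
            raise ValidationError("horizons must be non-empty, each >= 1")
        self.half_cycle_correction = bool(half_cycle_correction)
        for key, sched in self.schedules.items():
            sched.require(max(self.horizons))
        self._trace_cache: dict[tuple[str, int], CohortTrace] = {}

    @classmethod
    def from_csv(
        cls,
        schedules_csv: str | Path,
        params_csv: Optional[str | Path] = None,
        **kwargs,
    ) -> "CostEffectivenessModel":
        """Build a model from a schedule CSV and (optionally) a parameter CSV."""
        params = ParameterSet.from_csv(params_csv) if params_csv else None
        return cls(schedules_from_csv(schedules_csv), params=params, **kwargs)

    # ------------------------------------------------------------------
    def _traces(self, horizon: int) -> dict[str, CohortTrace]:
        for key, sched in self.schedules.items():
            if (key, horizon) not in self._trace_cache:
                self._trace_cache[(key, horizon)] = run_cohort(sched, horizon)
        return {
            key: self._trace_cache[(key, horizon)] for key in self.schedules
        }

    def evaluate(
        self, horizon: int, params: Optional[ParameterSet] = None
    ) -> dict[str, EconomicOutcome]:
        """Deterministic discounted (cost, QALY) per strategy at one horizon.

        ``params`` overrides the model's table for this evaluation only
        (used by the tornado / PSA / scenario machinery). Cohort traces
        depend only on the transition schedules and are cached.
        """
        params = params if params is not None else self.params
        traces = self._traces(horizon)
        out: dict[str, EconomicOutcome] = {}
        for strategy in (Strategy.CURRENT_PRACTICE, Strategy.SUBTYPE_BASED):
            spec = build_strategy(params, strategy)
            out[strategy.value] = evaluate_strategy(
                spec,
                self.schedules,
                horizon,
                params,
                half_cycle_correction=self.half_cycle_correction,
                traces=traces,
            )
        return out

    def fit(self) -> "CEAResults":
        """Evaluate the base case at every configured horizon."""
        wtp = self.params.value("wtp")
        outcomes = {}
        comparisons = {}
        for h in self.horizons:
            out = self.evaluate(h)
            outcomes[h] = out
            comparisons[h] = compare_strategies(
                out[Strategy.CURRENT_PRACTICE.value],
                out[Strategy.SUBTYPE_BASED.value],
                wtp=wtp,
            )
        return CEAResults(self, outcomes, comparisons)

    # -- sensitivity analyses -------------------------------------------
    def tornado(self, horizon: Optional[int] = None) -> list[TornadoEntry]:
        return one_way_tornado(self, horizon or max(self.horizons))

    def psa(
        self,
        n: int = 10_000,
        seed: int = 0,
        horizon: Optional[int] = None,
    ) -> PSAResult:
        return run_psa(self, horizon or max(self.horizons), n=n, seed=seed)

    def scenario(
        self, overrides: Mapping[str, float], horizon: Optional[int] = None
    ) -> CEResult:
        return run_scenario(self, overrides, horizon or max(self.horizons))


@dataclass
class CEAResults:
    """Deterministic base-case results across horizons."""

    model: CostEffectivenessModel
    outcomes: dict[int, dict[str, EconomicOutcome]]
    comparisons: dict[int, CEResult]

    def to_frame(self) -> pd.DataFrame:
        """Tidy results table: one row per (horizon, strategy), incremental
        columns populated on the intervention row."""
        rows = []
        for h in sorted(self.outcomes):
            comp = self.comparisons[h]
            for strat in (Strategy.CURRENT_PRACTICE, Strategy.SUBTYPE_BASED):
                o = self.outcomes[h][strat.value]
                is_intervention = strat is Strategy.SUBTYPE_BASED
                rows.append(
                    {
                        "horizon": h,
                        "strategy": strat.value,
                        "cost": o.total_cost,
                        "qaly": o.total_qaly,
                        "delta_cost": comp.delta_cost if is_intervention else np.nan,
                        "delta_qaly": comp.delta_qaly if is_intervention else np.nan,
                        "icer": (
                            comp.icer
                            if is_intervention and comp.icer is not None
                            else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable incremental cost-effectiveness table."""
        wtp = self.model.params.value("wtp")
        lines = [
            "Cost-effectiveness of subtype-based NAC de-escalation vs current practice",
            f"(discount rate {self.model.params.value('discount_rate'):.1%}/yr, "
            f"WTP {wtp:,.0f} EUR/QALY)",
            "",
            f"{'horizon':>8} {'strategy':<18} {'cost (EUR)':>12} {'QALYs':>8} "
            f"{'dCost':>9} {'dQALY':>7} {'ICER':>10}",
        ]
        for h in sorted(self.outcomes):
            comp = self.comparisons[h]
            for strat in (Strategy.CURRENT_PRACTICE, Strategy.SUBTYPE_BASED):
                o = self.outcomes[h][strat.value]
                if strat is Strategy.SUBTYPE_BASED:
                    icer = f"{comp.icer:,.0f}" if comp.icer is not None else comp.flag
                    inc = f"{comp.delta_cost:>9,.0f} {comp.delta_qaly:>7.3f} {icer:>10}"
                else:
                    inc = f"{'':>9} {'':>7} {'':>10}"
                lines.append(
                    f"{h:>7}y {strat.value:<18} {o.total_cost:>12,.0f} "
                    f"{o.total_qaly:>8.3f} {inc}"
                )
            verdict = self.verdict(h)
            lines.append(f"{'':>8} -> {verdict}")
        return "\n".join(lines)

    def verdict(self, horizon: int) -> str:
        comp = self.comparisons[horizon]
        # sub-milli-euro differences are renormalization round-off, not signal
        if comp.flag == "undefined" and abs(comp.delta_cost) < 1e-6:
            return "no difference between strategies"
        wtp = comp.wtp
        if comp.nmb_delta > 0:
            return (
                f"subtype-based strategy cost-effective at WTP {wtp:,.0f} EUR/QALY "
                f"(incremental NMB {comp.nmb_delta:,.0f} EUR)"
            )
        if comp.nmb_delta < 0:
            return (
                f"subtype-based strategy NOT cost-effective at WTP {wtp:,.0f} "
                f"EUR/QALY (incremental NMB {comp.nmb_delta:,.0f} EUR)"
            )
        return "strategies exactly break even at the stated WTP"
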