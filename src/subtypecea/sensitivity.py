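"""One-way (tornado), probabilistic (Monte Carlo + CEAC) and scenario
sensitivity analyses over the deterministic decision model.

Probabilistic sampling uses standard second-order CEA conventions:
probabilities, utilities and the disutility magnitude are drawn from beta
distributions and costs from gamma distributions, each moment-matched so
the mean equals the point estimate and ``(high - low) / (2 * 1.96)``
approximates the standard deviation (the plausible range read as an
approximate 95% interval). Complementary probability pairs (e.g. good/poor
prognosis) are sampled as one beta draw and its complement so branch
probabilities keep summing to one. Parameters declared ``fixed`` always
return their point estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Optional, Sequence

import numpy as np

from .economics import CEResult, compare_strategies
from .exceptions import ValidationError
from .markov import Strategy
from .params import Parameter, ParameterSet

if TYPE_CHECKING:  # pragma: no cover
    from .model import CostEffectivenessModel

logger = logging.getLogger(__name__)

#: (sampled, complemented-to-one) probability pairs.
COMPLEMENT_PAIRS: tuple[tuple[str, str], ...] = (
    ("p_nac_rc_current", "p_rc_only_current"),
    ("p_poor_current", "p_good_current"),
    ("p_uro_gu", "p_basq"),
    ("p_poor_basq", "p_good_basq"),
)

_PSA_MAX_RETRIES = 100


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    parameter: str
    icer_at_low: Optional[float]
    icer_at_high: Optional[float]
    span: float  # |icer_high - icer_low|; NaN when either endpoint is flagged
    flagged: bool = False  # a degenerate endpoint (dominance / zero dQALY)


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability_cost_effective: float


@dataclass
class PSAResult:
    """Monte Carlo cloud of (cost, QALY) per strategy, plus provenance."""

    n_iterations: int
    seed: int
    horizon: int
    costs: dict[str, np.ndarray]
    qalys: dict[str, np.ndarray]
    comparator: str = Strategy.CURRENT_PRACTICE.value
    intervention: str = Strategy.SUBTYPE_BASED.value

    @property
    def delta_cost(self) -> np.ndarray:
        return self.costs[self.intervention] - self.costs[self.comparator]

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qalys[self.intervention] - self.qalys[self.comparator]

    def ceac(self, wtp_grid: Sequence[float]) -> list[CEACPoint]:
        return ceac(self, wtp_grid)


def sample_parameter(spec: Parameter, rng: np.random.Generator) -> float:
    """Draw one value for a parameter; ``fixed`` entries return the point.

    Beta for unit-interval quantities, gamma for costs, both moment-matched
    to (point, range-implied sd). When the implied sd is infeasible for the
    beta support the draw falls back to uniform(low, high) with a warning.
    """
    if spec.is_fixed:
        return spec.point
    sd = (spec.high - spec.low) / (2.0 * 1.96)
    m = spec.point
    if spec.distribution == "beta":
        var = sd * sd
        if m <= 0.0 or m >= 1.0 or var >= m * (1.0 - m):
            logger.warning(
                "parameter %s: beta moment match infeasible "
                "(mean=%.4f, sd=%.4f); falling back to uniform(low, high)",
                spec.name, m, sd,
            )
            return float(rng.uniform(spec.low, spec.high))
        nu = m * (1.0 - m) / var - 1.0
        return float(rng.beta(m * nu, (1.0 - m) * nu))
    if spec.distribution == "gamma":
        shape = (m / sd) ** 2
        scale = sd * sd / m
        return float(rng.gamma(shape, scale))
    raise ValidationError(f"cannot sample distribution {spec.distribution!r}")


def sample_parameters(
    params: ParameterSet, rng: np.random.Generator
) -> ParameterSet:
    """One joint draw of the full parameter table (independent draws,
    complement pairs tied to sum to one)."""
    complements = dict(COMPLEMENT_PAIRS)
    skip = set(complements.values())
    overrides: dict[str, float] = {}
    for name, spec in params.items():
        if name in skip:
            continue
        value = sample_parameter(spec, rng)
        overrides[name] = value
        if name in complements and not spec.is_fixed:
            overrides[complements[name]] = 1.0 - value
    return params.with_overrides(overrides)


def run_psa(
    model: "CostEffectivenessModel",
    horizon: int,
    n: int,
    seed: int,
) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty.

    Per iteration: one joint parameter draw, both strategy trees rebuilt,
    the deterministic model run, (cost, QALY) stored per strategy. Fully
    reproducible from the seed. Draws that fail model validation are
    resampled, with a capped retry count.
    """
    if n < 1:
        raise ValidationError(f"PSA iteration count must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    strategies = (Strategy.CURRENT_PRACTICE.value, Strategy.SUBTYPE_BASED.value)
    costs = {s: np.empty(n) for s in strategies}
    qalys = {s: np.empty(n) for s in strategies}
    for i in range(n):
        for _ in range(_PSA_MAX_RETRIES):
            try:
                sampled = sample_parameters(model.params, rng)
                outcomes = model.evaluate(horizon, params=sampled)
                break
            except ValidationError:
                continue
        else:
            raise ValidationError(
                f"PSA iteration {i}: no valid parameter draw within "
                f"{_PSA_MAX_RETRIES} attempts"
            )
        for s in strategies:
            costs[s][i] = outcomes[s].total_cost
            qalys[s][i] = outcomes[s].total_qaly
    return PSAResult(
        n_iterations=n, seed=seed, horizon=horizon, costs=costs, qalys=qalys
    )


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> list[CEACPoint]:
    """Empirical probability the intervention is cost-effective at each WTP.

    A PSA iteration counts as a win at WTP ``w`` iff its incremental net
    monetary benefit ``w * dQALY - dCost`` is strictly positive (exact ties
    count as not cost-effective).
    """
    grid = list(wtp_grid)
    if len(grid) == 0:
        raise ValidationError("empty WTP grid")
    if any(w < 0 for w in grid):
        raise ValidationError("WTP grid values must be >= 0")
    if psa.n_iterations == 0:
        raise ValidationError("empty PSA")
    dc = psa.delta_cost
    dq = psa.delta_qaly
    return [
        CEACPoint(float(w), float(np.count_nonzero(w * dq - dc > 0)) / psa.n_iterations)
        for w in grid
    ]


def default_wtp_grid() -> np.ndarray:
    """0 to 50,000 EUR/QALY in 500 steps, always including 7,427 and 10,000."""
    grid = np.arange(0.0, 50_000.0 + 1, 500.0)
    return np.unique(np.concatenate([grid, [7_427.0, 10_000.0]]))


def run_scenario(
    model: "CostEffectivenessModel",
    overrides: Mapping[str, float],
    horizon: int,
) -> CEResult:
    """Deterministic incremental result under named parameter replacements.

    Unknown override names raise a ``KeyError`` listing the valid names.
    """
    params = model.params.with_overrides(overrides)
    outcomes = model.evaluate(horizon, params=params)
    return compare_strategies(
        outcomes[Strategy.CURRENT_PRACTICE.value],
        outcomes[Strategy.SUBTYPE_BASED.value],
        wtp=params.value("wtp"),
    )


def one_way_tornado(
    model: "CostEffectivenessModel", horizon: int
) -> list[TornadoEntry]:
    """One-way sensitivity: each parameter in turn set to its low and high
    with all others at their points; entries sorted by decreasing ICER span.

    Endpoints where the incremental analysis is degenerate (dominance or
    zero QALY difference) are flagged rather than raising.
    """
    entries = []
    for name, spec in model.params.items():
        icers = []
        flagged = False
        for value in (spec.low, spec.high):
            result = run_scenario(model, {name: value}, horizon)
            if result.icer is None:
                flagged = True
            icers.append(result.icer)
        span = (
            abs(icers[1] - icers[0])
            if icers[0] is not None and icers[1] is not None
            else float("nan")
        )
        entries.append(
            TornadoEntry(
                parameter=name,
                icer_at_low=icers[0],
                icer_at_high=icers[1],
                span=span,
                flagged=flagged,
            )
        )
    entries.sort(
        key=lambda e: (not np.isnan(e.span), e.span), reverse=True
    )
    return entries
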