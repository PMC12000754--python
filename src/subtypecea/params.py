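"""Model parameter table: point estimates, plausible ranges and sampling families.

Every scalar the decision model consumes — treatment-mix proportions,
prognosis splits, subtype prevalences, unit costs (EUR, 2022 price year),
health-state utilities, the chemotherapy disutility toll, the annual
discount rate and the willingness-to-pay threshold — lives in a single
:class:`ParameterSet`. Each entry carries a point estimate, a plausible
(low, high) range used by the one-way sensitivity analysis, a ``kind``
tag that fixes its admissible support, and the distribution family used
by the probabilistic sensitivity analysis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .exceptions import ConfigurationError, SchemaError, ValidationError

KINDS = ("probability", "cost", "utility", "disutility")
DISTRIBUTIONS = ("beta", "gamma", "fixed")

#: Parameters whose values live on [0, 1].
_UNIT_INTERVAL_KINDS = ("probability", "utility", "disutility")


@dataclass(frozen=True)
class Parameter:
    """One named model input with its point estimate and plausible range."""

    name: str
    point: float
    low: float
    high: float
    kind: str
    distribution: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(
                f"parameter {self.name!r}: kind {self.kind!r} not in {KINDS}"
            )
        if self.distribution not in DISTRIBUTIONS:
            raise ValidationError(
                f"parameter {self.name!r}: distribution {self.distribution!r} "
                f"not in {DISTRIBUTIONS}"
            )
        if not (self.low <= self.point <= self.high):
            raise ValidationError(
                f"parameter {self.name!r}: require low <= point <= high, got "
                f"({self.low}, {self.point}, {self.high})"
            )
        if self.kind in _UNIT_INTERVAL_KINDS:
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ValidationError(
                    f"parameter {self.name!r}: {self.kind} values must lie in "
                    f"[0, 1], got range ({self.low}, {self.high})"
                )
        elif self.kind == "cost" and self.low < 0:
            raise ValidationError(
                f"parameter {self.name!r}: costs must be >= 0, got low={self.low}"
            )

    @property
    def is_fixed(self) -> bool:
        return self.distribution == "fixed" or self.high == self.low


def _fixed(name: str, value: float, kind: str) -> Parameter:
    return Parameter(name, value, value, value, kind, "fixed")


#: Base-case inputs: treatment-mix and prognosis proportions from Swedish
#: registry data plus published subtype cohorts; costs valued via DRG in
#: EUR (EU-27, 2022); utilities and the chemotherapy disutility from the
#: literature. Discount rate, WTP threshold, SEK→EUR purchasing-power
#: factor and chemo toll durations are configuration scalars (fixed in PSA).
_DEFAULTS: tuple[Parameter, ...] = (
    Parameter("p_nac_rc_current", 0.280, 0.252, 0.740, "probability", "beta"),
    Parameter("p_rc_only_current", 0.720, 0.648, 0.811, "probability", "beta"),
    Parameter("p_poor_current", 0.053, 0.047, 0.058, "probability", "beta"),
    Parameter("p_good_current", 0.947, 0.853, 0.990, "probability", "beta"),
    Parameter("p_uro_gu", 0.696, 0.650, 0.779, "probability", "beta"),
    Parameter("p_basq", 0.303, 0.220, 0.349, "probability", "beta"),
    Parameter("p_poor_basq", 0.753, 0.734, 0.773, "probability", "beta"),
    Parameter("p_good_basq", 0.246, 0.227, 0.265, "probability", "beta"),
    Parameter("cost_rc", 14711.0, 13240.0, 17653.0, "cost", "gamma"),
    Parameter("cost_nac", 2270.0, 2043.0, 2724.0, "cost", "gamma"),
    Parameter("cost_ac", 2586.0, 2327.0, 3103.0, "cost", "gamma"),
    Parameter("cost_surveillance", 444.0, 400.0, 533.0, "cost", "gamma"),
    Parameter("cost_subtype_id", 341.0, 273.0, 409.0, "cost", "gamma"),
    Parameter("u_surveillance", 0.914, 0.800, 1.000, "utility", "beta"),
    Parameter("u_cystectomy", 0.800, 0.600, 1.000, "utility", "beta"),
    Parameter("disutility_chemo", 0.360, 0.300, 0.400, "disutility", "beta"),
    _fixed("discount_rate", 0.03, "probability"),
    _fixed("wtp", 7427.0, "cost"),
    # 100,000 SEK / 7,427 EUR: the purchasing-power pair that defines the
    # Swedish WTP threshold. Configurable; nothing internal depends on it.
    _fixed("sek_per_eur", 13.4644, "cost"),
    # One-time chemotherapy disutility toll durations, fractions of a year:
    # 3 NAC courses ~ a quarter, 4 AC courses ~ a third.
    _fixed("toll_duration_nac", 0.25, "probability"),
    _fixed("toll_duration_ac", 0.33, "probability"),
)

REQUIRED_NAMES: tuple[str, ...] = tuple(p.name for p in _DEFAULTS)

_CSV_HEADER = ["name", "point", "low", "high", "kind", "distribution"]

DEFAULT_HORIZONS: tuple[int, ...] = (2, 3, 5)


class ParameterSet(Mapping[str, Parameter]):
    """Immutable mapping of parameter name -> :class:`Parameter`.

    All :data:`REQUIRED_NAMES` must be present; unknown names are rejected
    so that typos in a parameter CSV fail loudly rather than silently
    falling back to defaults.
    """

    def __init__(
        self,
        parameters: Iterable[Parameter],
        horizons: Iterable[int] = DEFAULT_HORIZONS,
    ) -> None:
        self._params: dict[str, Parameter] = {}
        for p in parameters:
            if p.name not in REQUIRED_NAMES:
                raise ConfigurationError(
                    f"unknown parameter {p.name!r}; valid names: "
                    f"{', '.join(REQUIRED_NAMES)}"
                )
            if p.name in self._params:
                raise ConfigurationError(f"duplicate parameter {p.name!r}")
            self._params[p.name] = p
        missing = [n for n in REQUIRED_NAMES if n not in self._params]
        if missing:
            raise ConfigurationError(
                "missing required parameters: " + ", ".join(missing)
            )
        self.horizons = tuple(int(h) for h in horizons)
        if not self.horizons or any(h < 1 for h in self.horizons):
            raise ValidationError("horizons must be non-empty, each >= 1")

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, name: str) -> Parameter:
        try:
            return self._params[name]
        except KeyError:
            raise KeyError(
                f"unknown parameter {name!r}; valid names: "
                f"{', '.join(REQUIRED_NAMES)}"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ParameterSet)
            and self._params == other._params
            and self.horizons == other.horizons
        )

    # -- accessors ---------------------------------------------------------
    def value(self, name: str) -> float:
        """Point estimate of the named parameter."""
        return self[name].point

    def with_overrides(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """New ParameterSet with point estimates replaced.

        Ranges are widened, if necessary, to keep the low <= point <= high
        invariant, so scenario and sampled values outside the printed range
        remain representable.
        """
        new = dict(self._params)
        for name, value in overrides.items():
            old = self[name]  # raises KeyError listing valid names
            value = float(value)
            new[name] = replace(
                old,
                point=value,
                low=min(old.low, value),
                high=max(old.high, value),
            )
        return ParameterSet(new.values(), horizons=self.horizons)

    # -- construction / IO ---------------------------------------------------
    @classmethod
    def default(cls, horizons: Iterable[int] = DEFAULT_HORIZONS) -> "ParameterSet":
        """The base-case parameter table."""
        return cls(_DEFAULTS, horizons=horizons)

    @classmethod
    def from_csv(
        cls,
        path: str | Path | io.TextIOBase,
        horizons: Iterable[int] = DEFAULT_HORIZONS,
    ) -> "ParameterSet":
        df = pd.read_csv(path, comment="#")
        if list(df.columns) != _CSV_HEADER:
            raise SchemaError(
                f"parameter CSV header must be {_CSV_HEADER}, got {list(df.columns)}"
            )
        params = [
            Parameter(
                str(r.name_), float(r.point), float(r.low), float(r.high),
                str(r.kind), str(r.distribution),
            )
            for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
        ]
        return cls(params, horizons=horizons)

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (p.name, p.point, p.low, p.high, p.kind, p.distribution)
                for p in self._params.values()
            ],
            columns=_CSV_HEADER,
        )
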