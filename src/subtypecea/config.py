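"""Run configuration: YAML/JSON config files resolved into model inputs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .exceptions import ConfigurationError
from .markov import TransitionSchedule, schedules_from_csv
from .model import CostEffectivenessModel
from .params import DEFAULT_HORIZONS, ParameterSet
from .synthetic import TrueGeneratingModel, default_schedules, estimate_transitions, generate_cohort


@dataclass
class RunConfig:
    """Everything a command needs to assemble the model.

    Exactly one transition-probability source applies: a schedule CSV, a
    synthetic generating-model spec (generate a cohort, then estimate the
    schedules from it), or the built-in synthetic defaults.
    """

    parameters: Optional[str] = None  # CSV path; None -> base-case table
    schedules_csv: Optional[str] = None
    synthetic: Optional[dict[str, Any]] = None  # {n, seed, horizon}
    horizons: tuple[int, ...] = DEFAULT_HORIZONS
    wtp: Optional[float] = None
    discount_rate: Optional[float] = None
    psa_n: int = 10_000
    psa_seed: int = 1
    half_cycle_correction: bool = False
    output_dir: str = "results"
    timestamps: bool = False

    def __post_init__(self) -> None:
        if not self.horizons or any(h < 1 for h in self.horizons):
            raise ConfigurationError("horizons must be non-empty, each >= 1")
        if self.schedules_csv is not None and self.synthetic is not None:
            raise ConfigurationError(
                "specify exactly one transition source: schedules_csv OR synthetic"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = {
            "parameters", "schedules_csv", "synthetic", "horizons", "wtp",
            "discount_rate", "psa_n", "psa_seed", "half_cycle_correction",
            "output_dir", "timestamps",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config fields: {sorted(unknown)}; valid: {sorted(known)}"
            )
        kwargs = dict(raw)
        if "horizons" in kwargs:
            kwargs["horizons"] = tuple(int(h) for h in kwargs["horizons"])
        return cls(**kwargs)

    # ------------------------------------------------------------------
    def load_params(self) -> ParameterSet:
        params = (
            ParameterSet.from_csv(self.parameters, horizons=self.horizons)
            if self.parameters
            else ParameterSet.default(horizons=self.horizons)
        )
        overrides = {}
        if self.wtp is not None:
            overrides["wtp"] = float(self.wtp)
        if self.discount_rate is not None:
            overrides["discount_rate"] = float(self.discount_rate)
        return params.with_overrides(overrides) if overrides else params

    def load_schedules(self) -> dict[str, TransitionSchedule]:
        if self.schedules_csv is not None:
            return schedules_from_csv(self.schedules_csv)
        if self.synthetic is not None:
            spec = dict(self.synthetic)
            gen = TrueGeneratingModel.default(
                n=int(spec.get("n", 10_000)),
                horizon=int(spec.get("horizon", 10)),
                seed=int(spec.get("seed", 0)),
            )
            cohort = generate_cohort(gen)
            return estimate_transitions(cohort, horizon=max(self.horizons))
        return default_schedules()

    def build_model(self) -> CostEffectivenessModel:
        return CostEffectivenessModel(
            self.load_schedules(),
            params=self.load_params(),
            horizons=self.horizons,
            half_cycle_correction=self.half_cycle_correction,
        )

    def digest(self) -> str:
        """Stable hash of the resolved configuration (for output metadata)."""
        blob = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()
             if k not in ("output_dir", "timestamps")},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
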