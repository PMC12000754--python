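import numpy as np
import pytest
from dataclasses import replace

from subtypecea import (
    CostEffectivenessModel,
    ParameterSet,
    TransitionSchedule,
    default_schedules,
)
from subtypecea.params import Parameter


@pytest.fixture
def params():
    return ParameterSet.default()


@pytest.fixture
def schedules():
    return default_schedules()


@pytest.fixture
def model(schedules):
    return CostEffectivenessModel(schedules)


def all_fixed(params: ParameterSet) -> ParameterSet:
    """Copy of a parameter set with every entry declared fixed (PSA-degenerate)."""
    return ParameterSet(
        [replace(p, distribution="fixed") for p in params.values()],
        horizons=params.horizons,
    )


def random_schedule(rng: np.random.Generator, years: int, label: str = "arm") -> TransitionSchedule:
    """A random valid schedule: non-negative cause-specific probabilities
    summing to at most one in every year."""
    total = rng.uniform(0.0, 1.0, size=years)
    split = rng.uniform(0.0, 1.0, size=years)
    return TransitionSchedule(label, tuple(total * split), tuple(total * (1 - split)))


def enumerate_occupancy(p_bc, p_oth, horizon):
    """Exhaustive path-enumeration oracle for the cohort recursion.

    Walks every state sequence of length horizon+1 (alive until a death
    year and cause, or alive throughout), weights it by its probability,
    and accumulates per-cycle occupancy. Independent of the engine's
    running-product implementation.
    """
    occ = np.zeros((horizon + 1, 3))

    def rec(t, state, prob, hist):
        hist = hist + [state]
        if t == horizon:
            for cycle, st in enumerate(hist):
                occ[cycle, st] += prob
            return
        if state == 0:
            pb, po = p_bc[t], p_oth[t]
            rec(t + 1, 0, prob * (1 - pb - po), hist)
            rec(t + 1, 1, prob * pb, hist)
            rec(t + 1, 2, prob * po, hist)
        else:
            rec(t + 1, state, prob, hist)

    rec(0, 0, 1.0, [])
    return occ
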