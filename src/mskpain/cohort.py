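"""Prevalent cohort construction and the monthly Markov cohort trace.

The national prevalent population of each pathology enters the model split
across the three living severity states; the trace then advances in 1-month
cycles under a constant transition matrix over a 12-cycle (1-year) horizon.
Death from other causes is the only exit. No half-cycle correction is
applied: with a 1-month cycle the correction is negligible and plain cycle
accounting keeps the arithmetic transparent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .states import LIVING_STATES, HealthState, TransitionMatrix

__all__ = [
    "MortalityParameter",
    "PathologyCohort",
    "CohortTrace",
    "annual_to_monthly_prob",
    "annual_rate_to_monthly_prob",
    "initial_state_vector",
    "run_cohort",
    "apply_undiagnosed_scenario",
]

_SPLIT_TOL = 1e-9
_CONSERVATION_TOL = 1e-6
DEFAULT_HORIZON_CYCLES = 12


def annual_to_monthly_prob(p_annual: float) -> float:
    """Convert an annual probability to a monthly one at constant hazard.

    Returns ``1 - (1 - p)**(1/12)``: the monthly probability whose
    12-fold compounding reproduces the annual probability.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError("p_annual must lie in [0, 1]")
    return 1.0 - (1.0 - p_annual) ** (1.0 / 12.0)


def annual_rate_to_monthly_prob(rate_per_year: float) -> float:
    """Convert an annual event *rate* to a monthly probability.

    Crude mortality is reported as deaths per person-year (e.g. 5.1 per
    1000 inhabitants). Treating it as a constant instantaneous rate, the
    monthly probability is ``1 - exp(-rate/12)`` — for 5.1/1000 this gives
    0.42 per 1000 per month.
    """
    if rate_per_year < 0:
        raise ValueError("rate_per_year must be non-negative")
    return 1.0 - math.exp(-rate_per_year / 12.0)


@dataclass(frozen=True)
class MortalityParameter:
    """Background mortality, stored as the reported annual figure per 1000.

    The published series gives a crude annual rate; the monthly transition
    probability is derived under a constant instantaneous rate.
    """

    annual_per_1000: float = 5.1

    def __post_init__(self) -> None:
        if self.annual_per_1000 < 0:
            raise ValueError("annual_per_1000 must be non-negative")

    @property
    def monthly_probability(self) -> float:
        return annual_rate_to_monthly_prob(self.annual_per_1000 / 1000.0)


@dataclass(frozen=True)
class PathologyCohort:
    """One pathology's prevalent cohort and its severity allocation.

    ``diagnosed_fractions`` gate entry into the modelled (cost-incurring)
    cohort per living state; undiagnosed patients are tracked separately for
    prevalence reporting but accrue no management cost.
    """

    pathology: str
    prevalent_count: float
    severity_split: tuple[float, float, float]
    diagnosed_fractions: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.prevalent_count < 0:
            raise ValueError("prevalent_count must be non-negative")
        split = np.asarray(self.severity_split, dtype=float)
        if split.shape != (3,) or np.any(split < 0):
            raise ValueError("severity_split must be three non-negative proportions")
        if abs(split.sum() - 1.0) > _SPLIT_TOL:
            raise ValueError(f"severity_split must sum to 1 within {_SPLIT_TOL}")
        frac = np.asarray(self.diagnosed_fractions, dtype=float)
        if frac.shape != (3,) or np.any(frac < 0) or np.any(frac > 1):
            raise ValueError("diagnosed_fractions must lie in [0, 1]")
        object.__setattr__(self, "severity_split", tuple(split))
        object.__setattr__(self, "diagnosed_fractions", tuple(frac))

    @property
    def undiagnosed_count(self) -> float:
        split = np.asarray(self.severity_split)
        frac = np.asarray(self.diagnosed_fractions)
        return float(self.prevalent_count * (split * (1.0 - frac)).sum())


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy by cycle, rows 0..horizon, columns in state order."""

    occupancy: np.ndarray
    pathology: str = ""
    cycle_length_months: int = 1

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != 4:
            raise ValueError("occupancy must be (cycles+1, 4)")
        if np.any(occ < -_CONSERVATION_TOL):
            raise ValueError("occupancy must be non-negative")
        totals = occ.sum(axis=1)
        if occ.shape[0] and not np.allclose(totals, totals[0], atol=_CONSERVATION_TOL):
            raise ValueError("cohort size must be conserved across cycles")
        object.__setattr__(self, "occupancy", occ)

    @property
    def horizon_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        """Tidy view: pathology, cycle, state, occupancy."""
        rows = [
            (self.pathology, cycle, state.name.lower(), self.occupancy[cycle, state.value])
            for cycle in range(self.occupancy.shape[0])
            for state in HealthState
        ]
        return pd.DataFrame(rows, columns=["pathology", "cycle", "state", "occupancy"])


def initial_state_vector(cohort: PathologyCohort) -> np.ndarray:
    """Cycle-0 occupancy of the modelled (diagnosed) cohort.

    Living states receive prevalent_count x severity share x diagnosed
    fraction; the death state starts empty.
    """
    split = np.asarray(cohort.severity_split)
    frac = np.asarray(cohort.diagnosed_fractions)
    vec = np.zeros(4)
    vec[:3] = cohort.prevalent_count * split * frac
    return vec


def run_cohort(
    initial: np.ndarray,
    matrix: TransitionMatrix,
    horizon_cycles: int = DEFAULT_HORIZON_CYCLES,
    pathology: str = "",
) -> CohortTrace:
    """Advance the cohort ``horizon_cycles`` months under a constant matrix."""
    if horizon_cycles < 1:
        raise ValueError("horizon_cycles must be >= 1")
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (4,) or np.any(initial < 0):
        raise ValueError("initial occupancy must be 4 non-negative values")
    m = matrix.as_array()
    occ = np.empty((horizon_cycles + 1, 4))
    occ[0] = initial
    for t in range(horizon_cycles):
        occ[t + 1] = occ[t] @ m
    return CohortTrace(occupancy=occ, pathology=pathology)


def apply_undiagnosed_scenario(
    cohorts: list[PathologyCohort], mild_undx: float, moderate_undx: float
) -> list[PathologyCohort]:
    """Scenario in which a share of mild/moderate cases is never diagnosed.

    Severe pain is always assumed diagnosed. In the reference scenario 50%
    of mild and 25% of moderate cases lack a diagnosis, so diagnosed
    fractions become (0.5, 0.75, 1.0).
    """
    if not (0.0 <= mild_undx <= 1.0 and 0.0 <= moderate_undx <= 1.0):
        raise ValueError("undiagnosed proportions must lie in [0, 1]")
    fractions = (1.0 - mild_undx, 1.0 - moderate_undx, 1.0)
    return [replace(c, diagnosed_fractions=fractions) for c in cohorts]
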