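"""Health states and the monthly transition matrix of the chronic-pain model.

The cohort model distinguishes four states defined by self-reported pain
intensity on the visual analogue scale (VAS): mild (VAS 1-3), moderate
(VAS 4-6), severe (VAS 7-10) chronic pain, and death from other causes.
Chronic pain itself is assumed non-fatal, so the death state only absorbs
background mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = ["HealthState", "LIVING_STATES", "TransitionMatrix", "ROW_SUM_TOL"]

#: tolerance used for every "row sums to one" check
ROW_SUM_TOL = 1e-9


class HealthState(Enum):
    """The four model states; living states carry their VAS band."""

    MILD = 0
    MODERATE = 1
    SEVERE = 2
    DEAD = 3

    @property
    def vas_band(self) -> tuple[int, int] | None:
        """Inclusive VAS intensity band; ``None`` for the death state."""
        return _VAS_BANDS[self]

    @property
    def is_living(self) -> bool:
        return self is not HealthState.DEAD


_VAS_BANDS = {
    HealthState.MILD: (1, 3),
    HealthState.MODERATE: (4, 6),
    HealthState.SEVERE: (7, 10),
    HealthState.DEAD: None,
}

LIVING_STATES: tuple[HealthState, ...] = (
    HealthState.MILD,
    HealthState.MODERATE,
    HealthState.SEVERE,
)


@dataclass(frozen=True)
class TransitionMatrix:
    """A 4x4 row-stochastic monthly transition matrix.

    Rows/columns are indexed in ``HealthState`` order (mild, moderate,
    severe, dead). The death row must be absorbing. Validation happens at
    construction so downstream code can rely on a coherent matrix.
    """

    entries: np.ndarray = field()

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"transition matrix must be 4x4, got {m.shape}")
        if np.any(m < -ROW_SUM_TOL) or np.any(m > 1 + ROW_SUM_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rows = m.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=ROW_SUM_TOL):
            raise ValueError(f"rows must sum to 1 within {ROW_SUM_TOL}; got {rows}")
        dead = HealthState.DEAD.value
        if not np.allclose(m[dead], np.eye(4)[dead], atol=ROW_SUM_TOL):
            raise ValueError("death state must be absorbing")
        object.__setattr__(self, "entries", m)

    def __getitem__(self, key: tuple[HealthState, HealthState]) -> float:
        frm, to = key
        return float(self.entries[frm.value, to.value])

    def as_array(self) -> np.ndarray:
        return self.entries.copy()
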