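"""Structured expert elicitation: pooling, expectations, and PSA sampling.

Transition probabilities between pain-severity states are not available in
the literature, so they are encoded as expert judgements: each expert
distributes probability mass over a fixed grid of candidate values (21
options per question in the reference design). Judgements are aggregated by
a linear opinion pool — the weighted average of the experts' distributions —
which preserves both the expected probability and the uncertainty the panel
expressed. The pooled empirical density is resampled directly during
probabilistic sensitivity analysis rather than replaced by a parametric fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .states import LIVING_STATES, ROW_SUM_TOL, HealthState, TransitionMatrix

__all__ = [
    "ExpertJudgement",
    "PooledDensity",
    "pool_judgements",
    "elicited_mean",
    "sample_transition_prob",
    "build_transition_matrix",
    "panels_to_frame",
    "panels_from_frame",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class ExpertJudgement:
    """One expert's normalized histogram over the probability grid."""

    expert_id: str
    grid: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if grid.ndim != 1 or grid.shape != weights.shape:
            raise ValueError("grid and weights must be 1-d and equally long")
        if np.any(grid < 0) or np.any(grid > 1):
            raise ValueError("grid values must lie in [0, 1]")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(weights.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights must sum to 1 within {_WEIGHT_TOL}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "weights", weights)

    @property
    def mean(self) -> float:
        return float(self.grid @ self.weights)


@dataclass(frozen=True)
class PooledDensity:
    """Linear-pool aggregate of an expert panel.

    ``n_options`` records the number of (expert, bin) response options that
    back the density — 13 experts x 21 bins = 273 in the reference design —
    while ``support`` holds the shared grid itself.
    """

    support: np.ndarray
    weights: np.ndarray
    n_experts: int
    n_options: int = field(default=0)

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if support.shape != weights.shape or support.ndim != 1:
            raise ValueError("support and weights must be 1-d and equally long")
        if np.any(weights < 0):
            raise ValueError("pooled weights must be non-negative")
        if abs(weights.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"pooled weights must sum to 1 within {_WEIGHT_TOL}")
        n_options = self.n_options or self.n_experts * support.size
        if n_options != self.n_experts * support.size:
            raise ValueError("n_options must equal n_experts * n_bins")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "n_options", n_options)

    @property
    def mean(self) -> float:
        return elicited_mean(self)


def pool_judgements(
    judgements: Sequence[ExpertJudgement],
    expert_weights: Sequence[float] | None = None,
) -> PooledDensity:
    """Linear opinion pool of a panel sharing one probability grid.

    The pooled weight at each grid point is the (expert-)weighted average of
    the individual weights there. Expert weights default to equal; the
    aggregate is invariant to the order of the panel.
    """
    if len(judgements) == 0:
        raise ValueError("cannot pool an empty panel")
    grid = judgements[0].grid
    for j in judgements[1:]:
        if j.grid.shape != grid.shape or not np.allclose(j.grid, grid, atol=0):
            raise ValueError("all experts must share an identical grid")
    n = len(judgements)
    if expert_weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(expert_weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("expert_weights must match the number of experts")
        if np.any(w < 0) or abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError("expert_weights must be non-negative and sum to 1")
    pooled = np.zeros_like(grid)
    for we, j in zip(w, judgements):
        pooled += we * j.weights
    pooled /= pooled.sum()
    return PooledDensity(support=grid, weights=pooled, n_experts=n)


def elicited_mean(density: PooledDensity) -> float:
    """Expected transition probability under the pooled density."""
    return float(density.support @ density.weights)


def sample_transition_prob(
    density: PooledDensity, rng: np.random.Generator, size: int | None = None
):
    """Draw support points with probability equal to their pooled weight."""
    idx = rng.choice(density.support.size, size=size, p=density.weights)
    return density.support[idx]


_LIVING_INDEX = {s: s.value for s in LIVING_STATES}


def build_transition_matrix(
    elicited: Mapping[tuple[HealthState, HealthState], "PooledDensity | float"],
    monthly_death: float,
    mode: str = "mean",
    rng: np.random.Generator | None = None,
) -> TransitionMatrix:
    """Assemble the monthly 4x4 matrix from elicited severity transitions.

    ``elicited`` maps (from, to) pairs of living states to pooled densities
    or fixed probabilities. Missing diagonal entries default to the row
    remainder. Each living row of destination probabilities is renormalized
    to 1 (independent per-question elicitation does not guarantee coherent
    rows) and then scaled by ``1 - monthly_death``, with the remainder
    assigned to the absorbing death state — background mortality competes
    multiplicatively with severity transitions.
    """
    if not 0.0 <= monthly_death <= 1.0:
        raise ValueError("monthly_death must lie in [0, 1]")
    if mode not in ("mean", "sample"):
        raise ValueError("mode must be 'mean' or 'sample'")
    if mode == "sample" and rng is None:
        raise ValueError("mode='sample' requires an rng")

    def resolve(value) -> float:
        if isinstance(value, PooledDensity):
            return elicited_mean(value) if mode == "mean" else float(
                sample_transition_prob(value, rng)
            )
        return float(value)

    m = np.zeros((4, 4))
    for frm in LIVING_STATES:
        row = np.full(3, np.nan)
        for to in LIVING_STATES:
            if (frm, to) in elicited:
                row[_LIVING_INDEX[to]] = resolve(elicited[(frm, to)])
        if np.isnan(row).sum() > 1:
            raise ValueError(
                f"row {frm.name}: at most one living destination may be omitted"
            )
        if np.any(row[~np.isnan(row)] < 0):
            raise ValueError(f"row {frm.name}: negative transition probability")
        if np.isnan(row).any():
            given = np.nansum(row)
            row[np.isnan(row)] = max(0.0, 1.0 - given)
        total = row.sum()
        if total <= 0:
            raise ValueError(f"row {frm.name}: all destination probabilities zero")
        row = row / total
        m[frm.value, :3] = row * (1.0 - monthly_death)
        m[frm.value, HealthState.DEAD.value] = monthly_death
    m[HealthState.DEAD.value, HealthState.DEAD.value] = 1.0
    return TransitionMatrix(m)


def panels_to_frame(panels: Mapping[str, Sequence[ExpertJudgement]]) -> pd.DataFrame:
    """Long-format view of elicitation panels.

    Columns: question_id, expert_id, bin_midpoint, weight.
    """
    rows = []
    for qid in panels:
        for j in panels[qid]:
            for p, w in zip(j.grid, j.weights):
                rows.append((qid, j.expert_id, p, w))
    return pd.DataFrame(
        rows, columns=["question_id", "expert_id", "bin_midpoint", "weight"]
    )


def panels_from_frame(frame: pd.DataFrame) -> dict[str, list[ExpertJudgement]]:
    """Inverse of :func:`panels_to_frame`; preserves row order."""
    panels: dict[str, list[ExpertJudgement]] = {}
    for qid, qdf in frame.groupby("question_id", sort=False):
        panels[qid] = [
            ExpertJudgement(
                expert_id=str(eid),
                grid=edf["bin_midpoint"].to_numpy(),
                weights=edf["weight"].to_numpy(),
            )
            for eid, edf in qdf.groupby("expert_id", sort=False)
        ]
    return panels
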