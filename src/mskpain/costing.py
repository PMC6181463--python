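"""Cost-basket valuation and direct-cost accumulation over the cohort trace.

Each living severity state carries a basket of health resources (medical
visits, pharmacological treatment, physiotherapy, hospitalization). A
basket item contributes unit price x monthly quantity x the fraction of
state occupants who use it. Direct costs accrue per patient-month on the
state occupied at the start of each cycle; costs are valued in 2015 Chilean
pesos and converted to US dollars at purchasing power parity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .states import LIVING_STATES, HealthState
from .cohort import CohortTrace

__all__ = [
    "COST_CATEGORIES",
    "CostItem",
    "CostBasket",
    "CurrencyConfig",
    "state_monthly_cost",
    "expected_direct_cost",
    "to_usd",
    "cost_breakdown",
]

COST_CATEGORIES = ("medical_visit", "pharmacological", "physiotherapy", "hospitalization")


@dataclass(frozen=True)
class CostItem:
    resource: str
    category: str
    unit_price_clp: float
    monthly_quantity: float
    user_fraction: float

    def __post_init__(self) -> None:
        if self.category not in COST_CATEGORIES:
            raise ValueError(
                f"category must be one of {COST_CATEGORIES}, got {self.category!r}"
            )
        if self.unit_price_clp < 0:
            raise ValueError("unit_price_clp must be non-negative")
        if self.monthly_quantity < 0:
            raise ValueError("monthly_quantity must be non-negative")
        if not 0.0 <= self.user_fraction <= 1.0:
            raise ValueError("user_fraction must lie in [0, 1]")

    @property
    def monthly_cost_clp(self) -> float:
        return self.unit_price_clp * self.monthly_quantity * self.user_fraction


@dataclass(frozen=True)
class CostBasket:
    """Resource basket attached to one living severity state."""

    state: HealthState
    items: tuple[CostItem, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.state is HealthState.DEAD:
            raise ValueError("cost baskets attach to living states only")
        object.__setattr__(self, "items", tuple(self.items))


@dataclass(frozen=True)
class CurrencyConfig:
    """PPP conversion; default is the 2015 rate of 394.35 CLP per USD."""

    clp_per_usd: float = 394.35
    reference_year: int = 2015

    def __post_init__(self) -> None:
        if self.clp_per_usd <= 0:
            raise ValueError("clp_per_usd must be positive")


def state_monthly_cost(basket: CostBasket) -> float:
    """Expected management cost per patient-month in the basket's state (CLP)."""
    return float(sum(item.monthly_cost_clp for item in basket.items))


def expected_direct_cost(
    trace: CohortTrace,
    state_costs: Mapping[HealthState, float],
    state_multipliers: Mapping[HealthState, float] | None = None,
) -> float:
    """Total direct cost of a trace in CLP.

    Sums occupancy x per-patient-month state cost over cycles 0..T-1 (cost
    accrues on the state occupied at the start of each cycle). Optional
    ``state_multipliers`` scale the cost-incurring share of a state's
    occupants (used when consultation fractions are read as cost
    multipliers rather than as the severity split).
    """
    missing = [s for s in LIVING_STATES if s not in state_costs]
    if missing:
        raise KeyError(f"missing state costs for {[s.name for s in missing]}")
    costs = np.array([state_costs[s] for s in LIVING_STATES], dtype=float)
    if state_multipliers is not None:
        costs = costs * np.array([state_multipliers.get(s, 1.0) for s in LIVING_STATES])
    occ = trace.occupancy[:-1, :3]  # start-of-cycle living occupancy
    return float((occ * costs).sum())


def to_usd(amount_clp: float, fx: CurrencyConfig) -> float:
    """Convert a CLP amount to USD through the configured PPP rate."""
    return amount_clp / fx.clp_per_usd


def cost_breakdown(
    baskets: Mapping[str, Mapping[HealthState, CostBasket]],
    traces: Mapping[str, CohortTrace],
    state_multipliers: Mapping[str, Mapping[HealthState, float]] | None = None,
) -> dict[str, float]:
    """Share of total direct cost by resource category.

    ``baskets`` maps pathology -> state -> basket, ``traces`` maps pathology
    -> its cohort trace. Shares are non-negative and sum to 1.
    """
    totals = dict.fromkeys(COST_CATEGORIES, 0.0)
    for pathology, trace in traces.items():
        occ = trace.occupancy[:-1, :3]
        patient_months = occ.sum(axis=0)
        for state in LIVING_STATES:
            basket = baskets[pathology].get(state)
            if basket is None:
                continue
            mult = 1.0
            if state_multipliers is not None:
                mult = state_multipliers.get(pathology, {}).get(state, 1.0)
            pm = patient_months[state.value] * mult
            for item in basket.items:
                totals[item.category] += pm * item.monthly_cost_clp
    grand = sum(totals.values())
    if grand == 0:
        return dict.fromkeys(COST_CATEGORIES, 0.0)
    return {cat: totals[cat] / grand for cat in COST_CATEGORIES}
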