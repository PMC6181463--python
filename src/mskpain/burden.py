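"""Burden-of-disease and productivity-loss calculators.

Four consequences of chronic musculoskeletal pain are quantified:

* disability, as years lived with disability (YLD) restricted to the pain
  domain of the disability weight;
* depression attributable to chronic pain, via the population attributable
  fraction (Levin's formula) applied to background depression cases, with
  mild-pain patients excluded from attribution;
* anxiety co-occurring with chronic pain, as proportion x prevalent cases;
* productivity losses under the human capital approach (medical-leave days
  valued at the market wage), of which the health system bears only the
  fraction of leave days it pays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .states import HealthState

__all__ = [
    "BurdenParameters",
    "ProductivityParameters",
    "DEFAULT_DEPRESSION_GATE",
    "yld",
    "paf",
    "attributable_depression",
    "productivity_loss",
]

#: mild pain may co-occur with depression but is not credited as its cause
DEFAULT_DEPRESSION_GATE: Mapping[HealthState, bool] = {
    HealthState.MILD: False,
    HealthState.MODERATE: True,
    HealthState.SEVERE: True,
}


@dataclass(frozen=True)
class BurdenParameters:
    """Per-pathology inputs for the YLD, depression and anxiety calculators.

    ``case_count`` follows the convention flag of the caller: prevalent
    cases over a 1-year frame by default, or incident cases when combined
    with a multi-year duration. Costs per case are annual.
    """

    case_count: float
    duration_years: float
    disability_weight: float
    pain_domain_fraction: float
    depression_exposure_prevalence: float
    depression_relative_risk: float
    depression_background_cases: float
    anxiety_proportion: float
    depression_cost_per_case_clp: float
    anxiety_cost_per_case_clp: float

    def __post_init__(self) -> None:
        if self.case_count < 0 or self.depression_background_cases < 0:
            raise ValueError("case counts must be non-negative")
        if self.duration_years <= 0:
            raise ValueError("duration_years must be positive")
        for name in ("disability_weight", "pain_domain_fraction",
                     "depression_exposure_prevalence", "anxiety_proportion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.depression_relative_risk < 0:
            raise ValueError("depression_relative_risk must be non-negative")
        if self.depression_cost_per_case_clp < 0 or self.anxiety_cost_per_case_clp < 0:
            raise ValueError("per-case costs must be non-negative")


@dataclass(frozen=True)
class ProductivityParameters:
    """Human-capital inputs per pathology.

    ``structural_zero`` marks a pathology whose leave episodes cannot be
    identified at all in the medical-leave database (myofascial syndrome
    has no ICD-10 code); a structural zero is reported as "not estimable",
    distinct from a computed zero.
    """

    leave_episodes: float = 0.0
    mean_days_per_episode: float = 0.0
    daily_wage_clp: float = 0.0
    system_paid_fraction: float = 0.0
    structural_zero: bool = False

    def __post_init__(self) -> None:
        if min(self.leave_episodes, self.mean_days_per_episode, self.daily_wage_clp) < 0:
            raise ValueError("productivity inputs must be non-negative")
        if not 0.0 <= self.system_paid_fraction <= 1.0:
            raise ValueError("system_paid_fraction must lie in [0, 1]")


def yld(
    case_count: float,
    duration_years: float,
    disability_weight: float,
    pain_domain_fraction: float = 1.0,
) -> float:
    """Years lived with disability attributable to the pain domain.

    cases x duration x disability weight x pain-domain adjustment. The
    disability weight spans [0, 1] (0 = perfect health, 1 = health loss
    equivalent to death); the pain-domain fraction restricts it to the
    share of disability carried by pain itself.
    """
    if not 0.0 <= disability_weight <= 1.0:
        raise ValueError("disability_weight must lie in [0, 1]")
    if not 0.0 <= pain_domain_fraction <= 1.0:
        raise ValueError("pain_domain_fraction must lie in [0, 1]")
    if case_count < 0 or duration_years < 0:
        raise ValueError("case_count and duration_years must be non-negative")
    return case_count * duration_years * disability_weight * pain_domain_fraction


def paf(exposure_prevalence: float, relative_risk: float) -> float:
    """Population attributable fraction by Levin's formula.

    ``p(RR-1) / (1 + p(RR-1))``: the share of disease cases avoided if the
    exposure (chronic pain) were absent. Zero when RR = 1; strictly below 1
    for finite RR.
    """
    if not 0.0 <= exposure_prevalence <= 1.0:
        raise ValueError("exposure_prevalence must lie in [0, 1]")
    if relative_risk < 0:
        raise ValueError("relative_risk must be non-negative")
    excess = exposure_prevalence * (relative_risk - 1.0)
    denom = 1.0 + excess
    if denom <= 0:
        raise ValueError(
            "PAF undefined: 1 + p(RR-1) <= 0; with RR < 1 the exposure is "
            "protective and the attributable fraction is not meaningful here"
        )
    return excess / denom


def attributable_depression(
    paf_value: float,
    depression_cases_in_population: "float | Mapping[HealthState, float]",
    severity_gate: Mapping[HealthState, bool] | None = None,
) -> float:
    """Depression cases attributable to chronic pain.

    ``depression_cases_in_population`` is either a scalar of already
    eligible cases or a per-pain-state mapping; the severity gate (mild
    excluded by default) zeroes states whose depression is associated with
    but not attributable to pain.
    """
    if not 0.0 <= paf_value < 1.0:
        raise ValueError("paf_value must lie in [0, 1)")
    gate = DEFAULT_DEPRESSION_GATE if severity_gate is None else severity_gate
    if isinstance(depression_cases_in_population, Mapping):
        eligible = sum(
            count
            for state, count in depression_cases_in_population.items()
            if gate.get(state, False)
        )
    else:
        eligible = float(depression_cases_in_population)
    if eligible < 0:
        raise ValueError("case counts must be non-negative")
    return paf_value * eligible


def productivity_loss(params: ProductivityParameters) -> tuple[float, float] | None:
    """(societal loss, health-system cost) in CLP per year.

    Societal loss = leave episodes x mean days x daily wage; the health
    system bears only the paid fraction of those days. Returns ``None`` for
    a structural zero (loss exists but cannot be estimated), never 0.0.
    """
    if params.structural_zero:
        return None
    societal = params.leave_episodes * params.mean_days_per_episode * params.daily_wage_clp
    return societal, societal * params.system_paid_fraction
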