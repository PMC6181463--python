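"""Synthetic parameter bundles with known ground truth.

The study's parameter table cannot be redistributed, so this module
generates complete, internally consistent stand-ins: six musculoskeletal
pathologies (knee and hip osteoarthritis, lower back pain, chronic shoulder
pain, myofascial syndrome, fibromyalgia) with prevalences, severity splits,
cost baskets, burden and productivity inputs, plus synthetic expert panels
whose elicited transition probabilities are centred on configurable true
values — which makes parameter recovery testable end to end.

Expert histograms are produced by discretizing a beta distribution
moment-matched to (true value, concentration) over the option grid, with
per-expert jitter of the mean drawn from the same beta family, so the
panel-level expectation equals the true value. The option grid is the
``n_bins`` midpoints of an even partition of [0, 1] — a declared
convention, since only the number of options (21) is fixed by the design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .burden import ProductivityParameters
from .bundle import (
    SCHEMA_VERSION,
    TRANSITION_QUESTIONS,
    ParameterBundle,
    PathologyParameters,
)
from .cohort import MortalityParameter
from .costing import CostBasket, CostItem
from .elicitation import ExpertJudgement
from .states import HealthState

__all__ = [
    "DEFAULT_PATHOLOGIES",
    "DEFAULT_TRUE_TRANSITIONS",
    "SyntheticConfig",
    "generate_expert_panel",
    "reference_cost_baskets",
    "generate_parameter_set",
]

DEFAULT_PATHOLOGIES = ("knee_oa", "hip_oa", "lbp", "csp", "mfs", "fm")

#: ground-truth monthly severity transitions used by the default bundle;
#: each living row's stay-put probability is the complement of its exits
DEFAULT_TRUE_TRANSITIONS = {
    "mild_to_moderate": 0.15,
    "mild_to_severe": 0.03,
    "moderate_to_mild": 0.20,
    "moderate_to_severe": 0.10,
    "severe_to_mild": 0.05,
    "severe_to_moderate": 0.25,
}

#: consultation fractions by severity suggested for myofascial syndrome
#: (share of patients who see a specialist at each intensity)
CONSULT_FRACTIONS = (0.075, 0.35, 0.60)

_PPP_CLP_PER_USD = 394.35


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generated bundle.

    Defaults emulate the reference design: 6 pathologies, a 13-expert
    21-bin elicitation panel per transition question, an adult population
    of 13 million, and the published background mortality of 5.1 per 1000
    per year.
    """

    n_pathologies: int = 6
    pathology_names: tuple[str, ...] | None = None
    population_size: int = 13_000_000
    prevalence_range: tuple[float, float] = (0.01, 0.08)
    severity_split_concentration: float = 50.0
    true_transition_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_TRUE_TRANSITIONS)
    )
    mortality_annual_per_1000: float = 5.1
    n_experts: int = 13
    n_bins: int = 21
    expert_concentration: float = 30.0
    cost_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathologies < 1:
            raise ValueError("field 'n_pathologies' must be >= 1")
        names = self.pathology_names
        if names is None:
            if self.n_pathologies <= len(DEFAULT_PATHOLOGIES):
                names = DEFAULT_PATHOLOGIES[: self.n_pathologies]
            else:
                names = DEFAULT_PATHOLOGIES + tuple(
                    f"pathology_{i}"
                    for i in range(len(DEFAULT_PATHOLOGIES), self.n_pathologies)
                )
        names = tuple(names)
        if len(names) != self.n_pathologies:
            raise ValueError(
                "field 'pathology_names' must have n_pathologies entries"
            )
        if len(set(names)) != len(names):
            raise ValueError("field 'pathology_names' must be unique")
        object.__setattr__(self, "pathology_names", names)
        if self.population_size < 0:
            raise ValueError("field 'population_size' must be non-negative")
        lo, hi = self.prevalence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("field 'prevalence_range' must lie within [0, 1]")
        if self.severity_split_concentration <= 0:
            raise ValueError("field 'severity_split_concentration' must be > 0")
        if self.expert_concentration <= 0:
            raise ValueError("field 'expert_concentration' must be > 0")
        for qid, p in self.true_transition_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"field 'true_transition_probs[{qid}]' must lie in [0, 1]"
                )
        if self.n_experts < 1:
            raise ValueError("field 'n_experts' must be >= 1")
        if self.n_bins < 2:
            raise ValueError("field 'n_bins' must be >= 2")
        if self.cost_scale <= 0:
            raise ValueError("field 'cost_scale' must be > 0")
        if self.mortality_annual_per_1000 < 0:
            raise ValueError("field 'mortality_annual_per_1000' must be >= 0")


def _option_grid(n_bins: int) -> np.ndarray:
    return (np.arange(n_bins) + 0.5) / n_bins


def _point_mass(grid: np.ndarray, p: float) -> np.ndarray:
    weights = np.zeros_like(grid)
    weights[int(np.argmin(np.abs(grid - p)))] = 1.0
    return weights


def generate_expert_panel(
    true_p: float,
    n_experts: int = 13,
    n_bins: int = 21,
    concentration: float = 30.0,
    seed: "int | np.random.Generator" = 0,
) -> list[ExpertJudgement]:
    """Synthetic panel of normalized histograms centred on ``true_p``.

    Each expert's mean is jittered around ``true_p`` (beta with the given
    concentration) and their histogram is a discretized beta with that mean
    over the even-midpoint grid. ``concentration=inf`` gives the degenerate
    panel: every expert places mass 1 on the bin containing ``true_p``.
    """
    if not 0.0 <= true_p <= 1.0:
        raise ValueError("true_p must lie in [0, 1]")
    if n_experts < 1 or n_bins < 2:
        raise ValueError("need n_experts >= 1 and n_bins >= 2")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = _option_grid(n_bins)
    edges = np.arange(n_bins + 1) / n_bins

    panel = []
    for e in range(n_experts):
        if math.isinf(concentration) or true_p in (0.0, 1.0):
            weights = _point_mass(grid, true_p)
        else:
            mean_e = rng.beta(true_p * concentration, (1.0 - true_p) * concentration)
            mean_e = min(max(mean_e, 1e-6), 1.0 - 1e-6)
            cdf = stats.beta.cdf(
                edges, mean_e * concentration, (1.0 - mean_e) * concentration
            )
            weights = np.diff(cdf)
            total = weights.sum()
            if total <= 0 or not np.isfinite(total):
                weights = _point_mass(grid, mean_e)
            else:
                weights = weights / total
        panel.append(ExpertJudgement(expert_id=f"expert_{e:02d}", grid=grid, weights=weights))
    return panel


def reference_cost_baskets(
    cost_scale: float = 1.0, clp_per_usd: float = _PPP_CLP_PER_USD
) -> dict[HealthState, CostBasket]:
    """The package's reference per-state monthly cost baskets.

    Designed so that the expected management cost per patient-month is
    63.5 / 101.82 / 734.5 USD for mild / moderate / severe chronic pain at
    the 2015 PPP rate, with the severe basket carrying the 90% emergency
    department visit and the hospitalization admission probability.
    """
    usd = clp_per_usd * cost_scale

    def item(resource, category, price_usd, qty, frac):
        return CostItem(resource, category, price_usd * usd, qty, frac)

    return {
        HealthState.MILD: CostBasket(
            HealthState.MILD,
            (
                item("gp_visit", "medical_visit", 25.0, 1.0, 0.5),
                item("analgesics", "pharmacological", 20.0, 1.0, 1.0),
                item("physio_session", "physiotherapy", 15.5, 2.0, 1.0),
            ),
        ),
        HealthState.MODERATE: CostBasket(
            HealthState.MODERATE,
            (
                item("specialist_visit", "medical_visit", 40.0, 1.0, 0.6),
                item("gp_visit", "medical_visit", 25.0, 1.0, 0.4),
                item("pain_medication", "pharmacological", 32.82, 1.0, 1.0),
                item("physio_session", "physiotherapy", 17.5, 2.0, 1.0),
            ),
        ),
        HealthState.SEVERE: CostBasket(
            HealthState.SEVERE,
            (
                item("emergency_visit", "medical_visit", 120.0, 1.0, 0.9),
                item("specialist_visit", "medical_visit", 40.0, 2.0, 1.0),
                item("opioid_treatment", "pharmacological", 60.0, 1.0, 1.0),
                item("physio_session", "physiotherapy", 22.0, 6.0, 1.0),
                item("hospital_admission", "hospitalization", 1418.0, 1.0, 0.25),
            ),
        ),
    }


# Per-pathology burden/productivity defaults (synthetic stand-ins for the
# unpublished survey-derived inputs; osteoarthritis RR = 1 encodes the
# assumption that its depression attributable fraction is zero).
_BURDEN_DEFAULTS = {
    #            dw    pain_fr  rr    anx_prop
    "knee_oa": (0.13, 0.80, 1.0, 0.04),
    "hip_oa": (0.13, 0.80, 1.0, 0.03),
    "lbp": (0.20, 0.75, 2.0, 0.06),
    "csp": (0.11, 0.70, 1.8, 0.05),
    "mfs": (0.10, 0.85, 1.6, 0.04),
    "fm": (0.12, 0.60, 2.5, 0.08),
}
_GENERIC_BURDEN = (0.12, 0.70, 1.8, 0.05)

_PRODUCTIVITY_DEFAULTS = {
    #            episodes/yr  days  structural_zero
    "knee_oa": (10_000.0, 7.0, False),
    "hip_oa": (4_000.0, 7.0, False),
    "lbp": (30_000.0, 7.0, False),
    "csp": (8_000.0, 6.0, False),
    "mfs": (0.0, 0.0, True),  # not identifiable by ICD-10 code
    "fm": (6_000.0, 9.0, False),
}
_GENERIC_PRODUCTIVITY = (5_000.0, 7.0, False)

_DAILY_WAGE_CLP = 25_000.0
_SYSTEM_PAID_FRACTION = 0.7
_DEPRESSION_PREVALENCE = 0.17  # national background depression prevalence
_DEPRESSION_COST_PER_CASE_USD = 420.0
_ANXIETY_COST_PER_CASE_USD = 260.0
_BASE_SEVERITY_MEAN = np.array([0.45, 0.40, 0.15])


def generate_parameter_set(config: SyntheticConfig) -> ParameterBundle:
    """Generate the full model input bundle for the configured conditions.

    The same seed always yields the same bundle (and, through
    ``ParameterBundle.to_dir``, byte-identical files). Severity splits are
    Dirichlet draws around a common mean, except myofascial syndrome whose
    split defaults to the normalized consultation fractions because it was
    absent from the severity survey.
    """
    rng = np.random.default_rng(config.seed)
    names = config.pathology_names

    prevalences = rng.uniform(*config.prevalence_range, size=len(names))
    kappa = config.severity_split_concentration
    splits = rng.dirichlet(_BASE_SEVERITY_MEAN * kappa, size=len(names))
    baskets = reference_cost_baskets(config.cost_scale)

    pathologies: dict[str, PathologyParameters] = {}
    for i, name in enumerate(names):
        dw, pain_fr, rr, anx = _BURDEN_DEFAULTS.get(name, _GENERIC_BURDEN)
        episodes, days, structural = _PRODUCTIVITY_DEFAULTS.get(
            name, _GENERIC_PRODUCTIVITY
        )
        split = splits[i]
        if name == "mfs":
            consult = np.asarray(CONSULT_FRACTIONS)
            split = consult / consult.sum()
        split = split / split.sum()
        pathologies[name] = PathologyParameters(
            name=name,
            prevalence=float(prevalences[i]),
            severity_split=tuple(split),
            baskets=baskets,
            duration_years=1.0,
            disability_weight=dw,
            pain_domain_fraction=pain_fr,
            depression_relative_risk=rr,
            depression_background_cases=config.population_size
            * _DEPRESSION_PREVALENCE,
            anxiety_proportion=anx,
            depression_cost_per_case_clp=_DEPRESSION_COST_PER_CASE_USD
            * _PPP_CLP_PER_USD,
            anxiety_cost_per_case_clp=_ANXIETY_COST_PER_CASE_USD * _PPP_CLP_PER_USD,
            productivity=ProductivityParameters(
                leave_episodes=0.0 if structural else episodes,
                mean_days_per_episode=0.0 if structural else days,
                daily_wage_clp=0.0 if structural else _DAILY_WAGE_CLP,
                system_paid_fraction=0.0 if structural else _SYSTEM_PAID_FRACTION,
                structural_zero=structural,
            ),
        )

    panels = {
        qid: generate_expert_panel(
            config.true_transition_probs[qid],
            n_experts=config.n_experts,
            n_bins=config.n_bins,
            concentration=config.expert_concentration,
            seed=rng,
        )
        for qid in TRANSITION_QUESTIONS
        if qid in config.true_transition_probs
    }

    scenario_defaults = {
        "horizon_cycles": 12,
        "undiagnosed_mild": 0.5,
        "undiagnosed_moderate": 0.25,
        "consult_fractions": list(CONSULT_FRACTIONS),
        "mfs_split_mode": "normalized_consult",
        "clp_per_usd": _PPP_CLP_PER_USD,
    }
    meta = {
        "schema_version": SCHEMA_VERSION,
        "generator": "mskpain.synthetic.generate_parameter_set",
        "seed": config.seed,
        "n_experts": config.n_experts,
        "n_bins": config.n_bins,
        "expert_concentration": config.expert_concentration,
        "true_transition_probs": dict(config.true_transition_probs),
    }
    return ParameterBundle(
        population_size=config.population_size,
        mortality=MortalityParameter(config.mortality_annual_per_1000),
        pathologies=pathologies,
        panels=panels,
        scenario_defaults=scenario_defaults,
        meta=meta,
    )
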