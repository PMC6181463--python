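"""The cost-consequence model and its fitted results.

:class:`CostConsequenceModel` binds a parameter bundle to a scenario and
exposes the full pipeline — severity-state Markov trace, direct costs,
YLDs, attributable depression, anxiety, productivity losses — as a single
evaluation. ``fit()`` runs the probabilistic sensitivity analysis and
returns a :class:`CostConsequenceResults` carrying point estimates,
Monte Carlo samples and 95% Bayesian credibility intervals per outcome,
with a statsmodels-style ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import burden as burden_mod
from .bundle import ParameterBundle, question_states, validate_bundle
from .cohort import (
    CohortTrace,
    PathologyCohort,
    initial_state_vector,
    run_cohort,
)
from .costing import (
    CurrencyConfig,
    cost_breakdown,
    expected_direct_cost,
    state_monthly_cost,
    to_usd,
)
from .elicitation import pool_judgements
from .states import LIVING_STATES, HealthState
from .uncertainty import (
    Distribution,
    PSAConfig,
    PSAResult,
    beta_from_mean_sd,
    gamma_from_mean_sd,
    one_way_sa,
    run_psa,
)

__all__ = ["ScenarioConfig", "CostConsequenceModel", "CostConsequenceResults"]

#: relative spread assigned to cost-like (gamma) and proportion-like (beta)
#: parameters when moment-matching their PSA distributions
_GAMMA_CV = 0.20
_BETA_CV = 0.10
_SPLIT_CONCENTRATION = 100.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario policy layered over a bundle.

    ``name='undiagnosed'`` activates the reduced-diagnosis scenario in
    which the configured fractions of mild and moderate cases never enter
    the cost-incurring cohort (severe pain is always diagnosed).
    ``mfs_split_mode`` selects how the myofascial-syndrome consultation
    fractions are read: as its normalized severity split (default) or as
    cost-incurring multipliers on state occupancy.
    """

    name: str = "base"
    horizon_cycles: int = 12
    undiagnosed_fractions: tuple[float, float] = (0.5, 0.25)
    mfs_split_mode: str = "normalized_consult"
    consult_fractions: tuple[float, float, float] = (0.075, 0.35, 0.60)
    currency: CurrencyConfig = field(default_factory=CurrencyConfig)
    gdp_denominator_usd: float | None = None

    def __post_init__(self) -> None:
        if self.name not in ("base", "undiagnosed"):
            raise ValueError("scenario name must be 'base' or 'undiagnosed'")
        if self.horizon_cycles < 1:
            raise ValueError("horizon_cycles must be >= 1")
        for v in self.undiagnosed_fractions + self.consult_fractions:
            if not 0.0 <= v <= 1.0:
                raise ValueError("scenario proportions must lie in [0, 1]")
        if self.mfs_split_mode not in ("normalized_consult", "multiplier"):
            raise ValueError(
                "mfs_split_mode must be 'normalized_consult' or 'multiplier'"
            )
        if self.gdp_denominator_usd is not None and self.gdp_denominator_usd <= 0:
            raise ValueError("gdp_denominator_usd must be positive when given")

    @property
    def diagnosed_fractions(self) -> tuple[float, float, float]:
        if self.name == "undiagnosed":
            mild, moderate = self.undiagnosed_fractions
            return (1.0 - mild, 1.0 - moderate, 1.0)
        return (1.0, 1.0, 1.0)


class CostConsequenceModel:
    """Markov cohort cost-consequence model over one parameter bundle."""

    def __init__(self, bundle: ParameterBundle, scenario: ScenarioConfig | None = None):
        problems = validate_bundle(bundle)
        if problems:
            raise ValueError("invalid bundle: " + "; ".join(problems))
        self.bundle = bundle
        self.scenario = scenario or ScenarioConfig()
        self.pooled = {
            qid: pool_judgements(panel) for qid, panel in bundle.panels.items()
        }
        self._distributions = self._build_distribution_map()

    @classmethod
    def from_bundle_dir(
        cls, path: str | Path, scenario: ScenarioConfig | None = None
    ) -> "CostConsequenceModel":
        return cls(ParameterBundle.from_dir(path), scenario)

    # ------------------------------------------------------------ parameters

    @property
    def distributions(self) -> dict[str, Distribution]:
        """PSA distribution per parameter id (a copy; edit and pass to fit)."""
        return dict(self._distributions)

    @property
    def param_means(self) -> dict[str, Any]:
        return {name: d.mean() for name, d in self._distributions.items()}

    def _build_distribution_map(self) -> dict[str, Distribution]:
        dists: dict[str, Distribution] = {
            f"transition.{qid}": Distribution(
                "empirical_pooled", {"density": density}
            )
            for qid, density in self.pooled.items()
        }
        dists["mortality.monthly"] = Distribution(
            "fixed", {"value": self.bundle.mortality.monthly_probability}
        )
        for name, p in self.bundle.pathologies.items():
            dists[f"{name}.prevalence"] = beta_from_mean_sd(
                p.prevalence, _BETA_CV * p.prevalence
            )
            dists[f"{name}.severity_split"] = Distribution(
                "dirichlet",
                {"alpha": np.asarray(p.severity_split) * _SPLIT_CONCENTRATION},
            )
            for state, basket in p.baskets.items():
                for item in basket.items:
                    dists[f"{name}.cost.{state.name.lower()}.{item.resource}"] = (
                        gamma_from_mean_sd(
                            item.unit_price_clp, _GAMMA_CV * item.unit_price_clp
                        )
                    )
            dists[f"{name}.disability_weight"] = beta_from_mean_sd(
                p.disability_weight, _BETA_CV * p.disability_weight
            )
            dists[f"{name}.pain_domain_fraction"] = beta_from_mean_sd(
                p.pain_domain_fraction, _BETA_CV * p.pain_domain_fraction
            )
            if p.depression_relative_risk == 1.0:
                # attributable fraction assumed structurally zero (OA)
                dists[f"{name}.depression_rr"] = Distribution("fixed", {"value": 1.0})
            else:
                dists[f"{name}.depression_rr"] = gamma_from_mean_sd(
                    p.depression_relative_risk,
                    _BETA_CV * p.depression_relative_risk,
                )
            dists[f"{name}.depression_background_cases"] = Distribution(
                "fixed", {"value": p.depression_background_cases}
            )
            dists[f"{name}.anxiety_proportion"] = beta_from_mean_sd(
                p.anxiety_proportion, _BETA_CV * p.anxiety_proportion
            )
            dists[f"{name}.depression_cost_per_case"] = gamma_from_mean_sd(
                p.depression_cost_per_case_clp,
                _GAMMA_CV * p.depression_cost_per_case_clp,
            )
            dists[f"{name}.anxiety_cost_per_case"] = gamma_from_mean_sd(
                p.anxiety_cost_per_case_clp, _GAMMA_CV * p.anxiety_cost_per_case_clp
            )
            prod = p.productivity
            if prod.structural_zero:
                for pid in ("leave_episodes", "leave_days", "daily_wage",
                            "paid_fraction"):
                    dists[f"{name}.{pid}"] = Distribution("fixed", {"value": 0.0})
            else:
                dists[f"{name}.leave_episodes"] = gamma_from_mean_sd(
                    prod.leave_episodes, _GAMMA_CV * prod.leave_episodes
                )
                dists[f"{name}.leave_days"] = gamma_from_mean_sd(
                    prod.mean_days_per_episode,
                    _GAMMA_CV * prod.mean_days_per_episode,
                )
                dists[f"{name}.daily_wage"] = gamma_from_mean_sd(
                    prod.daily_wage_clp, _GAMMA_CV * prod.daily_wage_clp
                )
                dists[f"{name}.paid_fraction"] = beta_from_mean_sd(
                    prod.system_paid_fraction, _BETA_CV * prod.system_paid_fraction
                )
        return dists

    # ------------------------------------------------------------ evaluation

    def _transition_matrix(self, params: Mapping[str, Any]):
        from .elicitation import build_transition_matrix

        elicited = {
            question_states(qid): float(params[f"transition.{qid}"])
            for qid in self.pooled
        }
        return build_transition_matrix(elicited, float(params["mortality.monthly"]))

    def _mfs_multipliers(self, name: str) -> dict[HealthState, float] | None:
        if name == "mfs" and self.scenario.mfs_split_mode == "multiplier":
            return dict(zip(LIVING_STATES, self.scenario.consult_fractions))
        return None

    def cohort_traces(
        self, params: Mapping[str, Any] | None = None
    ) -> dict[str, CohortTrace]:
        params = self.param_means if params is None else params
        matrix = self._transition_matrix(params)
        diagnosed = self.scenario.diagnosed_fractions
        traces = {}
        for name in self.bundle.pathologies:
            prevalent = float(params[f"{name}.prevalence"]) * self.bundle.population_size
            split = np.asarray(params[f"{name}.severity_split"], dtype=float)
            cohort = PathologyCohort(name, prevalent, tuple(split / split.sum()),
                                     diagnosed)
            traces[name] = run_cohort(
                initial_state_vector(cohort),
                matrix,
                self.scenario.horizon_cycles,
                pathology=name,
            )
        return traces

    def evaluate(self, params: Mapping[str, Any] | None = None) -> dict[str, float]:
        """Run the full pipeline once; outcomes keyed by label.

        Monetary outcomes are reported in both CLP and USD (they agree
        exactly through the configured PPP rate). Structural zeros
        (myofascial productivity) contribute nothing and are reported as
        NaN in :meth:`consequences`, never as a computed 0.
        """
        params = self.param_means if params is None else params
        fx = self.scenario.currency
        matrix = self._transition_matrix(params)
        diagnosed = self.scenario.diagnosed_fractions

        out: dict[str, float] = {}
        agg = dict.fromkeys(
            ("direct_clp", "dep_clp", "anx_clp", "prod_societal_clp",
             "prod_system_clp", "yld", "dep_cases", "anx_cases"), 0.0
        )
        for name, p in self.bundle.pathologies.items():
            prevalent = float(params[f"{name}.prevalence"]) * self.bundle.population_size
            split = np.asarray(params[f"{name}.severity_split"], dtype=float)
            split = split / split.sum()
            cohort = PathologyCohort(name, prevalent, tuple(split), diagnosed)
            trace = run_cohort(
                initial_state_vector(cohort), matrix, self.scenario.horizon_cycles,
                pathology=name,
            )
            state_costs = {
                state: sum(
                    float(params[f"{name}.cost.{state.name.lower()}.{item.resource}"])
                    * item.monthly_quantity
                    * item.user_fraction
                    for item in p.baskets[state].items
                )
                for state in LIVING_STATES
                if state in p.baskets
            }
            direct_clp = expected_direct_cost(
                trace, state_costs, self._mfs_multipliers(name)
            )

            yld_p = burden_mod.yld(
                prevalent,
                p.duration_years,
                float(params[f"{name}.disability_weight"]),
                float(params[f"{name}.pain_domain_fraction"]),
            )
            exposure = min(
                1.0, float(params[f"{name}.prevalence"]) * (split[1] + split[2])
            )
            paf_p = burden_mod.paf(
                exposure, float(params[f"{name}.depression_rr"])
            )
            dep_cases = burden_mod.attributable_depression(
                paf_p, float(params[f"{name}.depression_background_cases"])
            )
            dep_clp = dep_cases * float(params[f"{name}.depression_cost_per_case"])
            anx_cases = float(params[f"{name}.anxiety_proportion"]) * prevalent
            anx_clp = anx_cases * float(params[f"{name}.anxiety_cost_per_case"])

            if p.productivity.structural_zero:
                prod_societal_clp = prod_system_clp = 0.0
            else:
                prod_societal_clp = (
                    float(params[f"{name}.leave_episodes"])
                    * float(params[f"{name}.leave_days"])
                    * float(params[f"{name}.daily_wage"])
                )
                prod_system_clp = prod_societal_clp * float(
                    params[f"{name}.paid_fraction"]
                )

            total_clp = direct_clp + dep_clp + anx_clp + prod_system_clp
            out[f"direct_cost_usd.{name}"] = to_usd(direct_clp, fx)
            out[f"total_cost_usd.{name}"] = to_usd(total_clp, fx)
            out[f"yld.{name}"] = yld_p

            agg["direct_clp"] += direct_clp
            agg["dep_clp"] += dep_clp
            agg["anx_clp"] += anx_clp
            agg["prod_societal_clp"] += prod_societal_clp
            agg["prod_system_clp"] += prod_system_clp
            agg["yld"] += yld_p
            agg["dep_cases"] += dep_cases
            agg["anx_cases"] += anx_cases

        total_clp = (
            agg["direct_clp"] + agg["dep_clp"] + agg["anx_clp"] + agg["prod_system_clp"]
        )
        out["direct_cost_clp"] = agg["direct_clp"]
        out["direct_cost_usd"] = to_usd(agg["direct_clp"], fx)
        out["depression_cost_usd"] = to_usd(agg["dep_clp"], fx)
        out["anxiety_cost_usd"] = to_usd(agg["anx_clp"], fx)
        out["productivity_societal_usd"] = to_usd(agg["prod_societal_clp"], fx)
        out["productivity_system_cost_usd"] = to_usd(agg["prod_system_clp"], fx)
        out["total_cost_clp"] = total_clp
        out["total_cost_usd"] = to_usd(total_clp, fx)
        out["yld_total"] = agg["yld"]
        out["depression_cases"] = agg["dep_cases"]
        out["anxiety_cases"] = agg["anx_cases"]
        if self.scenario.gdp_denominator_usd is not None:
            out["cost_gdp_share_pct"] = (
                100.0 * out["total_cost_usd"] / self.scenario.gdp_denominator_usd
            )
        return out

    # ---------------------------------------------------------- consequences

    def consequences(self, params: Mapping[str, Any] | None = None) -> pd.DataFrame:
        """Tidy per-pathology consequence table.

        Columns: pathology, consequence, cases, ylds, cost_usd,
        structural_zero. A structural zero carries NaN cases/cost with the
        flag set, distinguishing "not estimable" from a computed zero.
        """
        params = self.param_means if params is None else params
        fx = self.scenario.currency
        rows = []
        for name, p in self.bundle.pathologies.items():
            prevalent = float(params[f"{name}.prevalence"]) * self.bundle.population_size
            split = np.asarray(params[f"{name}.severity_split"], dtype=float)
            split = split / split.sum()
            yld_p = burden_mod.yld(
                prevalent, p.duration_years,
                float(params[f"{name}.disability_weight"]),
                float(params[f"{name}.pain_domain_fraction"]),
            )
            rows.append((name, "disability", prevalent, yld_p, np.nan, False))
            exposure = min(1.0, float(params[f"{name}.prevalence"]) * (split[1] + split[2]))
            paf_p = burden_mod.paf(exposure, float(params[f"{name}.depression_rr"]))
            dep_cases = burden_mod.attributable_depression(
                paf_p, float(params[f"{name}.depression_background_cases"])
            )
            rows.append(
                (name, "depression", dep_cases,
                 np.nan,
                 to_usd(dep_cases * float(params[f"{name}.depression_cost_per_case"]), fx),
                 False)
            )
            anx_cases = float(params[f"{name}.anxiety_proportion"]) * prevalent
            rows.append(
                (name, "anxiety", anx_cases, np.nan,
                 to_usd(anx_cases * float(params[f"{name}.anxiety_cost_per_case"]), fx),
                 False)
            )
            loss = burden_mod.productivity_loss(p.productivity)
            if loss is None:
                rows.append((name, "productivity", np.nan, np.nan, np.nan, True))
            else:
                societal_clp = (
                    float(params[f"{name}.leave_episodes"])
                    * float(params[f"{name}.leave_days"])
                    * float(params[f"{name}.daily_wage"])
                )
                system_clp = societal_clp * float(params[f"{name}.paid_fraction"])
                rows.append(
                    (name, "productivity",
                     float(params[f"{name}.leave_episodes"]),
                     np.nan, to_usd(system_clp, fx), False)
                )
        return pd.DataFrame(
            rows,
            columns=["pathology", "consequence", "cases", "ylds", "cost_usd",
                     "structural_zero"],
        )

    def cost_breakdown(self, params: Mapping[str, Any] | None = None) -> dict[str, float]:
        """Direct-cost shares by resource category at the given parameters."""
        traces = self.cohort_traces(params)
        baskets = {name: p.baskets for name, p in self.bundle.pathologies.items()}
        multipliers = {
            name: m
            for name in self.bundle.pathologies
            if (m := self._mfs_multipliers(name)) is not None
        }
        return cost_breakdown(baskets, traces, multipliers or None)

    # ------------------------------------------------------------------- fit

    def fit(
        self,
        n_iterations: int = 5000,
        seed: int = 0,
        credibility_level: float = 0.95,
    ) -> "CostConsequenceResults":
        """Probabilistic sensitivity analysis over all uncertain parameters."""
        config = PSAConfig(
            n_iterations=n_iterations,
            credibility_level=credibility_level,
            seed=seed,
            distribution_map=self._distributions,
        )
        psa = run_psa(self.evaluate, config)
        return CostConsequenceResults(model=self, psa=psa, psa_config=config)

    def one_way(
        self, parameter_id: str, low: float | None = None, high: float | None = None
    ) -> dict[str, tuple[float, float, float]]:
        """One-way deterministic sensitivity analysis on one parameter.

        Bounds default to +/-20% of the base value. Vector-valued
        parameters (severity splits) are not supported one-way.
        """
        if parameter_id not in self._distributions:
            raise KeyError(f"unknown parameter {parameter_id!r}")
        base = self.param_means
        if np.ndim(base[parameter_id]) != 0:
            raise ValueError(f"{parameter_id} is vector-valued; vary components instead")
        value = float(base[parameter_id])
        if low is None:
            low = 0.8 * value
        if high is None:
            high = min(1.2 * value, 1.0) if value <= 1.0 else 1.2 * value
        if not low <= value <= high:
            raise ValueError("need low <= base <= high")
        return one_way_sa(self.evaluate, base, parameter_id, low, high)

    def tornado(
        self, parameter_ids: list[str] | None = None, outcome: str = "total_cost_usd"
    ) -> pd.DataFrame:
        """One-way swings of ``outcome`` for a set of scalar parameters."""
        if parameter_ids is None:
            parameter_ids = [
                pid
                for pid, d in self._distributions.items()
                if d.family not in ("dirichlet", "fixed")
            ]
        rows = []
        for pid in parameter_ids:
            res = self.one_way(pid)[outcome]
            rows.append((pid, res[0], res[1], res[2], abs(res[2] - res[0])))
        frame = pd.DataFrame(
            rows, columns=["parameter", "outcome_low", "outcome_base",
                           "outcome_high", "swing"]
        )
        return frame.sort_values("swing", ascending=False, ignore_index=True)


@dataclass(frozen=True)
class CostConsequenceResults:
    """PSA-fitted results: point estimates, samples, credibility intervals."""

    model: CostConsequenceModel
    psa: Mapping[str, PSAResult]
    psa_config: PSAConfig

    @property
    def point_estimates(self) -> dict[str, float]:
        return {label: r.point_estimate for label, r in self.psa.items()}

    def summary(self) -> pd.DataFrame:
        """outcome, point estimate, sample mean, and the equal-tailed BCI."""
        rows = [
            (label, r.point_estimate, r.mean_of_samples, r.bci_low, r.bci_high)
            for label, r in self.psa.items()
        ]
        return pd.DataFrame(
            rows, columns=["outcome", "point", "mean", "bci_low", "bci_high"]
        )

    def samples_frame(self) -> pd.DataFrame:
        """Long format: outcome, iteration, value."""
        frames = [
            pd.DataFrame(
                {
                    "outcome": label,
                    "iteration": np.arange(r.samples.size),
                    "value": r.samples,
                }
            )
            for label, r in self.psa.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def __str__(self) -> str:
        level = self.psa_config.credibility_level
        head = (
            f"Cost-consequence model ({self.model.scenario.name} scenario), "
            f"{self.psa_config.n_iterations} PSA iterations, "
            f"{level:.0%} credibility intervals\n"
        )
        table = self.summary()
        main = table[~table["outcome"].str.contains(r"\.", regex=True)]
        return head + main.to_string(index=False, float_format=lambda v: f"{v:,.2f}")

    def plot_outcome(self, outcome: str = "total_cost_usd", ax=None):
        """Histogram of an outcome's PSA samples with its BCI marked."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        r = self.psa[outcome]
        ax.hist(r.samples, bins=50, color="#4878d0", alpha=0.8)
        ax.axvline(r.point_estimate, color="black", lw=1.5, label="point estimate")
        ax.axvline(r.bci_low, color="firebrick", ls="--", label="BCI")
        ax.axvline(r.bci_high, color="firebrick", ls="--")
        ax.set_xlabel(outcome)
        ax.set_ylabel("iterations")
        ax.legend(frameon=False)
        return ax
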