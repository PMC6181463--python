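"""The end-to-end model object: point evaluation, scenarios, PSA, one-way."""

import numpy as np
import pandas as pd
import pytest

from mskpain.model import CostConsequenceModel, ScenarioConfig
from mskpain.report import percent_decrease


@pytest.fixture(scope="module")
def base_model(default_bundle):
    return CostConsequenceModel(default_bundle)


@pytest.fixture(scope="module")
def point(base_model):
    return base_model.evaluate()


class TestPointEvaluation:
    def test_outcomes_finite_and_positive(self, point):
        for label in ("total_cost_usd", "direct_cost_usd", "yld_total",
                      "depression_cases", "anxiety_cases"):
            assert np.isfinite(point[label])
            assert point[label] > 0

    def test_total_is_sum_of_components(self, point):
        total = (
            point["direct_cost_usd"]
            + point["depression_cost_usd"]
            + point["anxiety_cost_usd"]
            + point["productivity_system_cost_usd"]
        )
        assert point["total_cost_usd"] == pytest.approx(total, rel=1e-12)

    def test_clp_and_usd_agree_through_ppp_rate(self, point, base_model):
        rate = base_model.scenario.currency.clp_per_usd
        assert point["total_cost_clp"] / rate == pytest.approx(
            point["total_cost_usd"], rel=1e-12
        )
        assert point["direct_cost_clp"] / rate == pytest.approx(
            point["direct_cost_usd"], rel=1e-12
        )

    def test_per_pathology_components_sum_to_totals(self, point, base_model):
        names = base_model.bundle.pathologies
        assert sum(point[f"direct_cost_usd.{n}"] for n in names) == pytest.approx(
            point["direct_cost_usd"], rel=1e-12
        )
        assert sum(point[f"yld.{n}"] for n in names) == pytest.approx(
            point["yld_total"], rel=1e-12
        )

    def test_oa_contributes_no_attributable_depression(self, base_model):
        table = base_model.consequences()
        dep = table[table["consequence"] == "depression"].set_index("pathology")
        assert dep.loc["knee_oa", "cases"] == 0.0
        assert dep.loc["hip_oa", "cases"] == 0.0
        assert dep.loc["lbp", "cases"] > 0.0

    def test_mfs_productivity_reported_as_structural_zero(self, base_model):
        table = base_model.consequences()
        prod = table[table["consequence"] == "productivity"].set_index("pathology")
        assert bool(prod.loc["mfs", "structural_zero"])
        assert np.isnan(prod.loc["mfs", "cost_usd"])
        assert not bool(prod.loc["lbp", "structural_zero"])
        assert prod.loc["lbp", "cost_usd"] > 0

    def test_breakdown_shares_sum_to_one(self, base_model):
        shares = base_model.cost_breakdown()
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_gdp_share_present_only_when_configured(self, default_bundle, point):
        assert "cost_gdp_share_pct" not in point
        with_gdp = CostConsequenceModel(
            default_bundle, ScenarioConfig(gdp_denominator_usd=250e9)
        ).evaluate()
        assert with_gdp["cost_gdp_share_pct"] == pytest.approx(
            100 * with_gdp["total_cost_usd"] / 250e9
        )


class TestScenarios:
    def test_undiagnosed_scenario_reduces_costs(self, default_bundle, point):
        undx = CostConsequenceModel(
            default_bundle, ScenarioConfig(name="undiagnosed")
        ).evaluate()
        assert undx["direct_cost_usd"] < point["direct_cost_usd"]
        assert undx["total_cost_usd"] < point["total_cost_usd"]
        # burden consequences are computed on the full prevalent cohort
        assert undx["yld_total"] == pytest.approx(point["yld_total"])

    def test_diagnosed_fractions(self):
        assert ScenarioConfig(name="undiagnosed").diagnosed_fractions == (
            0.5, 0.75, 1.0
        )
        assert ScenarioConfig().diagnosed_fractions == (1.0, 1.0, 1.0)

    def test_published_totals_scenario_arithmetic(self):
        """The printed annual totals imply a 21% decrease at integer rounding."""
        assert round(percent_decrease(1387.2, 1095.89)) == 21

    def test_mfs_multiplier_mode_reduces_mfs_cost(self, default_bundle, point):
        mult = CostConsequenceModel(
            default_bundle, ScenarioConfig(mfs_split_mode="multiplier")
        ).evaluate()
        assert mult["direct_cost_usd.mfs"] < point["direct_cost_usd.mfs"]
        assert mult["direct_cost_usd.lbp"] == pytest.approx(
            point["direct_cost_usd.lbp"]
        )


class TestOneWayAndTornado:
    def test_mortality_increase_never_increases_direct_cost(self, base_model):
        lo, base, hi = base_model.one_way(
            "mortality.monthly", 0.0, 0.01
        )["direct_cost_usd"]
        assert lo >= base >= hi

    def test_state_cost_moves_outcome_linearly(self, base_model):
        pid = "lbp.cost.severe.emergency_visit"
        value = base_model.param_means[pid]
        lo, base, hi = base_model.one_way(pid, 0.5 * value, 1.5 * value)[
            "direct_cost_usd"
        ]
        assert hi - base == pytest.approx(base - lo, rel=1e-9)

    def test_tornado_sorted_by_swing(self, base_model):
        frame = base_model.tornado(
            ["mortality.monthly", "lbp.prevalence", "lbp.disability_weight"][1:],
            outcome="total_cost_usd",
        )
        assert list(frame.columns) == [
            "parameter", "outcome_low", "outcome_base", "outcome_high", "swing"
        ]
        assert frame["swing"].is_monotonic_decreasing

    def test_unknown_parameter_rejected(self, base_model):
        with pytest.raises(KeyError):
            base_model.one_way("nonexistent.parameter")


@pytest.fixture(scope="module")
def fitted(base_model):
    return base_model.fit(n_iterations=300, seed=7)


class TestFit:
    def test_same_seed_reproduces_samples(self, base_model, fitted):
        again = base_model.fit(n_iterations=300, seed=7)
        for label in fitted.psa:
            np.testing.assert_array_equal(
                fitted.psa[label].samples, again.psa[label].samples
            )

    def test_bci_brackets_sample_mean(self, fitted):
        for r in fitted.psa.values():
            assert r.bci_low <= r.mean_of_samples <= r.bci_high

    def test_summary_table_structure(self, fitted):
        table = fitted.summary()
        assert list(table.columns) == ["outcome", "point", "mean", "bci_low",
                                       "bci_high"]
        assert "total_cost_usd" in set(table["outcome"])
        assert (table["bci_low"] <= table["bci_high"]).all()

    def test_str_summary_mentions_headline_outcome(self, fitted):
        assert "total_cost_usd" in str(fitted)

    def test_samples_frame_long_format(self, fitted):
        frame = fitted.samples_frame()
        assert list(frame.columns) == ["outcome", "iteration", "value"]
        assert frame.groupby("outcome").size().eq(300).all()

    def test_plot_outcome_returns_axis(self, fitted):
        ax = fitted.plot_outcome("total_cost_usd")
        assert ax.get_xlabel() == "total_cost_usd"


def test_invalid_bundle_rejected_at_construction(default_bundle):
    import dataclasses

    broken = dataclasses.replace(default_bundle, panels={"mild_to_moderate": []})
    with pytest.raises(ValueError, match="invalid bundle"):
        CostConsequenceModel(broken)
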