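"""Mortality conversion, initial allocation, and the cohort trace."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mskpain.cohort import (
    MortalityParameter,
    PathologyCohort,
    annual_rate_to_monthly_prob,
    annual_to_monthly_prob,
    apply_undiagnosed_scenario,
    initial_state_vector,
    run_cohort,
)
from mskpain.states import HealthState, TransitionMatrix


class TestMortalityConversion:
    def test_zero_maps_to_zero(self):
        assert annual_to_monthly_prob(0.0) == 0.0
        assert annual_rate_to_monthly_prob(0.0) == 0.0

    def test_probability_form_high_precision(self):
        # 1 - 0.88**(1/12)
        assert annual_to_monthly_prob(0.12) == pytest.approx(
            0.010596241035318976, abs=1e-15
        )

    def test_published_rate_converts_to_042_per_1000(self):
        """5.1 deaths per 1000 person-years -> 0.42 per 1000 per month."""
        monthly = MortalityParameter(5.1).monthly_probability
        assert round(monthly * 1000, 2) == 0.42

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_probability_form_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert annual_to_monthly_prob(lo) <= annual_to_monthly_prob(hi)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            annual_to_monthly_prob(1.2)
        with pytest.raises(ValueError):
            annual_rate_to_monthly_prob(-0.1)
        with pytest.raises(ValueError):
            MortalityParameter(-1.0)


class TestInitialAllocation:
    @pytest.mark.parametrize(
        "count,split,diagnosed,expected",
        [
            (1000, (0.5, 0.3, 0.2), (1, 1, 1), (500, 300, 200, 0)),
            (1000, (0.5, 0.3, 0.2), (0.5, 0.75, 1.0), (250, 225, 200, 0)),
            (0, (0.5, 0.3, 0.2), (1, 1, 1), (0, 0, 0, 0)),
        ],
    )
    def test_allocation_arithmetic(self, count, split, diagnosed, expected):
        cohort = PathologyCohort("x", count, split, diagnosed)
        np.testing.assert_allclose(initial_state_vector(cohort), expected)

    def test_undiagnosed_count_reported_separately(self):
        cohort = PathologyCohort("x", 1000, (0.5, 0.3, 0.2), (0.5, 0.75, 1.0))
        assert cohort.undiagnosed_count == pytest.approx(250 + 75)

    def test_split_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PathologyCohort("x", 100, (0.5, 0.5, 0.2))


def absorbing_death_matrix(stay=0.9):
    """Each living state keeps `stay` and sends the rest to death."""
    m = np.zeros((4, 4))
    for i in range(3):
        m[i, i] = stay
        m[i, 3] = 1 - stay
    m[3, 3] = 1.0
    return TransitionMatrix(m)


class TestCohortTrace:
    def test_identity_matrix_constant_trace(self):
        trace = run_cohort([100, 50, 25, 0], TransitionMatrix(np.eye(4)), 12)
        np.testing.assert_allclose(trace.occupancy, np.tile([100, 50, 25, 0], (13, 1)))

    def test_toy_death_matrix_matrix_power_oracle(self):
        """100 start in one state, 0.1/cycle absorbing death: 19 dead at t=2."""
        trace = run_cohort([100, 0, 0, 0], absorbing_death_matrix(0.9), 2)
        assert trace.occupancy[2, 3] == pytest.approx(19.0)

    def test_conservation_random_matrices(self, rng):
        for _ in range(200):
            rows = rng.dirichlet(np.ones(4), size=3)
            m = np.vstack([rows, [0, 0, 0, 1]])
            initial = rng.uniform(0, 1000, size=4)
            trace = run_cohort(initial, TransitionMatrix(m), 12)
            np.testing.assert_allclose(
                trace.occupancy.sum(axis=1), initial.sum(), atol=1e-6
            )

    def test_dead_occupancy_nondecreasing(self, rng):
        rows = rng.dirichlet(np.ones(4), size=3)
        m = np.vstack([rows, [0, 0, 0, 1]])
        trace = run_cohort([100, 100, 100, 0], TransitionMatrix(m), 24)
        assert np.all(np.diff(trace.occupancy[:, 3]) >= -1e-12)

    def test_living_distribution_converges_to_stationary(self, rng):
        """With no deaths the living mix approaches the eigenvector oracle."""
        living = rng.dirichlet(np.ones(3) * 2, size=3)
        m = np.zeros((4, 4))
        m[:3, :3] = living
        m[3, 3] = 1.0
        trace = run_cohort([300, 0, 0, 0], TransitionMatrix(m), 400)
        vals, vecs = np.linalg.eig(living.T)
        stat = np.real(vecs[:, np.argmax(np.real(vals))])
        stat = stat / stat.sum()
        final = trace.occupancy[-1, :3] / trace.occupancy[-1, :3].sum()
        np.testing.assert_allclose(final, stat, atol=1e-8)

    def test_nonstochastic_matrix_rejected_before_simulation(self):
        bad = np.eye(4)
        bad[0, 0] = 0.8
        with pytest.raises(ValueError):
            TransitionMatrix(bad)

    def test_trace_tidy_export(self):
        trace = run_cohort([10, 0, 0, 0], TransitionMatrix(np.eye(4)), 2, "lbp")
        frame = trace.to_frame()
        assert set(frame.columns) == {"pathology", "cycle", "state", "occupancy"}
        assert len(frame) == 3 * 4
        assert frame["pathology"].eq("lbp").all()


class TestUndiagnosedScenario:
    def make_cohorts(self):
        return [
            PathologyCohort("a", 1000, (0.5, 0.3, 0.2)),
            PathologyCohort("b", 500, (0.2, 0.3, 0.5)),
        ]

    def test_reference_scenario_fractions(self):
        out = apply_undiagnosed_scenario(self.make_cohorts(), 0.5, 0.25)
        assert all(c.diagnosed_fractions == (0.5, 0.75, 1.0) for c in out)

    def test_zero_undiagnosed_is_identity(self):
        out = apply_undiagnosed_scenario(self.make_cohorts(), 0.0, 0.0)
        assert all(c.diagnosed_fractions == (1.0, 1.0, 1.0) for c in out)

    def test_full_undiagnosed_empties_mild_and_moderate(self):
        out = apply_undiagnosed_scenario(self.make_cohorts(), 1.0, 1.0)
        vec = initial_state_vector(out[0])
        np.testing.assert_allclose(vec, [0, 0, 200, 0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_undiagnosed_scenario(self.make_cohorts(), 1.5, 0.0)
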