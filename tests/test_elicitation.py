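"""Linear opinion pooling, elicited expectations, and matrix assembly."""

import numpy as np
import pytest

from mskpain.elicitation import (
    ExpertJudgement,
    PooledDensity,
    build_transition_matrix,
    elicited_mean,
    pool_judgements,
    sample_transition_prob,
)
from mskpain.states import HealthState, LIVING_STATES

MILD, MODERATE, SEVERE = LIVING_STATES


def point_mass_judgement(expert_id, grid, p):
    weights = np.zeros_like(grid)
    weights[int(np.argmin(np.abs(grid - p)))] = 1.0
    return ExpertJudgement(expert_id, grid, weights)


def random_panel(rng, n_experts, n_bins):
    grid = (np.arange(n_bins) + 0.5) / n_bins
    return [
        ExpertJudgement(f"e{i}", grid, rng.dirichlet(np.ones(n_bins)))
        for i in range(n_experts)
    ]


class TestJudgementInvariants:
    def test_grid_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            ExpertJudgement("e", [0.5, 0.5], [0.5, 0.5])

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ExpertJudgement("e", [0.2, 0.8], [0.5, 0.6])

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ExpertJudgement("e", [0.2, 0.8], [-0.1, 1.1])


class TestPooling:
    def test_single_expert_point_mass_is_identity(self):
        grid = np.array([0.1, 0.3, 0.5])
        pooled = pool_judgements([point_mass_judgement("e0", grid, 0.3)])
        assert elicited_mean(pooled) == pytest.approx(0.3)
        assert pooled.weights[1] == 1.0

    def test_reference_panel_records_273_options(self):
        grid = (np.arange(21) + 0.5) / 21
        panel = [point_mass_judgement(f"e{i}", grid, 0.3) for i in range(13)]
        pooled = pool_judgements(panel)
        assert pooled.n_options == 273
        assert pooled.n_experts == 13

    def test_uniform_panel_over_symmetric_grid_has_mean_half(self):
        grid = (np.arange(21) + 0.5) / 21
        uniform = np.full(21, 1 / 21)
        panel = [ExpertJudgement("a", grid, uniform), ExpertJudgement("b", grid, uniform)]
        assert elicited_mean(pool_judgements(panel)) == pytest.approx(0.5)

    def test_three_point_density_mean(self):
        dens = PooledDensity([0.1, 0.5, 0.9], [0.2, 0.5, 0.3], n_experts=1)
        assert elicited_mean(dens) == pytest.approx(0.54)

    def test_pooled_mean_matches_bruteforce_oracle(self, rng):
        """Pooled mean == explicit average over every (expert, bin) pair."""
        for _ in range(100):
            n_experts = int(rng.integers(1, 15))
            n_bins = int(rng.integers(2, 30))
            panel = random_panel(rng, n_experts, n_bins)
            pooled = pool_judgements(panel)
            oracle = 0.0
            for j in panel:  # brute force, independent of the pooling code
                for p, w in zip(j.grid, j.weights):
                    oracle += w * p / n_experts
            assert elicited_mean(pooled) == pytest.approx(oracle, abs=1e-12)

    def test_pooling_is_order_invariant(self, rng):
        panel = random_panel(rng, 7, 11)
        a = pool_judgements(panel)
        b = pool_judgements(panel[::-1])
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-15)

    def test_expert_weights_applied(self):
        grid = np.array([0.0, 1.0])
        panel = [
            ExpertJudgement("a", grid, [1.0, 0.0]),
            ExpertJudgement("b", grid, [0.0, 1.0]),
        ]
        pooled = pool_judgements(panel, expert_weights=[0.25, 0.75])
        assert elicited_mean(pooled) == pytest.approx(0.75)

    def test_mismatched_grids_rejected(self):
        a = ExpertJudgement("a", [0.1, 0.9], [0.5, 0.5])
        b = ExpertJudgement("b", [0.2, 0.8], [0.5, 0.5])
        with pytest.raises(ValueError, match="identical grid"):
            pool_judgements([a, b])

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pool_judgements([])


class TestSampling:
    def test_point_mass_always_sampled(self, rng):
        dens = PooledDensity([0.3], [1.0], n_experts=1)
        draws = sample_transition_prob(dens, rng, size=50)
        assert np.all(draws == 0.3)

    def test_empirical_frequencies_converge_to_weights(self):
        dens = PooledDensity([0.2, 0.8], [0.5, 0.5], n_experts=1)
        rng = np.random.default_rng(7)
        draws = sample_transition_prob(dens, rng, size=10_000)
        assert np.mean(draws == 0.2) == pytest.approx(0.5, abs=0.02)

    def test_same_seed_same_draws(self):
        dens = PooledDensity([0.2, 0.5, 0.8], [0.3, 0.3, 0.4], n_experts=1)
        a = sample_transition_prob(dens, np.random.default_rng(11), size=100)
        b = sample_transition_prob(dens, np.random.default_rng(11), size=100)
        np.testing.assert_array_equal(a, b)


class TestBuildTransitionMatrix:
    def full_row_elicited(self):
        return {
            (MILD, MILD): 0.7, (MILD, MODERATE): 0.2, (MILD, SEVERE): 0.1,
            (MODERATE, MILD): 0.3, (MODERATE, MODERATE): 0.5, (MODERATE, SEVERE): 0.2,
            (SEVERE, MILD): 0.1, (SEVERE, MODERATE): 0.3, (SEVERE, SEVERE): 0.6,
        }

    def test_zero_mortality_preserves_elicited_rows(self):
        m = build_transition_matrix(self.full_row_elicited(), monthly_death=0.0)
        np.testing.assert_allclose(m.entries[0, :3], [0.7, 0.2, 0.1], atol=1e-12)
        assert m.entries[0, 3] == 0.0

    def test_mortality_rescales_living_row(self):
        d = 0.00042
        m = build_transition_matrix(self.full_row_elicited(), monthly_death=d)
        np.testing.assert_allclose(
            m.entries[0], [0.7 * (1 - d), 0.2 * (1 - d), 0.1 * (1 - d), d],
            atol=1e-15,
        )
        # matches the rescale-by-(1-d) arithmetic at 5 decimals
        np.testing.assert_allclose(
            np.round(m.entries[0], 5), [0.69971, 0.19992, 0.09996, 0.00042]
        )

    def test_rows_stochastic_and_death_absorbing(self, rng):
        for _ in range(50):
            elicited = {}
            for frm in LIVING_STATES:
                row = rng.dirichlet(np.ones(3)) * rng.uniform(0.5, 1.5)
                for to, v in zip(LIVING_STATES, row):
                    elicited[(frm, to)] = float(v)
            m = build_transition_matrix(elicited, monthly_death=rng.uniform(0, 0.05))
            np.testing.assert_allclose(m.entries.sum(axis=1), 1.0, atol=1e-9)
            np.testing.assert_array_equal(m.entries[3], [0, 0, 0, 1])

    def test_omitted_diagonal_gets_row_remainder(self):
        elicited = {
            (MILD, MODERATE): 0.15, (MILD, SEVERE): 0.03,
            (MODERATE, MILD): 0.20, (MODERATE, SEVERE): 0.10,
            (SEVERE, MILD): 0.05, (SEVERE, MODERATE): 0.25,
        }
        m = build_transition_matrix(elicited, monthly_death=0.0)
        assert m[(MILD, MILD)] == pytest.approx(0.82)
        assert m[(SEVERE, SEVERE)] == pytest.approx(0.70)

    def test_negative_probability_rejected(self):
        elicited = self.full_row_elicited()
        elicited[(MILD, SEVERE)] = -0.1
        with pytest.raises(ValueError, match="negative"):
            build_transition_matrix(elicited, monthly_death=0.0)

    def test_invalid_death_probability_rejected(self):
        with pytest.raises(ValueError, match="monthly_death"):
            build_transition_matrix(self.full_row_elicited(), monthly_death=1.5)
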