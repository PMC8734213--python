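import numpy as np
import pytest

from scdali import fixtures
from scdali.kernels import linear_factor, standardize_factor
from scdali.rate_field import (
    RatePosterior,
    correlate_activity,
    estimate_rates,
    lineage_rate_summary,
    qdiff10,
)


def _dense_gp_oracle(Eobs, y, dobs, Eall, alpha, s2k, s2n):
    """Plain dense GP regression with linear kernel and 1/d noise."""
    Knn = s2k * (Eobs @ Eobs.T)
    Ksn = s2k * (Eall @ Eobs.T)
    lam = np.diag(s2n / dobs)
    solve = np.linalg.solve(Knn + lam, y - alpha)
    return alpha + Ksn @ solve


class TestEstimateRates:
    def test_constant_field(self, rng):
        n = 300
        E, _, _ = fixtures.make_cell_states(n, seed=0)
        d = fixtures.make_depths(n, 1, 3.0, seed=1).ravel()
        a = rng.binomial(d, 0.7)
        post = estimate_rates(a, d, standardize_factor(linear_factor(E)), seed=0)
        assert np.all(np.abs(post.mean - 0.7) < 0.02)

    def test_matches_dense_gp_with_full_inducing_set(self, rng):
        """With inducing set = observed cells the variational posterior mean
        equals exact Gaussian-process regression."""
        n = 250
        E, _, _ = fixtures.make_cell_states(n, latent_dim=3, seed=2)
        f = standardize_factor(linear_factor(E))
        d = fixtures.make_depths(n, 1, 4.0, seed=3).ravel()
        obs = d > 0
        field = 0.5 + 0.2 * np.tanh(f.E @ rng.normal(size=3))
        a = rng.binomial(d, field)
        post = estimate_rates(a, d, f, n_inducing=1000, seed=0)
        assert post.inducing_count == obs.sum()
        oracle = _dense_gp_oracle(
            f.E[obs], a[obs] / d[obs], d[obs], f.E,
            post.alpha_hat, post.kernel_scale, post.noise_scale,
        )
        assert np.max(np.abs(post.mean_raw - oracle)) < 1e-4

    def test_heterogeneous_field_recovery(self, rng):
        n = 2000
        E, _, _ = fixtures.make_cell_states(n, seed=4)
        f = standardize_factor(linear_factor(E))
        field = 0.5 + 0.25 * np.tanh(f.E @ rng.normal(size=f.rank))
        d = fixtures.make_depths(n, 1, 2.0, seed=5).ravel()
        a = rng.binomial(d, field)
        post = estimate_rates(a, d, f, n_inducing=500, seed=0)
        assert np.corrcoef(post.mean, field)[0, 1] > 0.8

    def test_unobserved_cells_predicted(self, rng):
        n = 200
        E, _, _ = fixtures.make_cell_states(n, seed=6)
        d = fixtures.make_depths(n, 1, 2.0, seed=7).ravel()
        d[:20] = 0
        a = rng.binomial(d, 0.6)
        post = estimate_rates(a, d, standardize_factor(linear_factor(E)), seed=0)
        assert np.all(np.isfinite(post.mean[:20]))
        assert not post.observed_mask[:20].any()

    def test_dissimilar_cell_reverts_to_mean(self, rng):
        # a cell with zero kernel similarity to everything gets the fitted mean
        E = np.vstack([rng.normal(size=(99, 2)), np.zeros((1, 2))])
        d = np.concatenate([rng.poisson(5.0, 99) + 1, [0]])
        a = rng.binomial(d, 0.65)
        post = estimate_rates(a, d, linear_factor(E), seed=0)
        assert abs(post.mean_raw[-1] - post.alpha_hat) < 1e-8

    def test_elbo_nondecreasing(self, rng):
        n = 300
        E, _, _ = fixtures.make_cell_states(n, seed=8)
        d = fixtures.make_depths(n, 1, 3.0, seed=9).ravel()
        a = rng.binomial(d, 0.5)
        post = estimate_rates(a, d, standardize_factor(linear_factor(E)), seed=0)
        assert np.all(np.diff(post.elbo_trace) > -1e-6)

    def test_all_unobserved_rejected(self):
        with pytest.raises(ValueError):
            estimate_rates([0, 0], [0, 0], linear_factor(np.ones((2, 1))))


class TestQdiff10:
    def test_constant_mean_zero(self):
        post = RatePosterior(np.full(100, 0.4), np.zeros(100), 0.4, 10, np.ones(100, bool))
        assert qdiff10(post).qdiff10 == 0.0

    def test_evenly_spaced_grid(self):
        post = RatePosterior(np.linspace(0, 1, 1001), np.zeros(1001), 0.5, 10, np.ones(1001, bool))
        assert np.isclose(qdiff10(post).qdiff10, 0.8)


class TestLineageSummary:
    def test_identical_means(self):
        post = RatePosterior(np.full(60, 0.5), np.zeros(60), 0.5, 10, np.ones(60, bool))
        df = lineage_rate_summary(post, np.repeat(["a", "b", "c"], 20))
        assert np.allclose(df["mean_rate"], 0.5)

    def test_planted_two_lineages(self):
        means = np.where(np.arange(100) < 50, 0.3, 0.7)
        post = RatePosterior(means, np.zeros(100), 0.5, 10, np.ones(100, bool))
        df = lineage_rate_summary(post, np.repeat(["low", "high"], 50))
        got = df.set_index("lineage")["mean_rate"]
        assert abs(got["low"] - 0.3) < 0.03 and abs(got["high"] - 0.7) < 0.03

    def test_single_cell_lineage(self):
        means = np.array([0.1, 0.9, 0.9])
        post = RatePosterior(means, np.zeros(3), 0.5, 2, np.ones(3, bool))
        df = lineage_rate_summary(post, np.array(["solo", "x", "x"]))
        assert df.set_index("lineage")["mean_rate"]["solo"] == 0.1


class TestCorrelateActivity:
    def test_perfect_and_inverse_correlation(self, rng):
        means = rng.random(200)
        post = RatePosterior(means, np.zeros(200), 0.5, 10, np.ones(200, bool))
        df = correlate_activity(post, np.column_stack([means, -means]))
        assert np.isclose(df["pearson_r"].abs().iloc[0], 1.0)
        assert set(np.round(df["pearson_r"], 6)) == {1.0, -1.0}

    def test_independent_column_near_zero(self, rng):
        n = 5000
        means = rng.random(n)
        post = RatePosterior(means, np.zeros(n), 0.5, 10, np.ones(n, bool))
        df = correlate_activity(post, rng.normal(size=(n, 1)))
        assert abs(df["pearson_r"].iloc[0]) < 3 / np.sqrt(n) * 1.5

    def test_zero_variance_is_nan(self, rng):
        post = RatePosterior(rng.random(50), np.zeros(50), 0.5, 10, np.ones(50, bool))
        df = correlate_activity(post, np.ones((50, 1)))
        assert np.isnan(df["pearson_r"].iloc[0])
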