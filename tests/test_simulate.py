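import numpy as np
import pytest
from scipy.stats import chi2, f_oneway

from scdali import fixtures
from scdali.kernels import cluster_factor, linear_factor, standardize_factor
from scdali.simulate import (
    SimulationConfig,
    anova_test,
    _anova_batched,
    draw_counts,
    inflation_factor,
    ols_lrt,
)


class TestDrawCounts:
    def test_pure_binomial_null_mean(self, rng):
        n = 4000
        d = rng.poisson(3.0, n)
        cfg = SimulationConfig(rho=0.0, nu2=0.0, theta=0.0, n_cells=n, n_regions=1, seed=0)
        E = rng.normal(size=(n, 3))
        a = draw_counts(d, linear_factor(E), cfg)
        total = d.sum()
        se = np.sqrt(0.25 * total)
        assert abs(a.sum() - 0.5 * total) < 3 * se

    def test_zero_totals_give_zero_counts(self):
        cfg = SimulationConfig(n_cells=10, n_regions=1, seed=0)
        a = draw_counts(np.zeros(10, dtype=int), linear_factor(np.ones((10, 1))), cfg)
        assert np.all(a == 0)

    def test_seed_determinism(self, rng):
        d = rng.poisson(2.0, (200, 5))
        E = rng.normal(size=(200, 3))
        cfg = SimulationConfig(rho=0.3, nu2=0.05, theta=2.0, n_cells=200, n_regions=5, seed=7)
        a1 = draw_counts(d, linear_factor(E), cfg)
        a2 = draw_counts(d, linear_factor(E), cfg)
        assert np.array_equal(a1, a2)

    def test_rate_moments_match_independent_resimulation(self, rng):
        """Moments of simulated rates match a naive re-implementation of the
        generative chain (logit-normal latent field + Beta-Binomial)."""
        from scipy.special import expit, logit

        n = 200
        E = rng.normal(size=(n, 2))
        f = standardize_factor(linear_factor(E))
        d = np.full((n, 500), 8)
        cfg = SimulationConfig(rho=0.4, nu2=0.1, theta=1.0, n_cells=n, n_regions=500, seed=3)
        a = draw_counts(d, linear_factor(E), cfg)
        # oracle: independent chain with its own rng
        orng = np.random.default_rng(99)
        R = 500
        alpha = orng.normal(0, np.sqrt(0.4 * 0.1), R)
        z = orng.normal(size=(2, R))
        mu = expit(logit(0.5) + alpha[None, :] + np.sqrt(0.6 * 0.1) * (f.E @ z))
        p = orng.beta(mu / 1.0, (1 - mu) / 1.0)
        a_o = orng.binomial(d, p)
        r1 = (a / d).mean()
        r2 = (a_o / d).mean()
        v1 = (a / d).var()
        v2 = (a_o / d).var()
        assert abs(r1 - r2) < 0.01
        assert abs(v1 - v2) / v2 < 0.05

    def test_rho_convention_flag(self, rng):
        cfg = SimulationConfig(rho=1.0, nu2=0.1, theta=1.0, n_cells=10, n_regions=1, seed=0)
        assert cfg.hom_var == pytest.approx(0.1)
        assert cfg.het_var == 0.0
        cfg_flipped = SimulationConfig(rho=1.0, nu2=0.1, theta=1.0, n_cells=10,
                                       n_regions=1, seed=0, rho_is_het_fraction=True)
        assert cfg_flipped.het_var == pytest.approx(0.1)
        assert cfg_flipped.hom_var == 0.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(rho=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(nu2=-0.1)


class TestAnova:
    def test_identical_rates_give_unit_pvalue(self):
        a = np.array([2, 2, 2, 2])
        d = np.array([4, 4, 4, 4])
        assert anova_test(a, d, np.array([0, 0, 1, 1])) == 1.0

    def test_separated_groups_significant(self):
        d = np.full(40, 10)
        a = np.concatenate([np.full(20, 1), np.full(20, 9)])
        a[0] += 1
        a[-1] -= 1
        p = anova_test(a, d, np.repeat([0, 1], 20))
        assert p < 0.01

    def test_matches_scipy_oracle(self, rng):
        d = rng.poisson(4.0, 100) + 1
        a = rng.binomial(d, 0.5)
        labels = rng.integers(0, 4, 100)
        p = anova_test(a, d, labels)
        rates = a / d
        oracle = f_oneway(*[rates[labels == g] for g in range(4)]).pvalue
        assert np.isclose(p, oracle)

    def test_batched_matches_single(self, rng):
        d = rng.poisson(2.0, (20, 150))
        a = rng.binomial(d, 0.5)
        codes = rng.integers(0, 5, 150)
        p_b = _anova_batched(a.astype(float), d.astype(float), codes, 5)
        for r in range(0, 20, 5):
            obs = d[r] > 0
            p_s = anova_test(a[r], d[r], codes)
            assert np.isclose(p_b[r], p_s, atol=1e-10)

    def test_single_group_warns(self):
        with pytest.warns(RuntimeWarning):
            p = anova_test([1, 2], [2, 4], np.array([0, 0]))
        assert p == 1.0


class TestOlsLrt:
    def test_orthogonal_factor_null(self, rng):
        n = 500
        d = np.full(n, 20)
        a = rng.binomial(d, 0.5)
        E = rng.normal(size=(n, 3))
        p = ols_lrt(a, d, linear_factor(E))
        assert p > 0.001

    def test_high_dimensional_anticonservative(self):
        """With 24 cluster dims and 250 observed cells of sparse overdispersed
        counts, the Gaussian LRT is inflated under the null."""
        import warnings

        pvals = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(100):
                n = 600
                E, labels, _ = fixtures.make_cell_states(n, n_clusters=24, seed=rep)
                d = fixtures.make_depths(n, 1, 1.0, seed=1000 + rep).ravel()
                obs = np.flatnonzero(d > 0)[:250]
                cfg = SimulationConfig(rho=1.0, nu2=0.0, theta=2.0, n_cells=n,
                                       n_regions=1, seed=2000 + rep)
                a = draw_counts(d, linear_factor(E), cfg)
                pvals.append(ols_lrt(a[obs], d[obs], cluster_factor(labels.labels[obs])))
        assert np.median(pvals) < 0.5
        assert inflation_factor(pvals) > 1.0

    def test_matches_r2_identity(self, rng):
        n = 120
        d = np.full(n, 10)
        a = rng.binomial(d, 0.5)
        E = rng.normal(size=(n, 4))
        p = ols_lrt(a, d, linear_factor(E))
        y = a / d
        X = np.column_stack([np.ones(n), E])
        H = X @ np.linalg.lstsq(X, np.eye(n), rcond=None)[0]
        yc = y - y.mean()
        r2 = 1 - np.sum((y - H @ y) ** 2) / np.sum(yc**2)
        lr = -n * np.log(1 - r2)
        assert np.isclose(p, chi2.sf(lr, 4), atol=1e-10)


class TestInflationFactor:
    @pytest.mark.parametrize("med,expect", [(0.5, 1.0), (1.0, 0.0)])
    def test_reference_points(self, med, expect):
        assert np.isclose(inflation_factor([med]), expect)

    def test_anticonservative_value(self):
        assert np.isclose(inflation_factor([0.05]), np.log10(0.05) / np.log10(0.5))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            inflation_factor([])
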