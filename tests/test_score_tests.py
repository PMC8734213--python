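import numpy as np
import pytest
from scipy.stats import chi2, kstest

from scdali.glmm import NullModelSpec, fit_null
from scdali.kernels import KernelFactor, linear_factor, standardize_factor
from scdali.score_tests import (
    WeightedChiSqNull,
    bootstrap_pvalue,
    pvalue_weighted_chisq,
    score_test_batched,
)
from scdali.score_tests import test_binomial_het as binomial_het_test
from scdali.score_tests import test_het as het_test
from scdali.score_tests import test_hom as hom_test
from scdali.score_tests import test_joint as joint_test
from scdali.simulate import SimulationConfig, draw_counts
from scdali import fixtures


class TestWeightedChisqTail:
    def test_single_weight_reduces_to_chi2(self):
        assert abs(pvalue_weighted_chisq(np.array([1.0]), 3.841) - 0.05) < 1e-4

    def test_zero_statistic(self):
        assert pvalue_weighted_chisq(np.array([0.5, 0.5]), 0.0) == 1.0

    def test_all_zero_weights(self):
        assert pvalue_weighted_chisq(np.zeros(3), 5.0) == 1.0

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(1)
        w = np.array([0.5, 0.5])
        draws = w @ rng.chisquare(1, size=(2, 1_000_000))
        for q in (0.5, 1.5, 3.0, 6.0):
            p = pvalue_weighted_chisq(w, q)
            mc = (draws > q).mean()
            se = np.sqrt(mc * (1 - mc) / draws.size)
            assert abs(p - mc) < 3 * se

    def test_equal_weights_scale_as_chi2(self):
        # sum of k chi2_1 with equal weight w is w * chi2_k; agreement is
        # bounded by the quadrature tolerance of the inversion
        p = pvalue_weighted_chisq(np.array([2.0, 2.0, 2.0]), 10.0)
        assert abs(p - chi2.sf(5.0, 3)) < 2e-4

    def test_far_tail_saddlepoint(self):
        w = np.array([1.0, 0.5, 0.25])
        p = pvalue_weighted_chisq(w, 200.0)
        assert 0 < p < 1e-20

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            WeightedChiSqNull(np.array([-0.5]))


def _simulated_region(n, theta, het_share, seed, depth=2.0, latent_dim=4):
    E, _, _ = fixtures.make_cell_states(n, n_clusters=6, latent_dim=latent_dim, seed=seed)
    d = fixtures.make_depths(n, 1, depth, seed=seed + 1).ravel()
    if (d > 0).sum() < 2:
        d[:2] += 1
    cfg = SimulationConfig(
        rho=het_share, nu2=0.05, theta=theta, n_cells=n, n_regions=1,
        seed=seed + 2, rho_is_het_fraction=True,
    )
    a = draw_counts(d, linear_factor(E), cfg)
    return a, d, standardize_factor(linear_factor(E))


class TestHetTest:
    def test_null_pvalues_uniform(self):
        """Type-I control under the matched null (sigma2 = 0, alpha drawn)."""
        n, n_regions = 800, 300
        E, _, _ = fixtures.make_cell_states(n, seed=0)
        d = fixtures.make_depths(n, n_regions, 1.0, seed=1)
        cfg = SimulationConfig(rho=1.0, nu2=0.05, theta=2.0, n_cells=n,
                               n_regions=n_regions, seed=2)
        a = draw_counts(d, linear_factor(E), cfg)
        f = standardize_factor(linear_factor(E))
        _, p, _, _ = score_test_batched(a.T, d.T.astype(float), f.E, NullModelSpec())
        assert kstest(p, "uniform").pvalue > 0.01
        assert 0.02 < (p < 0.05).mean() < 0.09

    def test_zero_factor_gives_unit_pvalue(self):
        a, d, _ = _simulated_region(100, 2.0, 0.5, 0)
        res = het_test(a, d, KernelFactor(np.zeros((100, 2))))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_too_few_observed_cells(self):
        res = het_test([1, 0, 0], [2, 0, 0], KernelFactor(np.ones((3, 1))))
        assert res.p_value == 1.0 and res.warning is not None

    def test_agrees_with_parametric_bootstrap(self):
        """Analytic null vs refitted-bootstrap oracle on a small instance."""
        a, d, f = _simulated_region(80, 2.0, 0.5, 7, depth=15.0, latent_dim=2)
        res = het_test(a, d, f)
        fit = fit_null(a, d, NullModelSpec())
        pb = bootstrap_pvalue(fit, f, a, d, B=4000, seed=3)
        se = np.sqrt(max(pb * (1 - pb), 1e-12) / 4000)
        assert abs(res.p_value - pb) < 3.5 * se


class TestHomTest:
    def test_exactly_balanced_data(self):
        d = np.full(100, 4)
        res = hom_test(d // 2, d)
        assert res.statistic < 1e-10 and res.p_value > 0.999

    def test_type_one_error_in_binomial_band(self):
        n, n_regions = 800, 400
        E, _, _ = fixtures.make_cell_states(n, seed=3)
        d = fixtures.make_depths(n, n_regions, 1.0, seed=4)
        for theta in (2.0, 5.0):
            cfg = SimulationConfig(rho=0.0, nu2=0.0, theta=theta, n_cells=n,
                                   n_regions=n_regions, seed=5)
            a = draw_counts(d, linear_factor(E), cfg)
            from scdali.score_tests import hom_test_batched
            _, p, _ = hom_test_batched(a.T, d.T.astype(float),
                                       NullModelSpec(free_intercept=False))
            t1 = (p < 0.05).mean()
            assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / n_regions) < t1 < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_regions) + 0.01

    def test_strong_imbalance_detected(self, rng):
        n = 5000
        d = rng.poisson(2.0, n) + 1
        theta = 0.5
        mu = 1 / (1 + np.exp(-1.0))  # alpha = 1
        p = rng.beta(mu / theta, (1 - mu) / theta, n)
        a = rng.binomial(d, p)
        res = hom_test(a, d)
        assert res.p_value < 1e-10


class TestJointTest:
    def test_detects_homogeneous_signal(self, rng):
        n = 3000
        d = rng.poisson(2.0, n) + 1
        theta = 0.5
        mu = 1 / (1 + np.exp(-0.6))
        p = rng.beta(mu / theta, (1 - mu) / theta, n)
        a = rng.binomial(d, p)
        E, _, _ = fixtures.make_cell_states(n, seed=8)
        res = joint_test(a, d, standardize_factor(linear_factor(E)))
        assert res.p_value < 1e-4

    def test_detects_heterogeneous_signal(self):
        from scdali.simulate import SimulationConfig, draw_counts

        E, _, _ = fixtures.make_cell_states(4000, n_clusters=6, latent_dim=4, seed=30)
        d = fixtures.make_depths(4000, 1, 2.0, seed=31).ravel()
        cfg = SimulationConfig(rho=1.0, nu2=0.2, theta=2.0, n_cells=4000,
                               n_regions=1, seed=32, rho_is_het_fraction=True)
        a = draw_counts(d, linear_factor(E), cfg)
        res = joint_test(a, d, standardize_factor(linear_factor(E)))
        assert res.p_value < 0.01


class TestBinomialVariant:
    def test_anticonservative_under_overdispersion(self):
        n, n_regions = 800, 200
        E, _, _ = fixtures.make_cell_states(n, seed=9)
        d = fixtures.make_depths(n, n_regions, 1.0, seed=10)
        cfg = SimulationConfig(rho=1.0, nu2=0.0, theta=2.0, n_cells=n,
                               n_regions=n_regions, seed=11)
        a = draw_counts(d, linear_factor(E), cfg)
        f = standardize_factor(linear_factor(E))
        from scdali.glmm import fit_null_batched
        fit = fit_null_batched(a.T, d.T.astype(float), spec=NullModelSpec(), theta_fixed=1e-12)
        _, p, _, _ = score_test_batched(a.T, d.T.astype(float), f.E, NullModelSpec(), fit=fit)
        assert np.median(p) < 0.3

    def test_calibrated_when_data_are_binomial(self):
        n, n_regions = 800, 200
        E, _, _ = fixtures.make_cell_states(n, seed=12)
        d = fixtures.make_depths(n, n_regions, 1.0, seed=13)
        cfg = SimulationConfig(rho=1.0, nu2=0.0, theta=0.0, n_cells=n,
                               n_regions=n_regions, seed=14)
        a = draw_counts(d, linear_factor(E), cfg)
        f = standardize_factor(linear_factor(E))
        from scdali.glmm import fit_null_batched
        fit = fit_null_batched(a.T, d.T.astype(float), spec=NullModelSpec(), theta_fixed=1e-12)
        _, p, _, _ = score_test_batched(a.T, d.T.astype(float), f.E, NullModelSpec(), fit=fit)
        assert kstest(p, "uniform").pvalue > 0.01

    def test_matches_het_when_theta_at_bound(self):
        # on Binomial data the Beta-Binomial fit drives theta to its floor,
        # and the working-residual statistics coincide
        rng = np.random.default_rng(15)
        n = 300
        d = rng.poisson(5.0, n) + 1
        a = rng.binomial(d, 0.5)
        E, _, _ = fixtures.make_cell_states(n, seed=16)
        f = standardize_factor(linear_factor(E))
        r1 = het_test(a, d, f)
        r2 = binomial_het_test(a, d, f)
        assert np.isclose(r1.statistic, r2.statistic, rtol=1e-3)


class TestBootstrap:
    def test_lower_bound_honoured(self):
        a, d, f = _simulated_region(60, 2.0, 1.0, 20, depth=10.0)
        a = a + (d - a)  # force extreme imbalance: all reads maternal
        fit = fit_null(a, d)
        p = bootstrap_pvalue(fit, f, a, d, B=200, seed=0)
        assert p >= 1 / 201

    def test_b_validation(self):
        a, d, f = _simulated_region(50, 2.0, 0.5, 21)
        fit = fit_null(a, d)
        with pytest.raises(ValueError):
            bootstrap_pvalue(fit, f, a, d, B=10)


def test_het_power_monotone_in_variance():
    """Power is non-decreasing in the heterogeneous variance."""
    n, n_regions = 600, 80
    E, _, _ = fixtures.make_cell_states(n, seed=17)
    d = fixtures.make_depths(n, n_regions, 2.0, seed=18)
    f = standardize_factor(linear_factor(E))
    powers = []
    for nu2 in (0.0, 0.05, 0.2):
        rej = []
        for rep in range(3):
            cfg = SimulationConfig(rho=1.0, nu2=nu2, theta=2.0, n_cells=n,
                                   n_regions=n_regions, seed=100 + rep,
                                   rho_is_het_fraction=True)
            a = draw_counts(d, linear_factor(E), cfg,
                            rng=np.random.default_rng(200 + rep))
            _, p, _, _ = score_test_batched(a.T, d.T.astype(float), f.E, NullModelSpec())
            rej.append((p < 0.05).mean())
        powers.append(np.mean(rej))
    assert powers[0] <= powers[1] + 0.05
    assert powers[1] <= powers[2] + 0.05
    assert powers[2] > powers[0]
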