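import numpy as np
import pytest
import scipy.sparse as sp
from scipy.special import expit, logit

from scdali import fixtures
from scdali.data import AllelicCountMatrix
from scdali.kernels import KernelFactor, linear_factor, standardize_factor
from scdali.simulate import SimulationConfig, draw_counts
from scdali.workflow import (
    bh_adjust,
    lineage_scan,
    permute_within_groups,
    time_scan,
)
from scdali.workflow import test_regions as run_region_tests


def _bh_oracle(p):
    """Step-up BH reference implementation."""
    p = np.asarray(p, float)
    order = np.argsort(p)
    m = p.size
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestBH:
    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_stepup_oracle(self, rng):
        p = rng.random(200)
        assert np.allclose(bh_adjust(p), _bh_oracle(p))

    def test_q_at_least_p(self, rng):
        p = rng.random(50)
        assert np.all(bh_adjust(p) >= p - 1e-12)

    def test_nan_excluded(self):
        q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])


def _make_counts(a, d):
    return AllelicCountMatrix(sp.csr_matrix(a), sp.csr_matrix(d))


class TestTestRegions:
    def test_single_region_q_equals_p(self, rng):
        d = rng.poisson(3.0, (300, 1))
        a = rng.binomial(d, 0.6)
        counts = _make_counts(a, d)
        df = run_region_tests(counts, tests=("hom",))
        assert np.isclose(df["q"].iloc[0], df["p"].iloc[0])

    def test_all_tests_run_with_factor(self, small_study, std_factor):
        E, labels, t, d = small_study
        cfg = SimulationConfig(rho=0.5, nu2=0.05, theta=2.0, n_cells=400, n_regions=30, seed=1)
        a = draw_counts(d, linear_factor(E), cfg)
        counts = _make_counts(a, d)
        df = run_region_tests(counts, std_factor, tests=("hom", "het", "joint"))
        assert len(df) == 90
        ok = df["p"].notna()
        assert (df.loc[ok, "q"] >= df.loc[ok, "p"] - 1e-12).all()

    def test_empty_region_gets_nan(self, rng):
        d = rng.poisson(3.0, (100, 3))
        d[:, 1] = 0
        a = rng.binomial(d, 0.5)
        counts = _make_counts(a, d)
        df = run_region_tests(counts, tests=("hom",))
        assert np.isnan(df["p"].iloc[1])

    def test_determinism(self, small_study, std_factor):
        E, labels, t, d = small_study
        cfg = SimulationConfig(rho=0.0, nu2=0.05, theta=2.0, n_cells=400, n_regions=30, seed=2)
        a = draw_counts(d, linear_factor(E), cfg)
        counts = _make_counts(a, d)
        df1 = run_region_tests(counts, std_factor, tests=("het",))
        df2 = run_region_tests(counts, std_factor, tests=("het",))
        assert np.allclose(df1["p"], df2["p"], equal_nan=True)


class TestLineageScan:
    def test_planted_shift_found_in_right_lineage(self, rng):
        n = 3000
        labels = rng.integers(0, 4, n).astype(str)
        d = rng.poisson(2.0, (n, 1))
        mu = np.where(labels == "1", expit(logit(0.5) + 0.8), 0.5)
        theta = 0.3
        p = rng.beta(mu / theta, (1 - mu) / theta)
        a = rng.binomial(d.ravel(), p).reshape(-1, 1)
        counts = _make_counts(a, d)
        df = lineage_scan(counts, labels)
        best = df.loc[df["p"].idxmin(), "lineage"]
        assert best == "1"
        assert df[df["lineage"] == "1"]["q"].iloc[0] < 0.1

    def test_no_signal_controls_discoveries(self, rng):
        n = 800
        labels = rng.integers(0, 4, n).astype(str)
        d = rng.poisson(2.0, (n, 10))
        theta = 0.3
        p = rng.beta(0.5 / theta, 0.5 / theta, size=(n, 10))
        a = rng.binomial(d, p)
        df = lineage_scan(_make_counts(a, d), labels)
        assert df["n_significant_lineages"].max() <= 1


class TestTimeScan:
    def test_planted_linear_trend(self, rng):
        n = 3000
        t = rng.random(n)
        d = rng.poisson(2.0, (n, 1))
        mu = np.clip(0.35 + 0.3 * t, 0.01, 0.99)
        theta = 0.3
        p = rng.beta(mu / theta, (1 - mu) / theta)
        a = rng.binomial(d.ravel(), p).reshape(-1, 1)
        df = time_scan(_make_counts(a, d), t, np.ones(n, bool))
        assert df["p"].iloc[0] < 1e-4

    def test_no_trend_is_null(self, rng):
        n = 1500
        t = rng.random(n)
        d = rng.poisson(2.0, (n, 8))
        theta = 0.3
        p = rng.beta(0.5 / theta, 0.5 / theta, size=(n, 8))
        a = rng.binomial(d, p)
        df = time_scan(_make_counts(a, d), t, np.ones(n, bool))
        assert (df["p"] < 0.01).sum() <= 1

    def test_quadratic_needs_degree(self, rng):
        n = 3000
        t = rng.random(n)
        d = rng.poisson(3.0, (n, 1))
        mu = np.clip(0.22 + 0.56 * 4.0 * (t - 0.5) ** 2, 0.01, 0.99)
        theta = 0.05
        p = rng.beta(mu / theta, (1 - mu) / theta)
        a = rng.binomial(d.ravel(), p).reshape(-1, 1)
        counts = _make_counts(a, d)
        p3 = time_scan(counts, t, np.ones(n, bool), degree=3)["p"].iloc[0]
        p1 = time_scan(counts, t, np.ones(n, bool), degree=1)["p"].iloc[0]
        assert p3 < 1e-3
        assert p3 < p1

    def test_low_coverage_regions_masked(self, rng):
        n = 500
        d = rng.poisson(2.0, (n, 2))
        d[:, 1] = 0
        d[:3, 1] = 1  # mean well below 0.1
        a = rng.binomial(d, 0.5)
        df = time_scan(_make_counts(a, d), rng.random(n), np.ones(n, bool))
        assert not df["within_lineage_accessible"].iloc[1]
        assert np.isnan(df["p"].iloc[1])


class TestPermuteWithinGroups:
    def test_single_cell_groups_identity(self, rng):
        E = rng.normal(size=(10, 3))
        f = KernelFactor(E)
        out = permute_within_groups(f, np.arange(10), seed=0)
        assert np.allclose(out.E, E)

    def test_row_multiset_preserved_per_group(self, rng):
        E = rng.normal(size=(60, 2))
        groups = rng.integers(0, 5, 60)
        out = permute_within_groups(KernelFactor(E), groups, seed=1)
        for g in range(5):
            sel = groups == g
            orig = np.sort(E[sel], axis=0)
            perm = np.sort(out.E[sel], axis=0)
            assert np.allclose(orig, perm)

    def test_donor_confounding_diagnostic(self, rng):
        """Donor one-hot covariates restore calibration under within-donor
        permutation; omitting them inflates the heterogeneity test."""
        from scdali.data import onehot_covariates
        from scdali.glmm import NullModelSpec
        from scdali.score_tests import score_test_batched

        n, n_donors, n_regions = 1000, 15, 150
        donors = rng.integers(0, n_donors, n)
        E = rng.normal(size=(n, 4)) + 1.2 * rng.normal(size=(n_donors, 4))[donors]
        d = fixtures.make_depths(n, n_regions, 2.0, seed=3)
        alpha_donor = rng.normal(0, 0.3, n_donors)
        mu = expit(alpha_donor[donors])
        theta = 2.0
        pbb = rng.beta(mu / theta, (1 - mu) / theta, size=(n_regions, n)).T
        a = rng.binomial(d, pbb)
        f = standardize_factor(linear_factor(E))
        fperm = permute_within_groups(f, donors, seed=4)
        X = onehot_covariates(donors)
        _, p_no, _, _ = score_test_batched(a.T, d.T.astype(float), fperm.E, NullModelSpec())
        _, p_cov, _, _ = score_test_batched(
            a.T, d.T.astype(float), fperm.E, NullModelSpec(covariates=X)
        )
        band = 3 * np.sqrt(0.05 * 0.95 / n_regions)
        assert (p_no < 0.05).mean() > 0.05 + band  # inflated without donor terms
        assert abs((p_cov < 0.05).mean() - 0.05) < band + 0.02  # calibrated with them
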