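"""Genome-scale testing workflows: per-region tests with FDR control,
lineage and developmental-time scans, and the donor-permutation diagnostic.

Benjamini-Hochberg adjustment is applied per test family (hom / het / joint
separately; a lineage scan forms one combined family across regions and
lineages).  Regions without observed cells yield NA p-values and are excluded
from the BH denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import AllelicCountMatrix
from .glmm import NullModelSpec
from .kernels import (
    ClusterLabels,
    KernelFactor,
    TimeCoordinate,
    lineage_contrast_factor,
    polynomial_time_factor,
    standardize_factor,
)
from .score_tests import fit_null_batched, hom_test_batched, score_test_batched


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values; NaN entries are excluded and kept NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _counts_arrays(counts: AllelicCountMatrix):
    a = np.asarray(counts.a.todense(), dtype=float).T  # regions x cells
    d = np.asarray(counts.d.todense(), dtype=float).T
    return a, d


def test_regions(
    counts: AllelicCountMatrix,
    factor: KernelFactor | None = None,
    covariates: np.ndarray | None = None,
    tests=("hom", "het", "joint"),
    base_rate: float = 0.5,
    standardize: bool = True,
) -> pd.DataFrame:
    """Run the selected imbalance tests on every region.

    Returns one row per region per test with BH-adjusted q-values computed
    per test family.  Embedding factors are standardised (centered,
    trace-normalised) by default before testing.
    """
    a, d = _counts_arrays(counts)
    testable = (d > 0).sum(axis=1) >= 2
    E = None
    if factor is not None:
        E = (standardize_factor(factor) if standardize else factor).E
    spec_free = NullModelSpec(base_rate=base_rate, free_intercept=True, covariates=covariates)
    spec_pin = NullModelSpec(base_rate=base_rate, free_intercept=False, covariates=covariates)
    frames = []
    at, dt = a[testable], d[testable]
    for test in tests:
        p = np.full(counts.n_regions, np.nan)
        stat = np.full(counts.n_regions, np.nan)
        if testable.any():
            if test == "het":
                if E is None:
                    raise ValueError("het test requires a cell-state factor")
                Q, pv, _, _ = score_test_batched(at, dt, E, spec_free)
            elif test == "joint":
                if E is None:
                    raise ValueError("joint test requires a cell-state factor")
                from .score_tests import augment_with_intercept

                Q, pv, _, _ = score_test_batched(at, dt, augment_with_intercept(E), spec_pin)
            elif test == "hom":
                Q, pv, _ = hom_test_batched(at, dt, spec_pin)
            else:
                raise ValueError(f"unknown test {test!r}")
            p[testable] = pv
            stat[testable] = Q
        frames.append(
            pd.DataFrame(
                {
                    "region_id": counts.region_ids,
                    "test": test,
                    "statistic": stat,
                    "p": p,
                    "q": bh_adjust(p),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def lineage_scan(
    counts: AllelicCountMatrix,
    labels: ClusterLabels | np.ndarray,
    covariates: np.ndarray | None = None,
    base_rate: float = 0.5,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Test each (region, lineage) pair for lineage-contrast imbalance.

    Uses the heterogeneity test with a single-lineage indicator kernel, which
    contrasts the lineage's mean allelic rate against all remaining cells.
    BH adjustment spans the combined (region x lineage) family; the returned
    frame carries per-row q-values and a per-region count of significant
    lineages at ``q_threshold``.
    """
    if not isinstance(labels, ClusterLabels):
        labels = ClusterLabels(np.asarray(labels))
    a, d = _counts_arrays(counts)
    testable = (d > 0).sum(axis=1) >= 2
    spec = NullModelSpec(base_rate=base_rate, free_intercept=True, covariates=covariates)
    rows = []
    for lineage in labels.categories:
        E = lineage_contrast_factor(labels, lineage).E
        p = np.full(counts.n_regions, np.nan)
        stat = np.full(counts.n_regions, np.nan)
        if testable.any():
            Q, pv, _, _ = score_test_batched(a[testable], d[testable], E, spec)
            p[testable] = pv
            stat[testable] = Q
        rows.append(
            pd.DataFrame(
                {
                    "region_id": counts.region_ids,
                    "lineage": lineage,
                    "statistic": stat,
                    "p": p,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df["q"] = bh_adjust(df["p"].to_numpy())
    sig = (
        df.assign(sig=lambda t: t["q"] < q_threshold)
        .groupby("region_id", sort=False)["sig"]
        .sum()
        .rename("n_significant_lineages")
    )
    return df.merge(sig, on="region_id")


def time_scan(
    counts: AllelicCountMatrix,
    t: TimeCoordinate | np.ndarray,
    cell_mask: np.ndarray,
    degree: int = 3,
    covariates: np.ndarray | None = None,
    base_rate: float = 0.5,
    min_mean_within: float = 0.1,
) -> pd.DataFrame:
    """Test for changes of allelic imbalance along pseudotime within a lineage.

    Restricted to cells in ``cell_mask`` (one lineage); regions must be
    accessible within the lineage (mean allelic total count >= 0.1, the same
    inclusive threshold as the global filter).  The kernel is the polynomial
    pseudotime factor of the given degree.
    """
    if not isinstance(t, TimeCoordinate):
        t = TimeCoordinate(np.asarray(t, dtype=float))
    cell_mask = np.asarray(cell_mask, dtype=bool)
    a, d = _counts_arrays(counts)
    a, d = a[:, cell_mask], d[:, cell_mask]
    tm = t.t[cell_mask]
    E = polynomial_time_factor(tm, degree=degree).E
    covariates = None if covariates is None else np.atleast_2d(covariates)[cell_mask]
    accessible = d.mean(axis=1) >= min_mean_within
    testable = accessible & ((d > 0).sum(axis=1) >= 2)
    spec = NullModelSpec(base_rate=base_rate, free_intercept=True, covariates=covariates)
    p = np.full(counts.n_regions, np.nan)
    stat = np.full(counts.n_regions, np.nan)
    if testable.any():
        Q, pv, _, _ = score_test_batched(a[testable], d[testable], E, spec)
        p[testable] = pv
        stat[testable] = Q
    return pd.DataFrame(
        {
            "region_id": counts.region_ids,
            "test": "time",
            "statistic": stat,
            "p": p,
            "q": bh_adjust(p),
            "within_lineage_accessible": accessible,
        }
    )


def permute_within_groups(factor: KernelFactor, groups, seed: int = 0) -> KernelFactor:
    """Permute factor rows within each group (e.g. cells of the same donor).

    Destroys any true cell-state association while preserving group-level
    structure; used as a calibration diagnostic for group-confounded kernels.
    """
    groups = np.asarray(groups)
    if groups.size != factor.n_cells:
        raise ValueError("groups must match cells")
    rng = np.random.default_rng(seed)
    E = factor.E.copy()
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        E[idx] = E[rng.permutation(idx)]
    return KernelFactor(E, label=f"{factor.label}|permuted-within-groups")
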