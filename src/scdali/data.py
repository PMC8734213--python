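"""Shared data containers and count-matrix IO.

Allelic quantifications are pairs of sparse cells x regions matrices: ``a``
holds maternal-haplotype read counts and ``d`` total allelic counts
(maternal + paternal).  Matrices round-trip as paired MatrixMarket files with
plain-text cell/region indices, or as long-format TSV
(cell, region, a, d).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


@dataclass
class AllelicCountMatrix:
    """Paired sparse maternal (``a``) and total (``d``) allelic count matrices."""

    a: sp.csr_matrix
    d: sp.csr_matrix
    cell_ids: np.ndarray | None = None
    region_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a = sp.csr_matrix(self.a)
        self.d = sp.csr_matrix(self.d)
        if self.a.shape != self.d.shape:
            raise ValueError("a and d must have matching shapes")
        if (self.a.data < 0).any() or (self.d.data < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.a - self.d).max() > 0:
            raise ValueError("a must satisfy a <= d elementwise")
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell{i}" for i in range(self.a.shape[0])])
        if self.region_ids is None:
            self.region_ids = np.array([f"region{j}" for j in range(self.a.shape[1])])
        self.cell_ids = np.asarray(self.cell_ids)
        self.region_ids = np.asarray(self.region_ids)
        if self.cell_ids.size != self.a.shape[0] or self.region_ids.size != self.a.shape[1]:
            raise ValueError("index lengths must match matrix shape")

    @property
    def n_cells(self) -> int:
        return self.a.shape[0]

    @property
    def n_regions(self) -> int:
        return self.a.shape[1]

    def region(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Dense per-cell (a, d) vectors for region column j."""
        return (
            np.asarray(self.a[:, j].todense()).ravel(),
            np.asarray(self.d[:, j].todense()).ravel(),
        )


@dataclass
class CovariateMatrix:
    """Fixed-effect covariates (cells x p); may be empty (p = 0)."""

    X: np.ndarray

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.size == 0:
            X = X.reshape(X.shape[0] if X.ndim == 2 else 0, 0)
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates must be finite")
        self.X = X

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def onehot_covariates(groups, drop_first: bool = True) -> np.ndarray:
    """One-hot encode group identities (e.g. donors) as fixed-effect covariates.

    The first level is dropped by default so the design keeps full column rank
    once an intercept is included.
    """
    dummies = pd.get_dummies(pd.Categorical(np.asarray(groups)), drop_first=drop_first)
    return dummies.to_numpy(dtype=float)


def write_counts_mtx(prefix: str | os.PathLike, counts: AllelicCountMatrix) -> None:
    """Write paired MTX files ``<prefix>.a.mtx`` / ``<prefix>.d.mtx`` + indices."""
    prefix = os.fspath(prefix)
    mmwrite(prefix + ".a.mtx", sp.coo_matrix(counts.a))
    mmwrite(prefix + ".d.mtx", sp.coo_matrix(counts.d))
    np.savetxt(prefix + ".cells.txt", counts.cell_ids, fmt="%s")
    np.savetxt(prefix + ".regions.txt", counts.region_ids, fmt="%s")


def read_counts_mtx(prefix: str | os.PathLike) -> AllelicCountMatrix:
    prefix = os.fspath(prefix)
    a = sp.csr_matrix(mmread(prefix + ".a.mtx"))
    d = sp.csr_matrix(mmread(prefix + ".d.mtx"))
    cells = np.loadtxt(prefix + ".cells.txt", dtype=str, ndmin=1)
    regions = np.loadtxt(prefix + ".regions.txt", dtype=str, ndmin=1)
    return AllelicCountMatrix(a, d, cells, regions)


def write_counts_tsv(path, counts: AllelicCountMatrix) -> None:
    """Long-format TSV: cell, region, a, d (non-zero d entries only)."""
    coo = sp.coo_matrix(counts.d)
    a_lil = counts.a.tolil()
    rows = {
        "cell": counts.cell_ids[coo.row],
        "region": counts.region_ids[coo.col],
        "a": np.array([a_lil[i, j] for i, j in zip(coo.row, coo.col)], dtype=int),
        "d": coo.data.astype(int),
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> AllelicCountMatrix:
    df = pd.read_csv(path, sep="\t")
    cells = np.unique(df["cell"].to_numpy())
    regions = np.unique(df["region"].to_numpy())
    ci = pd.Categorical(df["cell"], categories=cells).codes
    rj = pd.Categorical(df["region"], categories=regions).codes
    shape = (cells.size, regions.size)
    a = sp.coo_matrix((df["a"].to_numpy(), (ci, rj)), shape=shape).tocsr()
    d = sp.coo_matrix((df["d"].to_numpy(), (ci, rj)), shape=shape).tocsr()
    return AllelicCountMatrix(a, d, cells, regions)
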