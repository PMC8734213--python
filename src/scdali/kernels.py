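"""Low-rank cell-state kernel factors.

All tests, simulations and rate models in this package characterise
cell-to-cell covariance through a linear kernel ``K = E Eᵀ`` where ``E`` is a
``cells x k`` factor derived from total counts (an embedding, a one-hot
cluster encoding, or a polynomial basis in pseudotime).  Kernels are never
materialised densely for large data sets; every consumer operates on the
factor itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class KernelFactor:
    """A cells x k factor ``E`` representing the kernel ``K = E Eᵀ``.

    The implied kernel is symmetric positive semidefinite by construction.
    ``label`` records provenance (embedding, clusters, time, mixture).
    """

    E: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        E = np.atleast_2d(np.asarray(self.E, dtype=float))
        if E.ndim != 2 or E.shape[1] < 1:
            raise ValueError("factor must be a 2-D cells x k matrix with k >= 1")
        if not np.all(np.isfinite(E)):
            raise ValueError("factor entries must be finite")
        object.__setattr__(self, "E", E)

    @property
    def n_cells(self) -> int:
        return self.E.shape[0]

    @property
    def rank(self) -> int:
        return self.E.shape[1]

    def dense_kernel(self) -> np.ndarray:
        """Materialise ``E Eᵀ``; intended for small inputs and tests only."""
        if self.n_cells > 2000:
            raise ValueError("refusing to materialise a dense kernel for n > 2000 cells")
        return self.E @ self.E.T


@dataclass(frozen=True)
class ClusterLabels:
    """Per-cell categorical lineage/cluster assignment."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 1 or labels.size < 1:
            raise ValueError("labels must be a non-empty 1-D vector")
        object.__setattr__(self, "labels", labels)

    @property
    def n_cells(self) -> int:
        return self.labels.size

    @property
    def categories(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass(frozen=True)
class TimeCoordinate:
    """Per-cell scalar pseudotime in [0, 1]."""

    t: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("t must be a non-empty 1-D vector")
        if not np.all(np.isfinite(t)) or t.min() < 0.0 or t.max() > 1.0:
            raise ValueError("time coordinates must lie in [0, 1]")
        object.__setattr__(self, "t", t)

    @property
    def n_cells(self) -> int:
        return self.t.size


def linear_factor(embedding: np.ndarray, label: str = "embedding") -> KernelFactor:
    """Wrap a cells x k embedding as a kernel factor (K = E Eᵀ, raw columns)."""
    return KernelFactor(np.asarray(embedding, dtype=float), label=label)


def cluster_factor(labels: ClusterLabels | np.ndarray, label: str = "clusters") -> KernelFactor:
    """One-hot encode cluster labels; K_ij = 1 iff cells i, j share a label."""
    if not isinstance(labels, ClusterLabels):
        labels = ClusterLabels(np.asarray(labels))
    onehot = pd.get_dummies(pd.Categorical(labels.labels)).to_numpy(dtype=float)
    return KernelFactor(onehot, label=label)


def lineage_contrast_factor(
    labels: ClusterLabels | np.ndarray, lineage, label: str | None = None
) -> KernelFactor:
    """Single indicator column for one lineage; K_ij = 1 iff both cells belong.

    Used for by-lineage scans: testing this kernel contrasts the mean allelic
    rate of the lineage against all remaining cells.
    """
    if not isinstance(labels, ClusterLabels):
        labels = ClusterLabels(np.asarray(labels))
    member = labels.labels == lineage
    if not member.any():
        raise ValueError(f"lineage {lineage!r} not present among labels")
    if label is None:
        label = f"lineage:{lineage}"
    return KernelFactor(member.astype(float)[:, None], label=label)


def polynomial_time_factor(
    t: TimeCoordinate | np.ndarray, degree: int = 3, label: str = "time"
) -> KernelFactor:
    """Polynomial basis in pseudotime: columns t⁰, t¹, ..., t^(degree-1)."""
    if not isinstance(t, TimeCoordinate):
        t = TimeCoordinate(np.asarray(t, dtype=float))
    if degree < 1:
        raise ValueError("degree must be >= 1")
    E = np.vander(t.t, N=degree, increasing=True)
    return KernelFactor(E.astype(float), label=label)


def mix_factors(f1: KernelFactor, f2: KernelFactor, eta: float, label: str = "mixture") -> KernelFactor:
    """Factor of the mixture kernel η·K1 + (1−η)·K2.

    Realised by horizontally concatenating √η·E1 and √(1−η)·E2, so the result
    stays low-rank and is exactly linear in η entrywise.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    if f1.n_cells != f2.n_cells:
        raise ValueError("factors must have the same number of cells (rows)")
    E = np.hstack([np.sqrt(eta) * f1.E, np.sqrt(1.0 - eta) * f2.E])
    return KernelFactor(E, label=label)


def standardize_factor(factor: KernelFactor) -> KernelFactor:
    """Center columns and rescale so that trace(K)/n = 1.

    This makes variance-component scales comparable across kernels.  Note that
    weighted-χ² p-values are invariant to the overall kernel scale, and the
    score-test projection removes the intercept direction, so standardisation
    mainly affects interpretability of fitted variance scales.  A factor whose
    kernel has zero trace after centering is returned unchanged (degenerate).
    """
    E = factor.E - factor.E.mean(axis=0, keepdims=True)
    mean_diag = float(np.sum(E * E) / E.shape[0])
    if mean_diag <= 0.0:
        return factor
    return KernelFactor(E / np.sqrt(mean_diag), label=factor.label)


def write_factor(path, factor: KernelFactor) -> None:
    """Write a factor as TSV with a one-line ``# label`` header."""
    with open(path, "w") as fh:
        fh.write(f"# {factor.label}\n")
        np.savetxt(fh, factor.E, delimiter="\t")


def read_factor(path) -> KernelFactor:
    with open(path) as fh:
        first = fh.readline()
        label = first[1:].strip() if first.startswith("#") else ""
        if not first.startswith("#"):
            fh.seek(0)
        E = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return KernelFactor(E, label=label)
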