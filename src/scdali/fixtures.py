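"""Deterministic generators for synthetic inputs.

These generators emulate the statistical structure of single-cell allelic
data — a clustered low-dimensional cell-state manifold with a developmental
time gradient, sparse per-cell allelic total counts, and a small haplotype-
tagged read set — without requiring any real data set.  All outputs are pure
functions of their parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .data import AllelicCountMatrix
from .kernels import ClusterLabels, TimeCoordinate


def make_cell_states(
    n_cells: int,
    n_clusters: int = 24,
    latent_dim: int = 8,
    seed: int = 0,
    cluster_spread: float = 2.0,
    noise: float = 0.5,
):
    """Gaussian-mixture cell-state embedding with a cluster-linked time gradient.

    Returns ``(embedding, ClusterLabels, TimeCoordinate)``.  Cluster centers
    are spread wide relative to the within-cluster noise so that clusters are
    separable, and each cluster carries a baseline developmental time; the
    time signal is embedded in the first latent dimension so that continuous
    temporal variation is visible to embedding kernels.
    """
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, cluster_spread, size=(n_clusters, latent_dim))
    labels = rng.integers(0, n_clusters, size=n_cells)
    base_time = rng.uniform(0.05, 0.95, size=n_clusters)
    t = np.clip(base_time[labels] + rng.normal(0.0, 0.08, size=n_cells), 0.0, 1.0)
    E = centers[labels] + rng.normal(0.0, noise, size=(n_cells, latent_dim))
    E[:, 0] += 2.0 * (t - t.mean())
    return E, ClusterLabels(labels), TimeCoordinate(t)


def make_depths(
    n_cells: int,
    n_regions: int,
    target_mean_allelic: float = 1.0,
    seed: int = 0,
    zero_inflation: float = 0.4,
    nb_shape: float = 1.5,
) -> np.ndarray:
    """Zero-inflated negative-binomial allelic total counts (cells x regions).

    Calibrated so the overall mean allelic total count hits
    ``target_mean_allelic`` (within ~10%), emulating the sparsity of
    haplotype-assignable single-cell ATAC reads.
    """
    if target_mean_allelic < 0:
        raise ValueError("target mean must be nonnegative")
    if target_mean_allelic == 0:
        return np.zeros((n_cells, n_regions), dtype=int)
    rng = np.random.default_rng(seed)
    mean_nb = target_mean_allelic / (1.0 - zero_inflation)
    p = nb_shape / (nb_shape + mean_nb)
    d = rng.negative_binomial(nb_shape, p, size=(n_cells, n_regions))
    d[rng.random(size=d.shape) < zero_inflation] = 0
    return d


# --------------------------------------------------------------------------
# read-level fixture
# --------------------------------------------------------------------------

@dataclass
class ReadFixture:
    """A small haplotype-tagged alignment fixture with its exact truth counts."""

    sam_text: str
    vcf_text: str
    bed_text: str
    truth: AllelicCountMatrix
    barcodes: list


_CONTIG = "chr2L"
_CONTIG_LEN = 10000
_READ_LEN = 40

# (pos0, maternal base, paternal base); positions are 0-based here.
_VARIANTS = [
    (1000, "A", "G"),
    (1049, "C", "T"),
    (3000, "G", "A"),
    (3080, "T", "C"),
    (5000, "A", "C"),
]
# BED-style half-open windows (1 kb windows centred on mock peaks, trimmed).
_REGIONS = [(950, 1150), (2950, 3150), (4950, 5150)]
_CELLS = ["CELL1", "CELL2"]


def _read_seq(start0: int, hap_bases: dict) -> str:
    seq = ["A"] * _READ_LEN
    # keep a neutral background distinct from variant alleles where possible
    for i in range(_READ_LEN):
        seq[i] = "N"
    for pos, base in hap_bases.items():
        off = pos - start0
        if 0 <= off < _READ_LEN:
            seq[off] = base
    return "".join(b if b != "N" else "A" for b in seq)


def make_read_fixture(seed: int = 0, flip_alleles: bool = False) -> ReadFixture:
    """Generate a ~50-read SAM/VCF/BED fixture with exact expected counts.

    Reads carrying variants are haplotype-consistent (multi-variant reads show
    the same haplotype at every covered variant), so the embedded truth does
    not depend on which overlapping variant the counter randomly selects.
    ``flip_alleles`` swaps the phased genotype in the VCF, which swaps the
    maternal and paternal interpretation (truth becomes ``d - a``).
    """
    rng = np.random.default_rng(seed)
    variants = {pos: (mat, pat) for pos, mat, pat in _VARIANTS}
    region_vars = [
        [p for p in variants if lo <= p < hi] for lo, hi in _REGIONS
    ]
    truth_a = np.zeros((len(_CELLS), len(_REGIONS)), dtype=int)
    truth_d = np.zeros_like(truth_a)
    reads = []
    serial = 0

    def add_read(name, start0, seq, cell, flag=0, mapq=60):
        reads.append((start0, f"{name}\t{flag}\t{_CONTIG}\t{start0 + 1}\t{mapq}\t{_READ_LEN}M\t*\t0\t0\t{seq}\t*\tCB:Z:{cell}"))

    # informative reads: random cell/haplotype/variant per region
    for j, (lo, hi) in enumerate(_REGIONS):
        for _ in range(14):
            serial += 1
            cell_idx = int(rng.integers(0, len(_CELLS)))
            hap = int(rng.integers(0, 2))  # 0 = maternal, 1 = paternal
            pos = int(rng.choice(region_vars[j]))
            start0 = int(rng.integers(max(lo - 10, pos - _READ_LEN + 1), pos + 1))
            # haplotype-consistent bases at every variant the read covers
            bases = {
                p: variants[p][hap]
                for p in variants
                if start0 <= p < start0 + _READ_LEN
            }
            add_read(f"read{serial}", start0, _read_seq(start0, bases), _CELLS[cell_idx])
            truth_d[cell_idx, j] += 1
            if hap == 0:
                truth_a[cell_idx, j] += 1

    # non-counting reads: PCR duplicate, unknown barcode, no variant, mismatch
    serial += 1
    pos = 1000
    add_read(f"dup{serial}", 990, _read_seq(990, {pos: variants[pos][0]}), _CELLS[0], flag=1024)
    serial += 1
    add_read(f"unk{serial}", 990, _read_seq(990, {pos: variants[pos][0]}), "TTTT")
    serial += 1
    add_read(f"novar{serial}", 1100, _read_seq(1100, {}), _CELLS[0])
    serial += 1
    add_read(f"mm{serial}", 990, _read_seq(990, {pos: "T"}), _CELLS[0])  # matches neither allele

    reads.sort(key=lambda r: r[0])
    sam_lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{_CONTIG}\tLN:{_CONTIG_LEN}",
    ] + [r[1] for r in reads]

    vcf_lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={_CONTIG},length={_CONTIG_LEN}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tF1",
    ]
    for pos, mat, pat in _VARIANTS:
        gt = "0|1" if not flip_alleles else "1|0"
        vcf_lines.append(
            f"{_CONTIG}\t{pos + 1}\t.\t{mat}\t{pat}\t.\tPASS\t.\tGT\t{gt}"
        )

    bed_lines = [f"{_CONTIG}\t{lo}\t{hi}\tregion{j + 1}" for j, (lo, hi) in enumerate(_REGIONS)]

    if flip_alleles:
        truth_a = truth_d - truth_a
    truth = AllelicCountMatrix(
        sp.csr_matrix(truth_a),
        sp.csr_matrix(truth_d),
        cell_ids=np.array(_CELLS),
        region_ids=np.array([f"region{j + 1}" for j in range(len(_REGIONS))]),
    )
    return ReadFixture(
        sam_text="\n".join(sam_lines) + "\n",
        vcf_text="\n".join(vcf_lines) + "\n",
        bed_text="\n".join(bed_lines) + "\n",
        truth=truth,
        barcodes=list(_CELLS),
    )


def make_binary_accessibility(
    n_cells: int = 2000,
    n_peaks: int = 500,
    n_batches: int = 2,
    n_time_categories: int = 3,
    seed: int = 0,
):
    """Binary accessibility matrix from the VAE's own generative model.

    A latent developmental time drives a subset of peak activities; batches
    shift sequencing depth (size factors) and add batch-specific peak offsets.
    Returns ``(x, batches, time_labels, t_true)``.
    """
    rng = np.random.default_rng(seed)
    t_true = rng.uniform(0.0, 1.0, size=n_cells)
    z = rng.normal(0.0, 1.0, size=(n_cells, 4))
    z[:, 0] = 3.0 * (t_true - 0.5) + 0.3 * z[:, 0]
    W = rng.normal(0.0, 1.2, size=(4, n_peaks))
    batches = rng.integers(0, n_batches, size=n_cells)
    batch_offset = rng.normal(0.0, 0.5, size=(n_batches, n_peaks))
    logits = z @ W + batch_offset[batches] - 1.0
    rho = 1.0 / (1.0 + np.exp(-logits))
    log_l = rng.normal(np.log(60.0) + 0.3 * batches, 0.3)
    l = np.exp(log_l)
    p_open = -np.expm1(l[:, None] * np.log1p(-np.clip(rho * 0.01, 0, 0.5)))
    x = (rng.random(size=p_open.shape) < p_open).astype(float)
    edges = np.quantile(t_true, np.linspace(0, 1, n_time_categories + 1)[1:-1])
    y = np.digitize(t_true, edges) + 1  # categories 1..t
    return x, batches, y, t_true
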