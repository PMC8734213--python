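"""Haplotype-aware allele-specific read counting.

Reads from a barcoded, coordinate-sorted alignment file are assigned to the
maternal or paternal haplotype through the phased heterozygous variants they
overlap: a read must cover at least one variant; if it covers several, one is
chosen uniformly at random (seeded per read name, so assignment is
order-independent and reproducible) and the read's base at that position
decides the haplotype.  Counts are aggregated per cell barcode and genomic
window; regions with mean allelic total count below a threshold are filtered.

Conventions: internal coordinates are BED-style 0-based half-open (VCF
positions are converted on read); the maternal allele is the first allele of
the phased genotype (``M|P``); a read overlapping a window by any amount is
counted towards it; PCR duplicates and reads from unknown barcodes are
ignored.  Sex chromosomes are excluded by default because the allelic base
rate is not well-defined there.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
import scipy.sparse as sp

from .data import AllelicCountMatrix

_SEX_CONTIGS = {"chrX", "chrY", "X", "Y"}


@dataclass(frozen=True)
class PhasedVariant:
    """A heterozygous single-nucleotide variant with phased alleles.

    ``position`` is 0-based; ``maternal``/``paternal`` are single bases and
    must differ (heterozygous by construction).
    """

    contig: str
    position: int
    maternal: str
    paternal: str

    def __post_init__(self) -> None:
        if self.maternal == self.paternal:
            raise ValueError("phased variant must be heterozygous (alleles differ)")


@dataclass(frozen=True)
class Region:
    """Half-open genomic window [start, end), 0-based."""

    contig: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")


def read_phased_variants(vcf_path, sample: int | str = 0, include_sex: bool = False) -> list[PhasedVariant]:
    """Load phased heterozygous SNVs from a VCF; maternal = first GT allele."""
    out = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            if not include_sex and rec.contig in _SEX_CONTIGS:
                continue
            sm = rec.samples[sample]
            alleles = sm.alleles
            if alleles is None or len(alleles) != 2 or None in alleles:
                continue
            mat, pat = alleles
            if mat == pat or len(mat) != 1 or len(pat) != 1:
                continue
            out.append(PhasedVariant(rec.contig, rec.pos - 1, mat, pat))
    return out


def read_regions(bed_path, include_sex: bool = False) -> list[Region]:
    """Load BED windows (0-based half-open)."""
    df = pd.read_csv(bed_path, sep="\t", header=None, comment="#")
    regions = []
    for i, row in df.iterrows():
        contig = str(row[0])
        if not include_sex and contig in _SEX_CONTIGS:
            continue
        name = str(row[3]) if df.shape[1] > 3 else f"region{i}"
        regions.append(Region(contig, int(row[1]), int(row[2]), name))
    return regions


def _read_rng(read_name: str, seed: int) -> np.random.Generator:
    # per-read-name seeding keeps variant choice order-independent
    return np.random.default_rng((zlib.crc32(read_name.encode()) ^ (seed & 0xFFFFFFFF)))


def assign_read(read, variants: list[PhasedVariant], seed: int = 0) -> str:
    """Assign one aligned read to 'maternal', 'paternal' or 'unassigned'.

    ``variants`` are the phased variants overlapping the read's reference
    span.  One is selected (uniformly at random under the per-read seeded rng
    if several), and the read's base at that reference position decides the
    haplotype; a base matching neither allele leaves the read unassigned.
    """
    if not variants:
        return "unassigned"
    covered = {}
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        covered[rpos] = qpos
    hits = [v for v in variants if v.position in covered]
    if not hits:
        return "unassigned"
    if len(hits) == 1:
        chosen = hits[0]
    else:
        chosen = hits[int(_read_rng(read.query_name, seed).integers(0, len(hits)))]
    base = read.query_sequence[covered[chosen.position]].upper()
    if base == chosen.maternal.upper():
        return "maternal"
    if base == chosen.paternal.upper():
        return "paternal"
    return "unassigned"


def count_alleles(
    alignment_path,
    variants: list[PhasedVariant],
    regions: list[Region],
    barcodes,
    barcode_tag: str = "CB",
    seed: int = 0,
    include_sex: bool = False,
) -> AllelicCountMatrix:
    """Count maternal / total allelic reads per cell barcode and region.

    A read contributes to every region it overlaps (any overlap); it is
    skipped if flagged as a PCR duplicate, unmapped, secondary or
    supplementary, if its barcode is not in ``barcodes``, or if it cannot be
    assigned to a haplotype.
    """
    barcodes = list(barcodes)
    cell_index = {b: i for i, b in enumerate(barcodes)}
    regions = [r for r in regions if include_sex or r.contig not in _SEX_CONTIGS]
    contigs = {r.contig for r in regions}
    var_by_contig: dict[str, list[PhasedVariant]] = {}
    for v in variants:
        var_by_contig.setdefault(v.contig, []).append(v)
    for vs in var_by_contig.values():
        vs.sort(key=lambda v: v.position)
    reg_by_contig: dict[str, list[tuple[int, int, int]]] = {}
    for j, r in enumerate(regions):
        reg_by_contig.setdefault(r.contig, []).append((r.start, r.end, j))

    a = np.zeros((len(barcodes), len(regions)), dtype=np.int64)
    d = np.zeros_like(a)
    skipped_malformed = 0
    mode = "rb" if str(alignment_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignment_path), mode) as sam:
        ref_names = set(sam.references)
        for r in regions:
            if r.contig not in ref_names:
                raise ValueError(f"region contig {r.contig!r} absent from alignment header")
        for read in sam.fetch(until_eof=True):
            try:
                if read.is_unmapped or read.is_duplicate or read.is_secondary or read.is_supplementary:
                    continue
                contig = read.reference_name
                if contig not in contigs:
                    continue
                if not read.has_tag(barcode_tag):
                    continue
                cell = cell_index.get(read.get_tag(barcode_tag))
                if cell is None:
                    continue
                start, end = read.reference_start, read.reference_end
                overlaps = [
                    j for (lo, hi, j) in reg_by_contig.get(contig, []) if start < hi and end > lo
                ]
                if not overlaps:
                    continue
                near = [
                    v for v in var_by_contig.get(contig, []) if start <= v.position < end
                ]
                hap = assign_read(read, near, seed=seed)
            except (ValueError, KeyError, AttributeError):
                skipped_malformed += 1
                continue
            if hap == "unassigned":
                continue
            for j in overlaps:
                d[cell, j] += 1
                if hap == "maternal":
                    a[cell, j] += 1
    if skipped_malformed:
        warnings.warn(f"skipped {skipped_malformed} malformed alignment records", RuntimeWarning, stacklevel=2)
    return AllelicCountMatrix(
        sp.csr_matrix(a),
        sp.csr_matrix(d),
        cell_ids=np.array(barcodes),
        region_ids=np.array([r.name or f"region{j}" for j, r in enumerate(regions)]),
    )


def filter_regions(counts: AllelicCountMatrix, min_mean: float = 0.1) -> np.ndarray:
    """Keep regions whose mean allelic total count across cells is >= min_mean.

    The boundary is inclusive: a region with mean exactly ``min_mean`` is kept.
    Returns a boolean mask over regions.
    """
    mean_d = np.asarray(counts.d.sum(axis=0)).ravel() / counts.n_cells
    # boundary kept: tolerate floating-point representation of the mean
    return mean_d >= min_mean - 1e-9 * max(1.0, min_mean)
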