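"""Per-base coverage from unique alignments, RPKM and transcriptional activity.

Coverage counts every aligned base of every uniquely mapped read,
strandlessly; multi-mapped reads are excluded.  Expression is quantified as
RPKM = C * 1e9 / (N * L) where C is the number of reads assigned to a
gene's exons, L the summed exon length in bases and N the total number of
uniquely mapped reads in the library (each mate counts as one read).

A read is assigned to a gene when at least half of its aligned bases fall
in that gene's exons; when several genes qualify the largest overlap wins
and exact ties assign the read to no gene.  Genes whose RPKM falls in the
lowest 5% of the library are flagged transcriptionally inactive, and the
remaining genes are binned by the 25th/75th RPKM percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pysam
from intervaltree import IntervalTree

from .genome_model import GeneModel, Genome

__all__ = [
    "CoverageTrack",
    "ExpressionRecord",
    "build_coverage",
    "compute_rpkm",
    "assign_reads_to_genes",
    "compute_expression",
    "activity_filter_and_bins",
    "default_is_unique",
]


@dataclass
class CoverageTrack:
    """Per-chromosome arrays of uniquely-mapped read-base counts."""

    arrays: dict[str, np.ndarray]

    def depth(self, chrom: str, pos: int) -> int:
        return int(self.arrays[chrom][pos])

    def total(self) -> int:
        return int(sum(a.sum() for a in self.arrays.values()))

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            return 0.0
        return float(self.arrays[chrom][start:end].mean())


@dataclass
class ExpressionRecord:
    gene_id: str
    C: int
    L: int
    N: int
    rpkm: float
    breadth: float
    active: bool = True
    bin: str | None = None


def default_is_unique(read: pysam.AlignedSegment, min_mapq: int = 1) -> bool:
    """Uniqueness from the NH tag when present, else mapping quality."""
    if read.has_tag("NH"):
        return read.get_tag("NH") == 1
    return read.mapping_quality >= min_mapq


def _iter_unique(
    sam_path: str | Path, is_unique: Callable[[pysam.AlignedSegment], bool]
):
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not is_unique(read):
                continue
            yield read


def build_coverage(
    sam_path: str | Path,
    genome: Genome,
    is_unique: Callable[[pysam.AlignedSegment], bool] = default_is_unique,
) -> CoverageTrack:
    """Accumulate per-base depth of uniquely mapped reads from a SAM/BAM file."""
    arrays = {c: np.zeros(n, dtype=np.int64) for c, n in genome.lengths.items()}
    for read in _iter_unique(sam_path, is_unique):
        chrom = read.reference_name
        if chrom not in arrays:
            raise ValueError(f"alignment on unknown chromosome {chrom!r}")
        for s, e in read.get_blocks():
            if e > len(arrays[chrom]):
                raise ValueError(
                    f"read {read.query_name} extends beyond chromosome {chrom} end"
                )
            arrays[chrom][s:e] += 1
    return CoverageTrack(arrays)


def compute_rpkm(C: int, L: int, N: int) -> float:
    """Reads per kilobase of exon region per million mapped reads."""
    if L <= 0:
        raise ValueError("exon length L must be >= 1")
    if N <= 0:
        raise ValueError("mapped read count N must be >= 1")
    if C < 0:
        raise ValueError("assigned read count C must be >= 0")
    return C * 1e9 / (N * L)


def assign_reads_to_genes(
    sam_path: str | Path,
    genes: Iterable[GeneModel],
    min_fraction: float = 0.5,
    is_unique: Callable[[pysam.AlignedSegment], bool] = default_is_unique,
) -> tuple[dict[str, int], int]:
    """Count reads per gene (majority-of-aligned-bases rule) and library size N.

    Returns ``(counts, N)`` where N is the total number of uniquely mapped
    reads, assigned or not.
    """
    trees: dict[str, IntervalTree] = {}
    genes = list(genes)
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            tree.addi(s, e, g.gene_id)
    counts = {g.gene_id: 0 for g in genes}
    n_total = 0
    for read in _iter_unique(sam_path, is_unique):
        n_total += 1
        tree = trees.get(read.reference_name)
        if tree is None:
            continue
        overlap: dict[str, int] = {}
        aligned = 0
        for s, e in read.get_blocks():
            aligned += e - s
            for iv in tree.overlap(s, e):
                overlap[iv.data] = overlap.get(iv.data, 0) + min(e, iv.end) - max(s, iv.begin)
        if not overlap or aligned == 0:
            continue
        qualifying = {g: ov for g, ov in overlap.items() if ov >= min_fraction * aligned}
        if not qualifying:
            continue
        best = max(qualifying.values())
        winners = [g for g, ov in qualifying.items() if ov == best]
        if len(winners) == 1:
            counts[winners[0]] += 1
    return counts, n_total


def compute_expression(
    genes: Iterable[GeneModel],
    counts: dict[str, int],
    n_total: int,
    coverage: CoverageTrack,
) -> list[ExpressionRecord]:
    """RPKM and exonic coverage breadth for every gene."""
    records = []
    for g in genes:
        L = g.exon_length
        C = counts.get(g.gene_id, 0)
        covered = sum(
            int((coverage.arrays[g.chrom][s:e] >= 1).sum()) for s, e in g.exons
        )
        records.append(
            ExpressionRecord(
                gene_id=g.gene_id,
                C=C,
                L=L,
                N=n_total,
                rpkm=compute_rpkm(C, L, n_total) if n_total > 0 else 0.0,
                breadth=covered / L,
            )
        )
    return records


def _nearest_rank_cutoff(sorted_values: np.ndarray, fraction: float) -> float:
    """Value below which the lowest ``fraction`` of the library falls.

    ``floor(fraction * n)`` values lie strictly below the returned cutoff
    when values are distinct; ties at the cutoff survive a strict filter.
    """
    n = len(sorted_values)
    k = min(int(np.floor(fraction * n)), n - 1)
    return float(sorted_values[k])


def activity_filter_and_bins(
    records: list[ExpressionRecord], inactive_fraction: float = 0.05
) -> list[ExpressionRecord]:
    """Flag the lowest-5%-RPKM genes inactive and quartile-bin the rest.

    A gene is inactive when its RPKM is strictly below the nearest-rank
    5th-percentile cutoff, so an all-tied library keeps every gene active.
    Active genes get bins 'low' (< 25th percentile), 'high' (>= 75th) and
    'mid' otherwise, percentiles taken over active genes only.
    """
    if not records:
        raise ValueError("no expression records")
    rpkms = np.sort([r.rpkm for r in records])
    cutoff = _nearest_rank_cutoff(rpkms, inactive_fraction)
    for r in records:
        r.active = r.rpkm >= cutoff
        r.bin = None
    active = sorted(r.rpkm for r in records if r.active)
    if active:
        arr = np.asarray(active)
        q25 = _nearest_rank_cutoff(arr, 0.25)
        q75 = _nearest_rank_cutoff(arr, 0.75)
        for r in records:
            if not r.active:
                continue
            if r.rpkm >= q75:
                r.bin = "high"
            elif r.rpkm < q25:
                r.bin = "low"
            else:
                r.bin = "mid"
    return records
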