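"""Intergenic novel-transcript discovery and intronic new-exon nomination.

A transcriptionally active region (TAR) is a maximal run of consecutive
intergenic bases each supported by at least two uniquely mapped reads, with
a length strictly greater than 35 bases.  TARs are linked into transcript
units (TUs) when at least three read pairs have one mate overlapping each
TAR; connected components of that graph become TUs, and TUs shorter than
150 bases (summed over member TARs) or with fewer than 2 covering
read-bases per base are excluded.

Novel transcript sequences are screened for ORFs in all six frames; an
intronic TAR-like run whose two ends are each joined to a flanking exon by
a called splice junction is nominated as a new-exon candidate (runs without
dual junction support count as retained-intron evidence instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pysam
from intervaltree import IntervalTree

from .coverage_expression import CoverageTrack, default_is_unique
from .genome_model import GeneModel, revcomp
from .junction_discovery import SpliceJunction

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class TAR:
    chrom: str
    start: int
    end: int
    min_depth: int
    mean_depth: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class MatePair:
    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int

    @property
    def same_chrom(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def span(self) -> int:
        return max(self.end1, self.end2) - min(self.start1, self.start2)


@dataclass
class ORF:
    strand: str
    frame: int  # 0..2 within the strand
    start: int  # forward coordinates on the input sequence
    end: int
    aa_length: int  # protein length, stop codon excluded
    protein: str


@dataclass
class TranscriptUnit:
    tu_id: str
    tars: list[TAR]
    link_counts: dict[tuple[int, int], int] = field(default_factory=dict)
    orfs: list[ORF] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.tars[0].chrom

    @property
    def span(self) -> tuple[int, int]:
        return (min(t.start for t in self.tars), max(t.end for t in self.tars))

    @property
    def length(self) -> int:
        """Summed member-TAR length (expressed bases, not genomic span)."""
        return sum(t.length for t in self.tars)

    @property
    def avg_reads_per_base(self) -> float:
        covering = sum(t.mean_depth * t.length for t in self.tars)
        return covering / self.length


@dataclass
class NewExonCandidate:
    gene_id: str
    intron_index: int
    chrom: str
    start: int
    end: int
    mean_depth: float
    left_support: int  # trans-reads of the junction joining the left boundary
    right_support: int


def detect_tars(
    coverage: CoverageTrack,
    intervals: dict[str, list[tuple[int, int]]],
    min_depth: int = 2,
    min_length: int = 36,
    max_gap: int = 0,
) -> list[TAR]:
    """Maximal runs of depth >= ``min_depth`` inside the given intervals.

    Runs are clipped at interval boundaries; runs shorter than
    ``min_length`` (the strict > 35 bp rule) are discarded.  Sub-threshold
    gaps up to ``max_gap`` bases may optionally be bridged (default: a
    single below-threshold base splits the run).
    """
    out: list[TAR] = []
    for chrom, ivs in intervals.items():
        depth = coverage.arrays[chrom]
        for s, e in ivs:
            window = depth[s:e]
            mask = window >= min_depth
            runs = _runs_from_mask(mask, max_gap)
            for rs, re_ in runs:
                if re_ - rs < min_length:
                    continue
                seg = window[rs:re_]
                out.append(
                    TAR(
                        chrom=chrom,
                        start=s + rs,
                        end=s + re_,
                        min_depth=int(seg.min()),
                        mean_depth=float(seg.mean()),
                    )
                )
    out.sort(key=lambda t: (t.chrom, t.start))
    return out


def _runs_from_mask(mask: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    runs = list(zip(starts.tolist(), ends.tolist()))
    if max_gap > 0 and len(runs) > 1:
        merged = [runs[0]]
        for s, e in runs[1:]:
            if s - merged[-1][1] <= max_gap:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        runs = merged
    return runs


def collect_mate_pairs(
    sam_path: str | Path, is_unique=default_is_unique
) -> list[MatePair]:
    """Aligned-interval pairs of uniquely mapped, both-mapped read pairs."""
    first_seen: dict[str, tuple[str, int, int]] = {}
    pairs: list[MatePair] = []
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for read in sam:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or not read.is_paired
                or read.mate_is_unmapped
            ):
                continue
            if not is_unique(read):
                continue
            iv = (read.reference_name, read.reference_start, read.reference_end)
            mate = first_seen.pop(read.query_name, None)
            if mate is None:
                first_seen[read.query_name] = iv
            else:
                pairs.append(MatePair(*mate, *iv))
    return pairs


def link_tars(
    tars: Sequence[TAR],
    pairs: Iterable[MatePair],
    min_pairs: int = 3,
    min_length: int = 150,
    min_avg_depth: float = 2.0,
    max_insert: int = 10_000,
    id_prefix: str = "TU",
) -> list[TranscriptUnit]:
    """Link TARs into transcript units with paired-end evidence.

    An edge joins two TARs when >= ``min_pairs`` read pairs have one mate
    overlapping each (>= 1 aligned base); pairs with mates on different
    chromosomes or spanning more than ``max_insert`` bases are ignored, as
    are pairs whose two mates hit the same TAR.  Connected components
    become TUs, then the length and average-depth filters apply.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, t in enumerate(tars):
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, idx)
    edge_counts: dict[tuple[int, int], int] = {}
    for p in pairs:
        if not p.same_chrom or p.span > max_insert:
            continue
        tree = trees.get(p.chrom1)
        if tree is None:
            continue
        hits1 = {iv.data for iv in tree.overlap(p.start1, p.end1)}
        hits2 = {iv.data for iv in tree.overlap(p.start2, p.end2)}
        for i in hits1:
            for j in hits2:
                if i == j:
                    continue
                key = (min(i, j), max(i, j))
                edge_counts[key] = edge_counts.get(key, 0) + 1
    graph = nx.Graph()
    graph.add_nodes_from(range(len(tars)))
    for (i, j), n in edge_counts.items():
        if n >= min_pairs:
            graph.add_edge(i, j, pairs=n)
    units: list[TranscriptUnit] = []
    for comp in sorted(nx.connected_components(graph), key=min):
        members = sorted(comp)
        tu = TranscriptUnit(
            tu_id="",
            tars=[tars[i] for i in members],
            link_counts={
                (i, j): edge_counts[(i, j)]
                for (i, j) in edge_counts
                if i in comp and j in comp and edge_counts[(i, j)] >= min_pairs
            },
        )
        if tu.length < min_length or tu.avg_reads_per_base < min_avg_depth:
            continue
        units.append(tu)
    for n, tu in enumerate(
        sorted(units, key=lambda u: (u.chrom, u.span[0])), start=1
    ):
        tu.tu_id = f"{id_prefix}{n:04d}"
    return sorted(units, key=lambda u: (u.chrom, u.span[0]))


def find_orfs(seq: str, min_aa: int = 33) -> list[ORF]:
    """Maximal ATG-to-stop ORFs in all six frames.

    For each in-frame stop codon the ORF from the first downstream-ATG
    since the previous stop is reported (ORF-finder style maximal ORFs).
    Coordinates are forward-strand positions on the input sequence;
    ``aa_length`` excludes the stop codon.
    """
    seq = seq.upper()
    out: list[ORF] = []
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            start_atg: int | None = None
            for q in range(frame, n - 2, 3):
                codon = s[q : q + 3]
                if codon == "ATG" and start_atg is None:
                    start_atg = q
                elif codon in STOP_CODONS:
                    if start_atg is not None:
                        aa = (q - start_atg) // 3
                        if aa >= min_aa:
                            if strand == "+":
                                fs, fe = start_atg, q + 3
                            else:
                                fs, fe = n - (q + 3), n - start_atg
                            out.append(
                                ORF(
                                    strand=strand,
                                    frame=frame,
                                    start=fs,
                                    end=fe,
                                    aa_length=aa,
                                    protein=_translate(s[start_atg:q]),
                                )
                            )
                    start_atg = None
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}


def _translate(seq: str) -> str:
    return "".join(
        _CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def detect_new_exons(
    coverage: CoverageTrack,
    genes: Sequence[GeneModel],
    junctions: Sequence[SpliceJunction],
    min_depth: int = 2,
    min_length: int = 36,
) -> list[NewExonCandidate]:
    """Intronic coverage runs with dual boundary-junction support.

    A candidate is a TAR-like run (depth >= ``min_depth``, length >
    35 bases) strictly inside an annotated intron whose left edge is the
    acceptor end of one called junction and whose right edge is the donor
    end of another (splicing the run into the transcript from both flanking
    exons).  Runs lacking either junction count as retained-intron
    evidence instead and are not reported here.
    """
    called = [j for j in junctions if j.called]
    by_end: dict[tuple[str, str, int], list[SpliceJunction]] = {}
    by_start: dict[tuple[str, str, int], list[SpliceJunction]] = {}
    for j in called:
        c = j.candidate
        by_end.setdefault((c.chrom, c.strand, c.intron_end), []).append(j)
        by_start.setdefault((c.chrom, c.strand, c.intron_start), []).append(j)
    out: list[NewExonCandidate] = []
    for g in genes:
        depth = coverage.arrays[g.chrom]
        for idx, (istart, iend) in enumerate(g.introns):
            window = depth[istart:iend]
            for rs, re_ in _runs_from_mask(window >= min_depth, 0):
                if re_ - rs < min_length:
                    continue
                if rs == 0 and re_ == iend - istart:
                    continue  # full-intron coverage is retained-intron evidence
                run_start, run_end = istart + rs, istart + re_
                left = [
                    j
                    for j in by_end.get((g.chrom, g.strand, run_start), [])
                    if j.candidate.intron_start >= istart - 1
                ]
                right = [
                    j
                    for j in by_start.get((g.chrom, g.strand, run_end), [])
                    if j.candidate.intron_end <= iend + 1
                ]
                if left and right:
                    out.append(
                        NewExonCandidate(
                            gene_id=g.gene_id,
                            intron_index=idx,
                            chrom=g.chrom,
                            start=run_start,
                            end=run_end,
                            mean_depth=float(window[rs:re_].mean()),
                            left_support=sum(len(j.trans_reads) for j in left),
                            right_support=sum(len(j.trans_reads) for j in right),
                        )
                    )
    return out
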