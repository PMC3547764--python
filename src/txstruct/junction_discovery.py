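"""Splice-junction discovery from genome-unmapped reads.

The stages mirror a classic trans-read junction caller for GT-AG introns:

1. enumerate candidate donor (GT forward / AC reverse) and acceptor
   (AG forward / CT reverse) dinucleotides inside the search regions,
   keeping only sites touched by uniquely-mapped read coverage;
2. pair same-strand donor->acceptor sites into junction candidates and
   stitch an exonic flank on each side into a junction sequence;
3. rescue reads that failed full-length genome mapping by progressively
   trimming one base at a time from the 3' end and re-searching the genome
   (exact substring search on both strands), stopping at the first match
   or below 40 retained bases;
4. align the rescued reads (and their reverse complements) against the
   junction sequences with at most 2 mismatches, requiring at least 5
   matched bases on each side of the junction midpoint; reads tied for
   their best placement across several candidates are dropped as
   ambiguous.  A junction is called when at least two unambiguous
   trans-reads support it at distinct offsets.

Junction sequences are stored in forward-genome orientation for both
strands; because every read is scanned in both orientations this is
equivalent to building reverse-strand junctions in transcription order.

The aligner uses a pigeonhole seed index (a read with at most k mismatches
must contain an exact segment of length len(read) // (k + 1)), which finds
exactly the placements a brute-force Hamming scan over all offsets and both
orientations would find.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .coverage_expression import CoverageTrack
from .genome_model import Genome, revcomp

__all__ = [
    "SpliceSite",
    "JunctionCandidate",
    "TransRead",
    "SpliceJunction",
    "RescuedRead",
    "enumerate_splice_sites",
    "build_junction_candidates",
    "rescue_unmapped_reads",
    "align_reads_to_junctions",
    "find_placements",
    "load_reads_fastq",
]

# dinucleotide -> (site kind, strand); positions follow the convention
# donor = first intronic base, acceptor = last intronic base, both in
# transcription order.
_SITE_PATTERNS = {
    "GT": ("donor", "+", 0),
    "AG": ("acceptor", "+", 1),
    "AC": ("donor", "-", 1),
    "CT": ("acceptor", "-", 0),
}


@dataclass(frozen=True)
class SpliceSite:
    chrom: str
    position: int
    kind: str  # donor | acceptor
    strand: str
    dinucleotide: str


@dataclass
class JunctionCandidate:
    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    donor: SpliceSite
    acceptor: SpliceSite
    seq: str
    flank_left: int  # bases of upstream-genome exon flank (junction midpoint)
    flank_right: int

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.intron_start, self.intron_end, self.strand)

    @property
    def intron_length(self) -> int:
        return self.intron_end - self.intron_start


@dataclass(frozen=True)
class TransRead:
    read_id: str
    offset: int
    mismatches: int
    orientation: str  # 'F' or 'R'


@dataclass
class SpliceJunction:
    candidate: JunctionCandidate
    trans_reads: list[TransRead] = field(default_factory=list)
    called: bool = False

    @property
    def distinct_offsets(self) -> int:
        return len({t.offset for t in self.trans_reads})


@dataclass
class RescuedRead:
    read_id: str
    seq: str
    retained_prefix: int


def enumerate_splice_sites(
    genome: Genome,
    regions: dict[str, list[tuple[int, int]]],
    coverage: CoverageTrack | None = None,
    support_margin: int = 1,
) -> list[SpliceSite]:
    """All GT/AG (forward) and AC/CT (reverse-strand) sites inside the regions.

    When a coverage track is given, a site must be supported by at least one
    uniquely mapped read within ``support_margin`` bases of its dinucleotide
    (coverage from spliced reads stops at the exon boundary, one base short
    of the intronic dinucleotide itself).
    """
    sites: list[SpliceSite] = []
    seen: set[tuple[str, int, str, str]] = set()
    for chrom, intervals in regions.items():
        seq = genome.sequences[chrom]
        depth = coverage.arrays[chrom] if coverage is not None else None
        for start, end in intervals:
            start = max(0, start)
            end = min(len(seq), end)
            for i in range(start, end - 1):
                dinuc = seq[i : i + 2]
                if dinuc not in _SITE_PATTERNS:
                    continue
                kind, strand, offset = _SITE_PATTERNS[dinuc]
                if depth is not None:
                    lo = max(0, i - support_margin)
                    hi = min(len(seq), i + 2 + support_margin)
                    if not (depth[lo:hi] > 0).any():
                        continue
                key = (chrom, i + offset, kind, strand)
                if key in seen:
                    continue
                seen.add(key)
                sites.append(SpliceSite(chrom, i + offset, kind, strand, dinuc))
    return sites


def build_junction_candidates(
    sites: Sequence[SpliceSite],
    genome: Genome,
    flank: int = 70,
    max_intron: int = 10_000,
    min_intron: int = 4,
    min_flank: int = 5,
) -> list[JunctionCandidate]:
    """All same-strand donor->acceptor pairs within the intron-length bounds.

    The default flank of 70 bases (read length 75 minus the 5-base minimum
    overhang) lets a full-length read overhang the junction by exactly the
    minimum on one side.  Flanks are clipped at contig bounds and the
    candidate kept while both flanks stay >= ``min_flank``.
    """
    donors: dict[tuple[str, str], list[SpliceSite]] = {}
    acceptors: dict[tuple[str, str], list[SpliceSite]] = {}
    for s in sites:
        target = donors if s.kind == "donor" else acceptors
        target.setdefault((s.chrom, s.strand), []).append(s)
    out: list[JunctionCandidate] = []
    for key, dlist in donors.items():
        alist = sorted(acceptors.get(key, []), key=lambda s: s.position)
        if not alist:
            continue
        chrom, strand = key
        seq = genome.sequences[chrom]
        for d in sorted(dlist, key=lambda s: s.position):
            for a in alist:
                if strand == "+":
                    istart, iend = d.position, a.position + 1
                else:
                    istart, iend = a.position, d.position + 1
                ilen = iend - istart
                if ilen < min_intron or ilen > max_intron:
                    continue
                left_lo = max(0, istart - flank)
                right_hi = min(len(seq), iend + flank)
                fl, fr = istart - left_lo, right_hi - iend
                if fl < min_flank or fr < min_flank:
                    continue
                out.append(
                    JunctionCandidate(
                        chrom=chrom,
                        intron_start=istart,
                        intron_end=iend,
                        strand=strand,
                        donor=d,
                        acceptor=a,
                        seq=seq[left_lo:istart] + seq[iend:right_hi],
                        flank_left=fl,
                        flank_right=fr,
                    )
                )
    out.sort(key=lambda c: c.key)
    return out


def load_reads_fastq(path: str | Path) -> list[tuple[str, str]]:
    """(read id, sequence) pairs from a FASTQ/FASTA file."""
    with pysam.FastxFile(str(path)) as fh:
        return [(rec.name, rec.sequence.upper()) for rec in fh]


def rescue_unmapped_reads(
    reads: Iterable[tuple[str, str]],
    genome: Genome,
    min_length: int = 40,
) -> list[RescuedRead]:
    """3'-trimming rescue of reads that failed full-length genome mapping.

    One base at a time is trimmed from the 3' end and the retained prefix
    searched in the genome (exact match, both strands) until the first hit,
    unless the read has been trimmed to fewer than ``min_length`` bases.
    """
    chrom_seqs = list(genome.sequences.values())

    def found(prefix: str) -> bool:
        rc = revcomp(prefix)
        return any(prefix in s or rc in s for s in chrom_seqs)

    out: list[RescuedRead] = []
    for read_id, seq in reads:
        seq = seq.upper()
        for L in range(len(seq) - 1, min_length - 1, -1):
            if found(seq[:L]):
                out.append(RescuedRead(read_id=read_id, seq=seq, retained_prefix=L))
                break
    return out


def _hamming(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


class _SeedIndex:
    """Pigeonhole seed index over the junction sequences.

    For reads of length R aligned with <= k mismatches, any placement has
    at least one exact segment among k+1 read segments of length
    R // (k+1); the index maps every such segment of every junction
    sequence to (candidate index, position).
    """

    def __init__(self, candidates: Sequence[JunctionCandidate], seg_len: int):
        self.seg_len = seg_len
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ci, cand in enumerate(candidates):
            s = cand.seq
            for pos in range(len(s) - seg_len + 1):
                self.index.setdefault(s[pos : pos + seg_len], []).append((ci, pos))

    def candidate_placements(self, read: str, n_segments: int) -> set[tuple[int, int]]:
        k = self.seg_len
        hits: set[tuple[int, int]] = set()
        for i in range(n_segments):
            seg = read[i * k : (i + 1) * k]
            if len(seg) < k:
                break
            for ci, pos in self.index.get(seg, ()):
                off = pos - i * k
                if off >= 0:
                    hits.add((ci, off))
        return hits


def find_placements(
    read: str,
    candidates: Sequence[JunctionCandidate],
    max_mismatch: int = 2,
    min_overhang: int = 5,
    _index_cache: dict | None = None,
) -> list[tuple[int, int, int, str]]:
    """All valid placements of a read (both orientations) on the candidates.

    Returns (candidate index, offset, mismatches, orientation) tuples for
    every placement with the read fully inside the junction sequence,
    <= ``max_mismatch`` mismatches and >= ``min_overhang`` bases on each
    side of the junction midpoint.  Exactly equivalent to a brute-force
    Hamming scan over all offsets and both orientations.
    """
    read = read.upper()
    seg_len = len(read) // (max_mismatch + 1)
    if seg_len < 1:
        return []
    if _index_cache is not None and seg_len in _index_cache:
        index = _index_cache[seg_len]
    else:
        index = _SeedIndex(candidates, seg_len)
        if _index_cache is not None:
            _index_cache[seg_len] = index
    out: list[tuple[int, int, int, str]] = []
    for orient, rseq in (("F", read), ("R", revcomp(read))):
        for ci, off in index.candidate_placements(rseq, max_mismatch + 1):
            cand = candidates[ci]
            if off + len(rseq) > len(cand.seq):
                continue
            mid = cand.flank_left
            if off > mid - min_overhang or off + len(rseq) < mid + min_overhang:
                continue
            mm = _hamming(rseq, cand.seq[off : off + len(rseq)], max_mismatch)
            if mm <= max_mismatch:
                out.append((ci, off, mm, orient))
    return out


def align_reads_to_junctions(
    reads: Iterable[tuple[str, str] | RescuedRead],
    candidates: Sequence[JunctionCandidate],
    max_mismatch: int = 2,
    min_overhang: int = 5,
    min_support: int = 2,
) -> list[SpliceJunction]:
    """Place reads on junction candidates and call supported junctions.

    Each read contributes at most one placement: its best-mismatch
    placement, provided that best score is achieved on a single candidate
    (reads tied across candidates are ambiguous and dropped).  A junction
    is called when supported by >= ``min_support`` unambiguous trans-reads
    with distinct start offsets.
    """
    junctions = {ci: SpliceJunction(candidate=c) for ci, c in enumerate(candidates)}
    index_cache: dict = {}
    for item in reads:
        if isinstance(item, RescuedRead):
            read_id, seq = item.read_id, item.seq
        else:
            read_id, seq = item
        placements = find_placements(
            seq, candidates, max_mismatch, min_overhang, _index_cache=index_cache
        )
        if not placements:
            continue
        best = min(p[2] for p in placements)
        best_placements = [p for p in placements if p[2] == best]
        if len({p[0] for p in best_placements}) > 1:
            continue  # ambiguous across candidates
        ci, off, mm, orient = min(best_placements, key=lambda p: p[1])
        junctions[ci].trans_reads.append(
            TransRead(read_id=read_id, offset=off, mismatches=mm, orientation=orient)
        )
    out = []
    for sj in junctions.values():
        if sj.trans_reads:
            sj.called = len(sj.trans_reads) >= min_support and sj.distinct_offsets >= 2
            out.append(sj)
    return out
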