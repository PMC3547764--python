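"""UTR boundary calling from coverage breaks, plus uORF / uATG screening.

UTR ends are found by walking outward from each annotated gene end, base by
base, while read depth stays above zero: the UTR ends at the last covered
base before the first zero-depth break (a single zero-depth base is a break
by default; the run length is configurable).  A walk that enters another
gene's span before finding a break marks that end neighbor-overlap-excluded;
a walk that reaches the chromosome end without a break discards the UTR.

5'-UTR sequences (mRNA sense) are then screened for upstream open reading
frames (uORFs: ATG .. in-frame stop wholly upstream of the main start, at
most 150 nt long, starting at most 500 nt before the main ATG) and for
alternative upstream initiation codons (uATGs: in frame with the coding
region, closer than 150 nt, with no in-frame stop codon between the uATG
and the main ATG).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .coverage_expression import CoverageTrack
from .genome_model import GeneModel, Genome, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")

STATUS_DEFINED = "defined"
STATUS_NO_BREAK = "no-break-discarded"
STATUS_NEIGHBOR = "neighbor-overlap-excluded"


@dataclass
class UTRAnnotation:
    gene_id: str
    utr5: tuple[int, int] | None
    utr3: tuple[int, int] | None
    utr5_len: int
    utr3_len: int
    status5: str
    status3: str


@dataclass
class UORF:
    gene_id: str
    start: int  # position of the uORF ATG within the 5'-UTR sequence
    end: int  # end of the stop codon (half-open)
    length: int  # nt, multiple of 3, stop codon included
    distance_to_cds_start: int  # uORF ATG -> main ATG, in bases


@dataclass
class UATG:
    gene_id: str
    position: int  # within the 5'-UTR sequence
    distance_to_cds_start: int
    in_frame: bool = True
    clean: bool = True  # no in-frame stop before the main ATG


def _walk_out(
    depth,
    start_pos: int,
    step: int,
    neighbor_spans: Sequence[tuple[int, int]],
    break_run: int,
) -> tuple[int, str]:
    """Walk outward from a gene end; return (utr length, status).

    ``start_pos`` is the first base outside the gene, ``step`` +1 or -1.
    """
    n = len(depth)
    length = 0
    zeros = 0
    off = 0
    while True:
        pos = start_pos + step * off
        if pos < 0 or pos >= n:
            return length, STATUS_NO_BREAK
        if depth[pos] == 0:
            zeros += 1
            if zeros >= break_run:
                return length, STATUS_DEFINED
        else:
            for s, e in neighbor_spans:
                if s <= pos < e:
                    return length, STATUS_NEIGHBOR
            zeros = 0
            length = off + 1
        off += 1


def annotate_utrs(
    gene: GeneModel,
    coverage: CoverageTrack,
    neighbors: Iterable[GeneModel],
    break_run: int = 1,
) -> UTRAnnotation:
    """Call the 5' and 3' UTR of one gene from the coverage track."""
    depth = coverage.arrays[gene.chrom]
    spans = [n.span for n in neighbors if n.gene_id != gene.gene_id and n.chrom == gene.chrom]
    gstart, gend = gene.span
    left_len, left_status = _walk_out(depth, gstart - 1, -1, spans, break_run)
    right_len, right_status = _walk_out(depth, gend, +1, spans, break_run)
    left_iv = (gstart - left_len, gstart) if left_status == STATUS_DEFINED else None
    right_iv = (gend, gend + right_len) if right_status == STATUS_DEFINED else None
    if gene.strand == "+":
        utr5, status5, len5 = left_iv, left_status, left_len
        utr3, status3, len3 = right_iv, right_status, right_len
    else:
        utr5, status5, len5 = right_iv, right_status, right_len
        utr3, status3, len3 = left_iv, left_status, left_len
    return UTRAnnotation(
        gene_id=gene.gene_id,
        utr5=utr5,
        utr3=utr3,
        utr5_len=len5 if status5 == STATUS_DEFINED else 0,
        utr3_len=len3 if status3 == STATUS_DEFINED else 0,
        status5=status5,
        status3=status3,
    )


def annotate_all_utrs(
    genes: Sequence[GeneModel], coverage: CoverageTrack, break_run: int = 1
) -> list[UTRAnnotation]:
    return [annotate_utrs(g, coverage, genes, break_run=break_run) for g in genes]


def utr5_sequence(gene: GeneModel, annotation: UTRAnnotation, genome: Genome) -> str:
    """The called 5'-UTR in mRNA sense orientation (empty if undefined)."""
    if annotation.utr5 is None:
        return ""
    s, e = annotation.utr5
    seq = genome.fetch(gene.chrom, s, e)
    return seq if gene.strand == "+" else revcomp(seq)


def _check_alphabet(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in UTR sequence: {sorted(bad)}")
    return seq


def scan_uorfs(
    utr5_seq: str,
    cds_offset: int | None = None,
    gene_id: str = "",
    max_length: int = 150,
    max_distance: int = 500,
) -> list[UORF]:
    """Find uORFs in a sense-strand 5'-UTR sequence.

    ``cds_offset`` is the position of the main ATG within ``utr5_seq``
    coordinates (defaults to ``len(utr5_seq)``, i.e. the CDS begins right
    after the supplied sequence).  Every ATG in any frame that reaches an
    in-frame stop codon ending at or before the CDS start is a candidate;
    candidates longer than ``max_length`` nt (stop included) or starting
    more than ``max_distance`` nt before the main ATG are removed.
    Overlapping or nested uORFs in different frames are all reported.
    """
    seq = _check_alphabet(utr5_seq)
    if cds_offset is None:
        cds_offset = len(seq)
    out: list[UORF] = []
    for p in range(min(cds_offset, len(seq) - 2)):
        if seq[p : p + 3] != "ATG":
            continue
        q = p + 3
        while q + 3 <= cds_offset and q + 3 <= len(seq):
            if seq[q : q + 3] in STOP_CODONS:
                length = q + 3 - p
                distance = cds_offset - p
                if length <= max_length and distance <= max_distance:
                    out.append(
                        UORF(
                            gene_id=gene_id,
                            start=p,
                            end=q + 3,
                            length=length,
                            distance_to_cds_start=distance,
                        )
                    )
                break
            q += 3
    return out


def scan_uatgs(
    utr5_seq: str,
    cds_offset: int | None = None,
    gene_id: str = "",
    max_distance: int = 150,
) -> list[UATG]:
    """Find in-frame alternative upstream start codons in a 5'-UTR.

    A uATG must lie closer than ``max_distance`` nt to the main ATG, in
    frame with it (distance divisible by 3), with no stop codon in that
    frame between the uATG and the main start.  The screen looks only at
    the supplied UTR sequence, so output is invariant to any sequence
    appended 5' of the screen window.
    """
    seq = _check_alphabet(utr5_seq)
    if cds_offset is None:
        cds_offset = len(seq)
    out: list[UATG] = []
    for p in range(min(cds_offset, len(seq) - 2)):
        if seq[p : p + 3] != "ATG":
            continue
        distance = cds_offset - p
        if distance <= 0 or distance >= max_distance or distance % 3 != 0:
            continue
        clean = True
        for q in range(p + 3, cds_offset, 3):
            if seq[q : q + 3] in STOP_CODONS:
                clean = False
                break
        if clean:
            out.append(
                UATG(gene_id=gene_id, position=p, distance_to_cds_start=distance)
            )
    return out
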