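"""Genome, gene-model and genomic-region containers plus FASTA/GFF3/BED I/O.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
GFF3 files use 1-based inclusive coordinates; the conversion happens here,
at the I/O boundary, and nowhere else.

A gene model is the exon chain of a protein-coding gene; introns are derived
as the gaps between consecutive exons.  The region partition labels every
base of every chromosome as exonic, intronic or intergenic, strandlessly:
the partition feeds a non-strand-specific read library, so a base inside one
gene's intron but another gene's exon counts as exonic (read-assignment
priority exon > intron > intergenic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
from Bio import SeqIO

from ._intervals import (
    complement_intervals,
    merge_intervals,
    subtract_intervals,
)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

REGION_LABELS = ("exonic", "intronic", "intergenic")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised when a genome or annotation file violates its contract."""


@dataclass
class Genome:
    """Chromosome name -> upper-case nucleotide sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise AnnotationError(f"chromosome {name!r} has an empty sequence")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise AnnotationError(
                f"fetch [{start}, {end}) outside chromosome {chrom} (length {len(seq)})"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class GeneModel:
    """Exon chain of one protein-coding gene, 0-based half-open coordinates.

    ``cds_start``/``cds_end`` bound the annotated coding span; for the
    CDS-only annotations this package works from they coincide with the
    gene span.  Introns are exactly the gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: no exons")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise AnnotationError(f"gene {self.gene_id}: empty exon [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"gene {self.gene_id}: overlapping exons at {s} < {prev_end}"
                )
            prev_end = e
        if self.cds_start is None:
            self.cds_start = self.exons[0][0]
        if self.cds_end is None:
            self.cds_end = self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def is_internal_exon(self, idx: int) -> bool:
        return 0 < idx < len(self.exons) - 1


@dataclass
class Region:
    chrom: str
    start: int
    end: int
    label: str


@dataclass
class RegionSet:
    """Strandless exonic/intronic/intergenic partition of a genome."""

    by_label: dict[str, dict[str, list[tuple[int, int]]]] = field(default_factory=dict)

    def intervals(self, label: str) -> dict[str, list[tuple[int, int]]]:
        return self.by_label.get(label, {})

    def __iter__(self) -> Iterator[Region]:
        for label, per_chrom in self.by_label.items():
            for chrom, ivs in per_chrom.items():
                for s, e in ivs:
                    yield Region(chrom, s, e, label)


# ---------------------------------------------------------------------------
# I/O


def load_genome(path: str | Path) -> Genome:
    """Read a FASTA file into a Genome; sequences are case-folded to upper."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise AnnotationError(f"{path}: line 1 is not a FASTA header: {first!r}")
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise AnnotationError(f"{path}: duplicate sequence name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise AnnotationError(f"{path}: no FASTA records found")
    return Genome(sequences)


def write_genome(genome: Genome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_annotation(path: str | Path, genome: Genome) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon/CDS features).

    GFF3 1-based inclusive coordinates are converted to the internal
    0-based half-open frame.  Exons outside chromosome bounds or
    overlapping within one gene raise :class:`AnnotationError`.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.seqid not in genome:
            raise AnnotationError(
                f"gene {gene.id}: unknown chromosome {gene.seqid!r}"
            )
        chrom_len = genome.lengths[gene.seqid]
        exons = []
        for exon in db.children(gene, featuretype="exon", order_by="start"):
            s, e = exon.start - 1, exon.end  # GFF3 1-based inclusive -> half-open
            if s < 0 or e > chrom_len:
                raise AnnotationError(
                    f"gene {gene.id}: exon [{exon.start}, {exon.end}] outside "
                    f"chromosome {gene.seqid} (length {chrom_len})"
                )
            exons.append((s, e))
        if not exons:
            # gene without exon children: treat the gene span as one exon
            exons = [(gene.start - 1, gene.end)]
        cds = [
            (c.start - 1, c.end) for c in db.children(gene, featuretype="CDS")
        ]
        cds_start = min(s for s, _ in cds) if cds else None
        cds_end = max(e for _, e in cds) if cds else None
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return genes


def write_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 with gene/mRNA/exon/CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s1, e1 = g.span[0] + 1, g.span[1]
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\ttxstruct\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\ttxstruct\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            exons = g.exons if g.strand == "+" else list(reversed(g.exons))
            phase = 0
            for i, (es, ee) in enumerate(sorted(g.exons)):
                fh.write(
                    f"{g.chrom}\ttxstruct\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i + 1};Parent={mrna_id}\n"
                )
            for es, ee in exons:
                fh.write(
                    f"{g.chrom}\ttxstruct\tCDS\t{es + 1}\t{ee}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna_id}.cds;Parent={mrna_id}\n"
                )
                phase = (3 - ((ee - es) - phase) % 3) % 3


def write_regions_bed(regions: RegionSet, path: str | Path) -> None:
    """BED6 dump of the region partition (score 0, strand '.')."""
    rows = sorted(regions, key=lambda r: (r.chrom, r.start))
    with open(path, "w") as fh:
        for r in rows:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t0\t.\n")


# ---------------------------------------------------------------------------
# Derived structures


def derive_regions(genes: Iterable[GeneModel], genome: Genome) -> RegionSet:
    """Partition each chromosome into exonic / intronic / intergenic bases.

    Exonic is the union of all exons of all genes (any strand); intronic is
    within-gene-span bases not exonic in any gene; intergenic is the rest.
    """
    exons_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.sequences}
    spans_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.sequences}
    for g in genes:
        if g.chrom not in exons_by_chrom:
            raise AnnotationError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
        exons_by_chrom[g.chrom].extend(g.exons)
        spans_by_chrom[g.chrom].append(g.span)
    out: dict[str, dict[str, list[tuple[int, int]]]] = {
        label: {} for label in REGION_LABELS
    }
    for chrom, length in genome.lengths.items():
        exonic = merge_intervals(exons_by_chrom[chrom])
        spans = merge_intervals(spans_by_chrom[chrom])
        intronic = subtract_intervals(spans, exonic)
        intergenic = complement_intervals(spans, length)
        out["exonic"][chrom] = exonic
        out["intronic"][chrom] = intronic
        out["intergenic"][chrom] = intergenic
    return RegionSet(out)


def find_overlapping_transcripts(genes: Iterable[GeneModel]) -> list[tuple[str, str]]:
    """All unordered pairs of genes whose genomic spans intersect by >= 1 base.

    Any strand combination counts; each pair is reported once, id-sorted.
    Uses a sweep over span starts (O(n log n + k)).
    """
    per_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        per_chrom.setdefault(g.chrom, []).append((g.span[0], g.span[1], g.gene_id))
    pairs: list[tuple[str, str]] = []
    for entries in per_chrom.values():
        entries.sort()
        active: list[tuple[int, str]] = []  # (end, gene_id)
        for start, end, gid in entries:
            active = [(e, i) for e, i in active if e > start]
            for _, other in active:
                pairs.append(tuple(sorted((other, gid))))
            active.append((end, gid))
    return sorted(set(pairs))
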