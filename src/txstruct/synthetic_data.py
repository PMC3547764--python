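"""Synthetic genomes, gene models, isoforms and paired-end reads with truth.

The generator emulates a deeply sequenced, non-strand-specific 75-bp
paired-end mRNA library from a compact, gene-dense fungal genome:

* random-base chromosomes with non-overlapping genes on both strands;
* CDS-only gene annotation, with true UTRs (lognormal lengths, 5' median
  102 bp, 3' median 85.5 bp) transcribed but not annotated, so UTR
  boundaries must be recovered from coverage;
* GT..AG introns (normal lengths, mean 99 bp; retained introns drawn
  shorter, mean 89 bp) with splice dinucleotides planted on the coding
  strand;
* alternative-splicing isoforms per requested event type (RI, SE, A5SS,
  A3SS, MXE) expressed alongside the canonical isoform — alternative
  first/last exons place their defining splice sites outside annotated
  introns and are exercised at the classifier level instead;
* 5'-UTRs of designated genes scrubbed of spurious ATGs and planted with
  one uORF or one clean in-frame uATG;
* intergenic novel transcripts (single- and two-block) plus a deliberately
  sub-150-bp unit that the transcript-unit filters must reject;
* fragments drawn from each expressed isoform as a deterministic tiling
  lattice (guaranteeing saturating coverage and multi-offset junction
  support) plus random fragments, mates 75 bp from the fragment ends;
  reads crossing a splice junction cannot map contiguously to the genome
  and are emitted into the unmapped set, everything else into a
  true-placement SAM.

Everything is deterministic given the seed.  The error model is
substitution-only; errors never move a read's true placement.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genome_model import GeneModel, Genome, revcomp, write_annotation, write_genome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NONSTOP_ALPHABET = "CGT"  # codons over C/G/T contain no ATG and no stop codon

AS_SIM_TYPES = ("RI", "SE", "A5SS", "A3SS", "MXE")


@dataclass
class SimulationParams:
    """Study conditions for the simulated library.

    Defaults follow the emulated study where it states a value (75-bp
    paired-end reads, ~99-bp canonical and ~89-bp retained introns, UTR
    medians 102 / 85.5 bp) and otherwise use realistic compact-yeast
    magnitudes.
    """

    seed: int = 1
    n_chromosomes: int = 1
    chromosome_length: int = 140_000
    # gene roster
    n_plain_single: int = 4
    n_plain_multi: int = 4
    n_uorf_genes: int = 5
    n_uatg_genes: int = 5
    n_new_exon_genes: int = 2
    as_events: dict = field(
        default_factory=lambda: {"RI": 10, "SE": 10, "A5SS": 10, "A3SS": 10, "MXE": 2}
    )
    # gene geometry (bases)
    exon_length_range: tuple[int, int] = (200, 400)
    internal_exon_length_range: tuple[int, int] = (80, 150)
    intron_length_mean: float = 99.0
    intron_length_sd: float = 15.0
    ri_intron_length_mean: float = 89.0
    min_intron_length: int = 60
    new_exon_intron_range: tuple[int, int] = (260, 330)
    new_exon_length: int = 120  # must exceed the read length so reads map inside
    alt_site_shift: int = 12
    utr5_median: float = 102.0
    utr3_median: float = 85.5
    utr_sigma: float = 0.45
    utr_min: int = 20
    utr_max: int = 300
    gap_range: tuple[int, int] = (200, 500)
    # novel intergenic transcripts
    n_novel_single: int = 5
    n_novel_spliced: int = 3
    novel_length_range: tuple[int, int] = (300, 600)
    novel_block_length: int = 200
    novel_gap_length: int = 80
    include_sub150_control: bool = True
    sub150_length: int = 140
    # reads
    read_length: int = 75
    tile_step: int = 25
    extra_depth: float = 4.0
    fragment_mean: float = 180.0
    fragment_sd: float = 20.0
    base_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.read_length < 45:
            raise ValueError("read_length must be >= 45 (trim floor is 40 bases)")
        for name in (
            "n_plain_single", "n_plain_multi", "n_uorf_genes", "n_uatg_genes",
            "n_new_exon_genes", "n_novel_single", "n_novel_spliced",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for t, n in self.as_events.items():
            if t not in AS_SIM_TYPES:
                raise ValueError(
                    f"cannot simulate AS type {t!r}; supported: {AS_SIM_TYPES}"
                )
            if n < 0:
                raise ValueError("as_events counts must be >= 0")

    @property
    def n_genes(self) -> int:
        return (
            self.n_plain_single
            + self.n_plain_multi
            + self.n_uorf_genes
            + self.n_uatg_genes
            + self.n_new_exon_genes
            + sum(self.as_events.values())
        )


@dataclass
class Isoform:
    tx_id: str
    chrom: str
    blocks: list[tuple[int, int]]  # genomic, ascending, half-open
    gene_id: str | None
    kind: str

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def junction_tx_positions(self) -> list[int]:
        """Transcript coordinates of internal block boundaries."""
        out, cum = [], 0
        for s, e in self.blocks[:-1]:
            cum += e - s
            out.append(cum)
        return out


@dataclass
class SimulationTruth:
    genes: list[GeneModel] = field(default_factory=list)
    gene_roles: dict[str, str] = field(default_factory=dict)
    utr5: dict[str, tuple[int, int]] = field(default_factory=dict)
    utr3: dict[str, tuple[int, int]] = field(default_factory=dict)
    utr5_len: dict[str, int] = field(default_factory=dict)
    utr3_len: dict[str, int] = field(default_factory=dict)
    uorfs: list[dict] = field(default_factory=list)
    uatgs: list[dict] = field(default_factory=list)
    junctions: set[tuple[str, int, int, str]] = field(default_factory=set)
    as_events: list[dict] = field(default_factory=list)
    new_exons: list[dict] = field(default_factory=list)
    novel_units: list[dict] = field(default_factory=list)
    isoforms: list[Isoform] = field(default_factory=list)
    read_origins: list[dict] = field(default_factory=list)


@dataclass
class MappedRead:
    qname: str
    mate: int  # 1 or 2
    chrom: str
    pos: int
    is_reverse: bool
    seq: str  # as sequenced (reverse reads are the reverse complement)


@dataclass
class ReadSet:
    read_length: int
    mapped: list[MappedRead] = field(default_factory=list)
    unmapped: list[tuple[str, str]] = field(default_factory=list)  # (id, seq)
    fastq1: list[tuple[str, str]] = field(default_factory=list)
    fastq2: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class Simulation:
    params: SimulationParams
    genome: Genome
    genes: list[GeneModel]
    truth: SimulationTruth
    reads: ReadSet


# ---------------------------------------------------------------------------
# genome + annotation


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _scrub_atg(seq: list[str], start: int, end: int) -> None:
    """Remove every sense-strand ATG in seq[start:end] (T -> C)."""
    for i in range(start, end - 2):
        if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G":
            seq[i + 1] = "C"


def _nonstop_codons(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, 3, 3 * n_codons)
    return "".join(_NONSTOP_ALPHABET[i] for i in idx)


def _draw_utr(rng: np.random.Generator, median: float, p: SimulationParams) -> int:
    val = int(round(rng.lognormal(np.log(median), p.utr_sigma)))
    return int(np.clip(val, p.utr_min, p.utr_max))


def _draw_intron(rng: np.random.Generator, mean: float, p: SimulationParams) -> int:
    val = int(round(rng.normal(mean, p.intron_length_sd)))
    return max(val, p.min_intron_length)


def _gaps_to_blocks(gaps: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    blocks, cur = [], 0
    for s, e in sorted(gaps):
        if s > cur:
            blocks.append((cur, s))
        cur = e
    if cur < length:
        blocks.append((cur, length))
    return blocks


class _GeneBuilder:
    """Builds one gene's sense-coordinate layout, sequence and truth."""

    def __init__(self, role: str, rng: np.random.Generator, p: SimulationParams):
        self.role = role
        self.rng = rng
        self.p = p
        self.utr5 = _draw_utr(rng, p.utr5_median, p)
        self.utr3 = _draw_utr(rng, p.utr3_median, p)
        if role in ("uorf", "uatg"):
            self.utr5 = max(self.utr5, 200)
        exon_lengths, intron_lengths = self._structure()
        # sense coordinates relative to the transcribed-region start
        self.exons_sense: list[tuple[int, int]] = []
        self.introns_sense: list[tuple[int, int]] = []
        pos = self.utr5
        for i, el in enumerate(exon_lengths):
            self.exons_sense.append((pos, pos + el))
            pos += el
            if i < len(intron_lengths):
                self.introns_sense.append((pos, pos + intron_lengths[i]))
                pos += intron_lengths[i]
        self.cds_end_sense = pos
        self.length = pos + self.utr3
        self.seq = [chr(b) for b in _random_seq(rng, self.length)]
        self._plant_codons()
        self.minor_gaps: list[list[tuple[int, int]]] = []
        self.event_region_sense: tuple[int, int] | None = None
        self.new_exon_sense: tuple[int, int] | None = None
        self.uorf_info: dict | None = None
        self.uatg_info: dict | None = None
        self._plant_role_features()

    def _structure(self) -> tuple[list[int], list[int]]:
        rng, p = self.rng, self.p
        exon = lambda: int(rng.integers(*p.exon_length_range))  # noqa: E731
        internal = lambda: int(rng.integers(*p.internal_exon_length_range))  # noqa: E731
        if self.role in ("plain_single", "uorf", "uatg"):
            return [exon()], []
        if self.role == "RI":
            return [exon(), exon()], [_draw_intron(rng, p.ri_intron_length_mean, p)]
        if self.role in ("plain_multi", "A5SS", "A3SS"):
            return [exon(), exon()], [_draw_intron(rng, p.intron_length_mean, p)]
        if self.role == "SE":
            return (
                [exon(), internal(), exon()],
                [_draw_intron(rng, p.intron_length_mean, p) for _ in range(2)],
            )
        if self.role == "MXE":
            return (
                [exon(), internal(), internal(), exon()],
                [_draw_intron(rng, p.intron_length_mean, p) for _ in range(3)],
            )
        if self.role == "new_exon":
            return [exon(), exon()], [int(rng.integers(*p.new_exon_intron_range))]
        raise ValueError(f"unknown role {self.role!r}")

    def _plant(self, pos: int, s: str) -> None:
        self.seq[pos : pos + len(s)] = list(s)

    def _plant_codons(self) -> None:
        self._plant(self.utr5, "ATG")
        self._plant(self.cds_end_sense - 3, "TAA")
        for s, e in self.introns_sense:
            self._plant(s, "GT")
            self._plant(e - 2, "AG")

    def _plant_role_features(self) -> None:
        rng, p = self.rng, self.p
        introns = self.introns_sense
        gaps_all = list(introns)
        if self.role == "RI":
            self.minor_gaps = [[]]  # intron retained: no splicing in the minor form
            self.event_region_sense = introns[0]
        elif self.role == "SE":
            self.minor_gaps = [[(introns[0][0], introns[1][1])]]
            self.event_region_sense = self.exons_sense[1]
        elif self.role == "A5SS":
            s, e = introns[0]
            shift = p.alt_site_shift
            self._plant(s + shift, "GT")
            self.minor_gaps = [[(s + shift, e)]]
            self.event_region_sense = (s, s + shift)
        elif self.role == "A3SS":
            s, e = introns[0]
            shift = p.alt_site_shift
            self._plant(e - shift - 2, "AG")
            self.minor_gaps = [[(s, e - shift)]]
            self.event_region_sense = (e - shift, e)
        elif self.role == "MXE":
            g1, g2, g3 = introns
            self.minor_gaps = [
                [g1, (g2[0], g3[1])],  # includes exon 2, skips exon 3
                [(g1[0], g2[1]), g3],  # includes exon 3, skips exon 2
            ]
            self.event_region_sense = (self.exons_sense[1][0], self.exons_sense[2][1])
        elif self.role == "new_exon":
            s, e = introns[0]
            margin = int(rng.integers(60, 90))
            xs = s + margin
            xe = xs + p.new_exon_length
            self._plant(xs - 2, "AG")
            self._plant(xe, "GT")
            self.minor_gaps = [[(s, xs), (xe, e)]]
            self.new_exon_sense = (xs, xe)
        elif self.role == "uorf":
            _scrub_atg(self.seq, 0, self.utr5)
            n_codons = int(rng.integers(4, 41))  # 12..120 nt including the stop
            length = 3 * n_codons
            distance = int(rng.integers(length, self.utr5 + 1))
            start = self.utr5 - distance
            self._plant(start, "ATG" + _nonstop_codons(rng, n_codons - 2) + "TAA")
            self.uorf_info = {"length": length, "distance": distance}
        elif self.role == "uatg":
            _scrub_atg(self.seq, 0, self.utr5)
            distance = 3 * int(rng.integers(10, 49))  # 30..144, in frame, < 150
            start = self.utr5 - distance
            self._plant(start, "ATG" + _nonstop_codons(rng, distance // 3 - 1))
            self.uatg_info = {"distance": distance}
        if self.role == "MXE":
            self.isoform_gaps = list(self.minor_gaps)  # no all-exon isoform
        else:
            self.isoform_gaps = [gaps_all] + self.minor_gaps


def _map_interval(
    iv: tuple[int, int], start: int, length: int, strand: str
) -> tuple[int, int]:
    a, b = iv
    if strand == "+":
        return (start + a, start + b)
    return (start + length - b, start + length - a)


def simulate_genome_and_annotation(
    params: SimulationParams,
) -> tuple[Genome, list[GeneModel], SimulationTruth]:
    """Deterministically build the genome, CDS-only annotation and truth."""
    rng = np.random.default_rng([params.seed, 0])
    chrom_names = [f"chr{i + 1}" for i in range(params.n_chromosomes)]
    chrom_arrays = {
        name: [chr(b) for b in _random_seq(rng, params.chromosome_length)]
        for name in chrom_names
    }
    truth = SimulationTruth()

    roles: list[str] = (
        ["plain_single"] * params.n_plain_single
        + ["plain_multi"] * params.n_plain_multi
        + ["uorf"] * params.n_uorf_genes
        + ["uatg"] * params.n_uatg_genes
        + ["new_exon"] * params.n_new_exon_genes
        + [t for t, n in params.as_events.items() for _ in range(n)]
    )
    elements = [("gene", r) for r in roles]
    elements += [("novel_single", i) for i in range(params.n_novel_single)]
    elements += [("novel_spliced", i) for i in range(params.n_novel_spliced)]
    if params.include_sub150_control:
        elements.append(("novel_sub150", 0))
    rng.shuffle(elements)

    chrom_idx = 0
    margin = 250
    cursor = margin
    gene_n = 0
    novel_n = 0
    for kind, payload in elements:
        gap = int(rng.integers(*params.gap_range))
        if kind == "gene":
            gene_n += 1
            builder = _GeneBuilder(payload, rng, params)
            span = builder.length
        elif kind == "novel_single":
            span = int(rng.integers(*params.novel_length_range))
        elif kind == "novel_spliced":
            span = 2 * params.novel_block_length + params.novel_gap_length
        else:
            span = params.sub150_length
        while cursor + gap + span > params.chromosome_length - margin:
            chrom_idx += 1
            cursor = margin
            if chrom_idx >= params.n_chromosomes:
                raise ValueError(
                    "simulated elements do not fit: increase chromosome_length "
                    "or n_chromosomes"
                )
        chrom = chrom_names[chrom_idx]
        start = cursor + gap
        cursor = start + span

        if kind == "novel_single":
            novel_n += 1
            tx_id = f"NOV{novel_n:03d}"
            if payload == 0:  # plant one protein-coding ORF in the first unit
                arr = chrom_arrays[chrom]
                orf = "ATG" + _nonstop_codons(rng, 34) + "TAA"
                arr[start + 10 : start + 10 + len(orf)] = list(orf)
            truth.novel_units.append(
                {
                    "tu_id": tx_id,
                    "chrom": chrom,
                    "blocks": [(start, start + span)],
                    "expect_reported": True,
                }
            )
            truth.isoforms.append(
                Isoform(tx_id, chrom, [(start, start + span)], None, "novel_single")
            )
            continue
        if kind == "novel_spliced":
            novel_n += 1
            tx_id = f"NOV{novel_n:03d}"
            b = params.novel_block_length
            blocks = [
                (start, start + b),
                (start + b + params.novel_gap_length, start + span),
            ]
            truth.novel_units.append(
                {"tu_id": tx_id, "chrom": chrom, "blocks": blocks,
                 "expect_reported": True}
            )
            truth.isoforms.append(Isoform(tx_id, chrom, blocks, None, "novel_spliced"))
            continue
        if kind == "novel_sub150":
            novel_n += 1
            tx_id = f"NOV{novel_n:03d}"
            truth.novel_units.append(
                {
                    "tu_id": tx_id,
                    "chrom": chrom,
                    "blocks": [(start, start + span)],
                    "expect_reported": False,
                }
            )
            truth.isoforms.append(
                Isoform(tx_id, chrom, [(start, start + span)], None, "novel_sub150")
            )
            continue

        # --- gene ----------------------------------------------------------
        gene_id = f"G{gene_n:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        sense_seq = "".join(builder.seq)
        arr = chrom_arrays[chrom]
        written = sense_seq if strand == "+" else revcomp(sense_seq)
        arr[start : start + span] = list(written)

        def gmap(iv: tuple[int, int]) -> tuple[int, int]:
            return _map_interval(iv, start, span, strand)

        exons = sorted(gmap(e) for e in builder.exons_sense)
        gene = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons)
        truth.genes.append(gene)
        truth.gene_roles[gene_id] = builder.role
        truth.utr5[gene_id] = gmap((0, builder.utr5))
        truth.utr3[gene_id] = gmap((builder.length - builder.utr3, builder.length))
        truth.utr5_len[gene_id] = builder.utr5
        truth.utr3_len[gene_id] = builder.utr3
        if builder.uorf_info:
            truth.uorfs.append({"gene_id": gene_id, **builder.uorf_info})
        if builder.uatg_info:
            truth.uatgs.append({"gene_id": gene_id, **builder.uatg_info})
        if builder.event_region_sense is not None:
            s, e = gmap(builder.event_region_sense)
            truth.as_events.append(
                {"gene_id": gene_id, "type": builder.role, "chrom": chrom,
                 "start": s, "end": e}
            )
        if builder.new_exon_sense is not None:
            s, e = gmap(builder.new_exon_sense)
            truth.new_exons.append(
                {"gene_id": gene_id, "intron_index": 0, "chrom": chrom,
                 "start": s, "end": e}
            )
        for iso_i, gaps in enumerate(builder.isoform_gaps, start=1):
            blocks = sorted(
                gmap(b) for b in _gaps_to_blocks(gaps, builder.length)
            )
            truth.isoforms.append(
                Isoform(f"{gene_id}.i{iso_i}", chrom, blocks, gene_id, builder.role)
            )
            for gs, ge in sorted(gmap(g) for g in gaps):
                truth.junctions.add((chrom, gs, ge, strand))

    genome = Genome({name: "".join(arr) for name, arr in chrom_arrays.items()})
    return genome, truth.genes, truth


# ---------------------------------------------------------------------------
# reads


def _fragment_starts(
    L: int, flen: int, junctions: list[int], step: int
) -> list[tuple[int, int]]:
    """Deterministic lattice of (start, length) fragments.

    A regular grid plus, at every junction J, boundary-anchored fragments
    whose mate windows end/start exactly at J (saturating coverage at the
    block edges) and three straddling fragments whose mates fall wholly on
    opposite sides of J (guaranteed paired-end linking evidence).
    """
    starts = [(s, flen) for s in range(0, L - flen + 1, step)]
    if (L - flen) % step != 0:
        starts.append((L - flen, flen))
    half = flen // 2
    for J in junctions:
        for s in (J - flen, J - half, J):
            if 0 <= s <= L - flen:
                starts.append((s, flen))
        for extra in (20, 40):
            s, fl = J - half - extra // 2, flen + extra
            if 0 <= s <= L - fl:
                starts.append((s, fl))
    return starts


def simulate_reads(
    genome: Genome, truth: SimulationTruth, params: SimulationParams
) -> ReadSet:
    """Emit paired reads from every isoform; junction-spanning mates are
    routed to the unmapped set, everything else carries a true placement."""
    rng = np.random.default_rng([params.seed, 1])
    R = params.read_length
    readset = ReadSet(read_length=R)
    for iso in truth.isoforms:
        tx = "".join(genome.sequences[iso.chrom][s:e] for s, e in iso.blocks)
        L = len(tx)
        if L < R:
            continue
        flen = min(2 * R, L)
        junctions = iso.junction_tx_positions()
        frags = _fragment_starts(L, flen, junctions, params.tile_step)
        n_extra = int(round(params.extra_depth * L / (2 * R)))
        for _ in range(n_extra):
            fl = int(np.clip(round(rng.normal(params.fragment_mean,
                                              params.fragment_sd)), R, L))
            frags.append((int(rng.integers(0, L - fl + 1)), fl))
        # cumulative tx offsets of block starts, for read placement
        cum = [0]
        for s, e in iso.blocks:
            cum.append(cum[-1] + e - s)
        for serial, (fs, fl) in enumerate(frags):
            qname = f"{iso.tx_id}.f{serial}"
            flip = serial % 2 == 1
            windows = [(fs, True), (fs + fl - R, False)]  # (tx offset, sense)
            if flip:
                windows.reverse()
            for mate, (off, sense) in enumerate(windows, start=1):
                wseq = tx[off : off + R]
                emitted = wseq if sense else revcomp(wseq)
                n_err = 0
                if params.base_error_rate > 0:
                    n_err = int(rng.binomial(R, params.base_error_rate))
                    if n_err:
                        emitted = _mutate(emitted, n_err, rng)
                read_id = f"{qname}/{mate}"
                block_i = bisect_right(cum, off) - 1
                spanning = off + R > cum[block_i + 1]
                if spanning:
                    readset.unmapped.append((read_id, emitted))
                else:
                    gpos = iso.blocks[block_i][0] + (off - cum[block_i])
                    readset.mapped.append(
                        MappedRead(
                            qname=qname,
                            mate=mate,
                            chrom=iso.chrom,
                            pos=gpos,
                            is_reverse=not sense,
                            seq=emitted,
                        )
                    )
                (readset.fastq1 if mate == 1 else readset.fastq2).append(
                    (read_id, emitted)
                )
                truth.read_origins.append(
                    {
                        "read_id": read_id,
                        "tx_id": iso.tx_id,
                        "tx_start": off,
                        "spanning": spanning,
                        "n_errors": n_err,
                    }
                )
    return readset


def _mutate(seq: str, n: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(n, len(chars)), replace=False):
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate(params: SimulationParams | None = None) -> Simulation:
    params = params or SimulationParams()
    genome, genes, truth = simulate_genome_and_annotation(params)
    reads = simulate_reads(genome, truth, params)
    return Simulation(params=params, genome=genome, genes=genes, truth=truth,
                      reads=reads)


# ---------------------------------------------------------------------------
# writers


def write_sam(readset: ReadSet, genome: Genome, path: str | Path) -> None:
    """True-placement SAM for all genome-contiguous reads (MAPQ 60)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in genome.lengths.items()],
    }
    by_qname: dict[str, dict[int, MappedRead]] = {}
    for r in readset.mapped:
        by_qname.setdefault(r.qname, {})[r.mate] = r
    aln_header = pysam.AlignmentHeader.from_dict(header)
    ref_ids = {n: i for i, n in enumerate(genome.lengths)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in readset.mapped:
            a = pysam.AlignedSegment(aln_header)
            a.query_name = r.qname
            a.reference_id = ref_ids[r.chrom]
            a.reference_start = r.pos
            a.mapping_quality = 60
            a.cigarstring = f"{len(r.seq)}M"
            a.query_sequence = revcomp(r.seq) if r.is_reverse else r.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            flag = 0x1 | (0x40 if r.mate == 1 else 0x80)
            if r.is_reverse:
                flag |= 0x10
            mate = by_qname[r.qname].get(3 - r.mate)
            if mate is None:
                flag |= 0x8  # mate unmapped (junction-spanning)
            else:
                if mate.is_reverse:
                    flag |= 0x20
                a.next_reference_id = ref_ids[mate.chrom]
                a.next_reference_start = mate.pos
                flag |= 0x2
            a.flag = flag
            out.write(a)


def _write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_simulation(sim: Simulation, outdir: str | Path) -> dict[str, Path]:
    """Write genome, annotation, reads and truth tables; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "genes.gff3",
        "sam": outdir / "alignments.sam",
        "unmapped": outdir / "unmapped.fastq",
        "fastq1": outdir / "reads_1.fastq",
        "fastq2": outdir / "reads_2.fastq",
    }
    write_genome(sim.genome, paths["genome"])
    write_annotation(sim.genes, paths["annotation"])
    write_sam(sim.reads, sim.genome, paths["sam"])
    _write_fastq(sim.reads.unmapped, paths["unmapped"])
    _write_fastq(sim.reads.fastq1, paths["fastq1"])
    _write_fastq(sim.reads.fastq2, paths["fastq2"])
    t = sim.truth
    tables = {
        "truth_utrs": pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "role": t.gene_roles[g.gene_id],
                    "utr5_len": t.utr5_len[g.gene_id],
                    "utr3_len": t.utr3_len[g.gene_id],
                }
                for g in t.genes
            ]
        ),
        "truth_junctions": pd.DataFrame(
            sorted(t.junctions), columns=["chrom", "intron_start", "intron_end",
                                          "strand"]
        ),
        "truth_as_events": pd.DataFrame(t.as_events),
        "truth_novel_units": pd.DataFrame(
            [
                {
                    "tu_id": u["tu_id"],
                    "chrom": u["chrom"],
                    "blocks": ";".join(f"{s}-{e}" for s, e in u["blocks"]),
                    "expect_reported": u["expect_reported"],
                }
                for u in t.novel_units
            ]
        ),
        "truth_uorfs": pd.DataFrame(t.uorfs),
        "truth_uatgs": pd.DataFrame(t.uatgs),
        "truth_read_origins": pd.DataFrame(t.read_origins),
    }
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths
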