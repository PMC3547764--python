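"""End-to-end orchestration of the annotation stages.

Stage order: coverage -> region partition -> expression -> UTRs (and
uORF/uATG screens) -> intergenic novel-transcript discovery -> splice-site
and junction discovery -> new-exon nomination -> retained-intron and
junction-based AS classification -> summary.

Novel-transcript search runs on the intergenic partition minus the called
UTR intervals, so continuous UTR coverage flanking a gene is not mistaken
for an independent transcription unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import as_classifier, coverage_expression, junction_discovery, novel_discovery
from . import utr_annotation
from ._intervals import merge_intervals, subtract_intervals
from .genome_model import GeneModel, Genome, RegionSet, derive_regions
from .junction_discovery import SpliceJunction


@dataclass
class PipelineConfig:
    # expression
    assign_fraction: float = 0.5
    inactive_fraction: float = 0.05
    # UTRs and upstream features
    break_run: int = 1
    uorf_max_length: int = 150
    uorf_max_distance: int = 500
    uatg_max_distance: int = 150
    # novel discovery
    tar_min_depth: int = 2
    tar_min_length: int = 36  # strict > 35 bases
    tar_max_gap: int = 0
    tu_min_pairs: int = 3
    tu_min_length: int = 150
    tu_min_avg_depth: float = 2.0
    max_insert: int = 10_000
    orf_min_aa: int = 33
    # junctions
    read_length: int = 75
    intron_slop: int = 0
    max_intron: int = 10_000
    max_mismatch: int = 2
    min_overhang: int = 5
    rescue_min_length: int = 40
    # AS classification
    ri_min_depth: int = 2
    ri_ratio: float = 0.25

    @property
    def junction_flank(self) -> int:
        return self.read_length - self.min_overhang


@dataclass
class PipelineResult:
    coverage: coverage_expression.CoverageTrack
    regions: RegionSet
    expression: list[coverage_expression.ExpressionRecord]
    utrs: list[utr_annotation.UTRAnnotation]
    uorfs: list[utr_annotation.UORF]
    uatgs: list[utr_annotation.UATG]
    tars: list[novel_discovery.TAR]
    transcript_units: list[novel_discovery.TranscriptUnit]
    junctions: list[SpliceJunction]
    new_exons: list[novel_discovery.NewExonCandidate]
    events: list[as_classifier.ASEvent]
    summary: as_classifier.ASSummary
    rescued: list[junction_discovery.RescuedRead] = field(default_factory=list)

    @property
    def called_junctions(self) -> list[SpliceJunction]:
        return [j for j in self.junctions if j.called]


def run_pipeline(
    genome: Genome,
    genes: Sequence[GeneModel],
    sam_path: str | Path,
    unmapped_reads: Sequence[tuple[str, str]],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    genes = list(genes)
    coverage = coverage_expression.build_coverage(sam_path, genome)
    regions = derive_regions(genes, genome)

    counts, n_total = coverage_expression.assign_reads_to_genes(
        sam_path, genes, min_fraction=cfg.assign_fraction
    )
    expression = coverage_expression.compute_expression(
        genes, counts, n_total, coverage
    )
    if expression:
        coverage_expression.activity_filter_and_bins(
            expression, cfg.inactive_fraction
        )

    utrs = utr_annotation.annotate_all_utrs(genes, coverage, break_run=cfg.break_run)
    gene_by_id = {g.gene_id: g for g in genes}
    uorfs: list[utr_annotation.UORF] = []
    uatgs: list[utr_annotation.UATG] = []
    for ann in utrs:
        if ann.utr5 is None:
            continue
        seq = utr_annotation.utr5_sequence(gene_by_id[ann.gene_id], ann, genome)
        uorfs.extend(
            utr_annotation.scan_uorfs(
                seq, gene_id=ann.gene_id,
                max_length=cfg.uorf_max_length,
                max_distance=cfg.uorf_max_distance,
            )
        )
        uatgs.extend(
            utr_annotation.scan_uatgs(
                seq, gene_id=ann.gene_id, max_distance=cfg.uatg_max_distance
            )
        )

    # novel discovery on intergenic space, excluding called UTR extensions
    utr_ivs: dict[str, list[tuple[int, int]]] = {}
    for ann in utrs:
        chrom = gene_by_id[ann.gene_id].chrom
        for iv in (ann.utr5, ann.utr3):
            if iv is not None:
                utr_ivs.setdefault(chrom, []).append(iv)
    search = {
        chrom: subtract_intervals(ivs, utr_ivs.get(chrom, []))
        for chrom, ivs in regions.intervals("intergenic").items()
    }
    tars = novel_discovery.detect_tars(
        coverage, search, min_depth=cfg.tar_min_depth,
        min_length=cfg.tar_min_length, max_gap=cfg.tar_max_gap,
    )
    pairs = novel_discovery.collect_mate_pairs(sam_path)
    tus = novel_discovery.link_tars(
        tars, pairs, min_pairs=cfg.tu_min_pairs, min_length=cfg.tu_min_length,
        min_avg_depth=cfg.tu_min_avg_depth, max_insert=cfg.max_insert,
    )
    for tu in tus:
        seq = "".join(genome.fetch(t.chrom, t.start, t.end) for t in tu.tars)
        tu.orfs = novel_discovery.find_orfs(seq, min_aa=cfg.orf_min_aa)

    # junction discovery inside annotated introns (plus optional slop)
    intron_ivs: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        for s, e in g.introns:
            intron_ivs.setdefault(g.chrom, []).append(
                (max(0, s - cfg.intron_slop),
                 min(genome.lengths[g.chrom], e + cfg.intron_slop))
            )
    intron_ivs = {c: merge_intervals(ivs) for c, ivs in intron_ivs.items()}
    sites = junction_discovery.enumerate_splice_sites(genome, intron_ivs, coverage)
    candidates = junction_discovery.build_junction_candidates(
        sites, genome, flank=cfg.junction_flank, max_intron=cfg.max_intron,
        min_flank=cfg.min_overhang,
    )
    rescued = junction_discovery.rescue_unmapped_reads(
        unmapped_reads, genome, min_length=cfg.rescue_min_length
    )
    junctions = junction_discovery.align_reads_to_junctions(
        rescued, candidates, max_mismatch=cfg.max_mismatch,
        min_overhang=cfg.min_overhang,
    )
    called = [j for j in junctions if j.called]

    new_exons = novel_discovery.detect_new_exons(
        coverage, genes, called, min_depth=cfg.tar_min_depth,
        min_length=cfg.tar_min_length,
    )
    events = as_classifier.detect_retained_introns(
        genes, coverage, new_exons, min_depth=cfg.ri_min_depth, ri_ratio=cfg.ri_ratio
    )
    events += as_classifier.classify_junction_events(genes, called, new_exons)
    summary = as_classifier.summarize_as(events, genes)

    return PipelineResult(
        coverage=coverage,
        regions=regions,
        expression=expression,
        utrs=utrs,
        uorfs=uorfs,
        uatgs=uatgs,
        tars=tars,
        transcript_units=tus,
        junctions=junctions,
        new_exons=new_exons,
        events=events,
        summary=summary,
        rescued=rescued,
    )
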