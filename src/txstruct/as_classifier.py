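"""Seven-type alternative-splicing classification and summary statistics.

Event types: retained intron (RI), skipped exon (SE), alternative 5'/3'
splice sites (A5SS/A3SS), mutually exclusive exons (MXE) and alternative
first/last exons (AFE/ALE).  RI is called from intronic coverage (a fully
covered intron at a depth comparable to its flanking exons); the other six
types are called from supported splice junctions, with strand-aware donor
(5') and acceptor (3') coordinates.

Classification precedence prevents double counting of one signal:
new-exon candidates exclude their boundary junctions from alternative-site
grouping, junctions classified SE are excluded from A5SS/A3SS grouping,
pairs of SE calls with mutually exclusive skipped exons merge into MXE,
and alternative outer sites beyond the outermost annotated exon reclassify
an A5SS/A3SS group as AFE/ALE.

The cassette-exon ratio CE/(RI + CE), with CE = SE + AFE + ALE + MXE,
summarises whether splicing is exon-defined or intron-defined; an
RI-dominated transcriptome with a ratio near zero points at intron
definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .coverage_expression import CoverageTrack
from .genome_model import GeneModel
from .junction_discovery import SpliceJunction
from .novel_discovery import NewExonCandidate

AS_TYPES = ("SE", "RI", "A5SS", "A3SS", "MXE", "AFE", "ALE")
CE_TYPES = ("SE", "AFE", "ALE", "MXE")


@dataclass
class ASEvent:
    gene_id: str
    type: str
    chrom: str
    start: int  # variable region, 0-based half-open
    end: int
    evidence: dict = field(default_factory=dict)


@dataclass
class ASSummary:
    events_per_type: dict[str, int]
    total_events: int
    genes_with_events: int
    ce_count: int
    ri_count: int
    ce_ratio: float | None
    mean_retained_intron_length: float | None
    mean_canonical_intron_length: float | None


def detect_retained_introns(
    genes: Sequence[GeneModel],
    coverage: CoverageTrack,
    new_exons: Iterable[NewExonCandidate] = (),
    min_depth: int = 2,
    ri_ratio: float = 0.25,
) -> list[ASEvent]:
    """Retained-intron events from intronic coverage.

    An annotated intron is retained when every base has depth >=
    ``min_depth`` and the intron's mean depth reaches ``ri_ratio`` times
    the mean depth of its two flanking exons, and no called new-exon
    candidate occupies it.
    """
    excluded = {(c.gene_id, c.intron_index) for c in new_exons}
    out: list[ASEvent] = []
    for g in genes:
        depth = coverage.arrays[g.chrom]
        for idx, (istart, iend) in enumerate(g.introns):
            if (g.gene_id, idx) in excluded:
                continue
            window = depth[istart:iend]
            if window.size == 0 or int(window.min()) < min_depth:
                continue
            ls, le = g.exons[idx]
            rs, re_ = g.exons[idx + 1]
            flank_bases = int(depth[ls:le].sum() + depth[rs:re_].sum())
            flank_mean = flank_bases / ((le - ls) + (re_ - rs))
            intron_mean = float(window.mean())
            if flank_mean > 0 and intron_mean < ri_ratio * flank_mean:
                continue
            out.append(
                ASEvent(
                    gene_id=g.gene_id,
                    type="RI",
                    chrom=g.chrom,
                    start=istart,
                    end=iend,
                    evidence={
                        "intron_index": idx,
                        "intron_mean_depth": intron_mean,
                        "flank_mean_depth": flank_mean,
                    },
                )
            )
    return out


def _donor_coord(j: SpliceJunction) -> int:
    c = j.candidate
    return c.intron_start if c.strand == "+" else c.intron_end


def _acceptor_coord(j: SpliceJunction) -> int:
    c = j.candidate
    return c.intron_end if c.strand == "+" else c.intron_start


def classify_junction_events(
    genes: Sequence[GeneModel],
    junctions: Sequence[SpliceJunction],
    new_exons: Iterable[NewExonCandidate] = (),
) -> list[ASEvent]:
    """Classify called junctions into SE/MXE/A5SS/A3SS/AFE/ALE events.

    Junctions are assigned to the same-strand gene whose span they overlap;
    junctions inside no gene are ignored here.  A junction matching an
    annotated intron exactly is constitutive: it raises no event but
    participates in alternative-site grouping.  Junctions that bound a
    called new-exon candidate are evidence for that candidate, not for an
    alternative-splicing event, and are excluded up front.
    """
    called = [j for j in junctions if j.called]
    new_exon_bounds = set()
    for c in new_exons:
        new_exon_bounds.add((c.chrom, c.start))
        new_exon_bounds.add((c.chrom, c.end))
    events: list[ASEvent] = []
    by_gene: dict[str, list[SpliceJunction]] = {}
    gene_map = {g.gene_id: g for g in genes}
    for j in called:
        c = j.candidate
        if (c.chrom, c.intron_end) in new_exon_bounds or (
            c.chrom,
            c.intron_start,
        ) in new_exon_bounds:
            continue
        best_gene, best_ov = None, 0
        for g in genes:
            if g.chrom != c.chrom or g.strand != c.strand:
                continue
            gs, ge = g.span
            ov = min(ge, c.intron_end) - max(gs, c.intron_start)
            if ov > best_ov:
                best_gene, best_ov = g.gene_id, ov
        if best_gene is not None:
            by_gene.setdefault(best_gene, []).append(j)

    for gene_id, gjunctions in by_gene.items():
        g = gene_map[gene_id]
        annotated = set(g.introns)
        internal_exons = [
            (i, ex) for i, ex in enumerate(g.exons) if g.is_internal_exon(i)
        ]
        # --- skipped exons -------------------------------------------------
        se_events: list[ASEvent] = []
        se_junctions: set[tuple[int, int]] = set()
        for j in gjunctions:
            c = j.candidate
            if (c.intron_start, c.intron_end) in annotated:
                continue
            skipped = [
                ex
                for _, ex in internal_exons
                if c.intron_start < ex[0] and ex[1] < c.intron_end
            ]
            if skipped:
                se_junctions.add((c.intron_start, c.intron_end))
                se_events.append(
                    ASEvent(
                        gene_id=gene_id,
                        type="SE",
                        chrom=c.chrom,
                        start=min(ex[0] for ex in skipped),
                        end=max(ex[1] for ex in skipped),
                        evidence={
                            "junction": c.key,
                            "skipped_exons": skipped,
                            "trans_reads": len(j.trans_reads),
                        },
                    )
                )
        # --- mutually exclusive exons --------------------------------------
        merged_mxe: set[int] = set()
        for a in range(len(se_events)):
            for b in range(a + 1, len(se_events)):
                if a in merged_mxe or b in merged_mxe:
                    continue
                ea, eb = se_events[a], se_events[b]
                ja, jb = ea.evidence["junction"], eb.evidence["junction"]
                exons_a = set(map(tuple, ea.evidence["skipped_exons"]))
                exons_b = set(map(tuple, eb.evidence["skipped_exons"]))
                if exons_a & exons_b:
                    continue
                introns_overlap = ja[1] < jb[2] and jb[1] < ja[2]
                a_excludes_b = not any(
                    ja[1] < ex[0] and ex[1] < ja[2] for ex in exons_b
                )
                b_excludes_a = not any(
                    jb[1] < ex[0] and ex[1] < jb[2] for ex in exons_a
                )
                if introns_overlap and a_excludes_b and b_excludes_a:
                    merged_mxe.update((a, b))
                    events.append(
                        ASEvent(
                            gene_id=gene_id,
                            type="MXE",
                            chrom=ea.chrom,
                            start=min(ea.start, eb.start),
                            end=max(ea.end, eb.end),
                            evidence={"junctions": [ja, jb]},
                        )
                    )
        events.extend(e for i, e in enumerate(se_events) if i not in merged_mxe)
        # --- alternative 5'/3' sites and alternative first/last exons ------
        grouping = [
            j
            for j in gjunctions
            if (j.candidate.intron_start, j.candidate.intron_end) not in se_junctions
        ]
        gs, ge = g.span
        if g.strand == "+":
            outer_first = lambda donor: donor < gs  # noqa: E731
            outer_last = lambda acceptor: acceptor > ge  # noqa: E731
        else:
            outer_first = lambda donor: donor > ge  # noqa: E731
            outer_last = lambda acceptor: acceptor < gs  # noqa: E731
        # shared acceptor, alternative donors -> A5SS (or AFE when the
        # alternative donor lies beyond the outermost annotated exon)
        by_acceptor: dict[int, list[SpliceJunction]] = {}
        by_donor: dict[int, list[SpliceJunction]] = {}
        for j in grouping:
            by_acceptor.setdefault(_acceptor_coord(j), []).append(j)
            by_donor.setdefault(_donor_coord(j), []).append(j)
        for acceptor, group in by_acceptor.items():
            donors = sorted({_donor_coord(j) for j in group})
            if len(donors) < 2:
                continue
            n_outer = sum(1 for d in donors if outer_first(d))
            lo, hi = min(donors), max(donors)
            keys = sorted(j.candidate.key for j in group)
            if n_outer:
                for _ in range(n_outer):
                    events.append(
                        ASEvent(gene_id, "AFE", g.chrom, lo, hi,
                                {"acceptor": acceptor, "junctions": keys})
                    )
            n_inner = len(donors) - n_outer
            for _ in range(max(0, n_inner - 1)):
                events.append(
                    ASEvent(gene_id, "A5SS", g.chrom, lo, hi,
                            {"acceptor": acceptor, "junctions": keys})
                )
        for donor, group in by_donor.items():
            acceptors = sorted({_acceptor_coord(j) for j in group})
            if len(acceptors) < 2:
                continue
            n_outer = sum(1 for a in acceptors if outer_last(a))
            lo, hi = min(acceptors), max(acceptors)
            keys = sorted(j.candidate.key for j in group)
            if n_outer:
                for _ in range(n_outer):
                    events.append(
                        ASEvent(gene_id, "ALE", g.chrom, lo, hi,
                                {"donor": donor, "junctions": keys})
                    )
            n_inner = len(acceptors) - n_outer
            for _ in range(max(0, n_inner - 1)):
                events.append(
                    ASEvent(gene_id, "A3SS", g.chrom, lo, hi,
                            {"donor": donor, "junctions": keys})
                )
    return events


def summarize_as(
    events: Sequence[ASEvent], genes: Sequence[GeneModel]
) -> ASSummary:
    """Per-type tallies, the CE/(RI+CE) ratio and intron-length contrasts.

    The mean canonical-intron length is taken over annotated introns that
    are not retained in any event; both means are None when their event
    sets are empty.  The ratio is order-invariant and depends only on the
    event multiset.
    """
    counts = {t: 0 for t in AS_TYPES}
    for e in events:
        if e.type not in counts:
            raise ValueError(f"unknown AS type {e.type!r}")
        counts[e.type] += 1
    ce = sum(counts[t] for t in CE_TYPES)
    ri = counts["RI"]
    ce_ratio = ce / (ri + ce) if (ri + ce) > 0 else None
    retained = {
        (e.chrom, e.start, e.end) for e in events if e.type == "RI"
    }
    retained_lengths = [e - s for _, s, e in retained]
    canonical_lengths = [
        ie - is_
        for g in genes
        for is_, ie in g.introns
        if (g.chrom, is_, ie) not in retained
    ]
    return ASSummary(
        events_per_type=counts,
        total_events=len(events),
        genes_with_events=len({e.gene_id for e in events}),
        ce_count=ce,
        ri_count=ri,
        ce_ratio=ce_ratio,
        mean_retained_intron_length=(
            sum(retained_lengths) / len(retained_lengths) if retained_lengths else None
        ),
        mean_canonical_intron_length=(
            sum(canonical_lengths) / len(canonical_lengths)
            if canonical_lengths
            else None
        ),
    )
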