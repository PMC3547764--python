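"""Tabular and track output for pipeline results (TSV / BED / bedGraph / GFF3 / JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .as_classifier import ASSummary
from .coverage_expression import CoverageTrack
from .pipeline import PipelineResult


def expression_frame(result: PipelineResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id, "C": r.C, "L": r.L, "N": r.N,
                "rpkm": r.rpkm, "breadth": r.breadth, "active": r.active,
                "bin": r.bin,
            }
            for r in result.expression
        ]
    )


def utr_frame(result: PipelineResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": u.gene_id, "utr5_len": u.utr5_len,
                "utr3_len": u.utr3_len, "status5": u.status5,
                "status3": u.status3,
            }
            for u in result.utrs
        ]
    )


def junction_frame(result: PipelineResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": j.candidate.chrom,
                "intron_start": j.candidate.intron_start,
                "intron_end": j.candidate.intron_end,
                "strand": j.candidate.strand,
                "trans_reads": len(j.trans_reads),
                "distinct_offsets": j.distinct_offsets,
                "called": j.called,
            }
            for j in result.junctions
        ]
    )


def tu_frame(result: PipelineResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tu_id": tu.tu_id, "chrom": tu.chrom,
                "span_start": tu.span[0], "span_end": tu.span[1],
                "n_tars": len(tu.tars), "length": tu.length,
                "avg_reads_per_base": tu.avg_reads_per_base,
                "n_orfs": len(tu.orfs),
            }
            for tu in result.transcript_units
        ]
    )


def event_frame(result: PipelineResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id, "type": e.type, "chrom": e.chrom,
                "start": e.start, "end": e.end,
            }
            for e in result.events
        ]
    )


def summary_dict(summary: ASSummary) -> dict:
    return {
        "events_per_type": summary.events_per_type,
        "total_events": summary.total_events,
        "genes_with_events": summary.genes_with_events,
        "ce_count": summary.ce_count,
        "ri_count": summary.ri_count,
        "ce_ratio": summary.ce_ratio,
        "mean_retained_intron_length": summary.mean_retained_intron_length,
        "mean_canonical_intron_length": summary.mean_canonical_intron_length,
    }


def write_bedgraph(coverage: CoverageTrack, path: str | Path) -> None:
    """Run-length-encoded bedGraph of the coverage track."""
    with open(path, "w") as fh:
        for chrom in sorted(coverage.arrays):
            depth = coverage.arrays[chrom]
            change = np.flatnonzero(np.diff(depth)) + 1
            bounds = np.concatenate(([0], change, [len(depth)]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = int(depth[s])
                if v:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def write_tu_gff3(result: PipelineResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tu in result.transcript_units:
            s, e = tu.span
            fh.write(
                f"{tu.chrom}\ttxstruct\tgene\t{s + 1}\t{e}\t.\t.\t.\tID={tu.tu_id}\n"
            )
            for i, t in enumerate(tu.tars, start=1):
                fh.write(
                    f"{t.chrom}\ttxstruct\texon\t{t.start + 1}\t{t.end}\t.\t.\t.\t"
                    f"ID={tu.tu_id}.tar{i};Parent={tu.tu_id}\n"
                )


def write_results(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write the standard result bundle; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = {
        "expression": expression_frame(result),
        "utrs": utr_frame(result),
        "uorfs": pd.DataFrame(
            [
                {"gene_id": u.gene_id, "start": u.start, "length": u.length,
                 "distance": u.distance_to_cds_start}
                for u in result.uorfs
            ]
        ),
        "uatgs": pd.DataFrame(
            [
                {"gene_id": u.gene_id, "position": u.position,
                 "distance": u.distance_to_cds_start}
                for u in result.uatgs
            ]
        ),
        "junctions": junction_frame(result),
        "novel_tus": tu_frame(result),
        "new_exons": pd.DataFrame(
            [
                {"gene_id": c.gene_id, "intron_index": c.intron_index,
                 "chrom": c.chrom, "start": c.start, "end": c.end,
                 "mean_depth": c.mean_depth,
                 "left_support": c.left_support, "right_support": c.right_support}
                for c in result.new_exons
            ]
        ),
        "as_events": event_frame(result),
    }
    paths: dict[str, Path] = {}
    for name, df in frames.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    p = outdir / "as_summary.json"
    with open(p, "w") as fh:
        json.dump(summary_dict(result.summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["as_summary"] = p
    p = outdir / "novel_tus.gff3"
    write_tu_gff3(result, p)
    paths["novel_tus_gff3"] = p
    p = outdir / "coverage.bedgraph"
    write_bedgraph(result.coverage, p)
    paths["coverage"] = p
    return paths
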