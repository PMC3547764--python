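"""Shared fixtures: tiny genomes, SAM writers and a cached simulation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam
import pytest

from txstruct.genome_model import Genome


@dataclass
class ReadSpec:
    qname: str
    chrom: str
    pos: int
    seq: str
    mapq: int = 60
    flag: int = 0


def write_sam(path, genome: Genome, reads: list[ReadSpec]) -> str:
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in genome.lengths.items()],
    }
    ref_ids = {n: i for i, n in enumerate(genome.lengths)}
    aln_header = pysam.AlignmentHeader.from_dict(header)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(aln_header)
            a.query_name = r.qname
            a.flag = r.flag
            a.reference_id = ref_ids[r.chrom]
            a.reference_start = r.pos
            a.mapping_quality = r.mapq
            a.cigarstring = f"{len(r.seq)}M"
            a.query_sequence = r.seq
            out.write(a)
    return str(path)


def random_genome(rng: np.random.Generator, length: int = 2000, name: str = "c1") -> Genome:
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    return Genome({name: seq})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def demo_simulation(tmp_path_factory):
    """One moderately sized simulation shared by integration tests."""
    from txstruct.synthetic_data import SimulationParams, simulate, write_simulation

    params = SimulationParams(
        seed=5,
        chromosome_length=70_000,
        n_plain_single=2,
        n_plain_multi=2,
        n_uorf_genes=2,
        n_uatg_genes=2,
        n_new_exon_genes=1,
        as_events={"RI": 3, "SE": 3, "A5SS": 3, "A3SS": 3, "MXE": 1},
        n_novel_single=2,
        n_novel_spliced=2,
    )
    sim = simulate(params)
    outdir = tmp_path_factory.mktemp("demo_sim")
    paths = write_simulation(sim, outdir)
    return sim, paths
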