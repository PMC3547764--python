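"""Splice-site enumeration, candidate building, trim rescue and the aligner."""

import numpy as np
import pytest

from txstruct.coverage_expression import CoverageTrack
from txstruct.genome_model import Genome, revcomp
from txstruct.junction_discovery import (
    JunctionCandidate,
    SpliceSite,
    align_reads_to_junctions,
    build_junction_candidates,
    enumerate_splice_sites,
    find_placements,
    rescue_unmapped_reads,
)

from conftest import random_genome


class TestEnumerateSites:
    def test_hand_scanned_toy_region(self):
        genome = Genome({"c1": "AAGTAAAGAA"})
        sites = enumerate_splice_sites(genome, {"c1": [(0, 10)]})
        fwd = [(s.kind, s.dinucleotide, s.position) for s in sites if s.strand == "+"]
        assert ("donor", "GT", 2) in fwd
        assert ("acceptor", "AG", 2) in fwd  # AG at string offset 1, last intron base 2
        assert all(s.strand == "+" for s in sites)

    def test_region_without_motifs_is_empty(self):
        genome = Genome({"c1": "AAAAAAAAAA"})
        assert enumerate_splice_sites(genome, {"c1": [(0, 10)]}) == []

    def test_uncovered_site_excluded_when_coverage_given(self):
        genome = Genome({"c1": "AAGTAAAAAAAAGTAA"})
        depth = np.zeros(16, dtype=np.int64)
        depth[0:8] = 3  # only the first GT neighbourhood is covered
        cov = CoverageTrack({"c1": depth})
        sites = enumerate_splice_sites(genome, {"c1": [(0, 16)]}, cov)
        donors = [s.position for s in sites if s.kind == "donor" and s.strand == "+"]
        assert donors == [2]


class TestBuildCandidates:
    def _sites(self, donors, acceptors, strand="+"):
        out = [SpliceSite("c1", p, "donor", strand, "GT") for p in donors]
        out += [SpliceSite("c1", p, "acceptor", strand, "AG") for p in acceptors]
        return out

    def test_one_pair_one_candidate(self, rng):
        genome = random_genome(rng, 1000)
        (cand,) = build_junction_candidates(
            self._sites([200], [319]), genome, flank=20
        )
        assert (cand.intron_start, cand.intron_end) == (200, 320)
        assert cand.seq == genome.sequences["c1"][180:200] + genome.sequences["c1"][320:340]

    def test_cartesian_product_of_compatible_sites(self, rng):
        genome = random_genome(rng, 5000)
        cands = build_junction_candidates(
            self._sites([200, 300], [999, 1499, 1999]), genome, flank=20
        )
        assert len(cands) == 6

    def test_acceptor_upstream_of_donor_is_not_paired(self, rng):
        genome = random_genome(rng, 1000)
        assert build_junction_candidates(self._sites([500], [100]), genome) == []

    def test_max_intron_bound(self, rng):
        genome = random_genome(rng, 30_000)
        cands = build_junction_candidates(
            self._sites([100], [15_000]), genome, flank=20, max_intron=10_000
        )
        assert cands == []

    def test_clipped_flank_below_minimum_drops_candidate(self, rng):
        genome = random_genome(rng, 400)
        cands = build_junction_candidates(self._sites([3], [199]), genome, flank=20)
        assert cands == []  # only 3 bases of left flank available


class TestRescue:
    def test_prefix_of_fifty_matches_and_is_retained(self, rng):
        genome = random_genome(rng, 3000)
        prefix = genome.sequences["c1"][100:150]
        tail = genome.sequences["c1"][2000:2025]
        (res,) = rescue_unmapped_reads([("r1", prefix + tail)], genome)
        assert res.retained_prefix == 50

    def test_reverse_strand_prefix_is_found(self, rng):
        genome = random_genome(rng, 3000)
        prefix = revcomp(genome.sequences["c1"][100:150])
        read = prefix + "A" * 25
        (res,) = rescue_unmapped_reads([("r1", read)], genome)
        assert res.retained_prefix >= 50

    def test_unmatchable_read_not_rescued(self):
        genome = Genome({"c1": "A" * 2000})
        assert rescue_unmapped_reads([("r1", "C" * 75)], genome) == []

    def test_trim_floor_of_forty_bases(self, rng):
        genome = random_genome(rng, 3000)
        # only the first 39 bases match the genome: below the floor, dropped
        read = genome.sequences["c1"][100:139] + "N" * 36
        assert rescue_unmapped_reads([("r1", read)], genome) == []


def _brute_force(read, cand, max_mismatch=2, min_overhang=5):
    out = []
    for orient, r in (("F", read), ("R", revcomp(read))):
        for off in range(len(cand.seq) - len(r) + 1):
            mid = cand.flank_left
            if off > mid - min_overhang or off + len(r) < mid + min_overhang:
                continue
            mm = sum(a != b for a, b in zip(r, cand.seq[off : off + len(r)]))
            if mm <= max_mismatch:
                out.append((0, off, mm, orient))
    return sorted(out)


def _candidate_from_seq(seq, flank_left):
    d = SpliceSite("c1", 0, "donor", "+", "GT")
    a = SpliceSite("c1", 1, "acceptor", "+", "AG")
    return JunctionCandidate("c1", 10, 20, "+", d, a, seq, flank_left, len(seq) - flank_left)


class TestAligner:
    def test_equals_brute_force_hamming_oracle(self, rng):
        for _ in range(1000):
            jseq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            cand = _candidate_from_seq(jseq, 30)
            if rng.random() < 0.5:
                off = int(rng.integers(0, 30))
                read = list(jseq[off : off + 30])
                for p in rng.choice(30, size=int(rng.integers(0, 4)), replace=False):
                    read[p] = "ACGT"[int(rng.integers(0, 4))]
                read = "".join(read)
                if rng.random() < 0.5:
                    read = revcomp(read)
            else:
                read = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
            assert sorted(find_placements(read, [cand])) == _brute_force(read, cand)

    def test_short_overhang_read_is_not_a_trans_read(self, rng):
        genome = random_genome(rng, 500)
        seq = genome.sequences["c1"]
        cand = _candidate_from_seq(seq[0:140], 70)
        read = seq[66:141]  # only 4 bases on the left of the junction midpoint
        assert find_placements(read, [cand]) == []
        read_ok = seq[65:140]  # 5-base overhang passes
        assert find_placements(read_ok, [cand]) != []

    def test_two_identical_offset_reads_do_not_call(self, rng):
        genome = random_genome(rng, 500)
        cand = _candidate_from_seq(genome.sequences["c1"][:140], 70)
        reads = [("r1", cand.seq[20:95]), ("r2", cand.seq[20:95])]
        (j,) = align_reads_to_junctions(reads, [cand])
        assert len(j.trans_reads) == 2
        assert j.distinct_offsets == 1
        assert not j.called

    def test_distinct_offsets_call_the_junction(self, rng):
        genome = random_genome(rng, 500)
        cand = _candidate_from_seq(genome.sequences["c1"][:140], 70)
        reads = [("r1", cand.seq[20:95]), ("r2", cand.seq[30:105])]
        (j,) = align_reads_to_junctions(reads, [cand])
        assert j.called and j.distinct_offsets == 2

    def test_ambiguous_read_across_candidates_is_dropped(self, rng):
        genome = random_genome(rng, 500)
        seq = genome.sequences["c1"][:140]
        c1 = _candidate_from_seq(seq, 70)
        c2 = _candidate_from_seq(seq, 70)
        c2.intron_start = 999  # same sequence, different putative intron
        out = align_reads_to_junctions([("r1", seq[20:95])], [c1, c2])
        assert out == []

    def test_mismatch_monotonicity(self, rng):
        genome = random_genome(rng, 2000)
        seq = genome.sequences["c1"]
        cands = [_candidate_from_seq(seq[i : i + 140], 70) for i in range(0, 560, 140)]
        reads = []
        for i, c in enumerate(cands):
            r = list(c.seq[20:95])
            r[10] = "A" if r[10] != "A" else "C"
            reads.append((f"r{i}a", "".join(r)))
            reads.append((f"r{i}b", c.seq[25:100]))
        called_strict = {
            j.candidate.intron_start
            for j in align_reads_to_junctions(reads, cands, max_mismatch=0)
            if j.called
        }
        called_loose = {
            j.candidate.intron_start
            for j in align_reads_to_junctions(reads, cands, max_mismatch=2)
            if j.called
        }
        assert called_strict <= called_loose
        tight_overhang = {
            j.candidate.intron_start
            for j in align_reads_to_junctions(reads, cands, min_overhang=30)
            if j.called
        }
        assert tight_overhang <= called_loose
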