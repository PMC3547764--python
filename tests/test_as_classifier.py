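"""Retained-intron calling, junction-based event typing and the AS summary."""

import numpy as np
import pytest

from txstruct.as_classifier import (
    ASEvent,
    classify_junction_events,
    detect_retained_introns,
    summarize_as,
)
from txstruct.coverage_expression import CoverageTrack
from txstruct.genome_model import GeneModel
from txstruct.junction_discovery import (
    JunctionCandidate,
    SpliceJunction,
    SpliceSite,
    TransRead,
)
from txstruct.novel_discovery import NewExonCandidate


def _cov(length, runs):
    d = np.zeros(length, dtype=np.int64)
    for s, e, v in runs:
        d[s:e] = v
    return CoverageTrack({"c1": d})


def _junction(s, e, strand="+", called=True, n_reads=4):
    d = SpliceSite("c1", s if strand == "+" else e - 1, "donor", strand, "GT")
    a = SpliceSite("c1", e - 1 if strand == "+" else s, "acceptor", strand, "AG")
    cand = JunctionCandidate("c1", s, e, strand, d, a, "N" * 20, 10, 10)
    j = SpliceJunction(candidate=cand)
    j.trans_reads = [TransRead(f"r{i}", i, 0, "F") for i in range(n_reads)]
    j.called = called
    return j


class TestRetainedIntrons:
    def _gene(self):
        return GeneModel("g", "c1", "+", [(0, 100), (200, 300)])

    def test_retained_intron_at_thirty_percent_of_gene_expression(self):
        cov = _cov(400, [(0, 100, 10), (200, 300, 10), (100, 200, 3)])
        (ev,) = detect_retained_introns([self._gene()], cov)
        assert (ev.type, ev.start, ev.end) == ("RI", 100, 200)

    def test_single_uncovered_base_blocks_the_call(self):
        cov = _cov(400, [(0, 100, 10), (200, 300, 10), (100, 200, 3)])
        cov.arrays["c1"][150] = 0
        assert detect_retained_introns([self._gene()], cov) == []

    def test_depth_ratio_below_threshold_blocks_the_call(self):
        cov = _cov(400, [(0, 100, 10), (200, 300, 10), (100, 200, 2)])
        assert detect_retained_introns([self._gene()], cov) == []

    def test_new_exon_candidate_excludes_the_intron(self):
        cov = _cov(400, [(0, 100, 10), (200, 300, 10), (100, 200, 5)])
        cand = NewExonCandidate("g", 0, "c1", 120, 180, 5.0, 3, 3)
        assert detect_retained_introns([self._gene()], cov, [cand]) == []

    def test_one_event_per_gene_intron(self):
        gene = GeneModel("g", "c1", "+", [(0, 100), (200, 300), (400, 500)])
        cov = _cov(600, [(0, 500, 10)])
        events = detect_retained_introns([gene], cov)
        assert [e.type for e in events] == ["RI", "RI"]
        assert len({(e.start, e.end) for e in events}) == 2


class TestClassifyJunctions:
    def test_constitutive_junction_raises_no_event(self):
        gene = GeneModel("g", "c1", "+", [(0, 100), (200, 300)])
        assert classify_junction_events([gene], [_junction(100, 200)]) == []

    def test_shared_acceptor_different_donors_is_a5ss(self):
        gene = GeneModel("g", "c1", "+", [(0, 100), (200, 300)])
        events = classify_junction_events(
            [gene], [_junction(100, 200), _junction(112, 200)]
        )
        (ev,) = events
        assert ev.type == "A5SS"
        assert (ev.start, ev.end) == (100, 112)

    def test_shared_donor_different_acceptors_is_a3ss(self):
        gene = GeneModel("g", "c1", "+", [(0, 100), (200, 300)])
        events = classify_junction_events(
            [gene], [_junction(100, 200), _junction(100, 188)]
        )
        (ev,) = events
        assert ev.type == "A3SS"

    def test_minus_strand_swaps_site_roles(self):
        # on the minus strand the donor is the right intron edge, so two
        # junctions sharing their left edge share an acceptor -> A5SS
        gene = GeneModel("g", "c1", "-", [(0, 100), (200, 300)])
        events = classify_junction_events(
            [gene], [_junction(100, 200, "-"), _junction(100, 188, "-")]
        )
        (ev,) = events
        assert ev.type == "A5SS"

    def test_exon_skipping_junction_is_se(self):
        gene = GeneModel("g", "c1", "+", [(0, 100), (200, 260), (400, 500)])
        events = classify_junction_events([gene], [_junction(100, 400)])
        (ev,) = events
        assert ev.type == "SE"
        assert (ev.start, ev.end) == (200, 260)

    def test_se_junction_does_not_double_count_as_alt_site(self):
        gene = GeneModel("g", "c1", "+", [(0, 100), (200, 260), (400, 500)])
        events = classify_junction_events(
            [gene], [_junction(100, 200), _junction(260, 400), _junction(100, 400)]
        )
        assert [e.type for e in events] == ["SE"]

    def test_mutually_exclusive_exons_merge_two_se_calls(self):
        gene = GeneModel(
            "g", "c1", "+", [(0, 100), (200, 300), (400, 500), (600, 700)]
        )
        junctions = [
            _junction(100, 200),  # constitutive, isoform with exon 2
            _junction(500, 600),  # constitutive, isoform with exon 3
            _junction(300, 600),  # exon2 isoform skips exon 3
            _junction(100, 400),  # exon3 isoform skips exon 2
        ]
        events = classify_junction_events([gene], junctions)
        (ev,) = events
        assert ev.type == "MXE"
        assert (ev.start, ev.end) == (200, 500)

    def test_alternative_first_exon_upstream_donor(self):
        gene = GeneModel("g", "c1", "+", [(100, 200), (300, 400)])
        events = classify_junction_events(
            [gene], [_junction(200, 300), _junction(50, 300)]
        )
        (ev,) = events
        assert ev.type == "AFE"

    def test_alternative_last_exon_downstream_acceptor(self):
        gene = GeneModel("g", "c1", "+", [(100, 200), (300, 400)])
        events = classify_junction_events(
            [gene], [_junction(200, 300), _junction(200, 450)]
        )
        (ev,) = events
        assert ev.type == "ALE"

    def test_new_exon_boundary_junctions_are_not_alt_site_events(self):
        gene = GeneModel("g", "c1", "+", [(0, 100), (500, 600)])
        cand = NewExonCandidate("g", 0, "c1", 200, 300, 5.0, 3, 3)
        junctions = [
            _junction(100, 500),  # constitutive
            _junction(100, 200),  # into the new exon
            _junction(300, 500),  # out of the new exon
        ]
        assert classify_junction_events([gene], junctions, [cand]) == []

    def test_uncalled_junctions_are_ignored(self):
        gene = GeneModel("g", "c1", "+", [(0, 100), (200, 300)])
        events = classify_junction_events(
            [gene], [_junction(100, 200), _junction(112, 200, called=False)]
        )
        assert events == []


class TestSummary:
    def _events(self, spec):
        out = []
        for i, t in enumerate(spec):
            out.append(ASEvent(f"g{i}", t, "c1", 100 * i, 100 * i + 50))
        return out

    def test_ce_ratio_quarter(self):
        s = summarize_as(self._events(["RI", "RI", "RI", "SE"]), [])
        assert s.ce_ratio == 0.25

    def test_all_ri_gives_zero_ratio(self):
        s = summarize_as(self._events(["RI", "RI"]), [])
        assert s.ce_ratio == 0.0

    def test_ratio_counts_all_cassette_types(self):
        s = summarize_as(self._events(["RI", "SE", "MXE", "AFE", "ALE"]), [])
        assert s.ce_count == 4
        assert s.ce_ratio == 0.8

    def test_ratio_invariant_to_event_order(self, rng):
        events = self._events(["RI", "SE", "A5SS", "RI", "MXE", "A3SS"])
        base = summarize_as(events, []).ce_ratio
        for _ in range(5):
            perm = [events[i] for i in rng.permutation(len(events))]
            assert summarize_as(perm, []).ce_ratio == base

    def test_intron_length_contrast(self):
        genes = [
            GeneModel("a", "c1", "+", [(0, 100), (189, 300)]),  # 89-base intron
            GeneModel("b", "c1", "+", [(400, 500), (599, 700)]),  # 99-base intron
        ]
        events = [ASEvent("a", "RI", "c1", 100, 189)]
        s = summarize_as(events, genes)
        assert s.mean_retained_intron_length == 89.0
        assert s.mean_canonical_intron_length == 99.0

    def test_counts_sum_and_gene_tally(self):
        events = self._events(["RI", "SE", "SE", "A5SS"])
        events[1].gene_id = events[2].gene_id = "same"
        s = summarize_as(events, [])
        assert s.total_events == sum(s.events_per_type.values()) == 4
        assert s.genes_with_events == 3
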