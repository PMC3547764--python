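"""Genome/annotation containers: I/O contracts, region partition, overlaps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txstruct.genome_model import (
    AnnotationError,
    GeneModel,
    Genome,
    derive_regions,
    find_overlapping_transcripts,
    load_annotation,
    load_genome,
    write_annotation,
)


def _write(path, text):
    path.write_text(text)
    return str(path)


class TestLoadGenome:
    def test_identity_readback(self, tmp_path):
        g = load_genome(_write(tmp_path / "g.fa", ">c1\nACGT\n"))
        assert g.sequences == {"c1": "ACGT"}
        assert g.lengths == {"c1": 4}

    def test_case_folded_to_upper(self, tmp_path):
        g = load_genome(_write(tmp_path / "g.fa", ">c1\nacgt\n"))
        assert g.sequences["c1"] == "ACGT"

    def test_duplicate_names_rejected(self, tmp_path):
        p = _write(tmp_path / "g.fa", ">c1\nACGT\n>c1\nGGGG\n")
        with pytest.raises(AnnotationError, match="duplicate"):
            load_genome(p)

    def test_non_fasta_names_offending_line(self, tmp_path):
        p = _write(tmp_path / "g.txt", "ACGT\n")
        with pytest.raises(AnnotationError, match="line 1"):
            load_genome(p)


GFF = """##gff-version 3
c1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g1
c1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=g1.t1;Parent=g1
c1\tsrc\texon\t1\t100\t.\t+\t.\tID=e1;Parent=g1.t1
c1\tsrc\texon\t201\t300\t.\t+\t.\tID=e2;Parent=g1.t1
c1\tsrc\tCDS\t1\t100\t.\t+\t0\tID=c1a;Parent=g1.t1
c1\tsrc\tCDS\t201\t300\t.\t+\t2\tID=c1b;Parent=g1.t1
"""


class TestLoadAnnotation:
    def test_coordinate_conversion_and_introns(self, tmp_path):
        genome = Genome({"c1": "A" * 400})
        genes = load_annotation(_write(tmp_path / "a.gff3", GFF), genome)
        (g,) = genes
        assert g.exons == [(0, 100), (200, 300)]
        assert g.introns == [(100, 200)]

    def test_single_exon_gene_has_no_introns(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "c1\ts\tgene\t10\t50\t.\t-\t.\tID=g1\n"
            "c1\ts\tmRNA\t10\t50\t.\t-\t.\tID=t1;Parent=g1\n"
            "c1\ts\texon\t10\t50\t.\t-\t.\tID=e;Parent=t1\n"
        )
        genome = Genome({"c1": "A" * 100})
        (g,) = load_annotation(_write(tmp_path / "a.gff3", gff), genome)
        assert g.introns == []
        assert g.strand == "-"

    def test_exon_beyond_chromosome_bounds(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "c1\ts\tgene\t1\t5000\t.\t+\t.\tID=g1\n"
            "c1\ts\texon\t1\t5000\t.\t+\t.\tID=e;Parent=g1\n"
        )
        genome = Genome({"c1": "A" * 4000})
        with pytest.raises(AnnotationError, match="outside"):
            load_annotation(_write(tmp_path / "a.gff3", gff), genome)

    def test_overlapping_exons_rejected(self):
        with pytest.raises(AnnotationError, match="overlap"):
            GeneModel("g", "c1", "+", [(0, 100), (50, 150)])

    def test_round_trip(self, tmp_path):
        genome = Genome({"c1": "A" * 400})
        genes = load_annotation(_write(tmp_path / "a.gff3", GFF), genome)
        write_annotation(genes, tmp_path / "out.gff3")
        again = load_annotation(tmp_path / "out.gff3", genome)
        assert [(g.gene_id, g.chrom, g.strand, g.exons) for g in again] == [
            (g.gene_id, g.chrom, g.strand, g.exons) for g in genes
        ]


def _label_oracle(genes, length):
    """Per-base labelling with priority exon > intron > intergenic."""
    labels = np.zeros(length, dtype=np.int8)  # 0 intergenic, 1 intronic, 2 exonic
    for g in genes:
        s, e = g.span
        labels[s:e] = np.maximum(labels[s:e], 1)
    for g in genes:
        for s, e in g.exons:
            labels[s:e] = 2
    return labels


def _regions_to_labels(regions, chrom, length):
    labels = np.zeros(length, dtype=np.int8)
    code = {"intergenic": 0, "intronic": 1, "exonic": 2}
    counts = np.zeros(length, dtype=np.int8)
    for label, per_chrom in regions.by_label.items():
        for s, e in per_chrom.get(chrom, []):
            labels[s:e] = code[label]
            counts[s:e] += 1
    assert (counts == 1).all(), "partition must cover every base exactly once"
    return labels


class TestDeriveRegions:
    def test_one_gene_with_intron(self):
        genome = Genome({"c1": "A" * 1000})
        g = GeneModel("g1", "c1", "+", [(100, 180), (220, 300)])
        regions = derive_regions([g], genome)
        assert regions.intervals("intergenic")["c1"] == [(0, 100), (300, 1000)]
        assert regions.intervals("exonic")["c1"] == [(100, 180), (220, 300)]
        assert regions.intervals("intronic")["c1"] == [(180, 220)]

    def test_no_genes_all_intergenic(self):
        genome = Genome({"c1": "A" * 50})
        regions = derive_regions([], genome)
        assert regions.intervals("intergenic")["c1"] == [(0, 50)]

    def test_opposite_strand_exon_over_intron_is_exonic(self):
        genome = Genome({"c1": "A" * 500})
        a = GeneModel("a", "c1", "+", [(100, 150), (250, 300)])
        b = GeneModel("b", "c1", "-", [(180, 220)])
        regions = derive_regions([a, b], genome)
        labels = _regions_to_labels(regions, "c1", 500)
        assert (labels == _label_oracle([a, b], 500)).all()

    @given(st.lists(st.tuples(st.integers(0, 180), st.integers(1, 4)), max_size=8))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_partition_matches_per_base_oracle(self, spec):
        length = 300
        genes = []
        for i, (start, n_exons) in enumerate(spec):
            exons, pos = [], start
            for _ in range(n_exons):
                exons.append((pos, pos + 10))
                pos += 25
            if exons[-1][1] > length:
                continue
            genes.append(GeneModel(f"g{i}", "c1", "+", exons))
        genome = Genome({"c1": "A" * length})
        regions = derive_regions(genes, genome)
        labels = _regions_to_labels(regions, "c1", length)
        assert (labels == _label_oracle(genes, length)).all()


class TestOverlappingTranscripts:
    def test_simple_overlap(self):
        a = GeneModel("a", "c1", "+", [(0, 100)])
        b = GeneModel("b", "c1", "-", [(50, 150)])
        assert find_overlapping_transcripts([a, b]) == [("a", "b")]

    def test_abutting_half_open_do_not_overlap(self):
        a = GeneModel("a", "c1", "+", [(0, 100)])
        b = GeneModel("b", "c1", "+", [(100, 200)])
        assert find_overlapping_transcripts([a, b]) == []

    def test_three_mutual_overlaps_give_three_pairs(self):
        genes = [
            GeneModel("a", "c1", "+", [(0, 100)]),
            GeneModel("b", "c1", "+", [(50, 150)]),
            GeneModel("c", "c1", "-", [(80, 120)]),
        ]
        assert len(find_overlapping_transcripts(genes)) == 3

    @given(
        st.lists(
            st.tuples(st.integers(0, 400), st.integers(1, 60)),
            min_size=0,
            max_size=40,
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_agrees_with_all_pairs_oracle(self, spec):
        genes = [
            GeneModel(f"g{i}", "c1", "+", [(s, s + ln)]) for i, (s, ln) in enumerate(spec)
        ]
        expected = set()
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                a, b = genes[i].span, genes[j].span
                if a[0] < b[1] and b[0] < a[1]:
                    expected.add(tuple(sorted((genes[i].gene_id, genes[j].gene_id))))
        assert set(find_overlapping_transcripts(genes)) == expected
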