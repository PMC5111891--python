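"""Annotation IO, position classification, intron inventory."""

import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from plastcomp import (
    AnnotationError,
    GeneFeature,
    classify_position,
    intron_inventory,
    read_annotations,
    write_gff3,
)


@pytest.fixture()
def toy_features():
    return [
        GeneFeature("gA", "CDS", "+", [(101, 200), (301, 400)]),
        GeneFeature("gB", "tRNA", "-", [(601, 680)]),
        GeneFeature("gC", "CDS", "+", [(901, 1000)]),
    ]


class TestReaders:
    def test_gff3_two_exon_cds(self, tmp_path):
        path = tmp_path / "toy.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr\tsrc\tgene\t101\t400\t.\t+\t.\tID=g1;Name=gA;gene_type=CDS\n"
            "chr\tsrc\texon\t101\t200\t.\t+\t.\tParent=g1\n"
            "chr\tsrc\texon\t301\t400\t.\t+\t.\tParent=g1\n"
        )
        (feature,) = read_annotations(path)
        assert feature.name == "gA"
        assert feature.exons == [(101, 200), (301, 400)]

    def test_gff3_requires_version_pragma(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("chr\tsrc\tgene\t1\t10\t.\t+\t.\tID=g1\n")
        with pytest.raises(AnnotationError):
            read_annotations(path)

    def test_genbank_join_location(self, tmp_path):
        record = SeqRecord(
            Seq("ACGT" * 500), id="toy",
            annotations={"molecule_type": "DNA"},
        )
        location = CompoundLocation(
            [SimpleLocation(99, 170, -1), SimpleLocation(300, 400, -1)]
        )
        record.features.append(
            SeqFeature(location, type="CDS", qualifiers={"gene": ["gX"]})
        )
        path = tmp_path / "toy.gb"
        SeqIO.write(record, str(path), "genbank")
        (feature,) = read_annotations(path, "genbank")
        assert feature.exons == [(100, 170), (301, 400)]  # ascending order
        assert feature.strand == "-"

    def test_roundtrip_through_gff3(self, small_pair, tmp_path):
        features = small_pair["features"]
        path = tmp_path / "planted.gff3"
        write_gff3(features, path, "g", small_pair["genome"].length)
        back = read_annotations(path)
        assert len(back) == len(features)
        for a, b in zip(sorted(features, key=lambda f: f.span), back):
            assert (a.name, a.ftype, a.strand, a.exons, a.is_trans_spliced) \
                == (b.name, b.ftype, b.strand, b.exons, b.is_trans_spliced)


class TestClassifyPosition:
    def test_exon_is_coding(self, toy_features):
        label = classify_position(150, toy_features, 1200)
        assert (label.category, label.context) == ("Coding", "gA")

    def test_between_exons_is_intron(self, toy_features):
        label = classify_position(250, toy_features, 1200)
        assert (label.category, label.context) == ("Intron", "gA intron")

    def test_between_genes_is_intergenic_with_flanking_pair(self, toy_features):
        label = classify_position(500, toy_features, 1200)
        assert (label.category, label.context) == ("Intergenic", "gA-gB")

    def test_intergenic_wraps_at_origin(self, toy_features):
        label = classify_position(1100, toy_features, 1200)
        assert (label.category, label.context) == ("Intergenic", "gC-gA")

    def test_no_features_gives_na_context(self):
        label = classify_position(10, [], 100)
        assert (label.category, label.context) == ("Intergenic", "NA-NA")

    def test_positions_partition_the_circle(self, toy_features):
        counts = {"Coding": 0, "Intron": 0, "Intergenic": 0}
        for pos in range(1, 1201):
            counts[classify_position(pos, toy_features, 1200).category] += 1
        assert counts["Coding"] == 100 + 100 + 80 + 100
        assert counts["Intron"] == 100
        assert sum(counts.values()) == 1200


class TestIntronInventory:
    def test_single_exon_genes_excluded(self, toy_features):
        records = intron_inventory(toy_features)
        assert [r.gene for r in records] == ["gA"]

    def test_three_exon_gene_lengths(self):
        # clpP-style layout: exons 71/292/228 with introns 951/601
        exons = [(1000, 1070), (2022, 2313), (2915, 3142)]
        gene = GeneFeature("g3", "CDS", "+", exons)
        (record,) = intron_inventory([gene])
        assert record.exon_lengths == [71, 292, 228]
        assert record.intron_lengths == [951, 601]
        span = exons[-1][1] - exons[0][0] + 1
        assert sum(record.exon_lengths) + sum(record.intron_lengths) == span

    def test_minus_strand_reports_transcript_order(self):
        gene = GeneFeature("gm", "CDS", "-", [(100, 150), (300, 320)])
        (record,) = intron_inventory([gene])
        assert record.exon_lengths == [21, 51]

    def test_trans_spliced_introns_absent(self):
        gene = GeneFeature(
            "rps12like", "CDS", "+",
            [(100, 213), (5000, 5230), (6000, 6026)],
            is_trans_spliced=True,
        )
        (record,) = intron_inventory([gene])
        assert record.exon_lengths == [114, 231, 27]
        assert record.intron_lengths == [None, None]


def test_overlapping_exons_rejected():
    with pytest.raises(AnnotationError):
        GeneFeature("bad", "CDS", "+", [(1, 100), (50, 150)])
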