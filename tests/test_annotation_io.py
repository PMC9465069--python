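"""Parsers and writers: GFF, FASTA, external-classifier tables, feature
tables, class-split FASTA."""

import random

import pytest

from karyon import annotation_io, features
from karyon.annotation_io import (
    merge_lengths,
    parse_prodigal_gff,
    parse_tiara_output,
    read_fasta_lengths,
    read_feature_table,
    read_prodigal_gff,
    read_tiara_output,
    split_fasta_by_class,
    write_feature_table,
    write_gff,
)
from karyon.exceptions import (
    CoordinateMismatchError,
    DuplicateIdError,
    GFFParseError,
    MissingLengthError,
)
from karyon.types import ContigAnnotation, GeneRecord

from .conftest import write_fasta
from .oracles import fuzz_annotation

GFF_HEADER = "##gff-version 3\n"


def gff_line(contig, start, end, strand="+", attrs="ID=1_1;rbs_motif=None;"):
    return f"{contig}\tProdigal_v2.6.3\tCDS\t{start}\t{end}\t88.2\t{strand}\t0\t{attrs}\n"


class TestReadProdigalGff:
    def test_rbs_motif_value_sets_flag(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text(
            GFF_HEADER
            + gff_line("c1", 1, 300, attrs="ID=1_1;rbs_motif=GGAGG;rbs_spacer=5-10bp")
            + gff_line("c1", 400, 900, attrs="ID=1_2;rbs_motif=None;")
        )
        (ann,) = read_prodigal_gff(p)
        assert [g.has_rbs for g in ann.genes] == [True, False]

    def test_missing_rbs_attribute_means_no_rbs(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text(GFF_HEADER + gff_line("c1", 1, 300, attrs="ID=1_1"))
        (ann,) = read_prodigal_gff(p)
        assert ann.genes[0].has_rbs is False

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.gff"
        p.write_text("")
        result = parse_prodigal_gff(p)
        assert result.annotations == []
        assert result.report.n_records == 0

    def test_genes_grouped_and_sorted(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text(
            GFF_HEADER
            + gff_line("c2", 500, 900)
            + gff_line("c1", 1000, 1500)
            + gff_line("c1", 1, 300)
        )
        anns = read_prodigal_gff(p)
        assert [a.contig_id for a in anns] == ["c2", "c1"]
        assert [g.start for g in anns[1].genes] == [1, 1000]
        assert [g.gene_index for g in anns[1].genes] == [0, 1]

    def test_seqlen_metadata_sets_length(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text(
            '# Sequence Data: seqnum=1;seqlen=4200;seqhdr="c1 flag=1"\n'
            + gff_line("c1", 1, 300)
        )
        (ann,) = read_prodigal_gff(p)
        assert ann.length == 4200

    def test_sequence_region_directive_sets_length(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text("##sequence-region c1 1 9999\n" + gff_line("c1", 1, 300))
        (ann,) = read_prodigal_gff(p)
        assert ann.length == 9999

    def test_malformed_coordinates_name_line(self, tmp_path):
        p = tmp_path / "bad.gff"
        p.write_text(GFF_HEADER + gff_line("c1", 1, 300) + gff_line("c1", "x", 900))
        with pytest.raises(GFFParseError, match="line 3"):
            read_prodigal_gff(p)

    def test_end_before_start_rejected_with_warning(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text(GFF_HEADER + gff_line("c1", 900, 300) + gff_line("c1", 1, 200))
        result = parse_prodigal_gff(p)
        assert result.report.n_rejected == 1
        assert len(result.annotations[0].genes) == 1

    def test_non_cds_features_skipped(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text(
            GFF_HEADER
            + "c1\tsrc\tgene\t1\t300\t.\t+\t0\tID=g1\n"
            + gff_line("c1", 1, 300)
        )
        (ann,) = read_prodigal_gff(p)
        assert len(ann.genes) == 1

    def test_write_read_roundtrip_never_loses_genes(self, tmp_path):
        """Fuzzed GFF round trip: no gene record lost or duplicated."""
        rnd = random.Random(7)
        for k in range(200):
            anns = [fuzz_annotation(rnd, f"r{k}_{i}") for i in range(rnd.randint(1, 4))]
            p = tmp_path / "roundtrip.gff"
            write_gff(anns, p)
            back = read_prodigal_gff(p)
            assert [a.contig_id for a in back] == [a.contig_id for a in anns]
            for orig, re_read in zip(anns, back):
                assert re_read.length == orig.length
                assert [
                    (g.start, g.end, g.strand, g.has_rbs) for g in re_read.genes
                ] == [(g.start, g.end, g.strand, g.has_rbs) for g in orig.genes]


class TestFastaLengths:
    def test_lengths_by_counting(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">c1 desc\n" + "A" * 30 + "\n" + "C" * 30 + "\n")
        assert read_fasta_lengths(p) == {"c1": 60}

    def test_empty_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">c1\n>c2\nACGT\n")
        assert read_fasta_lengths(p) == {"c1": 0, "c2": 4}

    def test_duplicate_ids_error(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">c1\nAC\n>c1\nGT\n")
        with pytest.raises(DuplicateIdError, match="c1"):
            read_fasta_lengths(p)


class TestMergeLengths:
    def ann(self, end=9000):
        return ContigAnnotation(
            "c1", None, [GeneRecord("c1", 1, 100, "+"), GeneRecord("c1", 200, end, "+")]
        )

    def test_length_populated(self):
        (m,) = merge_lengths([self.ann()], {"c1": 10000})
        assert m.length == 10000

    def test_gene_past_length_is_mismatch(self):
        with pytest.raises(CoordinateMismatchError):
            merge_lengths([self.ann(end=12000)], {"c1": 10000})

    def test_missing_id_named(self):
        with pytest.raises(MissingLengthError, match="c1"):
            merge_lengths([self.ann()], {"other": 10000})

    def test_empty_list(self):
        assert merge_lengths([], {}) == []


class TestTiaraTable:
    def test_native_multicolumn_layout(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "sequence_id\tclass_fst_stage\tclass_snd_stage\n"
            "c1 somedesc\teukarya\tn/a\n"
            "c2\tarchaea\tn/a\n"
            "c3\torganelle\torganelle\n"
        )
        preds = read_tiara_output(p)
        assert [(p.contig_id, p.code) for p in preds] == [
            ("c1", 0),
            ("c2", 1),
            ("c3", 2),
        ]

    def test_bare_two_column_table(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("c1\teukarya\nc2\tprokarya\n")
        preds = read_tiara_output(p)
        assert [(p.contig_id, p.code) for p in preds] == [("c1", 0), ("c2", 1)]

    def test_unknown_class_warns_and_maps_to_2(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sequence_id\tclass\nc1\tviroid\n")
        result = parse_tiara_output(p)
        assert result.predictions[0].code == 2
        assert any("viroid" in w for w in result.report.warnings)


class TestFeatureTable:
    def test_roundtrip_value_identical(self, tmp_path, rnd):
        anns = [fuzz_annotation(rnd, f"c{i}") for i in range(3)]
        frame, _ = features.build_feature_matrix(anns)
        p = tmp_path / "feat.tsv"
        write_feature_table(frame, p)
        back = read_feature_table(p)
        assert list(back.columns) == list(frame.columns)
        for col in frame.columns:
            assert back[col].to_numpy() == pytest.approx(
                frame[col].to_numpy(), rel=1e-11
            )

    def test_line_count(self, tmp_path, rnd):
        anns = [fuzz_annotation(rnd, f"c{i}") for i in range(3)]
        frame, _ = features.build_feature_matrix(anns)
        p = tmp_path / "feat.tsv"
        write_feature_table(frame, p)
        assert len(p.read_text().splitlines()) == 4

    def test_empty_table_is_header_only(self, tmp_path):
        frame, _ = features.build_feature_matrix([])
        p = tmp_path / "feat.tsv"
        write_feature_table(frame, p)
        assert len(p.read_text().splitlines()) == 1


class TestSplitFastaByClass:
    def test_partition(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        write_fasta(fasta, {f"c{i}": 40 for i in range(5)})
        preds = {
            "c0": "eukaryote",
            "c3": "eukaryote",
            "c1": "prokaryote",
            "c4": "prokaryote",
        }
        paths = split_fasta_by_class(fasta, preds, tmp_path / "out")
        euk = paths["eukaryote"].read_text()
        prok = paths["prokaryote"].read_text()
        # input order preserved inside each output
        assert euk.index(">c0") < euk.index(">c3")
        assert prok.index(">c1") < prok.index(">c4")
        assert paths["unclassified"].read_text().split() == ["c2"]

    def test_counts_always_partition_the_input(self, tmp_path, rnd):
        n = 8
        fasta = tmp_path / "in.fasta"
        write_fasta(fasta, {f"c{i}": 30 for i in range(n)})
        preds = {
            f"c{i}": rnd.choice(["eukaryote", "prokaryote"])
            for i in range(n)
            if rnd.random() < 0.6
        }
        paths = split_fasta_by_class(fasta, preds, tmp_path / "out")
        n_euk = paths["eukaryote"].read_text().count(">")
        n_prok = paths["prokaryote"].read_text().count(">")
        n_uncl = len(paths["unclassified"].read_text().split())
        assert n_euk + n_prok + n_uncl == n

    def test_all_absent(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        write_fasta(fasta, {f"c{i}": 30 for i in range(5)})
        paths = split_fasta_by_class(fasta, {}, tmp_path / "out")
        assert paths["eukaryote"].read_text() == ""
        assert len(paths["unclassified"].read_text().split()) == 5
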