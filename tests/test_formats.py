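"""I/O round trips and parsing rules for the external table formats."""

import pytest

from paleokaryo.formats import (
    FormatError,
    GeneRecord,
    HspRecord,
    TeRecord,
    group_hsps,
    read_block_table,
    read_gene_order,
    read_gff3,
    read_hsp_table,
    write_block_bed,
    write_block_table,
    write_gene_order,
    write_gff3,
    write_hsp_table,
)
from paleokaryo.synteny import Anchor, SyntenyBlock


def _hsp_row(q, s, pident, length, qstart=1, qend=None):
    qend = qend if qend is not None else qstart + length - 1
    return (
        f"{q}\t{s}\t{pident}\t{length}\t0\t0\t{qstart}\t{qend}"
        f"\t{qstart}\t{qend}\t1e-50\t200.0"
    )


class TestHspTable:
    def test_percent_identity_converted_to_counts(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text(_hsp_row("g1", "g2", 95.0, 200) + "\n")
        (rec,) = read_hsp_table(path, dialect="pct")
        assert rec.identities == 190
        assert rec.hsp_length == 200

    def test_empty_file_gives_empty_sequence(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("")
        assert read_hsp_table(path) == []

    def test_rows_group_by_gene_pair(self, tmp_path):
        path = tmp_path / "h.tsv"
        rows = [
            _hsp_row("a", "b", 90.0, 100, qstart=1),
            _hsp_row("a", "b", 88.0, 50, qstart=200),
            _hsp_row("a", "c", 80.0, 120),
        ]
        path.write_text("\n".join(rows) + "\n")
        records = read_hsp_table(path, dialect="pct")
        assert len(records) == 3
        groups = group_hsps(records)
        assert set(groups) == {("a", "b"), ("a", "c")}
        assert len(groups[("a", "b")]) == 2

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text(_hsp_row("a", "b", 90.0, 100) + "\nbad\trow\n")
        with pytest.raises(FormatError, match="line 2"):
            read_hsp_table(path, dialect="pct")

    def test_zero_length_rejected(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text(_hsp_row("a", "b", 90.0, 0) + "\n")
        with pytest.raises(FormatError):
            read_hsp_table(path, dialect="pct")

    def test_nident_dialect_roundtrip(self, tmp_path):
        recs = [
            HspRecord("a", "b", 137, 101, 5, 130),
            HspRecord("a", "c", 50, 25, 1, 50),
        ]
        path = tmp_path / "h.tsv"
        write_hsp_table(recs, path, dialect="nident")
        back = read_hsp_table(path, dialect="nident")
        assert [
            (r.query_id, r.subject_id, r.hsp_length, r.identities)
            for r in back
        ] == [
            (r.query_id, r.subject_id, r.hsp_length, r.identities)
            for r in recs
        ]


class TestGeneOrder:
    def test_ranks_follow_start_coordinates(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "genome_id\tchromosome_id\tgene_id\tstart\tend\tstrand\tcds_length\n"
            "G\tc1\tga\t100\t150\t+\t50\n"
            "G\tc1\tgb\t50\t80\t+\t30\n"
            "G\tc1\tgc\t200\t260\t-\t60\n"
        )
        genes = read_gene_order(path)["G"]
        assert {g.gene_id: g.rank for g in genes} == {"ga": 1, "gb": 0, "gc": 2}

    def test_chromosomes_rank_independently(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "genome_id\tchromosome_id\tgene_id\tstart\tend\tstrand\tcds_length\n"
            "G\tc1\tga\t100\t150\t+\t50\n"
            "G\tc2\tgb\t500\t580\t+\t80\n"
            "G\tc2\tgc\t100\t190\t+\t90\n"
        )
        genes = read_gene_order(path)["G"]
        ranks = {g.gene_id: g.rank for g in genes}
        assert ranks == {"ga": 0, "gb": 1, "gc": 0}

    def test_ranks_are_a_permutation_per_chromosome(self, tmp_path):
        # ties on start broken by gene id; ranks must be exactly 0..k-1
        path = tmp_path / "g.tsv"
        rows = [
            f"G\tc1\tg{i:02d}\t{start}\t{start + 10}\t+\t10"
            for i, start in enumerate([30, 10, 10, 50, 20, 20, 20])
        ]
        path.write_text(
            "genome_id\tchromosome_id\tgene_id\tstart\tend\tstrand\tcds_length\n"
            + "\n".join(rows) + "\n"
        )
        genes = read_gene_order(path)["G"]
        assert sorted(g.rank for g in genes) == list(range(7))

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "genome_id\tchromosome_id\tgene_id\tstart\tend\tstrand\tcds_length\n"
            "G\tc1\tga\t100\t150\t+\t50\n"
            "G\tc2\tga\t50\t80\t+\t30\n"
        )
        with pytest.raises(FormatError, match="duplicate"):
            read_gene_order(path)

    def test_write_read_roundtrip(self, tmp_path):
        genes = [
            GeneRecord("ga", "G", "c1", 0, 50, 80, 1, 31),
            GeneRecord("gb", "G", "c1", 1, 100, 150, -1, 51),
        ]
        path = tmp_path / "g.tsv"
        write_gene_order(genes, path)
        back = read_gene_order(path)["G"]
        assert back == genes


class TestGff3:
    def test_roundtrip_genes_and_tes(self, tmp_path):
        genes = [
            GeneRecord("ga", "G", "c1", 0, 100, 1300, 1, 1201),
            GeneRecord("gb", "G", "c1", 1, 2000, 2900, -1, 901),
        ]
        tes = [
            TeRecord("G", "c1", 500, 1500, "classI_LTR"),
            TeRecord("G", "c1", 1600, 1900, "classII"),
        ]
        path = tmp_path / "f.gff3"
        write_gff3(genes, tes, path)
        back_genes, back_tes = read_gff3(path)
        assert back_genes["G"] == genes
        assert back_tes == tes

    def test_te_without_class_rejected(self, tmp_path):
        path = tmp_path / "f.gff3"
        path.write_text(
            "##gff-version 3\n"
            "c1\tx\ttransposable_element\t1\t10\t.\t+\t.\tgenome=G\n"
        )
        with pytest.raises(FormatError, match="te_class"):
            read_gff3(path)

    def test_invalid_te_class_rejected(self):
        with pytest.raises(ValueError):
            TeRecord("G", "c1", 1, 10, "classIII")


def _toy_block(block_id="b1", n_anchors=5, bp_a=(1, 400_000)):
    anchors = [
        Anchor(f"a{i}", f"b{i}", rank_a=i, rank_b=i) for i in range(n_anchors)
    ]
    return SyntenyBlock(
        block_id=block_id, kind="orthologous",
        genome_a="A", chromosome_a="A_c1",
        genome_b="B", chromosome_b="B_c1",
        anchors=anchors, orientation="direct",
        density_ratio=10.0, p_value=0.001,
        bp_span_a=bp_a, bp_span_b=(1, 350_000),
    )


class TestBlockTables:
    def test_empty_block_set_writes_header_and_zero_summary(self, tmp_path):
        path = tmp_path / "blocks.tsv"
        write_block_table([], path, summaries={("A", "B"): (0, 0, 0)})
        text = path.read_text().splitlines()
        assert text[0].startswith("block_id\t")
        assert text[1] == "# summary\tA\tB\t0-0-0"
        assert read_block_table(path).empty

    def test_summary_triplet_from_coverage(self, tmp_path):
        # one 5-anchor block covering 40% of a 1 Mb toy genome
        from paleokaryo.synteny import coverage_summary

        block = _toy_block(bp_a=(1, 400_000))
        summary = coverage_summary([block], "A", 1_000_000)
        assert summary == (5, 1, 40)
        path = tmp_path / "blocks.tsv"
        write_block_table([block], path, summaries={("A", "B"): summary})
        assert "# summary\tA\tB\t5-1-40" in path.read_text()

    def test_block_table_roundtrip(self, tmp_path):
        blocks = [_toy_block("b1"), _toy_block("b2", n_anchors=7)]
        path = tmp_path / "blocks.tsv"
        write_block_table(blocks, path)
        df = read_block_table(path)
        assert list(df["block_id"]) == ["b1", "b2"]
        assert list(df["n_anchors"]) == [5, 7]
        assert list(df["bp_end_a"]) == [400_000, 400_000]

    def test_bed_export_is_zero_based_half_open(self, tmp_path):
        path = tmp_path / "blocks.bed"
        write_block_bed([_toy_block()], path, side="a")
        chrom, start, end, name = path.read_text().split()
        assert (chrom, int(start), int(end), name) == ("A_c1", 0, 400_000, "b1")
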