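"""Domain types, coordinate conventions and format round-trips."""

import math

import numpy as np
import pytest

from splicedrift import io as sio
from splicedrift.datamodel import (
    CoverageTrack,
    ExonRecord,
    Junction,
    JunctionSet,
    PasRecord,
)


@pytest.fixture
def exons():
    return [
        ExonRecord("gA", "gA.1", "chr1", 100, 200, "+"),
        ExonRecord("gA", "gA.2", "chr1", 400, 500, "+"),
        ExonRecord("gA", "gA.3", "chr1", 700, 800, "+"),
        ExonRecord("gB", "gB.1", "chr2", 50, 150, "-"),
        ExonRecord("gB", "gB.2", "chr2", 300, 360, "-"),
    ]


class TestExonAnnotation:
    def test_gtf_one_based_conversion(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; exon_id "g.1";\n')
        (ex,) = sio.read_exon_annotation(p, "gtf")
        assert (ex.start, ex.end) == (100, 200)

    def test_gtf_round_trip_identity(self, tmp_path, exons):
        p = tmp_path / "a.gtf"
        sio.write_exon_annotation(exons, p, "gtf")
        back = sio.read_exon_annotation(p, "gtf")
        assert sorted(back, key=lambda e: e.exon_id) == sorted(
            exons, key=lambda e: e.exon_id
        )
        # printed coordinates survive a second cycle byte-identically
        p2 = tmp_path / "b.gtf"
        sio.write_exon_annotation(back, p2, "gtf")
        assert p.read_text() == p2.read_text()

    def test_bed12_block_expansion_and_round_trip(self, tmp_path, exons):
        p = tmp_path / "a.bed"
        sio.write_exon_annotation(exons, p, "bed12")
        back = sio.read_exon_annotation(p, "bed12")
        assert {(e.gene_id, e.start, e.end, e.strand) for e in back} == {
            (e.gene_id, e.start, e.end, e.strand) for e in exons
        }
        assert sum(e.gene_id == "gA" for e in back) == 3

    def test_duplicates_collapsed(self, tmp_path):
        p = tmp_path / "a.gtf"
        row = 'chr1\ts\texon\t101\t200\t.\t+\t.\tgene_id "g";\n'
        p.write_text(row + row)
        assert len(sio.read_exon_annotation(p, "gtf")) == 1

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\ts\texon\t101\t200\t.\t+\t.\tgene_id "g";\nchr1\tbroken\n')
        with pytest.raises(ValueError, match=":2"):
            sio.read_exon_annotation(p, "gtf")

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text("")
        assert sio.read_exon_annotation(p, "gtf") == []

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            sio.read_exon_annotation(p, "gff9")

    def test_dot_strand_rejected_for_exons(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\ts\texon\t101\t200\t.\t.\t.\tgene_id "g";\n')
        with pytest.raises(ValueError, match="strand"):
            sio.read_exon_annotation(p, "gtf")


class TestJunctions:
    def test_bed12_intron_arithmetic(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text(
            "chr1\t100\t500\tJ\t7\t+\t100\t500\t0\t2\t50,60\t0,340\n"
        )
        js = sio.read_junctions(p, "bed12_junctions")
        (j,) = list(js)
        assert (j.intron_start, j.intron_end, j.read_count) == (150, 440, 7)

    def test_sj_tab_conversion(self, tmp_path):
        p = tmp_path / "SJ.out.tab"
        p.write_text("chr1\t151\t440\t1\t1\t1\t12\t0\t20\n")
        (j,) = list(sio.read_junctions(p, "sj_tab"))
        assert (j.intron_start, j.intron_end, j.strand, j.read_count) == (
            150, 440, "+", 12,
        )

    def test_duplicate_intron_rejected(self, tmp_path):
        p = tmp_path / "SJ.out.tab"
        p.write_text("chr1\t151\t440\t1\t1\t1\t12\t0\t20\n" * 2)
        with pytest.raises(ValueError, match="duplicate"):
            sio.read_junctions(p, "sj_tab")

    def test_blockcount_not_two_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "j.bed"
        p.write_text("chr1\t100\t500\tJ\t7\t+\t100\t500\t0\t3\t50,10,60\t0,100,340\n")
        js = sio.read_junctions(p, "bed12_junctions")
        assert len(js) == 0

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text("chr1\t100\t500\tJ\t-3\t+\t100\t500\t0\t2\t50,60\t0,340\n")
        with pytest.raises(ValueError, match="negative"):
            sio.read_junctions(p, "bed12_junctions")

    @pytest.mark.parametrize("dialect", ["bed12_junctions", "sj_tab"])
    def test_round_trip(self, tmp_path, dialect):
        js = JunctionSet("s1", [
            Junction("chr1", 150, 440, "+", 7),
            Junction("chr1", 600, 900, "-", 2),
            Junction("chr2", 30, 90, ".", 5),
        ])
        p = tmp_path / "j.txt"
        sio.write_junctions(js, p, dialect)
        back = sio.read_junctions(p, dialect, sample_id="s1")
        assert sorted(j.key + (j.read_count,) for j in back) == sorted(
            j.key + (j.read_count,) for j in js
        )

    def test_merge_sums_counts(self):
        a = JunctionSet("a", [Junction("chr1", 10, 50, "+", 3)])
        b = JunctionSet("b", [Junction("chr1", 10, 50, "+", 4),
                              Junction("chr1", 60, 90, "+", 1)])
        m = JunctionSet.merge("m", [a, b])
        counts = {j.key: j.read_count for j in m}
        assert counts[("chr1", 10, 50, "+")] == 7
        assert counts[("chr1", 60, 90, "+")] == 1


class TestCoverage:
    def test_sweep_line_from_reads(self):
        t = CoverageTrack.from_reads({"chr1": [(0, 10), (5, 15)]})
        assert t.intervals("chr1") == [(0, 5, 1.0), (5, 10, 2.0), (10, 15, 1.0)]

    def test_total_mass_equals_read_length_sum(self):
        rng = np.random.default_rng(11)
        reads = []
        for _ in range(200):
            s = int(rng.integers(0, 1000))
            reads.append((s, s + int(rng.integers(1, 80))))
        t = CoverageTrack.from_reads({"chr1": reads})
        assert t.total_mass() == pytest.approx(sum(e - s for s, e in reads))

    def test_empty_bedgraph_is_zero_everywhere(self, tmp_path):
        p = tmp_path / "c.bg"
        p.write_text("")
        t = sio.read_coverage(p, "bedgraph")
        assert t.window_sum("chr1", 0, 10_000) == 0.0

    def test_overlapping_bedgraph_rejected(self, tmp_path):
        p = tmp_path / "c.bg"
        p.write_text("chr1\t0\t10\t2\nchr1\t5\t8\t1\n")
        with pytest.raises(ValueError, match="overlap"):
            sio.read_coverage(p, "bedgraph")

    def test_unsorted_bedgraph_sorted_internally(self, tmp_path):
        p = tmp_path / "c.bg"
        p.write_text("chr1\t20\t30\t1\nchr1\t0\t10\t2\n")
        t = sio.read_coverage(p, "bedgraph")
        assert t.window_sum("chr1", 0, 30) == pytest.approx(30.0)

    def test_bedgraph_round_trip(self, tmp_path):
        t = CoverageTrack({"chr1": [(0, 10, 2.0), (10, 25, 0.5)],
                           "chr2": [(5, 6, 3.0)]})
        p = tmp_path / "c.bg"
        sio.write_coverage(t, p)
        back = sio.read_coverage(p, "bedgraph")
        for chrom in t.chroms:
            assert back.intervals(chrom) == t.intervals(chrom)

    def test_window_sum_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        ivs = []
        pos = 0
        for _ in range(40):
            pos += int(rng.integers(0, 20))
            end = pos + int(rng.integers(1, 30))
            ivs.append((pos, end, float(rng.integers(0, 5))))
            pos = end
        t = CoverageTrack({"chr1": ivs})
        per_base = np.zeros(pos + 10)
        for s, e, d in ivs:
            per_base[s:e] = d
        for _ in range(100):
            a = int(rng.integers(0, pos))
            b = a + int(rng.integers(1, 400))
            assert t.window_sum("chr1", a, b) == pytest.approx(
                per_base[a:min(b, len(per_base))].sum()
            )


class TestPasAndTables:
    def test_pas_round_trip_and_strand_required(self, tmp_path):
        sites = [PasRecord("gA", "chr1", 1000, "+"), PasRecord("gB", "chr2", 50, "-")]
        p = tmp_path / "pas.bed"
        sio.write_pas_bed(sites, p)
        assert sio.read_pas_bed(p) == sorted(sites, key=lambda x: (x.chrom, x.site))
        p.write_text("chr1\t10\t11\tg\t0\t.\n")
        with pytest.raises(ValueError, match="strand"):
            sio.read_pas_bed(p)

    def test_expression_round_trip_and_negativity(self, tmp_path):
        import pandas as pd
        from splicedrift.datamodel import ExpressionTable

        frame = pd.DataFrame({"s1": [1.0, 0.01], "s2": [2.5, 3.0]},
                             index=["gA", "gB"])
        frame.index.name = "gene_id"
        t = ExpressionTable(frame)
        p = tmp_path / "e.tsv"
        sio.write_expression_table(t, p)
        back = sio.read_expression_table(p)
        assert back.frame.equals(t.frame)
        p.write_text("gene_id\ts1\ngA\t-1\n")
        with pytest.raises(ValueError):
            sio.read_expression_table(p)

    def test_design_missing_column_named(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("sample_id\tfoo\nWT1\tx\n")
        with pytest.raises(ValueError, match="genotype"):
            sio.read_design(p)

    def test_delta_ct_tokens(self):
        d = sio.parse_delta_ct_token("> 9.4")
        assert d.value == pytest.approx(9.4) and d.is_lower_limit
        assert sio.parse_delta_ct_token("ND").is_missing
        assert sio.parse_delta_ct_token("−1.5").value == pytest.approx(-1.5)

    def test_qpcr_ct_table_nd(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text(
            "target\torgan\tgenotype\tmouse_id\tct_abnormal\tct_normal\n"
            "Pick1\tliver\tWT\tm1\tND\t30.6\n"
        )
        (m,) = sio.read_qpcr_table(p)
        assert m.ct_abnormal is None and m.ct_normal == pytest.approx(30.6)

    def test_fasta_round_trip(self, tmp_path):
        seqs = {"chr1": "ACGT" * 40, "chr2": "TTTTTGGGGG"}
        p = tmp_path / "g.fa"
        sio.write_fasta(seqs, p)
        assert sio.read_fasta(p) == seqs


class TestDomainInvariants:
    def test_exon_validation(self):
        with pytest.raises(ValueError):
            ExonRecord("g", "e", "chr1", 10, 10, "+")
        with pytest.raises(ValueError):
            ExonRecord("g", "e", "chr1", 5, 10, "*")

    def test_junction_validation(self):
        with pytest.raises(ValueError):
            Junction("chr1", 50, 40, "+", 1)
        with pytest.raises(ValueError):
            Junction("chr1", 10, 40, "+", -1)
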