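"""Chimeric parsing and back-splice junction calling."""

import random

import pytest

from circdec.annotation import GenomicInterval, build_splice_index
from circdec.backsplice import (
    BackspliceJunction,
    ChimericRecord,
    call_backsplices,
    classify_circ_type,
    parse_chimeric_file,
    snap_to_annotation,
)
from tests.conftest import make_gene


def chimeric_line(read_id, chrom, donor1, acceptor1, strand, seg1, cig1, seg2, cig2):
    return "\t".join(
        str(x)
        for x in (chrom, donor1, strand, chrom, acceptor1, strand, 1, 0, 0,
                  read_id, seg1, cig1, seg2, cig2)
    ) + "\n"


def bsj_record(read_id, chrom, s, e, strand, offset=30, rl=100):
    """Chimeric record of a read crossing the back-splice of circle [s, e)."""
    if strand == "+":
        seg_a = GenomicInterval(chrom, e - offset, e, strand)
        seg_b = GenomicInterval(chrom, s, s + rl - offset, strand)
    else:
        seg_a = GenomicInterval(chrom, s, s + offset, strand)
        seg_b = GenomicInterval(chrom, e - (rl - offset), e, strand)
    return ChimericRecord(read_id, chrom, chrom, strand, strand,
                          seg_a, seg_b, 0, offset)


class TestParseChimericFile:
    def test_read_split_30_70(self, tmp_path):
        """A 100 bp read whose first 30 bp map to an exon 3' end and the
        remaining 70 bp to an exon 5' start yields offsets 0 and 30."""
        p = tmp_path / "chim.junction"
        p.write_text(
            chimeric_line("r1", "chr1", 801, 300, "+", 771, "30M70S", 301, "30S70M")
        )
        (rec,) = parse_chimeric_file(p)
        assert rec.read_offset_a == 0
        assert rec.read_offset_b == 30
        assert (rec.seg_a.start, rec.seg_a.end) == (770, 800)
        assert (rec.seg_b.start, rec.seg_b.end) == (300, 370)

    def test_header_skipped_and_empty(self, tmp_path):
        p = tmp_path / "chim.junction"
        p.write_text("# header\n")
        assert parse_chimeric_file(p) == []
        p.write_text("")
        assert parse_chimeric_file(p) == []

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "chim.junction"
        p.write_text("chr1\t100\t+\n")
        with pytest.raises(ValueError, match=":1"):
            parse_chimeric_file(p)

    def test_minus_strand_offsets(self, tmp_path):
        # '-' alignment: leading reference clip is the read tail
        p = tmp_path / "chim.junction"
        p.write_text(
            chimeric_line("r1", "chr1", 300, 801, "-", 301, "70S30M", 731, "70M30S")
        )
        (rec,) = parse_chimeric_file(p)
        assert rec.read_offset_a == 0 and rec.read_offset_b == 30
        assert rec.seg_a.start == 300  # read prefix at genomic left on '-'


class TestCallBacksplices:
    def test_min_cjc_threshold(self, toy_index):
        recs = [
            bsj_record("r1", "chr1", 300, 600, "+"),
            bsj_record("r2", "chr1", 300, 600, "+"),
            bsj_record("r3", "chr1", 2200, 2500, "-"),
        ]
        called = call_backsplices(recs, toy_index, min_cjc=2)
        assert [(j.acceptor, j.donor, j.cjc) for j in called] == [(300, 600, 2)]

    def test_strand_mismatch_rejected(self, toy_index):
        rec = bsj_record("r1", "chr1", 300, 600, "+")
        bad = ChimericRecord("r1", "chr1", "chr1", "+", "-", rec.seg_a,
                             GenomicInterval("chr1", 300, 370, "-"), 0, 30)
        assert call_backsplices([bad], toy_index, min_cjc=1) == []

    def test_colinear_order_rejected(self, toy_index):
        # read prefix upstream of suffix: a linear splice, not a back-splice
        rec = ChimericRecord(
            "r1", "chr1", "chr1", "+", "+",
            GenomicInterval("chr1", 300, 370, "+"),
            GenomicInterval("chr1", 500, 530, "+"), 0, 70,
        )
        assert call_backsplices([rec], toy_index, min_cjc=1) == []

    def test_no_common_gene_rejected(self, toy_index):
        # one segment in a gene, the other outside any same-strand gene:
        # fusion-like, not a circle
        rec = ChimericRecord(
            "r1", "chr1", "chr1", "+", "+",
            GenomicInterval("chr1", 2100, 2150, "+"),
            GenomicInterval("chr1", 150, 220, "+"), 0, 50,
        )
        assert call_backsplices([rec], toy_index, min_cjc=1) == []

    def test_both_segments_one_gene_accepted(self, toy_index):
        rec = ChimericRecord(
            "r2", "chr1", "chr1", "+", "+",
            GenomicInterval("chr1", 750, 800, "+"),
            GenomicInterval("chr1", 100, 150, "+"), 0, 50,
        )
        assert len(call_backsplices([rec], toy_index, min_cjc=1)) == 1

    def test_unannotated_max_span(self):
        index = build_splice_index([make_gene("g", "chr9", "+", [(10, 20)])])
        rec = ChimericRecord(
            "r1", "chr3", "chr3", "+", "+",
            GenomicInterval("chr3", 5_000_000, 5_000_050, "+"),
            GenomicInterval("chr3", 1000, 1050, "+"), 0, 50,
        )
        assert call_backsplices([rec], index, min_cjc=1, max_span=100_000) == []
        ok = call_backsplices([rec], index, min_cjc=1, max_span=10_000_000)
        assert len(ok) == 1

    def test_read_id_deduplication(self, toy_index):
        # both mates of one fragment support the junction -> CJC 1
        recs = [bsj_record("frag1", "chr1", 300, 600, "+", offset=30),
                bsj_record("frag1", "chr1", 300, 600, "+", offset=40)]
        (j,) = call_backsplices(recs, toy_index, min_cjc=1)
        assert j.cjc == 1

    def test_ambiguous_read_discarded(self, toy_index):
        recs = [bsj_record("r1", "chr1", 300, 600, "+"),
                bsj_record("r1", "chr1", 300, 800, "+")]
        assert call_backsplices(recs, toy_index, min_cjc=1) == []

    def test_order_independence(self, toy_index):
        recs = [bsj_record(f"r{i}", "chr1", 300, 600, "+", offset=10 + i)
                for i in range(8)]
        recs += [bsj_record(f"q{i}", "chr1", 500, 800, "+") for i in range(3)]
        base = call_backsplices(recs, toy_index, min_cjc=1)
        for seed in range(3):
            shuffled = recs[:]
            random.Random(seed).shuffle(shuffled)
            permuted = call_backsplices(shuffled, toy_index, min_cjc=1)
            assert [(j.key, j.cjc) for j in permuted] == [
                (j.key, j.cjc) for j in base
            ]

    def test_multiple_circles_per_gene_distinct(self, toy_index):
        recs = [bsj_record("a1", "chr1", 300, 600, "+"),
                bsj_record("a2", "chr1", 300, 800, "+"),
                bsj_record("a3", "chr1", 500, 800, "+")]
        called = call_backsplices(recs, toy_index, min_cjc=1)
        assert {(j.acceptor, j.donor) for j in called} == {
            (300, 600), (300, 800), (500, 800)
        }

    def test_mirror_symmetry(self):
        """Detection commutes with a coordinate mirror of the locus."""
        L = 1000
        genes_fwd = [make_gene("g", "chrM", "+", [(100, 200), (300, 400), (500, 600)])]
        genes_rev = [make_gene("g", "chrM", "-",
                               [(L - e, L - s) for s, e in [(100, 200), (300, 400), (500, 600)]])]
        fwd = call_backsplices(
            [bsj_record(f"r{i}", "chrM", 300, 600, "+") for i in range(3)],
            build_splice_index(genes_fwd), min_cjc=1,
        )
        rev = call_backsplices(
            [bsj_record(f"r{i}", "chrM", L - 600, L - 300, "-") for i in range(3)],
            build_splice_index(genes_rev), min_cjc=1,
        )
        (jf,), (jr,) = fwd, rev
        assert (jr.acceptor, jr.donor) == (L - jf.donor, L - jf.acceptor)
        assert jf.cjc == jr.cjc

    def test_invariants_on_simulated_records(self, sim_small):
        plan = sim_small.sample_plan("c1", 1, junction_only=True)
        called = call_backsplices(
            sim_small.chimeric_records(plan), sim_small.index, min_cjc=2
        )
        for j in called:
            assert j.acceptor < j.donor
            assert j.cjc >= 2


class TestSnapAndClassify:
    def test_exact_match_assigns_gene(self, toy_index):
        j = BackspliceJunction("chr1", 300, 600, "+")
        snapped = snap_to_annotation(j, toy_index, tol=0)
        assert (snapped.acceptor, snapped.donor, snapped.gene_id) == (300, 600, "g1")

    def test_snap_within_tolerance(self, toy_index):
        j = BackspliceJunction("chr1", 298, 600, "+")
        snapped = snap_to_annotation(j, toy_index, tol=2)
        assert (snapped.acceptor, snapped.donor) == (300, 600)

    def test_no_snap_at_zero_tolerance(self, toy_index):
        j = BackspliceJunction("chr1", 298, 600, "+")
        snapped = snap_to_annotation(j, toy_index, tol=0)
        assert (snapped.acceptor, snapped.gene_id) == (298, "NA")

    def test_nearest_site_preferred(self, toy_index):
        j = BackspliceJunction("chr1", 301, 599, "+")
        snapped = snap_to_annotation(j, toy_index, tol=2)
        assert (snapped.acceptor, snapped.donor) == (300, 600)

    def test_classify_exonic(self, toy_index):
        j = snap_to_annotation(BackspliceJunction("chr1", 300, 600, "+"), toy_index, 0)
        assert classify_circ_type(j, toy_index) == "exonic"

    def test_classify_intronic(self, toy_index):
        j = BackspliceJunction("chr1", 410, 480, "+")
        assert classify_circ_type(j, toy_index) == "intronic"

    def test_classify_intergenic(self, toy_index):
        j = BackspliceJunction("chr7", 100, 500, "+")
        assert classify_circ_type(j, toy_index) == "intergenic"

    def test_within_gene_off_boundary_is_intronic(self, toy_index):
        j = BackspliceJunction("chr1", 310, 600, "+")
        assert classify_circ_type(j, toy_index) == "intronic"
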