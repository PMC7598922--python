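"""PBI estimation, Fisher testing, BH correction, DEC calling, reporting."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circdec.backsplice import BackspliceJunction
from circdec.diffexp import (
    DECRecord,
    bh_fdr,
    build_dec_records,
    call_decs,
    compute_pbi,
    fisher_test,
    pool_replicates,
    read_results,
    run_differential,
    write_results,
)
from circdec.linear import JunctionCountSet


class TestComputePbi:
    @pytest.mark.parametrize(
        "cjc,ljc,expected",
        [(10, 20, 0.5), (0, 50, 0.0), (7, 0, 1.0), (1, 2, 0.5), (5, 30, 0.25)],
    )
    def test_values(self, cjc, ljc, expected):
        assert compute_pbi(cjc, ljc).pbi == pytest.approx(expected)

    def test_undefined_when_no_reads(self):
        assert compute_pbi(0, 0).pbi is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_pbi(-1, 5)

    @given(c=st.integers(0, 5000), l=st.integers(0, 5000))
    @settings(max_examples=200, deadline=None)
    def test_algebraic_identity(self, c, l):
        est = compute_pbi(c, l)
        if 2 * c + l == 0:
            assert est.pbi is None
        else:
            assert est.pbi == pytest.approx(2 * c / (2 * c + l))

    @given(c=st.integers(0, 300), l=st.integers(1, 300))
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, c, l):
        assert compute_pbi(c + 1, l).pbi >= compute_pbi(c, l).pbi
        if c > 0:
            assert compute_pbi(c, l + 1).pbi <= compute_pbi(c, l).pbi


class TestPoolReplicates:
    def test_sum(self):
        pooled = pool_replicates(
            [JunctionCountSet(3, 4, 6), JunctionCountSet(2, 1, 1)]
        )
        assert (pooled.cjc, pooled.ujc, pooled.djc, pooled.ljc) == (5, 5, 7, 12)

    def test_single_is_identity(self):
        one = JunctionCountSet(3, 4, 6)
        pooled = pool_replicates([one])
        assert (pooled.cjc, pooled.ujc, pooled.djc) == (3, 4, 6)

    def test_commutative(self):
        a, b, c = (JunctionCountSet(3, 4, 6), JunctionCountSet(2, 1, 1),
                   JunctionCountSet(0, 9, 0))
        fwd = pool_replicates([a, b, c])
        rev = pool_replicates([c, b, a])
        assert (fwd.cjc, fwd.ujc, fwd.djc) == (rev.cjc, rev.ujc, rev.djc)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_replicates([])


def fisher_oracle(a, b, c, d):
    """Brute-force two-sided Fisher p: exact rational enumeration over all
    tables with the observed margins, probability-mass rule."""
    r1, r2, c1 = a + b, c + d, a + c
    total = comb(r1 + r2, c1)
    obs = comb(r1, a) * comb(r2, c1 - a)
    p = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= obs:
            p += Fraction(w, total)
    return float(p)


class TestFisher:
    def test_identical_rows_p_one(self):
        assert fisher_test(5, 5, 5, 5) == pytest.approx(1.0)

    def test_doubling_convention(self):
        """The tested table is [[2*CJC, LJC], [2*CJC, LJC]]: the circle
        presents one junction where the linear form presents two."""
        assert fisher_test(10, 5, 1, 40) == pytest.approx(
            fisher_oracle(20, 5, 2, 40), abs=1e-12
        )

    def test_row_swap_symmetry(self):
        assert fisher_test(10, 5, 1, 40) == pytest.approx(
            fisher_test(1, 40, 10, 5), abs=1e-12
        )

    def test_all_zero_undefined(self):
        assert fisher_test(0, 0, 0, 0) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_test(-1, 0, 0, 1)

    @given(
        c1=st.integers(0, 40), l1=st.integers(0, 40),
        c2=st.integers(0, 40), l2=st.integers(0, 40),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, c1, l1, c2, l2):
        p = fisher_test(c1, l1, c2, l2)
        if 2 * c1 + l1 + 2 * c2 + l2 == 0:
            assert p is None
        else:
            assert p == pytest.approx(
                min(1.0, fisher_oracle(2 * c1, l1, 2 * c2, l2)), abs=1e-9
            )

    def test_scipy_cross_check(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(42)
        for _ in range(300):
            c1, l1, c2, l2 = (int(x) for x in rng.integers(0, 60, 4))
            if 2 * c1 + l1 + 2 * c2 + l2 == 0:
                continue
            p_scipy = fisher_exact([[2 * c1, l1], [2 * c2, l2]])[1]
            assert fisher_test(c1, l1, c2, l2) == pytest.approx(p_scipy, abs=1e-9)

    def test_large_table_path(self):
        from scipy.stats import fisher_exact

        # beyond the exact-enumeration limit the scipy path takes over
        p = fisher_test(3000, 4000, 2500, 5000)
        assert p == pytest.approx(
            fisher_exact([[6000, 4000], [5000, 5000]])[1], rel=1e-6
        )


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_hand_computed_mixed(self):
        # m=4: sorted 0.005->0.02, 0.1->0.2, 0.03->0.06->min with later 0.06
        assert bh_fdr([0.1, 0.005, 0.03, 0.9]) == pytest.approx(
            [0.13333333333, 0.02, 0.06, 0.9]
        )

    def test_single_p(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance(self, ps, rnd):
        base = bh_fdr(ps)
        idx = list(range(len(ps)))
        rnd.shuffle(idx)
        permuted = bh_fdr([ps[i] for i in idx])
        assert permuted == pytest.approx([base[i] for i in idx])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_monotone_along_sorted_order(self, ps):
        order = np.argsort(ps)
        adj = bh_fdr(ps)[order]
        assert np.all(np.diff(adj) >= -1e-12)
        assert np.all((adj >= 0) & (adj <= 1))

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        ps = rng.uniform(size=200)
        assert bh_fdr(ps) == pytest.approx(
            multipletests(ps, method="fdr_bh")[1]
        )


def make_record(cjc1, ljc1, cjc2, ljc2, key=0):
    j = BackspliceJunction("chr1", 100 + 1000 * key, 500 + 1000 * key, "+")
    return DECRecord(j, JunctionCountSet(cjc1, ljc1, 0),
                     JunctionCountSet(cjc2, ljc2, 0))


class TestCallDecs:
    def test_small_effect_not_dec(self):
        rec = make_record(1, 1, 1, 1)
        rec.delta_pbi, rec.fdr = 0.04, 0.001
        (out,) = call_decs([rec])
        assert not out.is_dec  # |dPBI| below 5%

    def test_both_thresholds_met(self):
        rec = make_record(1, 1, 1, 1)
        rec.delta_pbi, rec.fdr = 0.30, 0.049
        assert call_decs([rec])[0].is_dec

    def test_fdr_boundary_strict(self):
        rec = make_record(1, 1, 1, 1)
        rec.delta_pbi, rec.fdr = -0.30, 0.06
        assert not call_decs([rec])[0].is_dec
        rec.fdr = 0.05
        assert not call_decs([rec])[0].is_dec  # FDR < cut is strict

    def test_dpbi_boundary_inclusive(self):
        rec = make_record(1, 1, 1, 1)
        rec.delta_pbi, rec.fdr = 0.05, 0.01
        assert call_decs([rec])[0].is_dec

    def test_permissive_cuts_flag_every_defined_record(self):
        records = [make_record(5, 10, 2, 30, key=k) for k in range(5)]
        run_differential(records)
        call_decs(records, dpbi_cut=0.0, fdr_cut=1.01)
        assert all(r.is_dec for r in records)

    def test_undefined_pbi_never_dec(self):
        rec = make_record(0, 0, 5, 5)
        run_differential([rec])
        call_decs([rec], dpbi_cut=0.0, fdr_cut=1.01)
        assert rec.delta_pbi is None and not rec.is_dec


class TestDifferentialAssembly:
    def test_untested_records_excluded_from_family(self):
        records = [make_record(8, 4, 1, 40, key=0), make_record(0, 0, 0, 0, key=1)]
        run_differential(records)
        assert records[0].fdr is not None
        assert records[1].p_value is None and records[1].fdr is None
        # family size m=1: FDR equals the raw p
        assert records[0].fdr == pytest.approx(records[0].p_value)

    def test_build_records_missing_key_zero_counts(self):
        j1 = BackspliceJunction("chr1", 100, 500, "+")
        j2 = BackspliceJunction("chr1", 700, 900, "+")
        counts1 = {j1.key: JunctionCountSet(5, 3, 3)}
        counts2 = {j1.key: JunctionCountSet(1, 10, 10),
                   j2.key: JunctionCountSet(4, 2, 2)}
        r1, r2 = build_dec_records([j1, j2], counts1, counts2)
        assert r2.counts_1.cjc == 0 and r2.pbi_1.pbi is None


class TestWriteResults:
    def test_empty_header_only(self, tmp_path):
        p = tmp_path / "out.tsv"
        write_results([], p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("chrom\t")

    def test_na_serialisation_and_round_trip(self, tmp_path):
        records = [make_record(5, 10, 2, 30, key=0), make_record(0, 0, 0, 0, key=1)]
        run_differential(records)
        call_decs(records)
        p = tmp_path / "out.tsv"
        write_results(records, p)
        assert "\tNA\t" in p.read_text()
        df = read_results(p)
        assert len(df) == 2
        row = df[df.start == 100].iloc[0]
        assert row.PBI_s1 == pytest.approx(0.5, abs=5e-7)
        assert row.p_value == pytest.approx(records[0].p_value, rel=1e-5)

    def test_sorted_by_fdr_then_effect(self, tmp_path):
        records = [make_record(20, 5, 1, 60, key=0), make_record(5, 5, 5, 5, key=1)]
        run_differential(records)
        p = tmp_path / "out.tsv"
        write_results(records, p)
        df = read_results(p)
        assert df.FDR.iloc[0] <= df.FDR.iloc[1]
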