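"""Seed-and-extend conserved-element detector vs brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conslocus.alignment_io import MultiAlignment, project_to_reference
from conslocus.mcs_core import (
    MCS,
    ParameterError,
    SeedParams,
    extend_and_merge,
    find_seeds,
    run_exactplus,
    summarize_mcs,
)
from conftest import random_alignment_rows
from oracles import oracle_exactplus, oracle_seeds

P754 = SeedParams(7, 5, 4)


def make_aln(rows, names=None, offset=0):
    names = names or [f"s{i}" for i in range(len(rows))]
    return MultiAlignment(names, rows, 0, "chr1", offset)


def as_tuples(mcs):
    return [
        (m.col_start, m.col_end, m.ref_start, m.ref_end, m.min_support, m.seeded_by)
        for m in mcs
    ]


def oracle_tuples(aln, params):
    return [
        (d["col_start"], d["col_end"], d["ref_start"], d["ref_end"],
         d["min_support"], d["seeded_by"])
        for d in oracle_exactplus(
            aln.rows, aln.reference_index, aln.ref_offset,
            params.L, params.S, params.E,
        )
    ]


class TestSeedParams:
    def test_754_defaults(self):
        p = SeedParams()
        assert (p.L, p.S, p.E) == (7, 5, 4)

    @pytest.mark.parametrize("L,S,E", [(0, 5, 4), (7, 4, 5), (7, 5, 1)])
    def test_invalid_rejected(self, L, S, E):
        with pytest.raises(ParameterError):
            SeedParams(L, S, E).validate()

    def test_s_beyond_species_count_rejected(self):
        with pytest.raises(ParameterError):
            SeedParams(7, 5, 4).validate(n_species=4)


class TestFindSeeds:
    def test_all_identical_every_window(self):
        aln = make_aln(["ACGTACGTAC"] * 7)
        assert find_seeds(aln, P754) == [(i, i + 7) for i in range(4)]

    def test_insufficient_agreement_no_seeds(self):
        # at every column at most 4 species agree: pairs of species
        # carry distinct bases (A,A,C,C,G,G,T) column-wise rotated
        rows = []
        base = "ACGT"
        for s in range(7):
            rows.append("".join(base[(s // 2 + c) % 4] for c in range(30)))
        aln = make_aln(rows)
        assert find_seeds(aln, P754) == []

    def test_gap_and_n_break_seed_words(self):
        rows = ["ACGTACGTACGTAC"] * 5
        rows = [r[:6] + "N" + r[7:] if i < 3 else r for i, r in enumerate(rows)]
        aln = make_aln(rows)
        got = find_seeds(aln, SeedParams(7, 5, 4))
        assert [a for a, _ in got] == oracle_seeds(aln.rows, 7, 5)
        assert got == [(7, 14)]

    def test_matches_subset_enumeration_on_random_alignment(self, rng):
        rows = random_alignment_rows(rng, 7, 200, 0.3, 0.0)
        aln = make_aln(rows)
        got = [a for a, _ in find_seeds(aln, P754)]
        assert got == oracle_seeds(rows, 7, 5)

    def test_per_column_rule_is_weaker(self, rng):
        rows = random_alignment_rows(rng, 7, 300, 0.25, 0.02)
        aln = make_aln(rows)
        word = set(find_seeds(aln, P754, seed_rule="word"))
        percol = set(find_seeds(aln, P754, seed_rule="per-column"))
        assert word <= percol


class TestExtendAndMerge:
    def test_extension_through_single_mismatch(self):
        # 5 species identical except one mismatch in one species in the
        # last column; 4 of 5 still agree there, so extension reaches the end
        rows = ["ACGTACGTACGT"] * 5
        rows[0] = rows[0][:-1] + "C"
        aln = make_aln(rows)
        params = SeedParams(7, 5, 4)
        mcs = extend_and_merge(aln, find_seeds(aln, params), params)
        assert as_tuples(mcs) == oracle_tuples(aln, params)
        assert mcs[0].col_start == 0 and mcs[0].col_end == 12

    def test_no_extension_when_flanks_fail(self):
        # seed flanked by columns where only 3 species agree
        mid = "ACGTACG"
        rows = []
        for s in range(5):
            left = "ACGT"[s % 4]
            right = "TGCA"[s % 4]
            rows.append(left + mid + right)
        aln = make_aln(rows)
        mcs = extend_and_merge(aln, [(1, 8)], SeedParams(7, 5, 4))
        assert len(mcs) == 1
        assert (mcs[0].col_start, mcs[0].col_end) == (1, 8)

    def test_overlapping_extensions_merge(self):
        aln = make_aln(["ACGTACGTACGTACGT"] * 5)
        mcs = extend_and_merge(aln, [(0, 7), (4, 11)], SeedParams(7, 5, 4))
        assert len(mcs) == 1 and mcs[0].seeded_by == 2

    def test_seed_out_of_bounds(self):
        aln = make_aln(["ACGTACGTAC"] * 5)
        with pytest.raises(IndexError):
            extend_and_merge(aln, [(5, 12)], SeedParams(7, 5, 4))

    def test_reference_gap_edges_trimmed(self):
        rows = ["--ACGTACGTA-", "CCACGTACGTAC", "CCACGTACGTAC",
                "CCACGTACGTAC", "CCACGTACGTAC", "CCACGTACGTAC"]
        aln = make_aln(rows, offset=10)
        params = SeedParams(5, 5, 4)
        mcs, _ = run_exactplus(aln, params)
        assert as_tuples(mcs) == oracle_tuples(aln, params)
        (m,) = mcs
        # reported interval excludes the reference-gap edge columns:
        # the reference row carries 9 bases (columns 2-10)
        assert m.ref_start == 10 and m.ref_end == 10 + 9


class TestRunExactplus:
    def test_all_identical_single_full_mcs(self):
        aln = make_aln(["ACGTACGTAC"] * 7, offset=100)
        mcs, summary = run_exactplus(aln)
        assert summary.count == 1
        assert (mcs[0].ref_start, mcs[0].ref_end) == (100, 110)
        assert mcs[0].min_support == 7

    def test_alignment_shorter_than_seed(self):
        aln = make_aln(["ACGT"] * 7)
        mcs, summary = run_exactplus(aln)
        assert mcs == [] and summary.count == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_random(self, seed):
        rng = np.random.default_rng(seed)
        n_sp = int(rng.integers(5, 9))
        n_col = int(rng.integers(20, 301))
        rows = random_alignment_rows(
            rng, n_sp, n_col,
            mismatch=float(rng.uniform(0.05, 0.5)),
            gap_rate=float(rng.uniform(0, 0.1)),
            n_rate=float(rng.uniform(0, 0.03)),
        )
        aln = make_aln(rows, offset=int(rng.integers(0, 10_000)))
        mcs, _ = run_exactplus(aln, P754)
        assert as_tuples(mcs) == oracle_tuples(aln, P754)

    def test_invariant_under_nonreference_row_permutation(self, rng):
        rows = random_alignment_rows(rng, 7, 250, 0.3, 0.03)
        aln = make_aln(rows)
        shuffled = [rows[0]] + [rows[i] for i in (4, 2, 6, 1, 5, 3)]
        aln2 = make_aln(shuffled)
        a, _ = run_exactplus(aln, P754)
        b, _ = run_exactplus(aln2, P754)
        assert as_tuples(a) == as_tuples(b)

    def test_mcs_pairwise_disjoint_and_sorted(self, rng):
        rows = random_alignment_rows(rng, 7, 300, 0.35, 0.05)
        mcs, _ = run_exactplus(make_aln(rows), P754)
        for a, b in zip(mcs, mcs[1:]):
            assert a.ref_end <= b.ref_start and a.col_end < b.col_start

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotonicity_in_parameters(self, seed):
        """Raising L, S or E never increases total conserved bp."""
        rng = np.random.default_rng(seed)
        rows = random_alignment_rows(rng, 7, 150, 0.25, 0.02)
        aln = make_aln(rows)
        _, base = run_exactplus(aln, SeedParams(6, 4, 3))
        for harder in (SeedParams(7, 4, 3), SeedParams(6, 5, 3), SeedParams(6, 4, 4)):
            _, s = run_exactplus(aln, harder)
            assert s.total_bp <= base.total_bp

    def test_every_mcs_contains_seed_and_satisfies_rules(self, rng):
        from conslocus.mcs_core import column_support

        rows = random_alignment_rows(rng, 7, 300, 0.3, 0.02)
        aln = make_aln(rows)
        support = column_support(aln)
        seeds = find_seeds(aln, P754)
        mcs, _ = run_exactplus(aln, P754)
        seed_starts = {a for a, _ in seeds}
        for m in mcs:
            assert (support[m.col_start : m.col_end] >= P754.E).all()
            assert any(
                m.col_start <= a and a + P754.L <= m.col_end for a in seed_starts
            )


class TestSummarize:
    def test_forced_arithmetic(self):
        mcs = [
            MCS("c", 0, 7, 0, 7, 5, 1),
            MCS("c", 50, 67, 50, 67, 4, 2),
        ]
        s = summarize_mcs(mcs, 100)
        assert (s.count, s.total_bp, s.mean_len) == (2, 24, 12.0)
        assert s.fraction_of_region == pytest.approx(0.24)
        assert (s.min_len, s.max_len) == (7, 17)

    def test_empty(self):
        s = summarize_mcs([], 100)
        assert (s.count, s.total_bp, s.fraction_of_region) == (0, 0, 0.0)
        assert s.min_len is None and s.max_len is None and s.mean_len is None

    def test_published_scale_fraction(self):
        """67 elements totalling 806 bp over a 40300 bp interval: ~2%."""
        lengths = [12] * 66 + [14]
        assert sum(lengths) == 806
        mcs = []
        pos = 0
        for ln in lengths:
            mcs.append(MCS("c", pos, pos + ln, pos, pos + ln, 5, 1))
            pos += ln + 500
        s = summarize_mcs(mcs, 40300)
        assert s.count == 67 and s.total_bp == 806
        assert s.fraction_of_region == pytest.approx(0.02, abs=0.0005)

    def test_bad_region(self):
        with pytest.raises(ParameterError):
            summarize_mcs([], 0)
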