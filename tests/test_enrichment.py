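import math
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import enum_hypergeom_tail_counts
from netpharm.enrichment import (
    AnnotationTable,
    bh_fdr,
    bubble_data,
    chord_data,
    enrich,
    hypergeom_p,
    read_gmt,
    top_terms,
    write_gmt,
)
from netpharm.synthetic_data import gen_annotations
from netpharm.target_sets import GeneSet


class TestHypergeomP:
    def test_enumerated_example(self):
        # all C(10, 4) draws, 5 marked: P[X >= 4] = 5/210
        assert hypergeom_p(4, 5, 4, 10) == pytest.approx(5 / 210)

    def test_k_zero_is_one(self):
        assert hypergeom_p(0, 5, 4, 10) == 1.0

    def test_certain_event(self):
        assert hypergeom_p(6, 6, 6, 6) == 1.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            hypergeom_p(3, 2, 5, 10)  # k > K
        with pytest.raises(ValueError):
            hypergeom_p(1, 11, 5, 10)  # K > N

    def test_matches_enumeration_small_grid(self):
        for N in (5, 8):
            for K in range(N + 1):
                for n in range(N + 1):
                    tails = enum_hypergeom_tail_counts(N, K, n)
                    for k, expected in tails.items():
                        assert hypergeom_p(k, K, n, N) == pytest.approx(float(expected), rel=1e-12)


class TestBhFdr:
    def test_hand_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_value_identity(self):
        assert bh_fdr([0.5]) == [0.5]

    def test_empty(self):
        assert bh_fdr([]) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        ps = [0.001, 0.08, 0.04, 0.04, 0.9, 0.32, 0.0003, 1.0]
        _, expected, _, _ = multipletests(ps, method="fdr_bh")
        assert bh_fdr(ps) == pytest.approx(list(expected))

    @given(ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_adjusted_at_least_raw(self, ps):
        adj = bh_fdr(ps)
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        assert all(0 <= a <= 1 for a in adj)

    @given(
        ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20),
        seed=st.integers(0, 99),
    )
    def test_permutation_equivariant(self, ps, seed):
        import random

        idx = list(range(len(ps)))
        random.Random(seed).shuffle(idx)
        shuffled = [ps[i] for i in idx]
        adj = bh_fdr(ps)
        adj_shuffled = bh_fdr(shuffled)
        assert adj_shuffled == pytest.approx([adj[i] for i in idx])

    def test_fixed_points_are_idempotent(self):
        # a monotone vector with p_i <= p_j * m / j for all j >= i is a
        # BH fixed point; tied (constant) adjusted vectors are the
        # canonical case
        tied = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert bh_fdr(tied) == pytest.approx(tied)
        assert bh_fdr([0.5]) == [0.5]
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])


def _table(terms, namespace="PATHWAY"):
    return AnnotationTable(namespace=namespace, terms=terms)


class TestEnrich:
    def test_query_equals_single_term(self):
        table = _table({"t1": ["A", "B", "C"], "t2": ["D", "E", "F", "G"]})
        rows, excluded = enrich(GeneSet("q", ["A", "B", "C"]), table)
        assert excluded == []
        row = rows[0]
        assert row.term == "t1" and row.k == 3 and row.K == 3 and row.n == 3
        # P[X >= 3], N=7, K=3, n=3 -> 1/C(7,3) = 1/35
        assert row.p_value == pytest.approx(1 / 35)

    def test_zero_overlap_terms_untested(self):
        table = _table({"hit": ["A", "B"], "miss": ["X", "Y"]})
        rows, _ = enrich(GeneSet("q", ["A"]), table)
        assert [r.term for r in rows] == ["hit"]

    def test_test_all_terms_flag_changes_m(self):
        table = _table({"hit": ["A", "B"], "miss": ["X", "Y"]})
        rows, _ = enrich(GeneSet("q", ["A"]), table, test_all_terms=True)
        assert {r.term for r in rows} == {"hit", "miss"}
        miss = next(r for r in rows if r.term == "miss")
        assert miss.p_value == 1.0 and miss.k == 0

    def test_out_of_universe_query_reported(self):
        table = _table({"t": ["A", "B"]})
        rows, excluded = enrich(GeneSet("q", ["A", "ZZZ"]), table)
        assert excluded == ["ZZZ"]
        assert rows[0].n == 1

    def test_empty_effective_query_errors(self):
        table = _table({"t": ["A"]})
        with pytest.raises(ValueError):
            enrich(GeneSet("q", ["ZZZ"]), table)

    def test_sorted_by_fdr_then_k_then_name(self):
        rows, _ = enrich(
            GeneSet("q", ["A", "B", "C", "D"]),
            _table({"big": ["A", "B", "C", "X"], "small": ["A", "Y", "Z"], "z_other": ["D", "W", "V"]}),
        )
        fdrs = [r.fdr for r in rows]
        assert fdrs == sorted(fdrs)

    def test_fdr_at_least_p(self):
        rows, _ = enrich(GeneSet("q", ["A", "B"]), _table({"t1": ["A", "X"], "t2": ["B", "Y", "Z"]}))
        for r in rows:
            assert r.fdr >= r.p_value - 1e-12

    def test_planted_term_ranks_first(self):
        universe = [f"G{i}" for i in range(200)]
        query = universe[:20]
        table, truth = gen_annotations(
            universe, query, n_terms=20, n_planted=1, enrichment_factor=8.0, seed=42,
            term_size_range=(25, 35),
        )
        rows, _ = enrich(GeneSet("q", query), table)
        assert rows[0].term in {t.split(":")[-1] for t in truth.planted_terms}


class TestTopTerms:
    def test_caps_per_namespace(self):
        universe = [f"G{i}" for i in range(100)]
        query = universe[:15]
        table, _ = gen_annotations(universe, query, n_terms=30, seed=1)
        rows, _ = enrich(GeneSet("q", query), table)
        assert len(top_terms(rows, 25)) == min(25, len(rows))

    def test_fewer_rows_than_n(self):
        rows, _ = enrich(GeneSet("q", ["A"]), _table({"t": ["A", "B"]}))
        assert len(top_terms(rows, 10)) == 1

    def test_bad_n_rejected(self):
        with pytest.raises(ValueError):
            top_terms([], 0)


class TestPlotData:
    def test_bubble_neg_log10(self):
        rows, _ = enrich(GeneSet("q", ["A", "B"]), _table({"t": ["A", "B"]}))
        df = bubble_data(rows)
        assert df.loc[0, "neg_log10_fdr"] == pytest.approx(-math.log10(rows[0].fdr))
        assert df.loc[0, "count"] == rows[0].k

    def test_chord_row_sums_equal_term_membership(self):
        table = _table({"t1": ["A", "B", "X"], "t2": ["A", "Y", "Z"], "t3": ["B", "W", "V"]})
        rows, _ = enrich(GeneSet("q", ["A", "B"]), table)
        df = chord_data(rows)
        assert df.loc["A"].sum() == 2  # A overlaps t1 and t2
        assert df.loc["B"].sum() == 2  # B overlaps t1 and t3
        assert set(df.values.flatten()) <= {0, 1}


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        table = _table({"term a": ["A", "B"], "term b": ["C"]}, namespace="GO_BP")
        p = tmp_path / "x.gmt"
        write_gmt(p, table)
        back = read_gmt(p, "GO_BP")
        assert back.terms == table.terms

    def test_malformed_line_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("only_name\n", encoding="utf-8")
        with pytest.raises(ValueError):
            read_gmt(p, "GO_BP")

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            _table({"t": []})

    def test_unknown_namespace_rejected(self):
        with pytest.raises(ValueError):
            AnnotationTable(namespace="KEGGish", terms={"t": ["A"]})
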