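import io
import math
from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from litrank.linktable import LinkRecord, LinkTable
from litrank.prioritize import (
    QueryContext,
    apply_threshold,
    build_query_context,
    hypergeom_tail,
    read_ranking_csv,
    score_genes,
    write_ranking_csv,
)
from litrank.retrieval import PmidSet


def exact_tail(m: int, n: int, j: int, k: int) -> Fraction:
    """Independent oracle: exact rational enumeration of the upper tail."""
    return Fraction(
        sum(comb(j, i) * comb(m - j, n - i) for i in range(k, min(n, j) + 1)),
        comb(m, n),
    )


# strategy producing valid (m, n, j, k) with m <= 60
@st.composite
def mnjk(draw, max_m=60):
    m = draw(st.integers(min_value=1, max_value=max_m))
    n = draw(st.integers(min_value=0, max_value=m))
    j = draw(st.integers(min_value=0, max_value=m))
    k = draw(st.integers(min_value=0, max_value=min(n, j)))
    return m, n, j, k


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((10, 5, 4, 3), Fraction(11, 42)),
            ((20, 10, 2, 2), Fraction(9, 38)),
        ],
    )
    def test_frozen_exact_values(self, args, expected):
        assert exact_tail(*args) == expected  # oracle agrees with hand enumeration
        assert hypergeom_tail(*args) == pytest.approx(float(expected), rel=1e-12)

    def test_k_zero_is_exactly_one(self):
        assert hypergeom_tail(10, 5, 4, 0) == 1.0
        assert hypergeom_tail(7, 0, 3, 0) == 1.0

    @pytest.mark.parametrize(
        "args", [(10, 11, 4, 3), (10, 5, 11, 3), (10, 5, 4, 5), (10, 5, 4, -1)]
    )
    def test_domain_violations_raise(self, args):
        with pytest.raises(ValueError):
            hypergeom_tail(*args)

    @settings(max_examples=300, deadline=None)
    @given(mnjk())
    def test_matches_exact_rational_oracle(self, args):
        m, n, j, k = args
        assert hypergeom_tail(m, n, j, k) == pytest.approx(float(exact_tail(m, n, j, k)), rel=1e-10)

    @settings(max_examples=200, deadline=None)
    @given(mnjk())
    def test_matches_scipy_survival_function(self, args):
        """Independent library cross-check: f(m,n,j,k) = P[X >= k] for
        X ~ Hypergeom(M=m, n=j, N=n)."""
        m, n, j, k = args
        assert hypergeom_tail(m, n, j, k) == pytest.approx(
            float(hypergeom.sf(k - 1, m, j, n)), rel=1e-9, abs=1e-300
        )

    @settings(max_examples=200, deadline=None)
    @given(mnjk())
    def test_decreasing_in_k_strictly_on_support(self, args):
        m, n, j, k = args
        if k >= min(n, j):
            return
        f_k = hypergeom_tail(m, n, j, k)
        f_next = hypergeom_tail(m, n, j, k + 1)
        if k < max(0, n + j - m):  # below the support: full mass both sides
            assert f_k == 1.0 == f_next
        else:
            assert f_next <= f_k * (1 + 1e-10)
            tail_k = exact_tail(m, n, j, k)
            pmf_k = tail_k - exact_tail(m, n, j, k + 1)
            if pmf_k / tail_k > 1e-9:  # resolvable at the tail's accuracy
                assert f_next < f_k

    @settings(max_examples=200, deadline=None)
    @given(mnjk())
    def test_symmetric_in_draws_and_successes(self, args):
        m, n, j, k = args
        assert hypergeom_tail(m, n, j, k) == pytest.approx(
            hypergeom_tail(m, j, n, k), rel=1e-10
        )

    def test_large_table_does_not_overflow(self):
        # m ~ realistic link-table size; direct binomials would overflow
        p = hypergeom_tail(650_000, 3000, 400, 60)
        assert 0 < p < 1e-20


def make_context():
    table = LinkTable(
        records=frozenset(
            [
                # gene 1: j=4, k=3 of n=5 (m=10)
                *[LinkRecord(9606, 1, p) for p in (11, 12, 13, 14)],
                # gene 2: j=7, k=1
                *[LinkRecord(9606, 2, p) for p in (11, 15, 16, 17, 18, 19, 20)],
                # gene 3: j=1, k=0 -> never emitted
                LinkRecord(9606, 3, 20),
            ]
        )
    )
    # n = 5: query pmids 11,12,13,15,16 occur in the table; 99 and 14000 do not
    query = PmidSet(pmids=frozenset({11, 12, 13, 15, 16, 99, 14_000}), query_label="demo")
    return build_query_context(table, query)


class TestBuildQueryContext:
    def test_n_counts_only_table_pmids(self, tiny_table):
        query = PmidSet(pmids=frozenset({5001, 5002, 5005, 9999, 8888, 7777, 6666}))
        ctx = build_query_context(tiny_table, query)
        assert ctx.m == 5
        assert ctx.n == 3

    def test_j_and_k_per_gene(self):
        ctx = make_context()
        j, k, support = ctx.evidence[1]
        assert (j, k) == (4, 3)
        assert support == (13, 12, 11)  # descending = most recent first

    def test_disjoint_query_gives_empty_evidence(self, tiny_table):
        ctx = build_query_context(tiny_table, PmidSet(pmids=frozenset({1, 2})))
        assert ctx.n == 0 and ctx.evidence == {}


class TestScoreGenes:
    def test_hypergeometric_score_matches_oracle(self):
        ctx = make_context()
        ranking = score_genes(ctx, method="hypergeometric")
        top = ranking.entries[0]
        assert top.gene_id == 1
        assert top.score == pytest.approx(-math.log10(11 / 42), rel=1e-9)
        assert top.p_value == pytest.approx(11 / 42, rel=1e-9)

    def test_counts_method_scores_by_j(self):
        ranking = score_genes(make_context(), method="counts")
        by_gene = {e.gene_id: e for e in ranking.entries}
        assert by_gene[2].score == 7.0
        assert by_gene[1].score == 4.0
        assert ranking.entries[0].gene_id == 2  # biggest j first

    def test_counts_method_k_variant(self):
        ranking = score_genes(make_context(), method="counts", count_by="k")
        assert ranking.entries[0].gene_id == 1
        assert ranking.entries[0].score == 3.0

    def test_k_zero_gene_never_emitted(self):
        ranking = score_genes(make_context())
        assert 3 not in ranking.gene_ids()

    def test_tied_scores_break_by_gene_id(self):
        ctx = QueryContext(
            m=10,
            n=5,
            evidence={
                9: (4, 2, (12, 11)),
                4: (4, 2, (12, 11)),
            },
        )
        ranking = score_genes(ctx)
        assert ranking.gene_ids() == [4, 9]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            score_genes(make_context(), method="tfidf")

    def test_score_cap_on_underflowing_p(self):
        ctx = QueryContext(m=1_000_000, n=500_000, evidence={1: (2000, 2000, tuple(range(2000, 0, -1)))})
        ranking = score_genes(ctx, max_score=308.0)
        assert ranking.entries[0].score == pytest.approx(308.0)

    def test_empty_context_gives_empty_ranking(self):
        ctx = QueryContext(m=10, n=0, evidence={})
        assert len(score_genes(ctx)) == 0


class TestApplyThreshold:
    def test_boundary_score_retained(self):
        ctx = QueryContext(
            m=10,
            n=5,
            evidence={1: (4, 3, (13, 12, 11)), 2: (7, 1, (11,))},
        )
        ranking = score_genes(ctx, method="counts")  # scores 4 and 7
        out = apply_threshold(ranking, min_score=4.0)
        assert out.gene_ids() == [2, 1]  # exactly-at-threshold entry kept
        assert out.threshold_applied == 4.0

    def test_zero_threshold_is_identity(self):
        ranking = score_genes(make_context())
        assert apply_threshold(ranking, 0.0).gene_ids() == ranking.gene_ids()

    def test_all_below_threshold_gives_empty_list(self):
        ranking = score_genes(make_context())
        assert len(apply_threshold(ranking, 1e6)) == 0

    def test_order_of_survivors_preserved(self):
        ranking = score_genes(make_context())
        kept = apply_threshold(ranking, 0.1).gene_ids()
        full = ranking.gene_ids()
        assert kept == [g for g in full if g in kept]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_threshold(score_genes(make_context()), -1.0)


def test_counts_and_hypergeometric_agree_when_j_uniform():
    """With identical j for every gene, the hypergeometric tail is a
    monotone function of k alone, so both methods order genes the same
    way (counts scored by k)."""
    evidence = {
        g: (10, k, tuple(range(100 + k, 100, -1)))
        for g, k in [(1, 5), (2, 3), (3, 8), (4, 1), (5, 6)]
    }
    ctx = QueryContext(m=200, n=40, evidence=evidence)
    hyper = score_genes(ctx, method="hypergeometric").gene_ids()
    counts_k = score_genes(ctx, method="counts", count_by="k").gene_ids()
    assert hyper == counts_k


def test_csv_round_trip():
    ranking = score_genes(make_context())
    buf = io.StringIO()
    write_ranking_csv(ranking, buf)
    buf.seek(0)
    back = read_ranking_csv(buf)
    assert back.method == ranking.method
    assert back.gene_ids() == ranking.gene_ids()
    assert [e.score for e in back.entries] == [e.score for e in ranking.entries]
    assert [e.supporting_pmids for e in back.entries] == [
        e.supporting_pmids for e in ranking.entries
    ]
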