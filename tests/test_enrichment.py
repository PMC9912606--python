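"""Hypergeometric enrichment, coverage, Venn retention, Jaccard similarity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fcig.enrichment import (
    functional_similarity,
    hypergeometric_enrich,
    pathway_coverage,
    read_gmt,
    venn_overlap,
    write_gmt,
)

from oracles import brute_hypergeom_upper_tail


def _genes(prefix, n):
    return {f"{prefix}{i}" for i in range(n)}


class TestHypergeometricEnrich:
    def test_disjoint_query_p_is_one(self):
        background = _genes("G", 20)
        terms = {"T": set(list(background)[:5])}
        query = set(list(background)[5:10]) - terms["T"]
        table = hypergeometric_enrich(query, terms, background)
        row = table.iloc[0]
        assert row["k"] == 0
        assert row["p"] == pytest.approx(1.0)
        assert not row["enriched"]

    def test_closed_form_full_hit(self):
        # N=20, K=5, n=5, k=5 -> p = 1/C(20,5) = 1/15504
        background = {f"G{i}" for i in range(20)}
        term = {f"G{i}" for i in range(5)}
        table = hypergeometric_enrich(term, {"T": term}, background)
        assert table.iloc[0]["p"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_matches_exhaustive_enumeration_small_universes(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            N = int(rng.integers(2, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            background = [f"G{i}" for i in range(N)]
            term = set(background[:K])
            query = set(rng.choice(background, size=n, replace=False).tolist())
            table = hypergeometric_enrich(query, {"T": term}, background)
            k = len(query & term)
            assert table.iloc[0]["k"] == k
            assert table.iloc[0]["p"] == pytest.approx(
                brute_hypergeom_upper_tail(N, K, n, k), abs=1e-9
            )

    def test_empty_background_raises(self):
        with pytest.raises(ValueError, match="background"):
            hypergeometric_enrich({"A"}, {}, background=set())

    def test_term_outside_background_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            table = hypergeometric_enrich({"A"}, {"T": {"Z9"}}, background={"A", "B"})
        assert len(table) == 0

    def test_query_genes_outside_background_dropped(self, caplog):
        background = _genes("G", 10)
        terms = {"T": set(list(sorted(background))[:4])}
        with caplog.at_level("WARNING"):
            table = hypergeometric_enrich({"G0", "ALIEN"}, terms, background)
        assert table.iloc[0]["n"] == 1

    def test_bh_adjustment_flag(self):
        background = _genes("G", 30)
        terms = {f"T{j}": set(list(sorted(background))[j : j + 6]) for j in range(10)}
        plain = hypergeometric_enrich(_genes("G", 6), terms, background)
        adjusted = hypergeometric_enrich(_genes("G", 6), terms, background, adjust=True)
        assert "p_adj" in adjusted.columns
        assert (adjusted["p_adj"] >= adjusted["p"] - 1e-12).all()
        assert adjusted["enriched"].sum() <= plain["enriched"].sum()

    @given(st.integers(0, 2**31 - 1))
    def test_adding_query_genes_weakly_increases_k(self, seed):
        rng = np.random.default_rng(seed)
        background = sorted(_genes("G", 15))
        term = set(rng.choice(background, 5, replace=False).tolist())
        small = set(rng.choice(background, 4, replace=False).tolist())
        extra = set(rng.choice(background, 4, replace=False).tolist())
        t_small = hypergeometric_enrich(small, {"T": term}, background)
        t_big = hypergeometric_enrich(small | extra, {"T": term}, background)
        assert t_big.iloc[0]["k"] >= t_small.iloc[0]["k"]


class TestCoverage:
    def test_identical_sets_give_full_coverage(self):
        report = pathway_coverage({"a", "b"}, {"a", "b"})
        assert report.coverage == 1.0

    def test_disjoint_sets_give_zero(self):
        assert pathway_coverage({"a"}, {"b"}).coverage == 0.0

    def test_direct_ratio(self):
        report = pathway_coverage({"t1", "t2", "t3", "t4", "x"}, {"t1", "t2", "t3", "t4", "t5"})
        assert report.coverage == pytest.approx(0.8)

    def test_empty_reference_is_nan(self, caplog):
        with caplog.at_level("WARNING"):
            report = pathway_coverage({"a"}, set())
        assert math.isnan(report.coverage)

    def test_superset_query_has_full_coverage(self):
        assert pathway_coverage({"a", "b", "c"}, {"a", "b"}).coverage == 1.0

    def test_accepts_enrichment_tables(self):
        table_a = pd.DataFrame({"term": ["t1", "t2"], "enriched": [True, False]})
        table_b = pd.DataFrame({"term": ["t1", "t2"], "enriched": [True, True]})
        assert pathway_coverage(table_a, table_b).coverage == 0.5


class TestVennOverlap:
    def test_printed_retention_ratio(self):
        """389 vs 348 reference-overlap counts give the printed 89.5%."""
        ref = _genes("P", 500)
        a = _genes("P", 389)  # 389 of the reference genes
        b = _genes("P", 348)
        result = venn_overlap(a, b, ref)
        assert result["a_in_ref"] == 389
        assert result["b_in_ref"] == 348
        assert result["retention_pct"] == 89.5

    def test_identical_sets_100_percent(self):
        a = _genes("G", 10)
        assert venn_overlap(a, a, _genes("G", 5))["retention_pct"] == 100.0

    def test_no_b_overlap_is_zero(self):
        assert venn_overlap(_genes("G", 5), _genes("X", 5), _genes("G", 5))["retention_pct"] == 0.0

    def test_empty_a_overlap_is_nan(self, caplog):
        with caplog.at_level("WARNING"):
            result = venn_overlap(_genes("X", 3), _genes("G", 3), _genes("G", 5))
        assert math.isnan(result["retention_pct"])

    def test_rounding_is_half_up(self):
        # 5/8 = 62.5% exactly: half-up keeps 62.5; 1/3 -> 33.3
        assert venn_overlap(_genes("P", 8), _genes("P", 5), _genes("P", 8))["retention_pct"] == 62.5
        assert venn_overlap(_genes("P", 3), _genes("P", 1), _genes("P", 3))["retention_pct"] == 33.3


class TestFunctionalSimilarity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [({"x", "y"}, {"x", "y"}, 1.0), ({"x"}, {"y"}, 0.0)],
    )
    def test_limits(self, a, b, expected):
        assert functional_similarity(a, b) == expected

    def test_direct_ratio(self):
        a = {"t1", "t2", "t3", "t4"}
        b = {"t3", "t4", "t5", "t6", "t1"}  # |A∩B|=3, |A∪B|=6
        assert functional_similarity(a, b) == pytest.approx(0.5)

    def test_both_empty_defined_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert functional_similarity(set(), set()) == 0.0


class TestGMTIO:
    def test_round_trip(self, tmp_path):
        terms = {"T1": {"A", "B"}, "T2": {"C"}}
        path = tmp_path / "sets.gmt"
        write_gmt(terms, path)
        assert read_gmt(path) == terms

    def test_malformed_line_skipped(self, tmp_path, caplog):
        path = tmp_path / "bad.gmt"
        path.write_text("T1\tdesc\tA\tB\nnogenes\tdesc\n")
        with caplog.at_level("WARNING"):
            terms = read_gmt(path)
        assert set(terms) == {"T1"}
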