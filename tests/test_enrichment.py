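import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brewcgh.enrichment import (
    bh_adjust,
    complete_linkage,
    heatmap_export,
    hypergeometric_upper_tail,
    overrepresentation,
    read_annotations_tsv,
)
from brewcgh.profiles import AnnotationMap


def enumerate_upper_tail(k, K, n, N):
    """Exact P(X >= k) by enumerating all C(N, n) draws."""
    hits = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if sum(1 for i in draw if i < K) >= k
    )
    return hits / comb(N, n)


class TestHypergeometric:
    def test_k_zero_is_one(self):
        assert hypergeometric_upper_tail(0, 3, 5, 10) == 1.0

    def test_fully_enriched_draw(self):
        assert hypergeometric_upper_tail(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_small_hand_case(self):
        assert hypergeometric_upper_tail(1, 2, 2, 4) == pytest.approx(5 / 6)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(3, 2, 2, 4)
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(1, 5, 2, 4)

    def test_agrees_with_enumeration_small(self):
        for N, K, n in [(6, 3, 2), (8, 4, 5), (10, 5, 5)]:
            for k in range(n + 1):
                if k > K:
                    continue
                assert hypergeometric_upper_tail(k, K, n, N) == pytest.approx(
                    enumerate_upper_tail(k, K, n, N), abs=1e-12
                )


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_arithmetic_ladder_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_equal_ps_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_step_up_formula_and_dominates_p(self, ps):
        q = bh_adjust(ps)
        m = len(ps)
        order = np.argsort(ps, kind="stable")
        sorted_p = np.asarray(ps)[order]
        expected_sorted = np.minimum.accumulate(
            (m * sorted_p / np.arange(1, m + 1))[::-1]
        )[::-1]
        expected_sorted = np.clip(expected_sorted, 0, 1)
        np.testing.assert_allclose(np.asarray(q)[order], expected_sorted, atol=1e-12)
        assert (np.asarray(q) >= np.asarray(ps) - 1e-12).all()
        # q monotone non-decreasing along sorted p
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()


class TestOverrepresentation:
    def test_everything_selected_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        cat = AnnotationMap("c", "c", frozenset(universe))
        (res,) = overrepresentation(universe, [cat], universe)
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_category_excluded(self):
        universe = {f"g{i}" for i in range(10)}
        sel = {"g0", "g1"}
        cat = AnnotationMap("c", "c", frozenset({"g8", "g9"}))
        assert overrepresentation(sel, [cat], universe) == []

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation(set(), [], set())

    def test_fully_contained_family_has_smallest_p(self):
        universe = {f"g{i}" for i in range(200)}
        selected = {f"g{i}" for i in range(20)}
        fam = AnnotationMap("fam", "family", frozenset({f"g{i}" for i in range(6)}))
        partial = AnnotationMap(
            "mix", "mixed", frozenset({"g0", "g1", "g50", "g51", "g52", "g53"})
        )
        res = overrepresentation(selected, [fam, partial], universe)
        assert res[0].category_id == "fam"
        assert res[0].p_value < res[1].p_value
        assert res[0].k == 6 and res[0].K == 6

    def test_k_zero_excluded_from_bh_m(self):
        universe = {f"g{i}" for i in range(40)}
        sel = {"g0", "g1", "g2"}
        hit = AnnotationMap("hit", "hit", frozenset({"g0", "g1", "g2"}))
        miss = [
            AnnotationMap(f"m{i}", "m", frozenset({f"g{i + 20}"})) for i in range(10)
        ]
        (res,) = overrepresentation(sel, [hit] + miss, universe)
        # only one category tested -> q equals p (m = 1, not 11)
        assert res.q_value == pytest.approx(res.p_value)


class TestClusteringExports:
    def test_two_strains_merge_at_euclidean_distance(self, small_matrix):
        m = small_matrix.with_data(small_matrix.data[["A", "B"]])
        tree = complete_linkage(m, axis="strains")
        expected = np.linalg.norm(
            small_matrix.data["A"] - small_matrix.data["B"]
        )
        assert tree.height == pytest.approx(expected)

    def test_duplicate_strains_merge_at_zero(self, small_matrix):
        data = small_matrix.data.copy()
        data["B"] = data["A"]
        tree = complete_linkage(small_matrix.with_data(data), axis="strains")
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert inner.height == pytest.approx(0.0)

    def test_gene_axis_and_too_few_items(self, small_matrix):
        tree = complete_linkage(small_matrix, axis="genes")
        assert len(tree.leaves()) == 6
        with pytest.raises(ValueError):
            complete_linkage(
                small_matrix.with_data(small_matrix.data[["A"]]), axis="strains"
            )

    def test_heatmap_grouping_and_ordering(self, small_matrix):
        tree = complete_linkage(small_matrix, axis="strains")
        cats = [
            AnnotationMap("catB", "b", frozenset({"g2"})),
            AnnotationMap("catA", "a", frozenset({"g1", "g0"})),
        ]
        selected = {"g0", "g1", "g2", "g4"}
        heat = heatmap_export(small_matrix, selected, tree, cats)
        assert list(heat.columns[1:]) == list(tree.leaves())
        assert heat["category"].tolist() == ["catA", "catA", "catB", "unassigned"]
        assert heat.index.tolist() == ["g0", "g1", "g2", "g4"]
        # values untouched
        for g in ("g0", "g2"):
            for s in small_matrix.strain_ids:
                assert heat.loc[g, s] == small_matrix.data.loc[g, s]


def test_annotation_tsv_round_trip(tmp_path):
    from brewcgh.enrichment import annotations_to_frame

    cats = [
        AnnotationMap("c1", "first", frozenset({"g1", "g2"})),
        AnnotationMap("c2", "second", frozenset({"g3"})),
    ]
    path = tmp_path / "ann.tsv"
    annotations_to_frame(cats).to_csv(path, sep="\t", index=False)
    back = read_annotations_tsv(path)
    assert back == cats
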