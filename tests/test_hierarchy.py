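import itertools

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from brewcgh.hierarchy import (
    DendrogramNode,
    agglomerate,
    complete_linkage_tree,
    cophenetic_matrix,
    to_newick,
    upgma,
)


def sim_frame(labels, values):
    return pd.DataFrame(np.asarray(values, dtype=float), index=labels, columns=labels)


def random_similarity(n, rng):
    d = rng.uniform(0.05, 1.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return sim_frame([f"s{i}" for i in range(n)], 1.0 - d)


class TestUpgma:
    def test_two_strains_merge_at_half_distance(self):
        tree = upgma(sim_frame(["A", "B"], [[1, 0.4], [0.4, 1]]))
        assert tree.height == pytest.approx(0.3)
        assert to_newick(tree) == "(A:0.3,B:0.3);"

    def test_three_strain_hand_computation(self):
        # d(A,B)=0.2, d(A,C)=d(B,C)=0.6 -> A,B at height 0.1, root at 0.3
        sim = sim_frame(
            ["A", "B", "C"],
            [[1, 0.8, 0.4], [0.8, 1, 0.4], [0.4, 0.4, 1]],
        )
        tree = upgma(sim)
        assert tree.height == pytest.approx(0.3)
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert sorted(inner.leaves()) == ["A", "B"]
        assert inner.height == pytest.approx(0.1)

    def test_ultrametric_input_reproduced_exactly(self):
        # a nested ultrametric structure: ((A,B),(C,D)) with merge distances
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0.0, 0.2, 0.8, 0.8],
                [0.2, 0.0, 0.8, 0.8],
                [0.8, 0.8, 0.0, 0.4],
                [0.8, 0.8, 0.4, 0.0],
            ]
        )
        tree = upgma(sim_frame(labels, 1.0 - d))
        coph = cophenetic_matrix(tree)
        np.testing.assert_allclose(coph.loc[labels, labels].to_numpy(), d, atol=1e-12)

    def test_output_always_ultrametric(self):
        rng = np.random.default_rng(5)
        for n in (3, 5, 8):
            tree = upgma(random_similarity(n, rng))
            coph = cophenetic_matrix(tree)
            # every leaf's distance to the root equals the root height
            def depth(node, acc=0.0):
                if node.is_leaf:
                    return {node.label: acc}
                out = {}
                for c in node.children:
                    out |= depth(c, acc + (node.height - c.height))
                return out
            depths = depth(tree)
            assert np.allclose(list(depths.values()), tree.height, atol=1e-9)
            vals = coph.to_numpy()
            assert np.allclose(vals, vals.T)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        sim = random_similarity(6, rng)
        perm = list(reversed(sim.index))
        t1 = upgma(sim)
        t2 = upgma(sim.loc[perm, perm])
        assert to_newick(t1) == to_newick(t2)

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(3)
        sim = random_similarity(7, rng)
        tree = upgma(sim)
        dist = 1.0 - sim.to_numpy()
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        coph_ref = squareform(cophenet(Z))
        coph = cophenetic_matrix(tree).loc[sim.index, sim.index].to_numpy()
        np.testing.assert_allclose(coph, coph_ref, atol=1e-12)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            upgma(sim_frame(["A"], [[1.0]]))


class TestCompleteLinkage:
    def test_two_items_merge_at_full_distance(self):
        d = sim_frame(["A", "B"], [[0.0, 2.5], [2.5, 0.0]])
        tree = complete_linkage_tree(d)
        assert tree.height == pytest.approx(2.5)

    def test_closest_rows_merge_first(self):
        rows = {"a": (0, 0), "b": (0, 1), "c": (10, 10)}
        labels = list(rows)
        d = np.zeros((3, 3))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                d[i, j] = np.hypot(*(np.subtract(rows[x], rows[y])))
        tree = complete_linkage_tree(sim_frame(labels, d))
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert sorted(inner.leaves()) == ["a", "b"]
        assert inner.height == pytest.approx(1.0)

    def test_duplicate_rows_merge_at_height_zero(self):
        d = sim_frame(["A", "B", "C"], [[0, 0, 5], [0, 0, 5], [5, 5, 0]])
        tree = complete_linkage_tree(d)
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert inner.height == 0.0

    def test_matches_scipy_complete_linkage(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 4))
        from scipy.spatial.distance import pdist

        dv = pdist(pts)
        labels = [f"s{i}" for i in range(6)]
        tree = complete_linkage_tree(sim_frame(labels, squareform(dv)))
        Z = linkage(dv, method="complete")
        coph_ref = squareform(cophenet(Z))
        coph = cophenetic_matrix(tree).loc[labels, labels].to_numpy() / 2.0
        np.testing.assert_allclose(coph, coph_ref, atol=1e-12)


class TestNewick:
    def test_round_trip_preserves_topology_and_heights(self):
        rng = np.random.default_rng(21)
        for n in (2, 4, 7):
            tree = upgma(random_similarity(n, rng))
            parsed = skbio.TreeNode.read([to_newick(tree)])
            # topology: identical leaf partitions with identical LCA depths
            coph = cophenetic_matrix(tree)
            for a, b in itertools.combinations(sorted(tree.leaves()), 2):
                got = parsed.find(a).distance(parsed.find(b))
                assert got == pytest.approx(coph.loc[a, b], abs=1e-9)

    def test_labels_with_spaces_are_quoted(self):
        tree = upgma(sim_frame(["lager 1", "ale 2"], [[1, 0.5], [0.5, 1]]))
        nwk = to_newick(tree)
        assert "'lager 1'" in nwk and "'ale 2'" in nwk
        parsed = skbio.TreeNode.read([nwk])
        assert {t.name for t in parsed.tips()} == {"lager 1", "ale 2"}


def test_agglomerate_input_validation():
    bad = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["a", "b"], columns=["a", "b"])
    with pytest.raises(ValueError):
        agglomerate(bad)
    with pytest.raises(ValueError):
        agglomerate(
            pd.DataFrame([[0.0]], index=["a"], columns=["a"]), linkage="average"
        )
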