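"""Agglomerative clustering with deterministic tie-breaking, plus Newick IO.

One routine serves both trees the analysis needs: UPGMA (size-weighted
average linkage, ultrametric heights at half the merge distance) for the
karyotype dendrogram, and complete linkage (maximum pairwise distance,
heights at the full merge distance) for the strain/gene similarity trees.
Ties between equally distant pairs are broken by the lexicographically
smallest label pair, so trees are reproducible regardless of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DendrogramNode",
    "agglomerate",
    "upgma",
    "complete_linkage_tree",
    "to_newick",
    "cophenetic_matrix",
]


@dataclass
class DendrogramNode:
    """Binary tree node; ``height`` is the merge level (0 at leaves)."""

    height: float
    label: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None
    _leaves: tuple[str, ...] = field(default=(), repr=False)

    @staticmethod
    def leaf(label: str) -> "DendrogramNode":
        return DendrogramNode(height=0.0, label=label, _leaves=(label,))

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> tuple[str, ...]:
        """Leaf labels in left-to-right order."""
        if self.is_leaf:
            return (self.label,)
        if not self._leaves:
            self._leaves = self.children[0].leaves() + self.children[1].leaves()
        return self._leaves


def _validate_distance(dist: pd.DataFrame) -> None:
    vals = dist.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1] or list(dist.index) != list(dist.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(vals, vals.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(vals), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be 0")
    if (vals < -1e-12).any():
        raise ValueError("distances must be non-negative")


def agglomerate(
    dist: pd.DataFrame,
    linkage: str = "average",
    height: str = "half",
) -> DendrogramNode:
    """Agglomerative clustering of a labelled distance matrix.

    ``linkage`` is ``"average"`` (size-weighted UPGMA update) or
    ``"complete"`` (maximum); ``height`` is ``"half"`` (ultrametric branch
    heights, half the merge distance) or ``"full"``.
    """
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if height not in ("half", "full"):
        raise ValueError(f"unknown height convention {height!r}")
    _validate_distance(dist)
    labels = [str(x) for x in dist.index]
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")

    nodes: dict[str, DendrogramNode] = {l: DendrogramNode.leaf(l) for l in labels}
    sizes: dict[str, int] = {l: 1 for l in labels}
    # cluster key = lexicographically smallest member leaf label
    d: dict[frozenset[str], float] = {}
    active = sorted(labels)
    for i, a in enumerate(active):
        for b in active[i + 1:]:
            d[frozenset((a, b))] = float(dist.loc[a, b])

    while len(active) > 1:
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                cand = (d[frozenset((a, b))], a, b)
                if best is None or cand < best:
                    best = cand
        dist_ab, a, b = best
        merged = DendrogramNode(
            height=dist_ab / 2.0 if height == "half" else dist_ab,
            children=(nodes[a], nodes[b]),
        )
        key = min(a, b)
        other = max(a, b)
        for c in active:
            if c in (a, b):
                continue
            if linkage == "average":
                new_d = (
                    sizes[a] * d[frozenset((a, c))] + sizes[b] * d[frozenset((b, c))]
                ) / (sizes[a] + sizes[b])
            else:
                new_d = max(d[frozenset((a, c))], d[frozenset((b, c))])
            d[frozenset((key, c))] = new_d
        nodes[key] = merged
        sizes[key] = sizes[a] + sizes[b]
        active.remove(other)
        del nodes[other]
    return nodes[active[0]]


def upgma(similarity: pd.DataFrame) -> DendrogramNode:
    """UPGMA dendrogram from a similarity matrix (distance = 1 - similarity).

    Merge heights are half the merged pair distance, so the tree is
    ultrametric and leaf-to-leaf cophenetic distances live on the original
    distance scale.
    """
    vals = similarity.to_numpy(dtype=float)
    if ((vals < -1e-12) | (vals > 1 + 1e-12)).any():
        raise ValueError("similarities must lie in [0, 1]")
    if not np.allclose(np.diag(vals), 1.0, atol=1e-12):
        raise ValueError("similarity diagonal must be 1")
    dist = pd.DataFrame(1.0 - vals, index=similarity.index, columns=similarity.columns)
    np.fill_diagonal(dist.values, 0.0)
    return agglomerate(dist, linkage="average", height="half")


def complete_linkage_tree(dist: pd.DataFrame) -> DendrogramNode:
    """Complete-linkage tree; merge heights equal the merge distance."""
    return agglomerate(dist, linkage="complete", height="full")


def _format_label(label: str) -> str:
    if any(ch in label for ch in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_rec(node: DendrogramNode, parent_height: float) -> str:
    branch = parent_height - node.height
    if node.is_leaf:
        return f"{_format_label(node.label)}:{branch:.12g}"
    inner = ",".join(_newick_rec(c, node.height) for c in node.children)
    return f"({inner}):{branch:.12g}"


def to_newick(node: DendrogramNode) -> str:
    """Serialize to Newick with branch lengths; root branch omitted."""
    if node.is_leaf:
        return f"{_format_label(node.label)};"
    inner = ",".join(_newick_rec(c, node.height) for c in node.children)
    return f"({inner});"


def cophenetic_matrix(node: DendrogramNode) -> pd.DataFrame:
    """Pairwise cophenetic distance: 2 x (or 1 x, for full-height trees)
    the height of the lowest common ancestor.

    For half-height (ultrametric UPGMA) trees the factor 2 restores the
    original distance scale; callers using full-height trees should halve.
    """
    labels = sorted(node.leaves())
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n))

    def visit(nd: DendrogramNode) -> tuple[str, ...]:
        if nd.is_leaf:
            return (nd.label,)
        left = visit(nd.children[0])
        right = visit(nd.children[1])
        for a in left:
            for b in right:
                out[idx[a], idx[b]] = out[idx[b], idx[a]] = 2.0 * nd.height
        return left + right

    visit(node)
    return pd.DataFrame(out, index=labels, columns=labels)
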