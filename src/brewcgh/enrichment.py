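"""Hypergeometric over-representation with BH FDR, and similarity clustering.

Divergent genes are tested category by category: does a functional category
contain more of the selected genes than drawing the same number of genes at
random from the array universe would give? P-values are upper-tail
hypergeometric, corrected by the Benjamini-Hochberg step-up procedure;
categories with no selected member are excluded before testing (they cannot
be over-represented and would only dilute the correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .hierarchy import DendrogramNode, complete_linkage_tree
from .normalize import Log2Matrix
from .profiles import AnnotationMap

__all__ = [
    "EnrichmentResult",
    "hypergeometric_upper_tail",
    "bh_adjust",
    "overrepresentation",
    "complete_linkage",
    "heatmap_export",
]


@dataclass(frozen=True)
class EnrichmentResult:
    category_id: str
    category_name: str
    k: int  # selected genes in category
    K: int  # category size within universe
    n: int  # selected gene count
    N: int  # universe size
    p_value: float
    q_value: float
    significant: bool


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The probability that a uniform draw of ``n`` genes from a universe of
    ``N`` (of which ``K`` belong to the category) contains at least ``k``
    category members. Computed via the log-space survival function.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overrepresentation(
    selected: set[str],
    annotations: list[AnnotationMap],
    universe: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-category hypergeometric over-representation of the selected genes.

    Categories are intersected with the universe first; categories with no
    selected member (k = 0) are dropped before BH correction. Results are
    sorted by q then p then category_id.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    N = len(universe)
    n = len(selected)
    rows = []
    for cat in annotations:
        members = set(cat.gene_ids) & universe
        k = len(members & selected)
        if k == 0:
            continue
        p = hypergeometric_upper_tail(k, len(members), n, N)
        rows.append((cat, k, len(members), p))
    if not rows:
        return []
    q = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(
            category_id=cat.category_id,
            category_name=cat.category_name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            q_value=float(qv),
            significant=bool(qv <= alpha),
        )
        for (cat, k, K, p), qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.category_id))
    return results


def complete_linkage(matrix: Log2Matrix, axis: str = "strains") -> DendrogramNode:
    """Complete-linkage Euclidean clustering of strains or genes."""
    if axis == "strains":
        table = matrix.data.T
    elif axis == "genes":
        table = matrix.data
    else:
        raise ValueError("axis must be 'strains' or 'genes'")
    if table.shape[0] < 2:
        raise ValueError(f"need >= 2 {axis} to cluster")
    labels = [str(i) for i in table.index]
    dist = squareform(pdist(table.to_numpy(dtype=float), metric="euclidean"))
    return complete_linkage_tree(pd.DataFrame(dist, index=labels, columns=labels))


def heatmap_export(
    matrix: Log2Matrix,
    selected: set[str],
    strain_tree: DendrogramNode,
    annotations: list[AnnotationMap],
) -> pd.DataFrame:
    """Heat-map-ready table: strain columns in tree leaf order, gene rows
    grouped by functional category then chromosome position.

    Genes in several categories appear once per category (category is a row
    group key, mirroring function-grouped heat maps); values are the
    untouched log2 ratios. Selected genes in no category are appended under
    ``unassigned``.
    """
    if not selected:
        raise ValueError("selected gene set must be non-empty")
    strain_order = [s for s in strain_tree.leaves()]
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    rows: list[tuple[str, str]] = []
    assigned: set[str] = set()
    for cat in sorted(annotations, key=lambda c: c.category_id):
        members = sorted(
            (g for g in cat.gene_ids if g in selected), key=lambda g: pos[g]
        )
        rows += [(cat.category_id, g) for g in members]
        assigned |= set(members)
    rows += [
        ("unassigned", g)
        for g in sorted(selected - assigned, key=lambda g: pos[g])
    ]
    out = matrix.data.loc[[g for _, g in rows], strain_order].copy()
    out.insert(0, "category", [c for c, _ in rows])
    return out


def read_annotations_tsv(path) -> list[AnnotationMap]:
    """Read a two-column (category_id, gene_id) TSV, optional category_name."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"category_id", "gene_id"} <= set(df.columns):
        raise ValueError("annotation TSV needs category_id and gene_id columns")
    out = []
    for cid, grp in df.groupby("category_id", sort=True):
        name = (
            str(grp["category_name"].iloc[0])
            if "category_name" in grp.columns
            else str(cid)
        )
        out.append(AnnotationMap(str(cid), name, frozenset(grp["gene_id"].astype(str))))
    return out


def annotations_to_frame(annotations: list[AnnotationMap]) -> pd.DataFrame:
    rows = [
        (a.category_id, a.category_name, g)
        for a in annotations
        for g in sorted(a.gene_ids)
    ]
    return pd.DataFrame(rows, columns=["category_id", "category_name", "gene_id"])
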