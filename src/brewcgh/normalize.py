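"""Two-channel intensity normalization and cohort re-referencing.

The chain: per-gene log2(test/reference) with an intensity floor, optional
within-array centering (median by default), then *re-referencing*: each
strain's profile is expressed relative to the average of all strains in the
panel. Re-referencing suppresses probe-level noise shared across strains
(sequence divergence from the laboratory reference hits every hybridization
the same way) and turns each profile into deviation-from-cohort-mean, which
is the space in which aneuploidies are called.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import chromosome_rank

__all__ = [
    "Log2Matrix",
    "log2_ratio",
    "median_center",
    "rereference_to_average",
    "build_log2_matrix",
    "default_floor",
    "read_log2_matrix_tsv",
]

_META_COLS = ["chromosome", "start", "end", "subtelomeric"]


@dataclass
class Log2Matrix:
    """Genes × strains matrix of log2 ratios with chromosome-ordered metadata.

    ``data`` is indexed by gene_id (rows, in chromosome-then-position order)
    with one column per strain; ``genes`` carries chromosome, start, end and
    the subtelomeric flag, aligned to ``data``'s index.
    """

    data: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.genes.index):
            raise ValueError("data and genes must share one gene index")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("log2 matrix must be finite (apply an intensity floor)")
        ranks = self.genes["chromosome"].map(chromosome_rank)
        order = np.lexsort((self.genes["start"].to_numpy(), ranks.to_numpy()))
        if not (order == np.arange(len(order))).all():
            raise ValueError("genes must be ordered by (chromosome, start)")

    @property
    def strain_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    def with_data(self, data: pd.DataFrame) -> "Log2Matrix":
        return Log2Matrix(data=data, genes=self.genes)

    def chromosome_track(self, strain_id: str, chromosome: str) -> pd.Series:
        mask = self.genes["chromosome"] == chromosome
        return self.data.loc[mask, strain_id]


def log2_ratio(
    test_intensity, reference_intensity, floor: float
) -> np.ndarray | float:
    """log2(max(test, floor) / max(reference, floor)); floor keeps ratios finite."""
    if floor <= 0:
        raise ValueError("floor must be > 0")
    t = np.maximum(np.asarray(test_intensity, dtype=float), floor)
    r = np.maximum(np.asarray(reference_intensity, dtype=float), floor)
    out = np.log2(t / r)
    return float(out) if out.ndim == 0 else out


def default_floor(reference_intensity) -> float:
    """Default intensity floor: 1% of the median reference-channel intensity."""
    med = float(np.median(np.asarray(reference_intensity, dtype=float)))
    if med <= 0:
        raise ValueError("median reference intensity must be > 0")
    return 0.01 * med


def median_center(row: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Subtract the median; output median is 0."""
    arr = np.asarray(row, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot center an empty row")
    centered = arr - np.median(arr)
    if isinstance(row, pd.Series):
        return pd.Series(centered, index=row.index, name=row.name)
    return centered


def rereference_to_average(matrix: Log2Matrix) -> Log2Matrix:
    """Express every strain relative to the across-strain average per gene.

    After this step a gene's values sum to zero across strains, so a copy
    change private to one strain necessarily shows with opposite sign in
    the others — the price of not having a trusted external reference.
    Idempotent; requires at least two strains.
    """
    if matrix.data.shape[1] < 2:
        raise ValueError(
            "re-referencing needs >= 2 strains (the average of one strain "
            "would zero its own profile)"
        )
    centered = matrix.data.sub(matrix.data.mean(axis=1), axis=0)
    return matrix.with_data(centered)


def build_log2_matrix(
    intensities: dict[str, pd.DataFrame],
    gene_metadata: pd.DataFrame,
    floor: float | None = None,
    center: str = "median",
) -> Log2Matrix:
    """Assemble a Log2Matrix from per-strain two-channel intensity tables.

    Parameters
    ----------
    intensities
        strain_id → DataFrame indexed by gene_id with ``test`` and
        ``reference`` columns.
    gene_metadata
        chromosome/start/end/subtelomeric per gene_id (any row order; the
        output is sorted into chromosome-then-position order).
    floor
        Intensity floor; per strain, defaults to 1% of that array's median
        reference intensity.
    center
        Within-array centering: ``"median"`` (default), ``"mean"`` or
        ``"off"``.
    """
    if center not in ("median", "mean", "off"):
        raise ValueError(f"unknown centering {center!r}")
    ranks = gene_metadata["chromosome"].map(chromosome_rank)
    order = np.lexsort((gene_metadata["start"].to_numpy(), ranks.to_numpy()))
    meta = gene_metadata.iloc[order]
    cols = {}
    for strain_id, df in intensities.items():
        df = df.reindex(meta.index)
        if df[["test", "reference"]].isna().any().any():
            raise ValueError(f"strain {strain_id}: missing intensities for some genes")
        f = floor if floor is not None else default_floor(df["reference"])
        ratios = log2_ratio(df["test"].to_numpy(), df["reference"].to_numpy(), f)
        if center == "median":
            ratios = ratios - np.median(ratios)
        elif center == "mean":
            ratios = ratios - np.mean(ratios)
        cols[strain_id] = ratios
    data = pd.DataFrame(cols, index=meta.index)
    return Log2Matrix(data=data, genes=meta)


def read_log2_matrix_tsv(path) -> Log2Matrix:
    """Read a Log2Matrix TSV (metadata columns first, then strain columns)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"log2 matrix TSV missing metadata columns {missing}")
    genes = df[_META_COLS].copy()
    genes["subtelomeric"] = genes["subtelomeric"].astype(bool)
    data = df.drop(columns=_META_COLS).astype(float)
    return Log2Matrix(data=data, genes=genes)
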