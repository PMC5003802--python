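"""Piecewise-constant segmentation and copy-number divergence tracks.

Aneuploidies and segmental gains/losses appear in a log2 profile as level
shifts. ``segment_track`` fits the exact least-squares piecewise-constant
model by dynamic programming: it minimizes the sum of squared residuals to
segment means plus a per-breakpoint penalty, with ties resolved toward
fewer segments. The divergence side (per-gene SD across strains, smoothed
by a within-chromosome moving average) locates the genome regions — mostly
subtelomeric — where strains differ most in gene dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .normalize import Log2Matrix

__all__ = [
    "Segment",
    "SegmentSet",
    "segment_track",
    "default_penalty",
    "call_segments",
    "segment_matrix",
    "gene_sd",
    "moving_average",
    "divergence_track",
    "select_divergent_genes",
]

#: Default gain/loss call thresholds in log2 units; ±0.3 sits below the
#: weakest single-copy event in a tetraploid (|log2(3/4)| ≈ 0.415) while
#: staying well above re-referencing side-effects of such events
#: (0.415/4 ≈ 0.10 with four strains).
GAIN_THRESHOLD = 0.3
LOSS_THRESHOLD = -0.3


@dataclass(frozen=True)
class Segment:
    """Half-open-free gene-index run [first, last] with its fitted mean."""

    first: int
    last: int
    mean: float
    call: str = "neutral"


@dataclass
class SegmentSet:
    strain_id: str
    chromosome: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_last = -1
        for seg in self.segments:
            if seg.first != prev_last + 1 or seg.last < seg.first:
                raise ValueError("segments must partition indices without gaps")
            prev_last = seg.last

    @property
    def n_breakpoints(self) -> int:
        return len(self.segments) - 1

    def gene_calls(self) -> np.ndarray:
        """Per-gene call labels expanded from segments."""
        n = self.segments[-1].last + 1
        out = np.empty(n, dtype=object)
        for seg in self.segments:
            out[seg.first : seg.last + 1] = seg.call
        return out


def segment_track(
    values, penalty: float, strain_id: str = "", chromosome: str = ""
) -> SegmentSet:
    """Exact penalized least-squares segmentation of one ordered track.

    Minimizes ``sum of squared residuals + penalty * (number of
    breakpoints)`` over all segmentations, by O(n^2) dynamic programming
    on prefix sums. Among cost-equal solutions the one with fewer segments
    wins (compared with a 1e-9 relative tolerance).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot segment an empty track")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    n = x.size
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: int, j: int) -> float:
        # residual sum of squares of x[i..j] around its mean (0-based incl.)
        tot = s1[j + 1] - s1[i]
        return max(0.0, (s2[j + 1] - s2[i]) - tot * tot / (j - i + 1))

    INF = float("inf")
    cost = np.full(n + 1, INF)
    nseg = np.zeros(n + 1, dtype=int)
    back = np.zeros(n + 1, dtype=int)
    cost[0] = -penalty  # first segment carries no breakpoint penalty
    nseg[0] = 0
    for j in range(1, n + 1):
        for i in range(j):
            c = cost[i] + sse(i, j - 1) + penalty
            k = nseg[i] + 1
            if cost[j] == INF:
                better = True
            else:
                tol = 1e-9 * (1.0 + abs(cost[j]))
                better = c < cost[j] - tol or (
                    abs(c - cost[j]) <= tol and k < nseg[j]
                )
            if better:
                cost[j], nseg[j], back[j] = c, k, i
    bounds = []
    j = n
    while j > 0:
        i = back[j]
        bounds.append((i, j - 1))
        j = i
    segments = [
        Segment(first=i, last=j, mean=float((s1[j + 1] - s1[i]) / (j - i + 1)))
        for i, j in reversed(bounds)
    ]
    return SegmentSet(strain_id=strain_id, chromosome=chromosome, segments=segments)


def default_penalty(values) -> float:
    """BIC-style default: 2 * sigma^2 * log(n).

    sigma is estimated robustly from the median absolute successive
    difference (scaled by sqrt(2) * 0.6745, the Gaussian consistency
    factor), so level shifts themselves barely inflate it.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return 0.0
    mad_diff = float(np.median(np.abs(np.diff(x))))
    sigma = mad_diff / (np.sqrt(2.0) * 0.6745)
    return 2.0 * sigma**2 * np.log(x.size)


def call_segments(
    segset: SegmentSet,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
) -> SegmentSet:
    """Label each segment gain/neutral/loss by its mean against thresholds."""
    if not (loss_threshold < 0 < gain_threshold):
        raise ValueError("need loss_threshold < 0 < gain_threshold")
    called = [
        replace(
            seg,
            call=(
                "gain"
                if seg.mean >= gain_threshold
                else "loss" if seg.mean <= loss_threshold else "neutral"
            ),
        )
        for seg in segset.segments
    ]
    return SegmentSet(segset.strain_id, segset.chromosome, called)


def segment_matrix(
    matrix: Log2Matrix,
    penalty: float | None = None,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
) -> dict[tuple[str, str], SegmentSet]:
    """Segment and call every strain-chromosome track of a Log2Matrix.

    ``penalty=None`` applies the per-track BIC-style default.
    """
    out: dict[tuple[str, str], SegmentSet] = {}
    chroms = matrix.genes["chromosome"].unique()
    for strain in matrix.strain_ids:
        for chrom in chroms:
            track = matrix.chromosome_track(strain, chrom).to_numpy()
            pen = default_penalty(track) if penalty is None else penalty
            segset = segment_track(track, pen, strain_id=strain, chromosome=chrom)
            out[(strain, chrom)] = call_segments(segset, gain_threshold, loss_threshold)
    return out


def gene_sd(matrix: Log2Matrix) -> pd.Series:
    """Per-gene sample standard deviation (n-1 denominator) across strains."""
    if matrix.data.shape[1] < 2:
        raise ValueError("gene SD needs >= 2 strains")
    return matrix.data.std(axis=1, ddof=1)


def moving_average(track: pd.Series | np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated edges; window must be odd."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    x = np.asarray(track, dtype=float)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def divergence_track(matrix: Log2Matrix, window: int = 25) -> pd.DataFrame:
    """SD divergence track with within-chromosome moving-average smoothing.

    Returns a DataFrame aligned to the matrix's gene order with columns
    chromosome, start, subtelomeric, sd and smoothed. Smoothing never
    crosses a chromosome boundary.
    """
    sd = gene_sd(matrix)
    smoothed = np.empty(len(sd))
    for chrom in matrix.genes["chromosome"].unique():
        mask = (matrix.genes["chromosome"] == chrom).to_numpy()
        smoothed[mask] = moving_average(sd.to_numpy()[mask], window)
    return pd.DataFrame(
        {
            "chromosome": matrix.genes["chromosome"],
            "start": matrix.genes["start"],
            "subtelomeric": matrix.genes["subtelomeric"],
            "sd": sd,
            "smoothed": smoothed,
        },
        index=sd.index,
    )


def select_divergent_genes(matrix: Log2Matrix, threshold: float = 2.0) -> set[str]:
    """Genes whose |log2 ratio| strictly exceeds the threshold in any strain.

    The strict inequality means a value of exactly ±threshold is *not*
    selected.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    mask = (matrix.data > threshold) | (matrix.data < -threshold)
    return set(matrix.data.index[mask.any(axis=1)])
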