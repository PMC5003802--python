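"""Karyotype similarity from electrophoretic band profiles.

Bands from different lanes that agree in size within a relative tolerance
are treated as the same chromosome band; strains are then compared by the
Jaccard coefficient on their shared band universe, and clustered with UPGMA
(see :mod:`brewcgh.hierarchy`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import BandProfile

__all__ = ["binarize_bands", "jaccard", "similarity_matrix", "band_profiles_from_tsv"]


def binarize_bands(
    profiles: list[BandProfile], size_tolerance: float = 0.015
) -> pd.DataFrame:
    """Presence/absence matrix (strains × band bins) over a shared bin universe.

    Bins are formed by single-linkage grouping of all observed band sizes:
    after sorting, consecutive sizes whose relative gap (to the smaller
    size) is <= ``size_tolerance`` join the same bin. This mirrors how bands
    are matched by eye across PFGE lanes; the tolerance is a free parameter.
    """
    if size_tolerance < 0:
        raise ValueError("size_tolerance must be >= 0")
    if not profiles:
        raise ValueError("need at least one band profile")
    sizes = sorted({s for p in profiles for s in p.band_sizes})
    if not sizes:
        raise ValueError("no bands in any profile")
    # single-linkage chaining along the sorted size axis
    bin_of: dict[float, int] = {sizes[0]: 0}
    n_bins = 1
    for prev, cur in zip(sizes, sizes[1:]):
        if (cur - prev) / prev > size_tolerance:
            n_bins += 1
        bin_of[cur] = n_bins - 1
    mat = np.zeros((len(profiles), n_bins), dtype=bool)
    for i, p in enumerate(profiles):
        for s in p.band_sizes:
            mat[i, bin_of[s]] = True
    centers = [
        float(np.mean([s for s in sizes if bin_of[s] == b])) for b in range(n_bins)
    ]
    return pd.DataFrame(
        mat,
        index=pd.Index([p.strain_id for p in profiles], name="strain_id"),
        columns=[f"band_{c:.1f}kb" for c in centers],
    )


def jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|; undefined (raises) when both sets are empty."""
    union = a | b
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def similarity_matrix(presence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard similarity between strains from a presence matrix."""
    strains = list(presence.index)
    sets = {s: set(presence.columns[presence.loc[s]]) for s in strains}
    n = len(strains)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = jaccard(sets[strains[i]], sets[strains[j]])
    return pd.DataFrame(vals, index=strains, columns=strains)


def band_profiles_from_tsv(path) -> list[BandProfile]:
    """Read a band TSV with columns strain_id, band_kb (one band per row)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        BandProfile(str(sid), tuple(sorted(grp["band_kb"].astype(float), reverse=True)))
        for sid, grp in df.groupby("strain_id", sort=True)
    ]
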