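"""Efficiency-corrected qPCR quantification and cross-platform validation.

Relative transcript levels are computed in the Pfaffl form — each amplicon's
measured amplification efficiency raised to its CT difference from the
reference strain, target over housekeeping gene — rather than 2^-ddCT,
because measured efficiencies below 2 (typically 1.9-2.0) bias the
power-of-two shortcut. To compare qPCR levels with array-CGH log2 profiles
(which are expressed relative to the strain-panel average), qPCR values are
divided by their per-gene across-strain average and log2-transformed, after
which the two platforms share a scale and a Pearson correlation is
meaningful.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .simulate import BACKGROUND_FRACTION, QpcrMeasurement

__all__ = [
    "efficiency_corrected_level",
    "relative_level_table",
    "normalize_per_gene_average",
    "platform_correlation",
    "load_qpcr_panel",
    "synthetic_matched_acgh_log2",
]

#: Floor for zero relative levels before log transformation; matches the
#: magnitude of the smallest reliably reportable qPCR level (~1e-4).
LEVEL_EPSILON = 1e-4


def efficiency_corrected_level(
    m: QpcrMeasurement, reference_strain_m: QpcrMeasurement
) -> float:
    """Pfaffl ratio of one sample measurement to the reference strain's.

    level = E_target^(dCT_target) / E_ref^(dCT_refgene), with each dCT
    taken as (reference strain CT - sample CT). The reference strain's own
    level is 1 by construction.
    """
    if m.efficiency_target <= 1 or m.efficiency_reference <= 1:
        raise ValueError("efficiencies must be > 1")
    if m.ct_target <= 0 or m.ct_reference_gene <= 0:
        raise ValueError("CT values must be positive")
    d_target = reference_strain_m.ct_target - m.ct_target
    d_ref = reference_strain_m.ct_reference_gene - m.ct_reference_gene
    return float(
        m.efficiency_target**d_target / m.efficiency_reference**d_ref
    )


def relative_level_table(
    measurements: list[QpcrMeasurement],
    reference_measurements: list[QpcrMeasurement],
) -> pd.DataFrame:
    """Strains × genes table of efficiency-corrected relative levels."""
    ref_by_gene = {m.gene_id: m for m in reference_measurements}
    records: dict[str, dict[str, float]] = {}
    for m in measurements:
        if m.gene_id not in ref_by_gene:
            raise ValueError(f"no reference-strain measurement for {m.gene_id}")
        records.setdefault(m.strain_id, {})[m.gene_id] = efficiency_corrected_level(
            m, ref_by_gene[m.gene_id]
        )
    table = pd.DataFrame.from_dict(records, orient="index").sort_index()
    table.index.name = "strain"
    return table


def normalize_per_gene_average(
    table: pd.DataFrame, epsilon: float = LEVEL_EPSILON
) -> pd.DataFrame:
    """Divide each gene's values by their across-strain mean, then log2.

    Zero levels are floored at ``epsilon`` before division; a gene that is
    zero in every strain has no meaningful average and raises.
    """
    if (table < 0).any().any():
        raise ValueError("relative levels must be >= 0")
    floored = table.clip(lower=epsilon)
    if (table.max(axis=0) <= 0).any():
        raise ValueError("gene with all-zero levels cannot be normalized")
    means = floored.mean(axis=0)
    return np.log2(floored / means)


def platform_correlation(
    qpcr_log2: pd.DataFrame, acgh_log2: pd.DataFrame
) -> float:
    """Pearson r between matched (strain, gene) log2 values of both platforms."""
    common_strains = qpcr_log2.index.intersection(acgh_log2.index)
    common_genes = qpcr_log2.columns.intersection(acgh_log2.columns)
    x = qpcr_log2.loc[common_strains, common_genes].to_numpy(dtype=float).ravel()
    y = acgh_log2.loc[common_strains, common_genes].to_numpy(dtype=float).ravel()
    if x.size < 3:
        raise ValueError("need >= 3 matched (strain, gene) pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(pearsonr(x, y)[0])


def load_qpcr_panel() -> pd.DataFrame:
    """Packaged qRT-PCR relative-level table (strains × genes).

    Four dosage-variable genes (FIT3, MAL13, AAD10, ALD2) measured in four
    brewing strains, already normalized to the ALG9 housekeeping gene and
    to the laboratory reference strain.
    """
    path = resources.files("brewcgh.data") / "qpcr_validation_levels.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    table = df.pivot(index="strain", columns="gene", values="level")
    table.index = table.index.astype(str)
    return table[["FIT3", "MAL13", "AAD10", "ALD2"]]


def synthetic_matched_acgh_log2(
    qpcr_levels: pd.DataFrame,
    absent_below: float = 1e-3,
    background_fraction: float = BACKGROUND_FRACTION,
) -> pd.DataFrame:
    """Synthetic stand-in for matched array-CGH log2 values.

    The real matched array values for the qPCR panel are not available as
    numbers, so this constructs the array-side log2 matrix the noiseless
    pipeline would produce from the copy-number states the qPCR table
    itself implies: a gene is called absent in a strain when its relative
    level falls below ``absent_below`` (non-detect regime) and present at
    the baseline dosage otherwise. Absent genes read at the background
    fraction of the diploid signal; profiles are then re-referenced to the
    per-gene strain average, exactly as the array pipeline does.

    Being synthetic, this table supports method demonstrations and
    structural tests, not reproduction of the originally reported
    correlation.
    """
    absent = qpcr_levels < absent_below
    raw = pd.DataFrame(
        np.where(absent, np.log2(background_fraction), 0.0),
        index=qpcr_levels.index,
        columns=qpcr_levels.columns,
    )
    return raw.sub(raw.mean(axis=0), axis=1)
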