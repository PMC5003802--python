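"""Forward simulators: two-channel probe intensities, PFGE band profiles and
qPCR crossing thresholds, all driven by :class:`~brewcgh.profiles.StrainProfile`
truth objects.

The intensity model is multiplicative: a probe's signal is proportional to
the gene's copy-equivalent level times a log-normal noise factor (Gaussian
on the log2 scale). Genes absent from a genome still yield a small positive
background signal (a configured fraction of the diploid signal), so log
ratios stay finite while preserving the "log2 below -2 means absent"
signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import GeneFeature, chromosome_length_bp, chromosome_rank
from .profiles import StrainProfile, effective_copy_signal

__all__ = [
    "QpcrMeasurement",
    "BandProfile",
    "simulate_two_channel",
    "simulate_band_profile",
    "simulate_qpcr",
    "expected_log2_ratios",
    "expected_log2_matrix",
]

#: Arbitrary fluorescence units for one haploid copy equivalent.
UNIT_SIGNAL = 1000.0
#: Background signal for absent genes, as a fraction of the diploid signal.
BACKGROUND_FRACTION = 0.01
#: Crossing threshold reported for non-detects (absent transcripts).
NONDETECT_CT = 38.0


@dataclass(frozen=True)
class BandProfile:
    """Electrophoretic karyotype: the multiset of band sizes (kb) in one lane."""

    strain_id: str
    band_sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.band_sizes):
            raise ValueError("band sizes must be positive")


@dataclass(frozen=True)
class QpcrMeasurement:
    strain_id: str
    gene_id: str
    ct_target: float
    ct_reference_gene: float
    efficiency_target: float
    efficiency_reference: float

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency_target <= 2.0):
            raise ValueError("efficiency_target must be in (1, 2]")
        if not (1.0 < self.efficiency_reference <= 2.0):
            raise ValueError("efficiency_reference must be in (1, 2]")


def _signal(copy_level: float, background_fraction: float) -> float:
    if copy_level > 0:
        return UNIT_SIGNAL * copy_level
    return UNIT_SIGNAL * 2.0 * background_fraction


def simulate_two_channel(
    copy_numbers: pd.Series,
    reference_copy_numbers: pd.Series,
    noise_sd: float,
    seed: int,
    background_fraction: float = BACKGROUND_FRACTION,
) -> pd.DataFrame:
    """Simulate co-hybridized test/reference intensities per gene.

    Returns a DataFrame indexed by gene_id with columns ``test`` and
    ``reference``. The expected log2(test/reference) equals
    log2(copy/ref copy) plus per-probe Gaussian noise of sd ``noise_sd``
    (placed on the test channel; only the ratio is analyzed downstream).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if (reference_copy_numbers <= 0).any():
        raise ValueError("reference copy numbers must all be > 0")
    copy_numbers, reference_copy_numbers = copy_numbers.align(
        reference_copy_numbers, join="inner"
    )
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd, size=len(copy_numbers)) if noise_sd > 0 else 0.0
    test = np.array(
        [_signal(c, background_fraction) for c in copy_numbers.to_numpy()]
    ) * np.exp2(eps)
    ref = np.array(
        [_signal(c, background_fraction) for c in reference_copy_numbers.to_numpy()]
    )
    return pd.DataFrame(
        {"test": test, "reference": ref},
        index=copy_numbers.index.rename("gene_id"),
    )


def simulate_band_profile(
    profile: StrainProfile,
    catalog: list[GeneFeature],
    size_polymorphism: float,
    seed: int,
) -> BandProfile:
    """PFGE lane: one band per retained nuclear chromosome.

    A whole-chromosome loss (copy number 0) removes its band. Band sizes are
    jittered by up to ``size_polymorphism`` (relative, uniform) to emulate
    length polymorphism between strains. Lager-like hybrid strains carry one
    extra band between the chromosome IV and VII sizes. The mitochondrial
    genome does not band on these gels.
    """
    if not (0 <= size_polymorphism < 1):
        raise ValueError("size_polymorphism must be in [0, 1)")
    rng = np.random.default_rng(seed)
    chroms = sorted(
        {g.chromosome for g in catalog} - {"Mt"}, key=chromosome_rank
    )
    bands: list[float] = []
    for c in chroms:
        copies = profile.base_ploidy + profile.chromosome_ploidy.get(c, 0)
        if copies <= 0:
            continue
        size_kb = chromosome_length_bp(c) / 1000.0
        jitter = rng.uniform(-size_polymorphism, size_polymorphism)
        bands.append(size_kb * (1.0 + jitter))
    if profile.lager_like:
        kb4 = chromosome_length_bp("IV") / 1000.0
        kb7 = chromosome_length_bp("VII") / 1000.0
        lo, hi = sorted((kb4, kb7))
        bands.append(float(rng.uniform(lo * 1.05, hi * 0.95)))
    return BandProfile(profile.strain_id, tuple(sorted(bands, reverse=True)))


def simulate_qpcr(
    copy_numbers: pd.Series,
    reference_strain_copy_numbers: pd.Series,
    genes: list[str],
    strain_id: str,
    seed: int,
    ct_noise_sd: float = 0.0,
    efficiency_target: float = 2.0,
    efficiency_reference: float = 2.0,
    base_ct_target: float = 24.0,
    base_ct_reference_gene: float = 20.0,
    nondetect_ct: float = NONDETECT_CT,
) -> list[QpcrMeasurement]:
    """Generate crossing thresholds coupled to copy number.

    Transcript abundance is modelled as proportional to gene copy number
    (dosage coupling). CTs are obtained by inverting the efficiency-based
    quantification model: one copy-ratio doubling advances the target CT by
    one cycle at efficiency 2. The housekeeping reference gene is assumed
    dosage-stable, so its CT is constant across strains up to noise.
    Zero-copy genes report the non-detect CT.
    """
    if not (1.0 < efficiency_target <= 2.0 and 1.0 < efficiency_reference <= 2.0):
        raise ValueError("efficiencies must be in (1, 2]")
    rng = np.random.default_rng(seed)
    out = []
    for gene in genes:
        c = float(copy_numbers[gene])
        r = float(reference_strain_copy_numbers[gene])
        if r <= 0:
            raise ValueError(f"reference strain has zero copies of {gene}")
        if c <= 0:
            ct_t = nondetect_ct
        else:
            ratio = c / r
            ct_t = base_ct_target - np.log(ratio) / np.log(efficiency_target)
        noise_t = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
        noise_r = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
        out.append(
            QpcrMeasurement(
                strain_id=strain_id,
                gene_id=gene,
                ct_target=float(ct_t + noise_t),
                ct_reference_gene=float(base_ct_reference_gene + noise_r),
                efficiency_target=efficiency_target,
                efficiency_reference=efficiency_reference,
            )
        )
    return out


def expected_log2_ratios(
    profile: StrainProfile,
    reference_profile: StrainProfile,
    catalog: list[GeneFeature],
    background_fraction: float = BACKGROUND_FRACTION,
) -> pd.Series:
    """Noiseless expected log2(test/reference) per gene, before normalization."""
    c = effective_copy_signal(profile, catalog)
    r = effective_copy_signal(reference_profile, catalog)
    sig_c = np.array([_signal(v, background_fraction) for v in c.to_numpy()])
    sig_r = np.array([_signal(v, background_fraction) for v in r.to_numpy()])
    return pd.Series(np.log2(sig_c / sig_r), index=c.index, name=profile.strain_id)


def expected_log2_matrix(
    profiles: list[StrainProfile],
    reference_profile: StrainProfile,
    catalog: list[GeneFeature],
    background_fraction: float = BACKGROUND_FRACTION,
) -> pd.DataFrame:
    """Analytic truth for the full normalization chain (genes × strains).

    Median-centers each strain's noiseless log2 ratios and subtracts the
    per-gene across-strain mean — the same chain the analysis applies to
    simulated intensities — without ever touching the intensity simulator,
    so it can serve as an independent expectation in round-trip checks.
    """
    cols = {
        p.strain_id: expected_log2_ratios(
            p, reference_profile, catalog, background_fraction
        )
        for p in profiles
    }
    df = pd.DataFrame(cols)
    df = df - df.median(axis=0)
    return df.sub(df.mean(axis=1), axis=0)
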