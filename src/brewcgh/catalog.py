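"""Synthetic yeast gene catalog.

The catalog emulates the layout of a *Saccharomyces cerevisiae* expression
array: sixteen nuclear chromosomes (labelled with roman numerals I..XVI,
with realistic, unequal lengths) plus one mitochondrial chromosome ``Mt``.
Genes are laid out non-overlapping along each chromosome and flagged as
subtelomeric when they fall within a configurable distance of either
chromosome end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneFeature",
    "CHROMOSOME_NAMES",
    "chromosome_rank",
    "build_gene_catalog",
    "catalog_to_frame",
    "write_catalog_tsv",
    "read_catalog_tsv",
]

_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
]

#: Nuclear chromosome labels in karyotype order, followed by the
#: mitochondrial chromosome.
CHROMOSOME_NAMES = _ROMAN + ["Mt"]

# Approximate S. cerevisiae chromosome sizes in kb (S288C), used to give the
# synthetic karyotype a realistic band spread for PFGE emulation.
_YEAST_CHROM_KB = [
    230, 813, 316, 1532, 577, 270, 1091, 563,
    440, 746, 667, 1078, 924, 784, 1091, 948,
]
_MT_KB = 86


@dataclass(frozen=True)
class GeneFeature:
    """One gene on the array, with 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    subtelomeric: bool

    def __post_init__(self) -> None:
        if self.start <= 0 or self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: need 0 < start < end, "
                f"got start={self.start} end={self.end}"
            )


def chromosome_rank(chromosome: str) -> int:
    """Sort key placing nuclear chromosomes in karyotype order, Mt last."""
    try:
        return CHROMOSOME_NAMES.index(chromosome)
    except ValueError:
        raise ValueError(f"unknown chromosome label {chromosome!r}") from None


def chromosome_length_bp(chromosome: str, n_chromosomes: int = 16) -> int:
    """Length in bp of a synthetic chromosome (cycled real yeast sizes)."""
    if chromosome == "Mt":
        return _MT_KB * 1000
    idx = chromosome_rank(chromosome)
    return _YEAST_CHROM_KB[idx % len(_YEAST_CHROM_KB)] * 1000


def build_gene_catalog(
    n_chromosomes: int = 16,
    genes_per_chromosome: int = 50,
    subtelomere_span: int = 30_000,
    seed: int = 0,
    include_mt: bool = True,
    mt_genes: int | None = None,
) -> list[GeneFeature]:
    """Build a deterministic synthetic gene catalog.

    Parameters
    ----------
    n_chromosomes
        Number of nuclear chromosomes (labelled I.., at most 16).
    genes_per_chromosome
        Genes laid out evenly (with seeded jitter) along each nuclear
        chromosome.
    subtelomere_span
        Distance in bp from either chromosome end within which a gene is
        flagged subtelomeric. The mitochondrial chromosome is never flagged.
    seed
        Seed for the coordinate jitter; identical seeds give identical
        catalogs.
    include_mt
        Append a mitochondrial chromosome ``Mt``.
    mt_genes
        Gene count on Mt (default: ``max(2, genes_per_chromosome // 3)``).
    """
    if n_chromosomes < 1 or genes_per_chromosome < 2:
        raise ValueError(
            "need n_chromosomes >= 1 and genes_per_chromosome >= 2"
        )
    if n_chromosomes > len(_ROMAN):
        raise ValueError(f"at most {len(_ROMAN)} nuclear chromosomes supported")
    if subtelomere_span < 0:
        raise ValueError("subtelomere_span must be >= 0")

    rng = np.random.default_rng(seed)
    genes: list[GeneFeature] = []
    chroms = _ROMAN[:n_chromosomes] + (["Mt"] if include_mt else [])
    for chrom in chroms:
        n = genes_per_chromosome
        if chrom == "Mt":
            n = mt_genes if mt_genes is not None else max(2, genes_per_chromosome // 3)
        length = chromosome_length_bp(chrom)
        # Even slots with jittered starts; gene bodies stay inside the slot,
        # which guarantees the non-overlap invariant.
        slot = length // n
        for i in range(n):
            slot_start = i * slot + 1
            jitter = int(rng.integers(0, max(1, slot // 4)))
            start = slot_start + jitter
            body = int(rng.integers(slot // 3, max(slot // 3 + 1, slot // 2)))
            end = min(start + max(body, 1), slot_start + slot - 1)
            subtel = (
                chrom != "Mt"
                and (start <= subtelomere_span or end > length - subtelomere_span)
            )
            genes.append(
                GeneFeature(
                    gene_id=f"g{chrom}_{i + 1:03d}",
                    chromosome=chrom,
                    start=start,
                    end=end,
                    subtelomeric=subtel,
                )
            )
    genes.sort(key=lambda g: (chromosome_rank(g.chromosome), g.start))
    return genes


def catalog_to_frame(catalog: list[GeneFeature]) -> pd.DataFrame:
    """Catalog as a DataFrame indexed by gene_id, in chromosome order."""
    df = pd.DataFrame(
        {
            "chromosome": [g.chromosome for g in catalog],
            "start": [g.start for g in catalog],
            "end": [g.end for g in catalog],
            "subtelomeric": [g.subtelomeric for g in catalog],
        },
        index=pd.Index([g.gene_id for g in catalog], name="gene_id"),
    )
    return df


def write_catalog_tsv(catalog: list[GeneFeature], path, header_lines: list[str] | None = None) -> None:
    """Write the catalog as a BED-like TSV with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("# coordinates: 1-based inclusive\n")
        fh.write("chromosome\tstart\tend\tgene_id\tsubtelomeric\n")
        for g in catalog:
            fh.write(
                f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t{int(g.subtelomeric)}\n"
            )


def read_catalog_tsv(path) -> list[GeneFeature]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        GeneFeature(
            gene_id=str(r.gene_id),
            chromosome=str(r.chromosome),
            start=int(r.start),
            end=int(r.end),
            subtelomeric=bool(int(r.subtelomeric)),
        )
        for r in df.itertuples()
    ]
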