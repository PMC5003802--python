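"""Strain copy-number ground truth: ploidy, aneuploidies and segment events.

A :class:`StrainProfile` is the simulator's truth object: a base ploidy, a
map of whole-chromosome copy deviations (aneuploidies) and a list of
segmental copy-number events. Four named archetypes mirror the karyotype
classes seen in ale/lager panels: a euploid strain with subtelomeric
segmental losses, a heavily rearranged lager-like strain with one
chromosome entirely absent, a strain with three whole-chromosome gains,
and a strain with four whole-chromosome losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import GeneFeature, chromosome_length_bp, chromosome_rank

__all__ = [
    "SegmentEvent",
    "StrainProfile",
    "AnnotationMap",
    "make_gene_families",
    "make_archetype_profiles",
    "make_annotation_maps",
    "copy_number_vector",
    "effective_copy_signal",
]


@dataclass(frozen=True)
class SegmentEvent:
    """A segmental gain/loss: [start, end] bp (1-based inclusive) on one chromosome."""

    chromosome: str
    start: int
    end: int
    copy_deviation: int

    def overlaps(self, gene: GeneFeature) -> bool:
        return (
            gene.chromosome == self.chromosome
            and gene.start <= self.end
            and gene.end >= self.start
        )


@dataclass
class StrainProfile:
    """Per-strain copy-number truth.

    ``mt_copy_factor`` is a multiplicative signal factor for mitochondrial
    genes: mitochondrial copy number per cell varies continuously and
    independently of nuclear ploidy, which is how whole-Mt divergence shows
    up on arrays.
    """

    strain_id: str
    base_ploidy: int
    chromosome_ploidy: dict[str, int] = field(default_factory=dict)
    segment_events: list[SegmentEvent] = field(default_factory=list)
    mt_copy_factor: float = 1.0
    lager_like: bool = False

    def validate(self, catalog: list[GeneFeature]) -> None:
        if self.base_ploidy < 1:
            raise ValueError(f"{self.strain_id}: base_ploidy must be >= 1")
        for ev in self.segment_events:
            length = chromosome_length_bp(ev.chromosome)
            if not (1 <= ev.start <= ev.end <= length):
                raise ValueError(
                    f"{self.strain_id}: segment {ev} outside chromosome bounds"
                )
        cn = copy_number_vector(self, catalog)
        # floored at zero by construction; validate() guards the pre-floor
        # model: deviations may not push below zero, only exactly to it
        for g in catalog:
            raw = (
                self.base_ploidy
                + self.chromosome_ploidy.get(g.chromosome, 0)
                + sum(ev.copy_deviation for ev in self.segment_events if ev.overlaps(g))
            )
            if raw < 0:
                raise ValueError(
                    f"{self.strain_id}: gene {g.gene_id} would have copy number {raw} < 0"
                )
        assert min(cn.values()) >= 0


@dataclass(frozen=True)
class AnnotationMap:
    """Flat functional category: a named set of gene ids."""

    category_id: str
    category_name: str
    gene_ids: frozenset[str]


def _subtelomeric_by_chrom(catalog: list[GeneFeature]) -> dict[str, list[GeneFeature]]:
    out: dict[str, list[GeneFeature]] = {}
    for g in catalog:
        if g.subtelomeric:
            out.setdefault(g.chromosome, []).append(g)
    for v in out.values():
        v.sort(key=lambda g: g.start)
    return out


def make_gene_families(catalog: list[GeneFeature]) -> dict[str, list[str]]:
    """Pick three subtelomeric gene families from the catalog.

    Emulates the telomere-associated AAD (aryl-alcohol dehydrogenase), MAL
    (maltose utilization) and FIT (siderophore transport) families: members
    sit in subtelomeric regions of distinct chromosomes, so a family-wide
    loss is a dispersed but functionally coherent event.
    """
    subtel = _subtelomeric_by_chrom(catalog)
    chroms = sorted(subtel, key=chromosome_rank)
    if len(chroms) < 3:
        raise ValueError("catalog has too few chromosomes with subtelomeric genes")

    def pick(chrom_subset: list[str], from_end: bool) -> list[str]:
        return [
            (subtel[c][-1] if from_end else subtel[c][0]).gene_id
            for c in chrom_subset
        ]

    # partition chromosomes mod 3 so the families never collide, mirroring
    # the dispersed one-member-per-chromosome layout of real subtelomeric
    # families (target sizes 6 / 4 / 5)
    aad_chroms = [c for i, c in enumerate(chroms) if i % 3 == 0][:6]
    fit_chroms = [c for i, c in enumerate(chroms) if i % 3 == 1][:4]
    mal_chroms = [c for i, c in enumerate(chroms) if i % 3 == 2][:5]
    return {
        "AAD_like": pick(aad_chroms, from_end=True),
        "FIT_like": pick(fit_chroms, from_end=True),
        "MAL_like": pick(mal_chroms, from_end=False),
    }


def _family_loss_events(
    catalog: list[GeneFeature], gene_ids: list[str], copy_deviation: int
) -> list[SegmentEvent]:
    by_id = {g.gene_id: g for g in catalog}
    return [
        SegmentEvent(by_id[i].chromosome, by_id[i].start, by_id[i].end, copy_deviation)
        for i in gene_ids
    ]


def _fragment(chrom: str, frac_lo: float, frac_hi: float, dev: int) -> SegmentEvent:
    length = chromosome_length_bp(chrom)
    return SegmentEvent(
        chrom, max(1, int(frac_lo * length)), int(frac_hi * length), dev
    )


def make_archetype_profiles(
    catalog: list[GeneFeature],
    seed: int = 0,
    n_extra_random: int = 0,
    subtelomere_span: int = 30_000,
) -> list[StrainProfile]:
    """Build the four named strain archetypes (plus optional random strains).

    * ``strain4-like`` — euploid tetraploid; only subtelomeric segmental
      losses (including a family-wide MAL-like loss).
    * ``strain6-like`` — lager-like: diploid with chromosome XII entirely
      absent, gross deficiencies of I and VI, a distal right-arm loss on
      XVI, multiple interstitial segmental gains/losses, and family-wide
      AAD-like and FIT-like losses.
    * ``strain8-like`` — diploid with trisomies of I, III and VI; no
      segmental events.
    * ``strain9-like`` — tetraploid with single-copy losses of I, III, VI
      and IX.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    rng = np.random.default_rng(seed)
    chrom_set = {g.chromosome for g in catalog}

    def have(*cs: str) -> bool:
        return all(c in chrom_set for c in cs)

    fams = make_gene_families(catalog)

    def mt_factor() -> float:
        # log2-normal with sd 0.5: whole-Mt copy level is highly strain-variable
        return float(2.0 ** rng.normal(0.0, 0.5))

    profiles: list[StrainProfile] = []

    # strain4-like: pure subtelomeric segmental losses on a tetraploid base
    s4_events = _family_loss_events(catalog, fams["MAL_like"], -4)
    by_id = {g.gene_id: g for g in catalog}
    for chrom in sorted(chrom_set - {"Mt"}, key=chromosome_rank):
        length = chromosome_length_bp(chrom)
        if chromosome_rank(chrom) % 3 != 0:  # deterministic subset of chromosomes
            continue
        for lo, hi in ((1, subtelomere_span), (max(1, length - subtelomere_span + 1), length)):
            cand = SegmentEvent(chrom, lo, hi, -2)
            # family-loss events already empty these genes; never double-hit
            if any(cand.overlaps(by_id[i]) for i in fams["MAL_like"]):
                continue
            s4_events.append(cand)
    profiles.append(
        StrainProfile("strain4-like", 4, {}, s4_events, mt_copy_factor=mt_factor())
    )

    # strain6-like: the heavily rearranged lager-like genome
    s6_chrom: dict[str, int] = {}
    if have("XII"):
        s6_chrom["XII"] = -2  # whole chromosome absent
    for c in ("I", "VI"):
        if have(c):
            s6_chrom[c] = -1  # gross deficiency
    s6_events: list[SegmentEvent] = []
    for c, (lo, hi) in {"II": (0.35, 0.55), "III": (0.05, 0.20), "VII": (0.6, 0.8),
                        "VIII": (0.2, 0.4), "XI": (0.45, 0.65)}.items():
        if have(c):
            s6_events.append(_fragment(c, lo, hi, +1))
    for c, (lo, hi) in {"III": (0.7, 0.9), "V": (0.3, 0.5), "X": (0.55, 0.75)}.items():
        if have(c):
            s6_events.append(_fragment(c, lo, hi, -1))
    if have("XVI"):
        s6_events.append(_fragment("XVI", 0.8, 1.0, -2))  # distal right arm absent
    # family-wide losses: zero each member's *remaining* copies, whatever
    # the chromosome-level deficiencies and fragment events left behind
    for gid in fams["AAD_like"] + fams["FIT_like"]:
        g = next(x for x in catalog if x.gene_id == gid)
        cur = (
            2
            + s6_chrom.get(g.chromosome, 0)
            + sum(ev.copy_deviation for ev in s6_events if ev.overlaps(g))
        )
        if cur > 0:
            s6_events.append(SegmentEvent(g.chromosome, g.start, g.end, -cur))
    profiles.append(
        StrainProfile(
            "strain6-like", 2, s6_chrom, s6_events,
            mt_copy_factor=mt_factor(), lager_like=True,
        )
    )

    # strain8-like: three trisomies, nothing else
    s8_chrom = {c: +1 for c in ("I", "III", "VI") if have(c)}
    profiles.append(
        StrainProfile("strain8-like", 2, s8_chrom, [], mt_copy_factor=mt_factor())
    )

    # strain9-like: four whole-chromosome losses on a tetraploid base; two of
    # four copies go, so the loss stays clearly visible (log2 ratio -1) even
    # after re-referencing against a cohort that alters the same chromosomes
    s9_chrom = {c: -2 for c in ("I", "III", "VI", "IX") if have(c)}
    profiles.append(
        StrainProfile("strain9-like", 4, s9_chrom, [], mt_copy_factor=mt_factor())
    )

    nuclear = sorted(chrom_set - {"Mt"}, key=chromosome_rank)
    for i in range(n_extra_random):
        ploidy = int(rng.choice([2, 2, 4]))
        devs: dict[str, int] = {}
        for c in nuclear:
            if rng.random() < 0.1:
                devs[c] = int(rng.choice([-1, 1]))
        events = []
        for c in nuclear:
            if rng.random() < 0.15:
                lo = rng.uniform(0.0, 0.8)
                hi = min(1.0, lo + rng.uniform(0.05, 0.2))
                dev = int(rng.choice([-1, 1]))
                if ploidy + devs.get(c, 0) + min(dev, 0) >= 0:
                    events.append(_fragment(c, lo, hi, dev))
        profiles.append(
            StrainProfile(
                f"random-{i + 1}", ploidy, devs, events, mt_copy_factor=mt_factor()
            )
        )

    for p in profiles:
        p.validate(catalog)
    return profiles


def copy_number_vector(
    profile: StrainProfile, catalog: list[GeneFeature]
) -> dict[str, int]:
    """Integer copy number per gene: base + chromosome deviation + segments, floored at 0."""
    out: dict[str, int] = {}
    for g in catalog:
        cn = profile.base_ploidy + profile.chromosome_ploidy.get(g.chromosome, 0)
        for ev in profile.segment_events:
            if ev.overlaps(g):
                cn += ev.copy_deviation
        out[g.gene_id] = max(cn, 0)
    return out


def effective_copy_signal(
    profile: StrainProfile, catalog: list[GeneFeature]
) -> pd.Series:
    """Per-gene signal-equivalent copy level (copy number × Mt factor on Mt)."""
    cn = copy_number_vector(profile, catalog)
    vals = {
        g.gene_id: cn[g.gene_id] * (profile.mt_copy_factor if g.chromosome == "Mt" else 1.0)
        for g in catalog
    }
    return pd.Series(vals, name=profile.strain_id)


def make_annotation_maps(
    catalog: list[GeneFeature],
    n_random_categories: int = 10,
    random_category_size: int = 8,
    seed: int = 0,
) -> list[AnnotationMap]:
    """Annotation input for enrichment: the three gene families plus random categories."""
    fams = make_gene_families(catalog)
    maps = [
        AnnotationMap("FAM_AAD", "aryl-alcohol dehydrogenase-like family",
                      frozenset(fams["AAD_like"])),
        AnnotationMap("FAM_FIT", "siderophore-transport-like family",
                      frozenset(fams["FIT_like"])),
        AnnotationMap("FAM_MAL", "maltose-metabolism-like family",
                      frozenset(fams["MAL_like"])),
    ]
    rng = np.random.default_rng(seed)
    all_ids = np.array([g.gene_id for g in catalog])
    for i in range(n_random_categories):
        members = rng.choice(all_ids, size=random_category_size, replace=False)
        maps.append(
            AnnotationMap(f"RND_{i + 1:03d}", f"random category {i + 1}",
                          frozenset(members.tolist()))
        )
    return maps
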