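"""End-to-end orchestration: simulate → karyotype → normalize → segment →
enrich/cluster → qPCR validation, as one reproducible, seeded run.

``run_all`` executes every stage in order, writes each intermediate as a
headered TSV (plus Newick trees and a JSON/Markdown report) and returns the
report dictionary. Identical config and seed give identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import hierarchy, karyotype, normalize, qpcr, segmentation
from .catalog import build_gene_catalog, catalog_to_frame, write_catalog_tsv
from .io import config_hash, write_tsv
from .profiles import (
    StrainProfile,
    copy_number_vector,
    effective_copy_signal,
    make_annotation_maps,
    make_archetype_profiles,
    make_gene_families,
)
from .simulate import (
    expected_log2_matrix,
    simulate_band_profile,
    simulate_qpcr,
    simulate_two_channel,
)

log = logging.getLogger("brewcgh")

__all__ = ["RunConfig", "run_all", "reference_profile", "simulate_panel"]


@dataclass
class RunConfig:
    """Fully serializable run configuration with field-level defaults."""

    seed: int = 0
    # catalog
    n_chromosomes: int = 16
    genes_per_chromosome: int = 50
    subtelomere_span: int = 30_000
    # strains
    n_extra_random_strains: int = 0
    strains: list[str] | None = None  # subset of archetype ids; None = all
    # noise / signal
    noise_sd: float = 0.2
    background_fraction: float = 0.01
    size_polymorphism: float = 0.02
    ct_noise_sd: float = 0.15
    # analysis
    band_tolerance: float = 0.015
    floor: float | None = None
    center: str = "median"
    penalty: float | None = None
    window: int = 25
    gain_threshold: float = 0.3
    loss_threshold: float = -0.3
    divergence_threshold: float = 2.0
    alpha: float = 0.05
    n_random_categories: int = 10
    random_category_size: int = 8
    # output
    outdir: str = "results/run"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def reference_profile() -> StrainProfile:
    """Euploid laboratory reference strain (no aberrations)."""
    return StrainProfile("reference", base_ploidy=2)


def simulate_panel(cfg: RunConfig):
    """Generate catalog, strain truth and all raw inputs for one run.

    Returns (catalog, profiles, reference, intensities, band_profiles).
    Per-strain simulation seeds are derived deterministically from
    ``cfg.seed`` via SeedSequence spawning.
    """
    catalog = build_gene_catalog(
        cfg.n_chromosomes,
        cfg.genes_per_chromosome,
        cfg.subtelomere_span,
        seed=cfg.seed,
    )
    profiles = make_archetype_profiles(
        catalog,
        seed=cfg.seed,
        n_extra_random=cfg.n_extra_random_strains,
        subtelomere_span=cfg.subtelomere_span,
    )
    if cfg.strains is not None:
        keep = set(cfg.strains)
        unknown = keep - {p.strain_id for p in profiles}
        if unknown:
            raise ValueError(f"unknown strain ids in config: {sorted(unknown)}")
        profiles = [p for p in profiles if p.strain_id in keep]
    ref = reference_profile()
    ref_signal = effective_copy_signal(ref, catalog)
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * len(profiles))]
    intensities = {}
    bands = []
    for i, p in enumerate(profiles):
        sig = effective_copy_signal(p, catalog)
        intensities[p.strain_id] = simulate_two_channel(
            sig, ref_signal, cfg.noise_sd, seed=child_seeds[2 * i],
            background_fraction=cfg.background_fraction,
        )
        bands.append(
            simulate_band_profile(
                p, catalog, cfg.size_polymorphism, seed=child_seeds[2 * i + 1]
            )
        )
    return catalog, profiles, ref, intensities, bands


def _truth_calls(truth: pd.DataFrame, genes: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Per-gene truth gain/loss/neutral labels from the noiseless expectation."""
    labels = pd.DataFrame("neutral", index=truth.index, columns=truth.columns)
    labels = labels.mask(truth >= cfg.gain_threshold, "gain")
    labels = labels.mask(truth <= cfg.loss_threshold, "loss")
    return labels


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also written to disk)."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = cfg.to_dict()
    # the hash identifies the scientific configuration; where the artifacts
    # land does not change what they are
    h = config_hash({k: v for k, v in cfg_dict.items() if k != "outdir"})
    seed = cfg.seed
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)

    def stage(name):
        log.info("stage %-12s [%6.2fs]", name, time.time() - t0)

    try:
        stage("simulate")
        catalog, profiles, ref, intensities, bands = simulate_panel(cfg)
        if len(profiles) < 2:
            raise ValueError(
                "re-referencing against the cohort average needs >= 2 strains; "
                f"got {len(profiles)}"
            )
        meta = catalog_to_frame(catalog)
        write_catalog_tsv(
            catalog, outdir / "catalog.tsv",
            header_lines=[f"module: synthetic_data", f"config_hash: {h}", f"seed: {seed}"],
        )
        truth_cn = pd.DataFrame(
            {p.strain_id: copy_number_vector(p, catalog) for p in profiles}
        ).reindex(meta.index)
        truth_cn.index.name = "gene_id"
        write_tsv(truth_cn, outdir / "truth_copy_number.tsv", "synthetic_data", h, seed)
        for sid, df in intensities.items():
            write_tsv(df, outdir / f"intensities_{sid}.tsv", "synthetic_data", h, seed)
        band_rows = pd.DataFrame(
            [(b.strain_id, s) for b in bands for s in b.band_sizes],
            columns=["strain_id", "band_kb"],
        )
        write_tsv(band_rows, outdir / "bands.tsv", "synthetic_data", h, seed, index=False)

        stage("karyotype")
        presence = karyotype.binarize_bands(bands, cfg.band_tolerance)
        sim = karyotype.similarity_matrix(presence)
        write_tsv(sim, outdir / "karyotype_similarity.tsv", "karyotype_similarity", h, seed)
        ktree = hierarchy.upgma(sim)
        (outdir / "karyotype_upgma.nwk").write_text(
            f"[module: karyotype_similarity config_hash: {h} seed: {seed}]\n"
            + hierarchy.to_newick(ktree) + "\n"
        )

        stage("acgh")
        mat = normalize.build_log2_matrix(
            intensities, meta, floor=cfg.floor, center=cfg.center
        )
        mat = normalize.rereference_to_average(mat)
        out = pd.concat([mat.genes, mat.data], axis=1)
        write_tsv(out, outdir / "log2_matrix.tsv", "acgh_normalization", h, seed)

        stage("diverge")
        segs = segmentation.segment_matrix(
            mat, cfg.penalty, cfg.gain_threshold, cfg.loss_threshold
        )
        seg_rows = []
        for (strain, chrom), segset in segs.items():
            for s in segset.segments:
                seg_rows.append((strain, chrom, s.first, s.last, s.mean, s.call))
        seg_df = pd.DataFrame(
            seg_rows,
            columns=["strain_id", "chromosome", "first_gene", "last_gene", "mean", "call"],
        )
        write_tsv(seg_df, outdir / "segments.tsv", "segmentation_divergence", h, seed, index=False)
        div = segmentation.divergence_track(mat, cfg.window)
        write_tsv(div, outdir / "divergence.tsv", "segmentation_divergence", h, seed)
        divergent = segmentation.select_divergent_genes(mat, cfg.divergence_threshold)
        (outdir / "divergent_genes.txt").write_text(
            f"# module: segmentation_divergence\n# config_hash: {h}\n# seed: {seed}\n"
            + "\n".join(sorted(divergent, key=list(mat.gene_ids).index)) + "\n"
        )

        stage("enrich")
        annotations = make_annotation_maps(
            catalog, cfg.n_random_categories, cfg.random_category_size, seed=cfg.seed
        )
        universe = set(mat.gene_ids)
        results = enr.overrepresentation(divergent, annotations, universe, cfg.alpha)
        enr_df = pd.DataFrame([asdict(r) for r in results])
        write_tsv(enr_df, outdir / "enrichment.tsv", "enrichment_clustering", h, seed, index=False)
        stree = enr.complete_linkage(mat, axis="strains")
        (outdir / "strain_tree.nwk").write_text(
            f"[module: enrichment_clustering config_hash: {h} seed: {seed}]\n"
            + hierarchy.to_newick(stree) + "\n"
        )
        if divergent:
            heat = enr.heatmap_export(mat, divergent, stree, annotations)
            write_tsv(heat, outdir / "heatmap.tsv", "enrichment_clustering", h, seed)

        stage("qpcr")
        fams = make_gene_families(catalog)
        panel = sorted({fams["AAD_like"][0], fams["FIT_like"][0], fams["MAL_like"][0]})
        # one dosage-stable control gene from mid-chromosome territory
        interior = meta.index[~meta["subtelomeric"] & (meta["chromosome"] != "Mt")]
        panel.append(str(interior[len(interior) // 2]))
        ss = np.random.SeedSequence((cfg.seed, 17))
        qseeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(profiles) + 1)]
        ref_cn = pd.Series(copy_number_vector(ref, catalog))
        ref_meas = simulate_qpcr(
            ref_cn, ref_cn, panel, "reference", seed=qseeds[-1], ct_noise_sd=0.0
        )
        meas = []
        for i, p in enumerate(profiles):
            cn = pd.Series(copy_number_vector(p, catalog))
            meas += simulate_qpcr(
                cn, ref_cn, panel, p.strain_id,
                seed=qseeds[i], ct_noise_sd=cfg.ct_noise_sd,
            )
        levels = qpcr.relative_level_table(meas, ref_meas)
        write_tsv(levels, outdir / "qpcr_levels.tsv", "qpcr_validation", h, seed)
        qpcr_log2 = qpcr.normalize_per_gene_average(levels)
        # array-side relative levels for the same genes, normalized identically
        centered = normalize.build_log2_matrix(
            intensities, meta, floor=cfg.floor, center=cfg.center
        )
        acgh_levels = np.exp2(centered.data.loc[panel].T)
        acgh_log2 = qpcr.normalize_per_gene_average(acgh_levels)
        r = qpcr.platform_correlation(qpcr_log2, acgh_log2)

    except Exception as exc:  # annotate failures with the stage context
        raise RuntimeError(f"pipeline failed ({outdir}): {exc}") from exc

    truth = expected_log2_matrix(profiles, ref, catalog, cfg.background_fraction)
    truth = truth.reindex(meta.index)
    truth_calls = _truth_calls(truth, meta, cfg)
    write_tsv(truth_calls, outdir / "truth_calls.tsv", "synthetic_data", h, seed)

    n_sig = int(sum(r_.significant for r_ in results))
    report = {
        "config_hash": h,
        "seed": seed,
        "n_strains": len(profiles),
        "n_genes": len(mat.gene_ids),
        "karyotype_tree": hierarchy.to_newick(ktree),
        "strain_tree": hierarchy.to_newick(stree),
        "n_segments": int(len(seg_df)),
        "n_called_gain": int((seg_df["call"] == "gain").sum()),
        "n_called_loss": int((seg_df["call"] == "loss").sum()),
        "divergent_gene_count": len(divergent),
        "significant_categories": [
            r_.category_id for r_ in results if r_.significant
        ],
        "n_significant_categories": n_sig,
        "platform_correlation": r,
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    md = ["# brewcgh run report", ""]
    md += [f"- **{k}**: {v}" for k, v in report.items() if k not in ("karyotype_tree", "strain_tree")]
    (outdir / "report.md").write_text("\n".join(md) + "\n")
    stage("done")
    return report


def truth_call_segments(labels) -> list[tuple[int, int, str]]:
    """Maximal runs of identical non-neutral labels as (first, last, call)."""
    out = []
    start, cur = 0, None
    seq = list(labels) + [None]
    for i, v in enumerate(seq):
        if v != cur:
            if cur in ("gain", "loss"):
                out.append((start, i - 1, cur))
            start, cur = i, v
    return out


def recovered_fraction(
    segs: dict, truth_calls: pd.DataFrame, genes: pd.DataFrame,
    min_gene_agreement: float = 0.9,
) -> tuple[int, int]:
    """Count truth gain/loss segments whose genes are called correctly.

    A truth segment counts as recovered when at least ``min_gene_agreement``
    of its genes receive the truth's call. Returns (recovered, total).
    """
    recovered = total = 0
    for (strain, chrom), segset in segs.items():
        idx = genes.index[genes["chromosome"] == chrom]
        truth_col = truth_calls.loc[idx, strain].to_numpy()
        calls = segset.gene_calls()
        for first, last, lab in truth_call_segments(truth_col):
            total += 1
            if (calls[first : last + 1] == lab).mean() >= min_gene_agreement:
                recovered += 1
    return recovered, total
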