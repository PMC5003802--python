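# Methods

This note documents the models behind `brewcgh`, the defaults that matter,
and what the synthetic data does and does not emulate. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic genomes and strain truth

The gene catalog lays out 16 nuclear chromosomes (roman numerals, realistic
*S. cerevisiae* lengths from 230 kb to 1.53 Mb) plus one mitochondrial
chromosome, default 50 genes per nuclear chromosome (816 genes total with
the Mt genes), non-overlapping, with seeded coordinate jitter. A gene is
*subtelomeric* when it lies within 30 kb of either chromosome end — the
span is arbitrary but configurable, and at default geometry flags roughly
one to six genes per chromosome end.

Strain truth is a `StrainProfile`: base ploidy, whole-chromosome copy
deviations, and segmental events (bp intervals with integer copy
deviations); per-gene copy number is the floored sum. Four archetypes mirror
the karyotype classes of ale/lager panels:

- **strain4-like** — tetraploid, euploid at chromosome scale; only
  subtelomeric segmental losses (half-dosage at chromosome ends of every
  third chromosome, plus a complete loss of the MAL-like family).
- **strain6-like** — lager-like diploid: chromosome XII entirely absent,
  single-copy deficiencies of I and VI, a zero-copy distal segment on the
  right arm of XVI, interstitial fragment gains (II, III, VII, VIII, XI) and
  losses (III, V, X), and family-wide zero-copy losses of the AAD-like and
  FIT-like families.
- **strain8-like** — diploid with trisomies of I, III and VI and no
  segmental events.
- **strain9-like** — tetraploid losing two of four copies of I, III, VI and
  IX. Two copies rather than one is a deliberate choice: a single-copy
  tetraploid loss (|log2(3/4)| ≈ 0.415) shrinks below the call threshold
  after re-referencing on chromosomes that other strains alter too, whereas
  the archetype is meant to carry unambiguous whole-chromosome losses.

Three subtelomeric gene families (AAD-like, 6 members; FIT-like, 4;
MAL-like, 5) occupy one subtelomeric gene each on a mod-3 partition of the
chromosomes, so family-wide loss is a dispersed, functionally coherent event
— the signature the enrichment stage is built to detect. Family-loss events
always zero the member's *remaining* copies, whatever chromosome-level
deficiencies apply.

Mitochondrial copy number varies continuously and independently of nuclear
ploidy; each strain carries a log2-normal Mt signal factor (sd 0.5), which
makes the whole Mt chromosome a high-divergence region by construction.

## Intensity, band and CT models

Probe intensities are multiplicative: signal = 1000 arbitrary units per
copy-equivalent, times 2^ε with ε ~ N(0, noise_sd) per probe on the test
channel. The default noise_sd is 0.2 log2 units — a typical probe-level
scatter for two-color arrays; it is a free parameter, and the acceptance
checks exercise both 0 and 0.2. Genes absent from a genome emit background
at 1% of the diploid signal, keeping log ratios finite while landing absent
genes near log2(0.01) ≈ −6.6, comfortably below the −2 "absent" rule.

PFGE lanes carry one band per retained nuclear chromosome (a zero-copy
chromosome loses its band), with uniform relative size jitter
(default 2%) emulating length polymorphism; lager-like strains gain one
extra band between the chromosome IV and VII sizes, as hybrid karyotypes
show. Gel physics is not modelled; bands are numbers.

qPCR crossing thresholds are generated by inverting the efficiency model:
CT = CT_ref − log(copy ratio)/log(E), baseline CTs 24 (target) and 20
(housekeeping gene, dosage-stable), Gaussian CT noise (default sd 0.15
cycles), non-detects reported at CT 38. At efficiency 2 a copy-ratio
doubling advances CT by exactly one cycle.

## Normalization chain

log2 ratios use an intensity floor (default 1% of each array's median
reference intensity) so zero or near-zero signals stay finite. Within-array
normalization is median centering (configurable off/median/mean): the
minimal standard correction, chosen because nothing stronger is warranted
for simulated data and the real instrument-side step is vendor-specific.
Median centering also removes the global ploidy offset, which is why base
ploidies enter only through *relative* event sizes.

Re-referencing subtracts each gene's across-strain mean of log2 ratios
(averaging in log space, i.e. the geometric mean of ratios — the profiles
being averaged are log-ratio tracks). Closed-form consequences, all tested:
the operation is idempotent; adding c to one strain's row moves that row by
c(n−1)/n and every other row by −c/n; and with k of n strains sharing an
event the event's apparent size shrinks by factor (n−k)/n while the other
strains acquire an opposite-sign echo. Calls are therefore defined — for
pipeline and ground truth alike — in this re-referenced space: the truth
table is the noiseless analytic expectation pushed through the same
centering and averaging, then thresholded.

## Segmentation and calling

`segment_track` minimizes Σ residual² + λ·(#breakpoints) exactly by O(n²)
dynamic programming on prefix sums, ties resolved toward fewer segments
(1e−9 relative tolerance). The default penalty is BIC-style,
λ = 2·σ̂²·log n, with σ̂ the median absolute successive difference scaled by
√2·0.6745 — robust to the level shifts themselves; a noiseless track yields
λ = 0, where the fewest-segments tie-break recovers the minimal exact
segmentation. Calls use thresholds ±0.3 log2 units: below the weakest event
the archetypes produce (|log2(3/4)| ≈ 0.415 pre-re-referencing) and above
the ±~0.1–0.17 re-referencing echoes of single-strain events in a
four-strain panel.

Truth recovery is scored as: a truth gain/loss segment (maximal run of one
non-neutral truth label) counts as recovered when ≥ 90% of its genes get
that call; the acceptance criterion asks ≥ 95% of truth segments recovered
pooled over 20 simulations at noise 0.2. Both fractions were fixed before
measurement.

## Divergence track

Per-gene sample SD uses the n−1 denominator — material at n = 4 strains.
Smoothing is a centered moving average, truncated at chromosome boundaries
(never crossing them), default window 25 genes (≈ half a default
chromosome): wide enough to expose regional structure, narrow enough to
keep chromosome ends distinct. The subtelomeric-versus-interior comparison
excludes mitochondrial genes, which have no subtelomeres and whose whole-
chromosome divergence is a separate, deliberately simulated phenomenon.
Divergent-gene selection is strictly |log2| > 2: a value of exactly ±2 is
not selected.

## Enrichment and clustering

Over-representation is the upper-tail hypergeometric probability
P(X ≥ k) for k selected members of a K-gene category among n selected genes
in a universe of N (the full catalog, not only annotated genes — the
broader, more conservative reference set; configurable by passing a
different universe). Categories with k = 0 are excluded before testing and
from the BH correction's m, mirroring standard over-representation tools.
BH q-values come from the step-up procedure; significance is q ≤ 0.05.

Both trees come from one agglomerative routine with deterministic
lexicographic tie-breaking, so input order never changes a tree. UPGMA
(size-weighted average linkage) uses half-distance merge heights, making
the tree ultrametric with cophenetic distances on the original 1−Jaccard
scale; complete linkage (Euclidean, for the strain/gene similarity trees)
uses full-distance heights, so two items merge at exactly their distance.
Band binning is single-linkage chaining of sorted sizes at 1.5% relative
tolerance — a free parameter standing in for by-eye band matching, since no
published binning rule exists.

## qPCR validation

Relative levels are Pfaffl ratios E_t^(ΔCT_target)/E_r^(ΔCT_refgene) with
per-amplicon efficiencies in (1, 2]; the 2^−ΔΔCT shortcut is wrong whenever
measured efficiencies are below 2 (typically 1.9–2.0), which is why the
two-efficiency form is the default and only implementation. Cross-platform
comparison divides each gene's levels by their across-strain arithmetic
mean, floors zeros at ε = 10⁻⁴ (the magnitude of the smallest reliably
reportable level), log2-transforms, and computes Pearson r over matched
(strain, gene) pairs. Pearson (not Spearman) because the comparison is on
log2-linearized values.

The package ships one real validation table (four genes × four strains of
efficiency-corrected relative transcript levels). The matched array-side
values for that panel are not available as numbers, so
`synthetic_matched_acgh_log2` builds a clearly-labelled synthetic stand-in:
the noiseless array profile implied by the table's own presence/absence
pattern (levels below 10⁻³ are non-detects → background at 1% of diploid
signal), re-referenced per gene. Because this stand-in is two-valued per
gene, the correlation it yields is invariant to the background level and
reflects only the presence/absence pattern; it demonstrates the procedure
and supports structural tests, but is not a reconstruction of the original
measured array values, and correlations computed against it should not be
read as reproducing any particular measured value.

## Problem sizes and determinism

Default analyses run at 4 strains × 816 genes; acceptance-level checks use
20 independent simulations for the noisy-recovery and divergence-geography
properties, 100 random categories for enrichment specificity, exhaustive
enumeration up to n = 12 (segmentations) and N = 12 (hypergeometric draws)
for the oracles. A full pipeline run takes well under a second; the whole
acceptance script a few seconds. All randomness flows from
`numpy.random.default_rng` seeded from the run seed (per-strain streams via
`SeedSequence.spawn`), and identical config + seed reproduce every output
byte-for-byte (the config hash excludes only the output directory).

## What the simulation does not capture

No dye bias, print-tip or spatial array artifacts, probe-specific affinity
differences, GC effects, or cross-hybridization; noise is i.i.d. per probe,
so segmentation sees no autocorrelated noise. Band profiles ignore
co-migration physics and partial-length translocations. Annotation
categories are flat sets — no ontology structure or term propagation.
Expression is strictly proportional to gene dosage in the qPCR simulator,
so passing validation shows the quantification arithmetic is right, not
that real transcription is dosage-linear. Results on synthetic data bound
what the pipeline can do under its own assumptions; they do not certify
performance on real arrays with structured noise.
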