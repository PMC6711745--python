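# Methods

This note records the models behind `dediffquant`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions that make results reproducible.

## Imaging arm

### Scene model

A simulated tumor image is a multi-channel uint16 raster.  Nuclei are disks
with radius ~ Normal(6, 1) px truncated at 2 px, placed by rejection
sampling so that nucleus-to-nucleus distance exceeds the sum of radii plus
a 2 px gap (a bounded retry budget raises a placement error for impossible
densities).  A cell is its nucleus dilated outward by `cytoplasm_width_px`
(default 10 px), clipped against neighbors by nearest-seed assignment with
ties to the lower cell id.  Nuclear channels (DNA stain, nuclear TF) carry
signal only on nucleus pixels; marker channels on whole-cell pixels.  A
horizontal background ramp (200 → 300 intensity units), Gaussian
smoothing (σ = 0.8) and Gaussian read noise (SD 20) complete the render.
Acquisition is kept below saturation by construction.

Per-cell intensities are log-normal.  Each marker channel has a *retained*
mode (median ≈ 3000, log-SD 0.3) and a *lost* mode (median ≈ 600, log-SD
0.4); a cell draws from the lost mode with probability
`marker_loss_fraction`, independently of position — the cell-autonomous,
spatially interspersed ("variegated") loss pattern.  How dim a lost cell is
in real tissue is not well characterized; the two-mode log-normal with a
five-fold separation is a modeling choice, exposed in `ChannelModel`.
Channels share a Gaussian copula whose exchangeable latent correlation is
set from the requested Spearman correlation (ρ_z = 2·sin(πρ_s/6)), so tests
can dial rank correlations directly.

The default cytoplasm width equals the segmentation propagation cap
(10 px) so that the rendered cell and the measured cell compartment
coincide; with a narrower rendered cytoplasm the measured compartment
would include background and medians would no longer track the true
per-cell intensity.

What the generator does **not** emulate: 3D structure, optics (PSF),
touching or multinucleated cells, stromal contamination, illumination
fields beyond a linear ramp, and tumor-boundary tracing (tumor identity is
metadata, not inferred from morphology).  Passing tests therefore validate
the measurement and statistical machinery on well-formed scenes, not
robustness to histological artifacts.

### Segmentation and measurement

Nucleus detection: Gaussian smoothing (σ = 1.5) → global Otsu threshold →
hole filling → distance-transform watershed seeded at distance-map peaks
(minimum peak separation 5 px) → area filter (30–5000 px) → removal of
border-touching objects (bias guard for truncated compartments; can be
disabled).  A zero-variance channel yields zero objects with a warning
rather than an error.  All thresholds are recorded in `params_used`.

Cell construction is exact nearest-seed Euclidean growth computed per
nucleus on a padded bounding box (distance to the nucleus *region*, not its
centroid), capped at `max_distance_px` (default 10) in propagation mode or
`ring_width_px` (default 3) in ring mode; equidistant pixels go to the
lower label.  Ring mode exists for diffuse tumors where propagation
over-reaches.  Cytoplasm is the per-label set difference, which guarantees
|cell| = |nucleus| + |cytoplasm| exactly; empty cytoplasms are legal and
flagged.

The per-object statistic is the median intensity; for even pixel counts the
*lower* middle value is used so a reported median is always an attained
pixel value, identical across numeric backends.

### Statistics

Tumors are the independent units: per-cell medians are averaged within
tumor ("mean of medians") before two-group comparisons.  The negativity
threshold is mean − 1·sample SD (n−1) of per-cell medians pooled over all
cells of the reference genotype; positivity is median ≥ cutoff, so for a
Normal reference ≈ 15.9% of reference cells are called negative by
construction.  Quadrant classes pair the nuclear-TF nucleus median with the
marker cytoplasm median.  Association of genotype with class distribution
uses Pearson chi-squared without continuity correction (warning when an
expected count is below 5).  Rank-sum comparisons use the exact null for
combined n ≤ 12 without ties and the tie-corrected normal approximation
otherwise; note the exact test's attainable rejection rate at α = 0.05 is
0.029/0.032/0.041 for 4/5/6 tumors per group — calibration scenarios use
six per group for this reason.  ANOVA + Tukey HSD use the studentized-range
distribution.  Spearman correlations pool cells across tumors within
genotype (matching per-cell scatter plots); a tumor-stratified analysis is
out of scope.

`power_n_per_group` solves the two-sided two-sample t-test power equation
with the noncentral-t distribution by Brent root-finding on continuous n
(bracket grown by doubling; extreme noncentrality treated as power 1).  It
matches R's `power.t.test` to four decimals; the negligible
wrong-direction tail (< 1e−7 here) is included for correctness.

## Expression arm

### Count-matrix generator

Counts are negative binomial: K ~ NB(mean μ, dispersion α) with
log μ = log(base mean) + module latent + gene noise + group effect +
log(sample depth).  Defaults: 2000 genes, 8 samples/group, four modules of
250/150/150/150 genes, module latent SD 0.28 and gene-level noise SD 0.12
on the natural-log scale, NB dispersion 0.01, depth factors uniform on
[0.7, 1.3].  The total per-gene between-sample coefficient of variation is
≈ 33%, in line with between-animal variability of sorted tumor-cell
RNA-seq, while the shared latent dominates it, giving within-module Pearson
correlations ≈ 0.7 — coherent modules without drowning single-gene
contrasts in noise.

Module latent factors are **centered within each sample group**, so the
planted group contrast of every gene is exact by construction: the truth
table's `true_log2fc` is the realized, not just expected, effect.  The
affected module houses both alveolar marker programs and the planted
regulator; its genes shift by `effect_log2fc` (default −1, a 2-fold loss)
in group B, except the AT1-like markers, which move oppositely scaled by
`at1_gain_ratio` (default 0.7) — type-2 identity is lost while type-1
character rises, the co-regulated but divergent behavior seen in
de-differentiating alveolar tumors.

Cell-type reference profiles are deterministic: exclusive markers are high
(1000 vs 100) in exactly one type; pair-shared markers are equally high in
their two types, tying at zero specificity score and entering both top-100
sets through the builder's gene-id tie-break; everything else is flat.
With overlap counts (2, 4, 6, 8, 10, 12) across the six type pairs, the
four top-100 sets overlap pairwise by exactly 2–12 genes.  A consequence
of the max-of-others specificity score is that a gene cannot *strictly*
dominate in two types at once, so "specific to a type" is read as
"greater than or equal to every other type", with shared markers tied at
the top in exactly two.

The TF list is the planted regulator plus 50 decoys sampled (seeded) from
well-expressed genes outside the affected module; a correct screen must
reject every decoy on the co-expression criterion alone.

### Differential expression

Size factors are median-of-ratios against the per-gene geometric mean,
computed over genes with all-positive counts (a pseudocount mode covers
degenerate matrices) and rescaled to geometric mean 1.  The Wald test works
entirely on normalized counts q: per-gene total overdispersion is estimated
by method of moments as Var(q)/μ² pooled within groups — shot noise is
absorbed as a 1/μ component rather than modeled per sample, which makes
every statistic exactly invariant to rescaling one sample's counts together
with its size factor.  Gene-wise estimates are shrunk halfway (weight 0.5)
toward the parametric trend α(μ) = a₀ + a₁/μ fit by least squares (the
1/μ term captures shot noise, a₀ the asymptotic biological CV²).  The Wald
statistic is log₂FC over the delta-method SE √(α(1/n_A + 1/n_B))/ln 2 with
a standard-normal reference; BH correction across tested genes; all-zero
genes are excluded and reported.  This is a deliberately small estimator —
no GLM iteration, outlier refitting or fold-change shrinkage — calibrated
on synthetic truth (type-I ≈ 0.05 on exchangeable nulls at n = 8/group),
not a reimplementation of any specific DE package.  Null-calibration runs
use matrices without module latents, since the per-gene error rate is
defined over exchangeable genes; under correlated modules the *count* of
false positives fluctuates more, as it would in real data.

### Marker enrichment

Preranked GSEA ranks genes by the Wald statistic (descending, ties by gene
id).  The running sum gains |r|^w/Σ_hits|r|^w at hits (weight w = 1 by
default; w = 0 retained for the unweighted symmetry property) and loses
1/(N−N_h) at misses; the ES is the extremum of largest absolute value
(exact ties prefer the positive side).  The null is Monte-Carlo: random
same-size gene sets (default 10 000 permutations; pipeline default 2000),
seeded per set by a CRC-32 hash of the set name so collection order is
irrelevant.  NES divides the ES by the mean |null ES| of matching sign; the
p-value is the add-one fraction of same-sign nulls at least as extreme; BH
runs across the whole collection as one family.  A gene-permutation null
is anti-conservative for strongly internally correlated sets — inherent to
preranked GSEA and visible here because marker sets coincide with planted
modules; the calibration claim is for independent sets.

### Co-expression modules and the screen

Genes are first filtered to mean normalized count > 40 (strict).  The
network is unsigned soft-threshold adjacency |cor|^β with β = 3; the
clustering dissimilarity is 1 − TOM (topological overlap) by default.
When sample group labels are supplied — as the pipeline does — each gene is
centered within groups before correlation, so modules reflect
co-variation rather than the treatment contrast; without this, module
membership preferentially recruits null genes whose chance group shift
aligns with the treatment-driven eigengene, corrupting the screen's
independence of its module and DE criteria.

Average-linkage clustering is cut statically at height 0.8 (between the
within-module TOM dissimilarity ≈ 0.6–0.7 at default correlation strength
and the module–background level ≈ 0.95); clusters under 10 genes dissolve.
Two eigengene-based refinements follow, both deterministic: modules whose
eigengenes (leading PCs of standardized expression, oriented positively)
correlate above 0.75 are merged — fragments of one module share its latent
signal and are nearly collinear, distinct modules are not — and every gene
is then reassigned to the module maximizing |kME| (correlation with the
eigengene) when that exceeds 0.4, or to module 0 otherwise.  The
consolidation step exists because static-cut membership of a *single* gene
at 16 samples is noisy; dynamic tree cutting is deliberately out of scope.
Module ids are relabeled by decreasing size; the result is invariant to
sample order and to positive affine rescaling of genes.

The marker-bearing module is the one holding the largest combined count of
AT1+AT2 marker-set members (ties to the lower id, flagged), with the full
per-module count table emitted for audit.  The screen intersects module
membership, TF-list membership, and DE adjP < 0.2 (a deliberately
permissive discovery cutoff); the audit table lists every gene with its
three flags.

## Reproducibility conventions

One run seed fans out to per-stage seeds via
`SeedSequence([seed, crc32(stage_name), index])`, so any stage can be
re-run in isolation bit-identically; rerunning an arm with the same config
reproduces identical tables.  All validation runs at desk scale — 2000
genes, 8 samples per group, 200-cell scenes at 512², 20-seed batteries,
2000-replicate null calibrations — sizes at which every check completes in
seconds to a couple of minutes on one core while leaving clear margins on
the tested properties.

## Known limitations

* Segmentation accuracy claims hold for non-touching nuclei on smooth
  backgrounds; dense tissue would need declumping and threshold tuning.
* Cells within a tumor are treated as exchangeable given the tumor; no
  hierarchical model of cell-within-tumor correlation is provided.
* The DE estimator's normal reference is slightly anti-conservative at
  very small n; at n = 8/group the measured type-I error is ≈ 0.055.
* GSEA p-values use plain Monte-Carlo permutations; very small p-values
  are bounded by 1/(n_perm+1).
* The screen's decoy-exclusion behavior depends on module membership
  precision, which is sample-size limited; with far fewer than 16 samples
  membership noise dominates.
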