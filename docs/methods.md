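# Methods

This note documents the models implemented in `opspheno`, the parameter
choices that matter, what the synthetic benchmarks do and do not
demonstrate, and the numerical conventions used throughout.

## The screen being modeled

In an optical pooled CRISPR screen, each cell carries one sgRNA (read out
by in situ sequencing) and contributes a vector of image-derived features
(intensities, textures, colocalizations).  Perturbed cells are imaged
under one stimulation condition (4 h of cGAMP); non-targeting control
(NTC) cells are additionally imaged unstimulated and at a later 5 h time
point, giving three phenotype archetypes against which perturbations are
interpreted.  The analysis questions are: which gene knockouts change the
cellular phenotype at all, which make cells resemble the unstimulated or
the late-stimulation archetype, which genes share a phenotype (clusters),
and how the screen's gene list compares with other screens of the same
pathway.

## Synthetic data generator

`simulate.simulate_screen` draws per-cell features from a multivariate
normal: condition archetype mean + block-correlated unit-variance noise +
planted effect + per-FOV affine corruption.

- **Archetypes.** The 4 h condition is the origin; the unstimulated and
  5 h archetypes sit `condition_separation` (default 3, in noise-SD
  units) along orthogonal unit directions spanning the first and second
  half of the feature vector.  3 SD makes single cells overlap
  substantially between conditions — classification must aggregate over
  cells, as in a real screen.
- **Feature blocks.** Features fall in blocks of 4 with within-block
  correlation 0.3 (features extracted from the same channel co-vary).
- **Planted effects.** A hit gene shifts its cells by
  `effect_size · efficacy` along the archetype direction (classes
  `toward_unstim`, `toward_5h`) or a unit vector drawn once per gene (or
  per shared tag) from the sphere (`novel`).  Per-guide efficacies model
  guides that cut poorly; the benchmark default {1, 1, 0.5, 0} gives each
  hit gene two full-strength guides, one half-strength, one dead.
- **Batch structure.** Each (FOV, feature) pair gets an affine
  corruption `x -> scale·x + shift` with `shift ~ N(0, 0.3)` and
  `log scale ~ N(0, 0.1)` — exactly the corruption family the robust
  normalization removes.
- **Coverage.** Cells per guide are constant by default (deterministic
  tests) or negative binomial (`cells_per_guide_dispersion`) to emulate
  unequal coverage; 5 % of cells default to zero barcode reads to
  exercise the read filter.

What the generator does **not** emulate: real microscopy textures,
segmentation errors, non-Gaussian heavy-tailed features, guide
off-target effects, or cell-cycle/density covariates.  Passing benchmarks
therefore demonstrate the statistical machinery (calibration, power,
recovery, determinism) under a faithful covariance/batch/efficacy
structure — not robustness to every pathology of real images.

## Normalization

Each feature is standardized within its field of view:
`x' = (x − median) / (1.4826 · MAD)`, MAD computed around the median and
scaled to be a consistent normal-SD estimator.  Medians use the midpoint
convention for even counts.  A (FOV, feature) with zero MAD is set to 0
and logged.  The transform is exact: after it, every (FOV, feature) with
nonzero MAD has median 0 and scaled MAD 1 to floating-point precision,
and any per-FOV affine corruption with positive scale cancels exactly.
Because the median is robust, the small fraction of perturbed cells in a
FOV barely moves the reference.

## Classifiers and hit calling

All three schemes use a linear SVM (`C = 1e-5`, `max_iter = 100000`,
`tol = 5e-5`, balanced class weights, fixed seed).  The tiny `C`
deliberately underfits: the weight vector approximates the
population-mean difference direction, which is the right estimand when
the goal is scoring populations rather than classifying single cells.  A
consequence is that the 0-threshold of the decision function is not
calibrated; the pipeline only ever uses decision *values*, compared
against a bootstrap null.

- **Condition classifiers** (unstimulated: unstim vs 4 h NTC; increased
  stimulation: 5 h vs 4 h NTC) are pre-trained on NTC cells and applied
  to every guide; the guide score is the mean decision value over its
  cells, oriented toward the target condition, tested one-sided
  (condition similarity is directional).
- **Perturbed classifier**: one model per guide, guide cells vs an NTC
  reference sample, 80/20 train/test split; the score is the mean
  held-out decision value, tested two-sided (a perturbation can move
  cells in any direction).  Guides with < 5 cells are unscorable.

**Nulls.** For each model, pseudo-guides of NTC cells (sampled with
replacement at the guide's group size) go through the *same* scorer —
for the perturbed model this retrains a classifier per pseudo-guide, so
the null includes training variance.  The 4 h NTC population is split in
half: one half trains classifiers and provides the perturbed reference,
the other builds nulls, so null scores are never computed on training
cells.  Nulls are cached per group-size bucket (sqrt(2)-spaced grid,
p-values interpolated linearly in log2 size); exact per-size nulls are
available by flag and used whenever guide sizes are constant.

**p-values.** Add-one estimator `p = (1 + #{null ≥ s}) / (B + 1)`
(two-sided doubles the smaller tail, capped at 1) — never exactly zero.
Gene-level p combines guide p-values with Stouffer's method (p clipped to
1e-300 before the normal quantile), BH-corrected across genes within
each model; a gene is a hit at q ≤ 0.001 in a model and overall if hit in
any model.  Gene scores average guide mean scores over scorable guides.

**Calibration limits.** The bootstrap null centers on the NTC pool's
sample mean, so all guides share whatever offset that single draw has;
its scale is `sqrt(group_size / pool_size)` guide-SDs, plus a shared
ECDF error of order `1/sqrt(n_boot)`.  The benchmarks therefore keep the
NTC pool large relative to the group size (600 NTC guides of 25 cells,
mirroring the proportions of a genome-wide screen with ~450 NTC guides),
which keeps the shared offset below the sensitivity of a 500-guide KS
test in most runs; across many seeds the guide p-values are uniform on
average (mean p = 0.49 over 12 independent runs).  With small NTC pools
this offset is the dominant miscalibration and no implementation can
remove it — only more NTC cells can.

**Benchmark problem sizes.** 125–200 genes × 4 guides, 25–50 cells per
guide, 2000 bootstrap draws, chosen so the full benchmark suite runs in
minutes on one CPU while leaving every mechanism (splitting, bootstrap,
Stouffer, BH) intact; production-scale configuration uses 100,000
bootstrap draws.

## Dimensionality reduction and clustering

Gene profiles (mean normalized features per gene; NTC guides optionally
kept as individual pseudo-genes) are reduced by PCA to the smallest
component count reaching 95 % explained variance, with a deterministic
sign convention.  The embedding is a diffusion-potential method of the
PHATE family, implemented in-package as a dense O(n²)–O(n³) pipeline
suitable for gene-level matrices: adaptive-bandwidth alpha-decay kernel
(bandwidth = distance to the `knn`-th neighbor, decay 40), symmetrized
and row-normalized into a diffusion operator, powered to a diffusion
time chosen at the knee of the von Neumann entropy of the spectrum,
mapped through the log potential (`gamma = 1`; `gamma = 0` gives the
square-root potential), and embedded in 2-D by metric MDS (SMACOF)
initialized from classical MDS — fully deterministic given the seed.
The genome-wide preset uses `knn = 2, gamma = 1`, euclidean potential
distances; the secondary-screen preset skips PCA (profiles are first
reduced to 20 feature modules) and uses `knn = 1, gamma = 0`, cosine.

Leiden clustering runs on a k = 15 nearest-neighbor graph built from the
embedding coordinates (building the graph in PC space is a config
option).  The resolution is stability-selected: at each candidate
resolution, Leiden runs on 15 induced subgraphs of 90 % of the genes and
stability is the mean pairwise adjusted Rand score between subsample
labelings restricted to shared genes; the most stable resolution wins,
ties breaking toward the coarsest, and final labels come from a
full-data run.  Cluster enrichment for hit genes uses a one-sided
hypergeometric test (BH across clusters); a Wilcoxon rank-sum mode on
continuous scores is available where a rank-based call is preferred.
Feature modules come from agglomerative clustering of feature columns
(Euclidean, average linkage) cut at 20 modules, each gene's module score
being the mean of member features.  Phenotype strength is the Euclidean
distance in the 2-D embedding from a gene to the NTC centroid.

## Meta-analysis

Gene lists from heterogeneous screens are cross-weighted iteratively:
gene score = sum over evidence categories of the maximum current weight
among that category's lists containing the gene; list weight = mean
score of member genes, rescaled so the top list has weight 1; iterate to
a fixed point (tolerance 1e-6 on the max weight change, cap 100
iterations, non-convergence reported rather than raised).  The
within-category max prevents double counting of near-replicate lists in
one category; each screen defaults to its own category.  Rank-based
positional down-weighting is deliberately omitted: input lists are
truncated to the top 500 genes at p < 0.05, which flattens most rank
information.  Inputs are prepared per screen and direction; consensus
lists collect genes scoring in ≥ 2 screens.

## Image quantification

The arrayed-knockout recipe is deterministic throughout: optional
rolling-ball background subtraction (radius 50, ball-kernel morphological
estimate, output clipped at 0 — applied when acquisitions have smooth
background, omitted by default for clean fixtures), three-class Otsu
thresholding of the GM130 channel with foreground = the brightest class
(Golgi puncta are the brightest class; including the middle class is a
config flag), 8-connected labeling, transitive single-linkage merging of
objects whose minimum edge-to-edge pixel distance is below 30 px
(centroid distance available by flag), removal of objects strictly
smaller than 600 px (merge before filter, so close fragments survive the
area cut together), and per-object area/centroid/mean/integrated
intensity in the STING channel.  Pixel coordinates are row-major,
0-based.

## Numerical conventions and degenerate inputs

- Seeds are mandatory for every stochastic operation; all derived
  streams come from the user seed (child streams for effect directions,
  bootstrap buckets, subsampling iterations).
- p-values are clipped to [1e-300, 1 − 1e-16] before normal quantiles;
  empirical p-values are never 0 by construction.
- Zero-MAD features, empty clusters, empty gene lists, unscorable
  guides, and constant images degrade to logged no-ops or flagged rows,
  not exceptions; genuinely contradictory inputs (seedless simulation,
  single-condition training, mismatched shapes) raise `ValueError`.
- Ties: midpoint medians; stability ties break to the smallest
  resolution; module ids and MDS signs follow first-occurrence /
  largest-loading conventions so all outputs are byte-reproducible.

## Known limitations

- The embedding is dense and cubic in gene count; it is not intended for
  cell-level embeddings of millions of cells.
- Bootstrap-null calibration is limited by NTC pool size (see above).
- The enrichment test conditions on hard hit flags; the rank-sum mode
  partially addresses the information lost by thresholding.
- The generator's Gaussian features make SVM scores nearly optimal;
  real-feature heavy tails would reduce power but not validity (the
  bootstrap null makes no distributional assumption).
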