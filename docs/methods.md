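# Methods

This note documents the models and procedures the package implements,
the defaults that matter, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## The synthetic landscape

`sdmpipe.synthetic` simulates every input the analysis needs.

**Climate.** Each of the 19 bioclimatic layers is a Gaussian random
field: white noise smoothed with a Gaussian kernel of width
`spatial_range` cells (default 10 — on a ~10 km grid spanning a few
hundred kilometres, real temperature and precipitation fields are
smooth at roughly this scale) and re-standardized, so layers are
zero-mean, unit-variance in "climate sd" units. Layers are mixed by
the Cholesky factor of a target correlation matrix. The default
`default_mixing()` has a temperature block (first 11 variables) and a
precipitation block with 0.95^|i−j| correlation within blocks and 0.5
across — strong enough collinearity that five-to-six principal axes
carry 95% of variance, which is the regime the PCA step exists for.
Simulation of spatial structure by kernel smoothing (rather than
variogram-based geostatistical simulation) is deliberate: it is
simpler, exactly reproducible, and sufficient to induce the spatial
autocorrelation the checkerboard partitioning has to cope with.

**Scenario futures.** A `ScenarioShift` applies a per-variable affine
change (future = present × mult + add). The default shift set emulates
two emission pathways × five GCM realizations: a mitigation scenario
(temperature block +0.6 sd, precipitation −0.3 sd) and a high-emission
scenario with twice the shift, each fanned across five GCM factors
0.8–1.2. Futures are projected into the PCA space with the
*present-day* coefficients, never refit.

**Virtual species.** True suitability is a product of per-variable
Gaussian responses exp(−(x−opt)²/2b²), rescaled to peak 1. Defaults:
two niche variables — one from the temperature block and one from the
precipitation block, since ecological niches span distinct climate
gradients; drawing both from one block would make the niche an almost
one-dimensional band because of the within-block collinearity — optima
within ±0.6 sd of the climate mean and breadth 0.4 sd, giving species
that occupy roughly 15–30% of the landscape. The "true range" is
where suitability reaches `prevalence_threshold`, default 0.05 of
peak. The low cutoff is intentional: occurrences are sampled with
probability proportional to suitability, so every cell above a few
percent of peak has non-negligible occupancy, and the occupied area
(the 0.05 contour holds ~97% of the occurrence probability mass) is
the quantity a presence-only workflow can actually recover. A
50%-of-peak "core range" is *not* recoverable from presence data and
would make any recovery benchmark meaningless.

**Land cover.** A categorical raster whose classes follow fixed
standard-normal thresholds on the first climate layer plus small
seeded noise: the five permitted broadleaf forest classes share the
cool and middle part of the gradient and a non-forest class occupies
the warm tail (~15% at present). Because the thresholds are fixed in
climate units, a warm-shifted future monotonically converts forest to
non-forest — the mechanism by which land-cover masking amplifies
climate-driven range loss.

**Protected areas.** Footprints grow by random-walk accretion from a
seed cell, which guarantees rook-connectedness; sizes are uniform over
a configurable cell range and categories are drawn from the three
management classes (integral protection, sustainable use, indigenous
lands). The simulated PAs are placed independently of richness, so the
correct null-model outcome on synthetic data is "not effective".

What the generator does *not* emulate: geographic sampling bias
(records are unbiased given suitability), taxonomic error, coastline
and elevation structure, non-Gaussian or interacting niche responses,
dispersal limits, and PA placement that correlates with biodiversity
(real reserves are not random). Passing the recovery benchmark
therefore shows the pipeline's machinery is correct and internally
consistent — not that real-data applications reach the same accuracy.

## Climate space

Correlation-matrix PCA (each variable standardized by its present
mean and sd) because bioclim variables mix °C and mm; the retained
dimensionality is the smallest k with cumulative explained variance
≥ 0.95. Sign convention: the largest-magnitude loading of each axis is
forced positive, so results do not depend on the linear-algebra
backend. Cells that are nodata in any layer are excluded from fitting
and propagate as nodata through projection.

## Occurrence preparation

Thinning keeps one record per cell of a grid at twice the predictor
resolution (chosen uniformly at random, seeded); the operation is
idempotent. The environmental envelope is the per-axis min–max box of
the presence scores — rectilinear (BIOCLIM-style) and computed on the
PCA axes rather than raw variables so that restriction and modelling
share one space. Pseudo-absences are sampled uniformly *without*
replacement among cells outside the envelope and never on presence
cells; sampling switches to with-replacement (with a warning) only
when eligible cells run short. A flag (`inside=True`) instead samples
within the envelope for users who prefer placing pseudo-absences in
climatically suitable areas.

## Partitioning

The checkerboard path is taken when the post-thinning presence count
is ≥ 15. Candidate block sizes run from twice the predictor
resolution up to half the domain extent (eight geometric steps); for
each candidate the two-fold parity split is scored by (a) Moran's I of
the presence/pseudo-absence labels with inverse-distance weights
truncated at 5× the block size, (b) the Euclidean distance between
fold centroids in standardized predictor space, and (c) the SD of fold
record counts — all "lower is better", aggregated by unweighted rank
sum, ties to the smallest block. Candidates leaving an empty fold are
invalid; if all are invalid the split falls back to the random K-fold
(k = 3, sizes within one of n/k).

## Models, evaluation, ensemble

All five algorithms are probability-producing classifiers on the PCA
scores: GLM is an unpenalized binomial regression with linear and
quadratic terms; the MaxEnt-like model is the penalized-logistic
equivalent of MaxEnt's exponential model, fit on presences against
uniform background cells drawn from the study area (an approximation:
no hinge/threshold features); random forest (200 trees), an RBF SVM
with probability calibration, and a Gaussian-process classifier with
an RBF kernel complete the set. Hyperparameters are fixed defaults,
not tuned. Every stochastic learner takes an explicit seed.

Evaluation on held-out folds uses the Jaccard index at the fold's
max-Jaccard threshold, and the rank-based AUC (ties counted ½, equal
to the normalized Mann–Whitney U). Per-algorithm fold maps are
averaged *before* thresholding. The ensemble keeps algorithms whose
mean test Jaccard strictly exceeds the across-algorithm mean (all are
kept when scores are equal, e.g. a single algorithm) and averages
their maps unweighted. The species threshold is the max-Jaccard
threshold of the ensemble suitability at the occurrence and
pseudo-absence points (each point served as a test point once), with
ties broken to the lowest qualifying score; future maps reuse the
present threshold, since the future has no evaluation data. Per
scenario, the continuous map is the mean of the per-GCM ensemble maps,
binarized once.

## Range accounting

Land-cover masking keeps presence cells whose class is one of the five
permitted forest classes, each scenario using its own land-cover
raster. Areas are sums of per-cell areas — uniform on synthetic grids,
cosine-latitude-weighted for geographic grids. The stability rule is
strict: |Δarea| < 5% is "stable", a change of exactly 5% already
counts as loss or gain. Suitability change is the percent change of
the domain-wide *sum* of continuous ensemble suitability; the metric
is declared here because several definitions are in use — a
within-range mean can be obtained by passing the range as the mask
(ratios of sums and of means over the same mask coincide).

## Protected-area effectiveness

PAs are clipped to the biome mask first and then dropped if the
clipped area is below 50 km². The representation target is 100% for
ranges ≤ 1,000 km², 10% for ranges ≥ 250,000 km², and linear in
log(area) between (the logarithm base cancels). Attainment =
achieved/target × 100 is classified at ≥90 / ≥70 / ≥20% into
P / PP / G / NP; the classification is invariant to rescaling achieved
and target together. Protection is computed over the *union* of PA
footprints, so overlapping PAs never double-count.

The null model translates a PA's exact cell footprint to a uniformly
random position among all placements that keep every cell inside the
domain (no rotation or reflection; valid positions found by
convolving the domain mask with the footprint). The test statistic is
the mean per-cell richness inside the footprint (robust to PA size; a
summed-richness variant is available via `stat="sum"`), and
p = (1 + #{null ≥ observed})/(n + 1) with n = 999 replicates,
"effective" at p < 0.05 — i.e., observed richness at or above the 95th
percentile of the null distribution. With the add-one correction the
test is valid (type-I error ≤ α) even for spatially structured
richness, and ties (e.g., constant richness) correctly give p = 1.

## Problem sizes and determinism

The package's own validation runs use a 60×60 grid (≈ the linear
resolution of a regional study at 10-km cells) with three virtual
species of 200 presences each for recovery checks, and a 40×40 grid
for end-to-end reproducibility checks; both complete in minutes on one
CPU. Every stochastic stage derives its seed from the master seed and
a stage name (CRC32 mix), so a rerun of `run_pipeline` with one master
seed reproduces byte-identical tables and rasters, verified by SHA-256
manifest comparison.

## Known limitations

- The MaxEnt-like algorithm is a penalized logistic approximation,
  not a reimplementation of MaxEnt's feature classes.
- No dispersal constraints: future ranges assume unlimited ability to
  occupy newly suitable cells (and the land-cover mask is the only
  non-climatic filter).
- The geographic-grid area weighting assumes small cells; no
  reprojection is provided (inputs must be co-registered).
- The block-size optimizer evaluates the two-fold checkerboard only;
  buffered or environmentally clustered cross-validation variants are
  out of scope.
- Recovery benchmarks quantify machinery, not real-world accuracy
  (see the generator's non-goals above).
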