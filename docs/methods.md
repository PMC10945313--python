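# Methods

This note documents the models and procedures `rangegap` implements, the
parameters that matter, what the synthetic data does and does not emulate,
and the design choices made where the design was genuinely open.

## The synthetic study system

The generator produces everything the analysis consumes, with the
statistical structure the downstream stages assume, so every stage can be
validated against known truth.

**Climate.** Each variable is white noise smoothed with a Gaussian kernel
of scale `autocorr_scale` (in cells, default 5) and standardized to zero
mean, unit variance over valid cells — a cheap, controllable stand-in for
spatially autocorrelated bioclimatic surfaces. Six variables by default,
on a 50×50 (demo) or 80×80 (study) grid of uniform 25 km² cells, echoing
~5 km cells at 2.5-arcmin resolution near the equator; no geodesic area
computation is attempted on synthetic grids. Future scenarios add a uniform
shift to the first half of the variables (the "temperature-like" block;
+1 SD for the optimistic scenario, +2 SD for the pessimistic, defaults
chosen to produce the strong majority-of-taxa range losses characteristic
of pessimistic-warming assessments of range-restricted tropical taxa) plus
autocorrelated noise of SD 0.2.

**Virtual species.** Suitability follows the standard virtual-species
convention: independent Gaussian response curves per variable, multiplied
and rescaled so the best valid cell scores exactly 1. Optima are anchored
at a real cell's climate (the range is never empty by construction);
breadths are drawn uniformly from [0.6, 1.4] SD. The true range is
suitability ≥ 0.5; the endemism region — the calibration area — is the
range's bounding box dilated by 5 cells. Because of the rescaling, an empty
true range is only reachable with a cut above 1; the generator warns and
returns it.

**Occurrences.** Sampled without replacement, probability proportional to
suitability within the true range, with per-taxon counts drawn log-uniform
over [8, 518] (the realistic span for compiled records of rare endemics)
and capped at the range size. Survey bias is *not* modelled: real
occurrence compilations are road-, river- and museum-biased, so passing
recovery tests here show the chain works under ideal sampling, not that it
is robust to bias.

**Protected areas and land cover.** PAs are axis-aligned rectangles (side
2–8 cells) placed uniformly at random, with categories SPA/SUA/IT drawn by
configurable weights — placement is independent of richness, which is
exactly the null the effectiveness test should *not* reject more than ~5%
of the time. Land cover thresholds the same kind of autocorrelated field at
the (1 − forest_fraction) quantile (so the realized forest share matches
the target up to quantile discreteness), splitting non-forest cells into
two filler categories; default forest share 0.8.

## Axis reduction

PCA is fit by SVD of the standardized present-scenario cell × variable
matrix over valid cells. The number of axes kept is the smallest k with
cumulative explained variance ≥ `variance_target` (default 0.95).
Standardization constants and loadings come from the present only and are
reused to project futures — futures are never re-standardized, otherwise a
uniform climate shift would vanish from the predictor space. Sign
convention: each loading column's largest-magnitude entry is made positive,
so results are reproducible across linear-algebra backends. Constant
(zero-variance) layers are dropped with a warning before fitting. The fit
uses the whole valid mask rather than the union of calibration areas; this
is configurable by passing a masked stack.

## SDM fitting and evaluation

* **Pseudo-absences**: uniform random background within the calibration
  area excluding presence cells, ratio 1:1 (configurable). Uniform
  background is the most common default when true absences are unavailable.
* **Partitioning**: checkerboard for ≥ 15 unique occurrences — fold =
  (⌊r/b⌋ + ⌊c/b⌋) mod 2, block size defaulting to calibration-width/10
  (min 2) — is a pure function of cell coordinates, which the tests
  exploit. If a fold ends up with no presences the block is halved and
  retried; at block 1 the taxon falls back to k-fold with a warning.
  K-fold (k = 5 capped at the occurrence count) assigns presences and
  absences round-robin after shuffling, so folds are balanced in both
  classes.
* **Metrics**: AUC by the rank (Mann–Whitney) formulation with ties
  counting one half; Jaccard maximized over candidate thresholds, the
  candidates being the unique evaluation scores (the maximum over all of
  [0, 1] is attained at one of them, which the oracle tests verify by
  dense sweep).
* **Ensemble**: algorithms with mean threshold-maximized Jaccard at or
  above the across-algorithm mean are averaged cell-wise. "At or above"
  (with a 1e-9 floating-point tolerance) rather than strictly above, so the
  retained set is provably non-empty even when all algorithms tie. The
  selection metric is configurable to AUC.
* **Estimators**: a regularized logistic regression (GLM family;
  scikit-learn, C = 1, L2) and a Gaussian environmental envelope fitted to
  presences only (Mahalanobis density exp(−d²/2) with a regularized,
  variance-floored covariance). These represent the discriminative and
  profile families of SDM algorithms; the registry accepts any object with
  `fit(X, y)` and `score_samples(X)`.
* **Scaling across scenarios**: each algorithm's raw present scores are
  min-max scaled to [0, 1] over calibration cells. Future surfaces are
  scaled with the *present-fit* bounds (clipped to [0, 1]), not their own
  extrema — rescaling each scenario by itself would hide an absolute loss
  of suitability, the very signal the study measures. This mirrors the
  coefficient-reuse logic of the axis reduction.

## Ranges, richness, area change

The binarization threshold is selected once per taxon on present evaluation
data (ties broken toward the smallest candidate) and reused for that
taxon's futures, keeping present/future ranges comparable. Cells compare
with ≥, so a cell exactly at the threshold is suitable. The forest mask is
applied after binarization (configurable in principle; masking the binary
map keeps threshold selection independent of land cover). Floodplain-
restricted taxa have future ranges clipped to their present range. Area
change is 100 × (future − present)/present; a loss above 99% is flagged as
total loss. Richness is the plain cell-wise count of binary ranges.

## PA effectiveness null model

Relocation is rigid translation only — no rotation or reflection, because
the test is defined as preserving size, shape *and orientation* — with
rejection sampling until every translated cell lies inside the study area
(cap 10,000 attempts; a PA that cannot be placed is flagged untestable and
excluded, not fatal). Relocated footprints may overlap real PAs or each
other (a pure translation null; configurable in principle). Effectiveness
uses the strict-greater counting rule — observed > null in ≥ ⌈0.95 n⌉ of
n = 999 randomizations — so ties count against effectiveness, the
conservative reading. The add-one permutation p-value is reported
alongside; the two can disagree only exactly at the boundary. Each PA draws
from a stream seeded by (global seed, CRC32 of its id), so results are
reproducible and independent of processing order, and two PAs with the same
id and footprint get identical null draws regardless of category label.

Calibration: on 200 random PAs over a richness field generated
independently of PA placement, the flagged fraction lands near the nominal
5% (the tests accept [0.01, 0.10], covering discreteness of the counting
rule and the spatial autocorrelation of the field).

## Gap analysis

The target curve interpolates linearly in log₁₀(area) between the two
standard anchors — 100% at 1,000 km² and 10% at 250,000 km² — and
saturates outside them; the interpolation form is the standard
area-scaled-target construction. Achieved representation divides range
cells inside the cell-level union of the scenario's PA footprints
(overlaps counted once) by total range cells. Category boundaries are
inclusive per their definitions: attainment ≥ 90 is Protected, exactly 20
is Gap, exactly 0 (or an empty range — a taxon with no suitable area in a
scenario is always Not protected) is Not protected. Attainment above 100%
is reported as-is; categories saturate at Protected. Range area for target
setting uses the same post-masking binary range used everywhere else.

## Problem sizes and determinism

The bundled demo (50×50, 12 taxa, 60 PAs, 999 randomizations) finishes in
seconds; the analysis scripts use 80×80, 20 taxa and 150 PAs, sizes at
which every spatial behaviour of interest (blocked folds, autocorrelation,
nested PA unions) is expressed while a full run stays under a minute on one
CPU. All randomness descends from a single seed through named CRC32-derived
substreams (`derive_seed`), so reruns are byte-identical, which the test
suite asserts on the demo's CSV outputs.

## Known limitations

* Synthetic landscapes are stationary Gaussian fields: no rivers, coasts,
  elevation gradients or dispersal barriers, and the endemism region is a
  bounding box, not a biogeographic polygon.
* Occurrence sampling is suitability-proportional and unbiased; real
  compilations are not.
* The two shipped estimators bracket, but do not reproduce, the behaviour
  of Maxent, random forests, SVMs or Gaussian-process SDMs; conclusions
  about algorithm-specific behaviour require plugging those in.
* Thresholds are evaluated on the same presences/pseudo-absences used for
  fitting the final maps (after cross-validated metric estimation), as is
  conventional; threshold uncertainty is not propagated.
* No dispersal constraint or connectivity metric: future ranges assume
  unlimited (or for floodplain taxa, zero) dispersal.
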