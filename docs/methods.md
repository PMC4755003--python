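# Methods

This note records the models, parameter choices and numerical conventions
behind `tilquant`, and what the synthetic generators do and do not
emulate.

## Image pyramid and tissue detection

Slides are represented as four-level pyramids L0…L3 with an integer
downsample factor between consecutive levels (default 4, so L3 is 1/64 of
L0 per axis; typical of slide-scanner pyramids).  Levels are produced by
block-mean pooling; partial edge blocks average over their actual area,
so the global mean intensity is preserved exactly.  The physical scale is
carried as microns per pixel at L0 (default 0.5 µm/px, a common 20×
scan resolution).

Tissue is found on L3.  The image is tiled into half-open blocks (default
16 px on L3 ≈ 0.5 mm of tissue); a pixel is background iff it is both
bright (Rec. 709 luminance ≥ 220/255) and nearly grey (HSV saturation ≤
0.08) — the standard white-space signature of an H&E scan, which keeps
even pale eosin-only stroma in play because stained tissue is saturated.
A block counts as tissue when ≥ 25 % of its pixels are non-background.
Partial edge blocks are analysed, not dropped, with fractions taken over
their actual area.  All three thresholds are configurable
(`tissue.t_lum`, `tissue.t_sat`, `tissue.min_fraction`); they are
declared defaults, not values fitted to any dataset.

Coordinates are 0-based, x rightward / y downward, rectangles half-open;
a block maps to L0 by scaling its rectangle by factor³ and clipping,
which preserves disjointness.

## Stain separation and nucleus segmentation

Optical density per channel is OD = −log₁₀((I+1)/256); the +1 offset
keeps OD finite at I = 0 and puts pure white at OD ≈ 0.  The 3-channel
OD vector of each pixel is resolved onto two fixed stain direction
vectors (Ruifrok-style haematoxylin (0.650, 0.704, 0.286) and eosin
(0.072, 0.990, 0.105), unit-normalised, overridable in config) by least
squares, and concentrations are clipped at zero.

Detection operates on the haematoxylin raster.  Background and noise are
estimated on a coarse grid (64-px cells): the 25th percentile estimates
the nucleus-free background level (robust as long as nuclei cover less
than ~75 % of a cell) and 1.4826·MAD the pixel noise, floored at 0.02 OD
so a perfectly flat synthetic background cannot produce a degenerate
threshold.  Both maps are bilinearly interpolated to full resolution and
pixels above background + 3σ form the nucleus mask.

Touching nuclei are split by a watershed on the (lightly smoothed,
σ = 1 px) distance transform.  Seeds are its h-maxima with h = 1 px —
a flat ridge inside an elongated nucleus yields one connected seed
rather than a chain of spurious peaks — and seeds with centroids closer
than 5 px are merged.  Components outside the area gate [15, 2000] px²
(at 0.5 µm/px: roughly a small lymphocyte to a very large or doubled
nucleus) or with solidity < 0.7 are discarded.

Each component is summarised by its moment-equivalent ellipse.  Pixels
are treated as unit squares, so the coordinate covariance carries a
+1/12 term per axis; semi-axes are 2·√(eigenvalues), which makes a
filled w×h rectangle yield exactly the continuous-moment axis ratio and
a disc of radius r an ellipse with a ≈ b ≈ r.  Single-pixel components
receive the declared floor a = b = 0.5 px instead of an error.  The
8-value feature vector is: area, log₁₀ area, ellipticity 1−b/a,
semi-major axis, mean and SD of interior haematoxylin OD, mean interior
eosin OD, and a local-contrast feature (mean haematoxylin OD of a
2-px dilated ring minus the interior mean, negative for dark nuclei on
pale background).

Whole-slide runs process tissue blocks with an 8-px overlap margin;
duplicate detections across block boundaries (centroids < 4 px apart)
are merged keeping the larger object, so catalogue content is invariant
to block enumeration order.

No edge correction is applied at tissue boundaries anywhere in the
pipeline; densities of cells near a boundary are biased low.  This is a
known, documented limitation.

## Cell classification

A three-way SVM with RBF kernel, one-vs-one decision structure, features
standardised by training-set mean and SD.  C ∈ {10⁻¹…10³} and
γ ∈ {10⁻³…10¹} are chosen by stratified 5-fold cross-validated grid
search with a fixed fold seed, so the same data and seed always select
the same model.  Each class needs ≥ 50 training examples; the intended
operating point is ~1,000 per class.  Objects with non-finite features
are labelled `unclassified`, excluded from metric denominators and
counted in the run log.  Adipocytes are not separately detected; weakly
staining large objects fall to whichever of the three classes the
training set supports (in practice stromal).

## Spatial density metrics

The per-cell density estimator is the classical k-NN density: with d₍k₎
the Euclidean centroid distance (converted to mm) to the k-th nearest
*same-class* cell, self excluded, D = k/(π·d₍k₎²) — the count inside the
disc that just reaches the k-th like-class neighbour.  k = 50 by
default.  Distance ties cannot change d₍k₎, so no tie-break affects the
density value.  A cell of a class with ≤ k members carries no estimate,
and that class's density summaries are reported missing rather than
computed at reduced k (logged).  An alternative convention (mean of the
k distances) would be monotonically related but numerically different;
per-unit odds ratios are therefore not comparable across conventions.

The 15 sample metrics are the three class counts, three fractions
(unclassified cells excluded from denominators) and per class the
min / median / max of the defined per-cell densities.  Patient-level
aggregation sums counts, recomputes fractions from pooled counts, and
pools per-cell density estimates across slides *before* taking
min/median/max; densities themselves are always computed within a
single slide.  Density fields for contour display evaluate the same
formula from grid nodes to the k-th nearest cell.

## Cohort statistics

Logistic models are fitted by maximum likelihood (statsmodels `Logit`,
IRLS/Newton).  Reporting is per term: OR = exp(β) with Wald 95 % CIs and
p-values — Wald rather than profile intervals, matching the
OR + CI + p reporting convention of clinical tables.  All analyses are
complete-case with the dropped-row count recorded.  Constant and
collinear predictors are flagged and excluded (not silently estimated);
perfect separation is flagged with no estimates reported.

Modelling scales: absolute counts enter as log₁₀(count+1) (offset keeps
zero counts finite), densities as log₁₀, fractions raw.  The 15-metric
univariate screen reports nominal p-values; a Bonferroni column is
emitted for information only, with no correction applied to inference.
Backward stepwise elimination starts from the full multivariate fit and
repeatedly removes the largest-p term at p ≥ 0.05, refitting until all
survivors pass; exact p ties remove the lexicographically later column
name (documented, deterministic).  The clinically adjusted model adds
age (continuous), tumour size > 50 mm, node status, ER, HER2 (binary)
and grade as a single ordinal numeric term (dummy coding available via
`grade_coding="dummy"`).

The taxane-sequence interaction test compares
`pCR ~ metric + group + metric:group` to the model without the product
term on identical complete cases: LRT = 2(LL_full − LL_reduced) on 1 df,
with per-group single-predictor fits reported alongside.  The same
machinery supports the ER-status interaction; the modifier can multiply
either the log or the raw density scale by passing the transformed or
untransformed column (`transform=False`).

Paired change analysis defines Δ = log₁₀(post) − log₁₀(pre) median
lymphocyte density; Δ < 0 is a decrease, exact zeros count as no-change
and are logged.  The change table is waterfall-ordered (treatment
sequence first, Δ second).  pCR is modelled on continuous Δ and again
adjusted for the pre-treatment log density.

Two-group comparisons use the rank-sum test — exact enumeration when
both groups have ≤ 10 untied values, otherwise the tie-corrected normal
approximation; more groups use Kruskal–Wallis with the χ² reference.
Correlation matrices are pairwise-complete Pearson (≥ 3 pairs per
entry), with constant metrics flagged undefined.  Decile tables rank by
the metric, spread the remainder over the lowest bins and send tied
values to the lowest decile any of them would occupy, so bins can be
unequal in the presence of heavy ties.

## Synthetic data

**Tiles.**  Nuclei are placed by a homogeneous Poisson process (a Thomas
cluster process is available for clustering experiments), by default
kept non-overlapping by dart-throwing with a 2-px gap so that
segmentation accuracy is well-posed.  Classes are morphologically
distinct by construction: lymphocytes small/round/dark (mean semi-axis
3.2 px, haematoxylin OD 0.95), cancer nuclei large and pleomorphic
(7 px, OD 0.55, ellipticity up to 0.45), stromal nuclei elongated and
pale (axis ratio ~3.5, OD 0.35).  Rendering composites anti-aliased
ellipse absorbances over a textured pink stroma (eosin OD 0.25,
haematoxylin OD 0.05, Gaussian texture σ = 0.02) via Beer–Lambert and
the same stain vectors the deconvolution uses; white-space rectangles
have zero OD.  The ground truth lists every planted nucleus with flag
for tile-edge clipping.  The renderer does **not** emulate stain
variation between slides, scanner artefacts, out-of-focus regions,
overlapping nuclei by default, or non-nuclear haematoxylin uptake —
passing segmentation/classification tests on these tiles demonstrates
correctness of the operators, not performance on real stained tissue.

**Cohorts.**  Patients carry clinical covariates drawn independently
from published trial marginals (node-positive 49.3 %, taxane-first
50.6 %, tumour > 50 mm 19.9 %, grade 3.7/41.2/55.1 %, ER+ 68 %, HER2+
26.7 %).  The pre-treatment log₁₀ median lymphocyte density is
N(2.5, 0.4) — the real density scale is unrecoverable from published
odds ratios, so this is a declared realistic default (~300 cells/mm²
typical).  The paired change Δ is Gaussian with total SD 0.35,
correlated −0.6 with the pre-treatment level and shifted so 75.6 % of
patients decrease.  pCR is generated in one of two modes:

* *direction-conditional* (default): pCR probability 17.0 % after a
  density decrease and 6.7 % after an increase — the calibration that
  reproduces published conditional response proportions;
* *logistic*: logit(pCR) = logit(0.162) + β_dens·(L−μ) + β_Δ·(Δ−Δ̄)
  (+ optional taxane interaction and clinical effects), used for
  parameter-recovery, CI-coverage and power studies.

The other 14 metrics are generated from the latent density and a shared
log-cellularity factor, with noise calibrated to the published
correlations (density–fraction ~0.69; shared-cellularity count
correlation; cancer–lymphocyte fraction anticorrelation).  A
consequence worth knowing when interpreting screen simulations: the
min/median/max of one class's density distribution are order statistics
of the same draw and correlate at ~0.94, so a signal planted on the
median is inherited almost fully by its companions — the median then
dominates all *unrelated* metrics but wins the overall screen only by
plurality, just as the real study found maximum lymphocyte density to
be the runner-up.  Missingness (pre 18.6 %, post 8.6 %, pCR 1.3 %,
grade 22.2 %, receptors 11.9 %, pathologist score 39.5 % of those with
pre data) is applied last, independently of everything else — the
simulator has no informative missingness.  Pathologist TIL categories
are a noisy ordinal readout (tertiles of L + N(0, 0.25)).

## Problem sizes used in tests and the acceptance script

Oracle equivalence uses 50 random catalogues of up to 500 cells;
segmentation recovery one 1650-px tile (~500 nuclei); classifier
recovery 1,000 training and 300 held-out objects per class; CI coverage
500 cohorts of n = 600 (the 500-replicate version pins the Monte-Carlo
sd of the coverage estimate at ~1 percentage point, which the 93–97 %
band requires); LRT size 1,000 cohorts of n = 550; simulator
calibration one cohort of 20,000 (100,000 for the 0.5-point
baseline-rate check).  These sizes make every stochastic assertion a
≥ 4σ check under the binomial error of the replicate count.

## Known limitations

* No boundary correction for the density estimator; no support for
  proprietary scanner formats; no learning-based segmentation; no
  mitosis or texture features beyond the 8 listed.
* The SVM matches the contract (3-way nuclear-feature classifier), not
  any particular published weight set; absolute odds-ratio magnitudes
  per density unit are convention-dependent and not comparable across
  implementations.
* The cohort simulator draws covariates independently; real trials have
  covariate dependence (e.g., grade with ER status) that complete-case
  multivariate analyses would feel.
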