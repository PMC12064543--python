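# Methods

`ithrad` quantifies intratumoral heterogeneity (ITH) from a CT lesion and
its segmentation, and evaluates how well that quantity predicts distant
metastasis (DM) and distant-metastasis-free survival (DMFS). This note
documents the models, the numerical choices, and what the synthetic
validation does and does not establish.

## The ITH-score

Each in-mask pixel receives a vector of local radiomic features computed
on the square window of radius `r` (default 2, a 5x5 patch) intersected
with the mask. Per lesion, the feature maps are smoothed within the mask
(Gaussian, sigma = 0.22 x equivalent radius; see *Spatial regularization*
below), z-scored, and clustered with k-means (k-means++ initialization,
10 restarts, 300-iteration cap, seed-derived state). The resulting label
map partitions the tumor into k spatial habitats. With

- `V` — number of nonempty clusters,
- `n_i` — connected regions within cluster `i` (4-connectivity in 2D,
  6-connectivity in 3D, recorded in the result),
- `S_i,max` — area of the largest such region,
- `S_total` — tumor area in pixels,

the score is

```
ITH = 1 - (1/S_total) * sum_{i=1..V} S_i,max / n_i
```

It is 0 exactly when every habitat is one connected blob and grows toward
1 as habitats shatter into many comparable islands (the supremum over a
3x3 lattice is 0.95, attained by the two-label checkerboard). Scores are
computed for k = 2..5 (k up to 8 supported for single-k evaluation) and
concatenated — not averaged — into a 4-vector that feeds the risk model;
empty k-means clusters are simply dropped from `V`.

### Local feature set

Thirteen local features are implemented: first-order (mean, variance,
skewness, kurtosis, min, max, range, energy = windowed mean square,
16-bin entropy) and pair-based co-occurrence statistics averaged over the
four unit offsets (contrast, dissimilarity, homogeneity, correlation).
The *clustering default* uses the four intensity summaries (mean, min,
max, energy) only. This is deliberate: features that carry no habitat
signal but are spatially autocorrelated (skewness, kurtosis, GLCM
correlation) let a z-scored k-means lock onto coherent noise patches,
and edge-sensitive features (variance, contrast, entropy) make the
habitat *interfaces* emerge as their own cluster. On phantoms with known
habitats, clustering on the full set drops pixel agreement with ground
truth from ~0.96 to ~0.51; the intensity core recovers habitats at
0.95+ when textures are well separated. The full set remains available
through `LocalFeatureConfig(features=EXTENDED_LOCAL_FEATURES)`.

### Spatial regularization

Two steps keep pixel-scale noise from dominating the component counts:

1. in-mask Gaussian smoothing of each feature map before clustering, at
   a scale proportional to the lesion's equivalent radius
   (`0.22 * sqrt(area/pi)`), i.e. a fixed number of effective spatial
   cells per lesion regardless of size;
2. one 3x3 in-mask majority vote on the fitted label map, removing
   single-pixel speckle (ties keep the current label).

Without them, clustering any noisy lesion yields dozens of one- and
two-pixel islands and every tumor — homogeneous or not — scores near 1.
With them, habitat-free phantoms score < 0.2 in median across k = 2..5
while planted fragmentation is still recovered (Spearman ~0.88 between
true and computed ITH over a mixed 100-lesion cohort).

## Whole-ROI radiomics and feature filtering

The conventional radiomics path extracts a named per-lesion vector:
16 first-order statistics plus GLCM (7), run-length GLRLM (7) and
size-zone GLSZM (7) texture features on the lesion discretized to a
fixed bin count (default 32) over its in-mask range — 37 features with
the default configuration. 3D inputs are analysed on the largest-area
mask slice. No attempt is made to reproduce any specific extraction
tool's feature count numerically.

Filtering runs in a fixed order:

1. **Stability (ICC)** — features are re-extracted under a second,
   boundary-perturbed segmentation; two-way random-effects,
   absolute-agreement, single-measure ICC(2,1) per feature; keep
   ICC > 0.90.
2. **mRMR** — greedy MID ranking (mutual information relevance minus
   mean redundancy) on tertile-discretized features; score ties break
   lexicographically so the ranking is deterministic.
3. **Lasso** — L1-penalized logistic path; the penalty is chosen by
   stratified cross-validated deviance with the one-standard-error rule
   (strongest penalty within one SE of the minimum).

## Batch harmonization

`combat_harmonize` implements parametric empirical-Bayes ComBat
(location/scale model, normal prior on batch means, inverse-gamma on
batch variances, moment-matched, iterated to 1e-4), with no covariate
preservation term. Parameters are estimated on a designated fit subset —
by default the training split, so validation rows never influence the
estimate — and applied to all rows; each batch needs at least 3 fit
subjects, and constant features pass through with a warning. The
implementation agrees with `sva::ComBat` (R) to 1e-3 on shared fixtures.
Note that EB ComBat is *not* exactly idempotent: a second pass
re-estimates residual batch structure from finite samples, moving values
at the estimation-noise scale (about 0.04 sd at 200 subjects per batch).

## Risk models

All model flavours (clinical, conventional radiomics, ITH, combined) use
one recipe: a random-forest classifier with SMOTE minority oversampling
applied inside each training fold only, and sequential model-based
hyperparameter search (trees 50-300, depth 2-16, min leaf 1-10, feature
fraction 0.1-1.0) scored by stratified cross-validated AUC. The search
is a random initial design followed by expected-improvement proposals
from a random-forest surrogate; the default budget is 50 evaluations
with 10-fold CV. SMOTE synthesizes minority points as convex
combinations of a minority sample and one of its k = 5 minority nearest
neighbors. Clinical covariates are screened by univariate logistic
regression; covariates with p < 0.1 advance to one multivariate model
(odds ratios with Wald 95% intervals; separation and collinearity are
flagged, not raised). The combined model column-binds clinical
covariates, the ITH 4-vector, and an optional externally supplied
auxiliary score, aligned and validated on subject ids.

## Survival evaluation

- **AUC** — rank-based (Mann-Whitney) with midrank ties; model
  comparisons by DeLong's structural-components test, two-sided, no
  multiplicity correction.
- **Harrell's C** — pairs comparable when the earlier time is an
  observed event; risk ties count 1/2.
- **Brier / IBS** — inverse-probability-of-censoring weights from the
  Kaplan-Meier estimate of the censoring distribution (G(T-) for
  failures, G(t) for survivors); trapezoidal integration over [0, t_max]
  (left-constant below the first grid point), normalized by t_max. The
  default grid is the distinct event times up to the 80th percentile of
  follow-up.
- **Time-dependent AUC** — IPCW cumulative/dynamic estimator (cases:
  event by t; controls: beyond t).
- **Decision curves** — net benefit `TP/N - FP/N * p/(1-p)` with
  treat-all / treat-none references; thresholds 0.2-0.9 by default.
- **Calibration** — equal-frequency bins (bin count clamped to the
  number of distinct predictions).
- **Cutoff** — one cutoff, two groups: grid search over observed score
  values maximizing the two-group log-rank statistic, both groups at
  least 10% of subjects, ties resolved toward the lowest cutoff. The
  cutoff is learned on the training split and applied to validation; no
  cross-validation correction is applied to the maximally selected
  statistic, which overstates significance if the same data pick the
  cutoff and test it — a known caveat of outcome-driven cutpoints.
- **KM / log-rank** — product-limit curves and the k-sample log-rank
  test via lifelines.

Months are the time unit throughout; DMFS is months from surgery to DM,
censored at last follow-up.

## Synthetic cohorts: what they emulate

The generator builds single-lesion phantoms on a pixel grid: a disk mask
partitioned into `V` habitats by capacity-constrained multi-source
region growing, so that each habitat occupies its requested area share
(within 2% of the tumor area) in exactly the requested number of
connected fragments (same-habitat fragments are kept separated by a
one-pixel moat; equal-area splits make the ground-truth ITH available in
closed form, `1 - sum_i f_i / m_i^2`). Texture is an independent
Gaussian random field per habitat (default noise sd 5 HU, correlation
length 2 px) around evenly spaced habitat means (35 HU apart), plus a
smooth center-to-rim enhancement gradient (18 HU) shared by the whole
lesion — venous-phase lesions are not flat, and this large-scale
structure is what keeps a habitat-free tumor from fragmenting under any
clustering. Scanner batches act as image-level location/scale shifts;
a second segmentation per lesion comes from perturbing the mask's signed
distance field by a bounded smooth random field.

Survival follows an exponential proportional-hazards model: the
log-hazard loads on true ITH (default beta 1.5) and optionally on the
cystic/necrosis indicator and T stage; the baseline hazard is 0.015 per
month; censoring is the minimum of uniform dropout on (0, 2*horizon) and
a 60-month administrative horizon. The high-ITH phenotype prevalence
defaults to 0.303, a typical pooled DM rate for surgically resected
retroperitoneal sarcoma; covariate mixes (T-stage distribution,
cystic/necrosis rates by phenotype, age, sex) follow the margins seen
in such cohorts. Imageless cohorts (`with_images=False`) carry the
closed-form ground-truth ITH instead of a realized partition, making
large survival-only simulations cheap.

Not emulated: CT physics (beam hardening, partial volume, contrast
kinetics), 3D acquisition anisotropy, multi-phase imaging, multifocal
disease (one lesion per subject by default), non-exponential baseline
hazards, and informative censoring. Passing tests on these phantoms show
the pipeline recovers planted structure under its own generative
assumptions; they do not certify performance on patient data.

## Problem sizes in the test suite

The default test run keeps simulations at desk scale: phantom grids of
32-48 pixels (roughly 500-1500 in-mask pixels), cohorts of 100-800
subjects (2000 for distributional checks, imageless), 10 replicates for
ordering/stratification properties, and model-search budgets of 5-8
evaluations with 5-fold CV inside tests (the library defaults remain
50 evaluations / 10 folds). The DeLong cross-check uses a 10,000-rep
paired bootstrap at n = 60.

## Known limitations

- 2D analysis is the default; full-3D feature extraction and component
  counting are supported but lightly exercised.
- The per-pixel feature set is intentionally small and intensity-led;
  lesions whose habitats differ in texture but not attenuation need the
  extended set (and benefit less from the intensity-core default).
- The RF's probabilities are used as risk scores without recalibration;
  the IBS converts them to survival forecasts through a proportional
  exponential model calibrated to the cohort event rate.
- Outcome-driven cutoffs are maximally selected; interpret their
  training-split log-rank p-values with care.
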