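# Methods

`ecrad` implements a contrast-enhanced-CT radiomics analysis for predicting
chemoradiotherapy response in esophageal carcinoma, exercised end to end on
a synthetic cohort generator because no clinical image set is distributed
with it. This note documents the models, the parameters that matter, the
numerical conventions, and what the synthetic experiments do and do not
demonstrate.

## Pipeline

1. **Preprocessing.** Each volume is resampled to isotropic 1×1×1 mm voxels
   (cubic spline for intensities, nearest-neighbour for masks). ROI voxels
   are then quantized to a finite gray-level range:

       V(x) = floor( 2^k · (I(x) − min_Ω I) / (max_Ω I − min_Ω I) ),

   with Ω the contoured ROI and the maximum clamped to `2^k − 1`, so the
   output occupies exactly `2^k` levels. All reported analyses use
   `k = 4` (16 levels).

2. **Feature extraction.** A pinned 214-feature inventory — 60 3D + 154 2D —
   built from four families (shape, histogram, gray-level texture matrices,
   transform filters). The 2D branch operates on the largest axial
   cross-section of the resampled mask, with quantization recomputed over
   that section's pixels.

3. **Reproducibility filtering.** Every feature is computed from both
   observers' contours and screened with a two-way mixed-effects,
   single-measure, absolute-agreement ICC; features with ICC < 0.8 are
   dropped.

4. **Univariate screening.** Kruskal–Wallis tests on three contrasts
   (responders CR+PR vs nonresponders SD, SD vs PR, SD vs CR) at α = 0.05
   with raw p-values (no multiple-testing correction, by design), plus ROC
   analysis (Mann–Whitney AUC, DeLong SE, normal 95% CI, Youden cut-off)
   for main-contrast hits and DeLong tests between AUCs. The positive
   class is the nonresponder group, so cut-off side ">" reads "above the
   cut-off indicates a nonresponder".

5. **Modeling.** 37 train / 12 test stratified split (5 test
   nonresponders). Per algorithm (RBF-SVM, single-hidden-layer MLP),
   wrapper-based backward feature elimination scored by stratified 10-fold
   CV accuracy, then 10-fold CV metrics from pooled out-of-fold
   predictions, a McNemar comparison of the two models' out-of-fold
   predictions, and hold-out evaluation with training-set standardization.

## Feature inventory

The manifest (`ecrad.features.manifest`) is the single source of truth:

| branch | families | count |
|---|---|---|
| 3D | 4 shape + 6 histogram + 19 GLCM + 13 GLRLM + 13 GLSZM + 5 NGTDM | 60 |
| 2D | 6 histogram + 9 GLCM + 13 GLRLM + 13 GLSZM + 5 NGTDM + 10 GLGCM + 18 LoG + 80 Gabor | 154 |

Conventions:

* **GLCM** — symmetric, distance 1, accumulated over 4 (2D) / 13 (3D)
  directions into a single matrix (the common toolbox convention).
* **GLRLM** — features computed per direction, averaged over directions.
* **GLSZM** — zones are connected components of equal level with
  8-connectivity (2D) / 26-connectivity (3D).
* **NGTDM** — full 8/26 neighbourhood; every in-mask voxel with at least
  one in-mask neighbour contributes.
* **GLGCM** (2D) — joint histogram of quantized level × Sobel gradient
  magnitude (16 bins, min–max over interior pixels, i.e. pixels whose full
  3×3 stencil lies in the ROI).
* **LoG** (2D) — Gaussian–Laplacian at σ ∈ {1.0, 2.0, 2.5} mm (fine,
  medium, coarse texture); six first-order statistics of the filtered
  in-mask values per σ.
* **Gabor** (2D) — 5 scales × 8 orientations (θ = (o−1)π/8). Center
  frequencies are log-spaced over 0.05–0.4 cycles/pixel (the stated band;
  exact power-of-two spacing cannot place 5 scales in that band), with
  1-octave bandwidth. Per filter, MSA = mean magnitude of the complex
  response over in-mask pixels, and MSE = Shannon entropy (bits) of the
  16-bin magnitude histogram — magnitude summaries chosen because a mean
  amplitude / histogram entropy pairing matches the reported scale of such
  features (thousands for MSA, ≈1 for MSE).
* Gray-level weights in run/zone/gradient features use `i + 1` (levels
  start at 0; the shift keeps low-gray emphasis finite).
* Degenerate-input conventions: zero-variance skewness/kurtosis/correlation
  → 0; `0·log 0` → 0; zero NGTDM denominators → 0; a flat ROI quantizes to
  level 0 with a warning. These guarantee every feature vector is finite.

Ambiguities resolved as package design choices: the quantization-then-
features order is resample → quantize (quantized levels are not
meaningfully interpolatable); 2D quantization uses the section's own
min/max; kurtosis is Pearson (non-excess); histogram features appear in
both branches.

## Statistics

* **ICC** — two-way layout mean squares: `ICC = (MSR − MSE) / (MSR +
  (k−1)·MSE + k·(MSC − MSE)/n)` with k = 2 raters; zero total variance is
  reported as 1 (trivial perfect agreement). Cross-checked against
  `pingouin`'s ICC(A,1) in the test suite. Threshold comparison is
  `ICC ≥ 0.8`.
* **Kruskal–Wallis** — tie-corrected rank H, chi-square reference (via
  `scipy.stats.kruskal`); all-identical inputs return (0, 1).
* **AUC / DeLong** — the Mann–Whitney pair-counting estimator with ties
  counting ½; variance and paired tests from the placement-value
  (structural-component) covariance. The 95% CI is AUC ± 1.96·SE clipped
  to [0, 1] (the normal approximation; no CI method is prescribed beyond
  reporting an SE). Cut-offs are searched over midpoints of adjacent
  observed scores, maximizing Youden's J with ties broken toward higher
  sensitivity.
* **McNemar** — exact two-sided binomial p for b + c < 25, chi-square with
  continuity correction otherwise (via `statsmodels`); b = c = 0 gives 1.
* **CV metrics** — per-class TP-rate, FP-rate, precision and F-measure are
  support-weighted averages from the pooled out-of-fold confusion matrix
  (so weighted TP-rate ≈ accuracy, matching the reporting style); MCC from
  the same matrix with zero factors → 0; AUC from pooled out-of-fold
  scores.

## Classifiers and selection

Hyperparameters are fixed, not tuned (only the wrapper search is a search):
SVM = RBF kernel, C = 1, γ = 1/n_features; ANN = one hidden layer of
⌈(n_features + 2)/2⌉ logistic units, seeded LBFGS with a 400-iteration cap.
Features are z-scored inside each fit using training-fold statistics only.

The wrapper is greedy backward elimination: from the current set, drop the
feature whose removal maximizes 10-fold CV accuracy (ties drop the
later-manifest feature) and return the best subset encountered (ties favor
the smaller subset). Selection runs once on the training split, *outside*
the CV loop used for reporting — the sequence of the analysis this package
reproduces. That ordering optimistically biases the reported CV metrics;
it is documented rather than "fixed", and the untouched hold-out split is
the unbiased check. To keep the search tractable the pipeline hands the
wrapper the top-12 screened features (configurable) rather than all
reproducible ones.

## Synthetic cohort generator

Each case is a random ellipsoid (radius 8–15 mm, semi-axes jittered ±25%,
random orientation) in a 64×64×40 volume at 0.97×0.97×2.5 mm voxels.
In-mask intensity = class mean (60 HU) + a Gaussian random field (white
noise smoothed at the class correlation length) passed through the
monotone skewing map `(exp(s·z) − 1)/s`, scaled to the heterogeneity SD
(15 HU), + independent noise (SD 5 HU). Class contrast is carried by the
texture, not the geometry: responders have symmetric histograms
(s = 0, correlation length 4 mm), nonresponders right-skewed ones
(s = 1.2, 8 mm) — the direction in which higher skewness marks
nonresponders. Default cohort: 33 responders (CR/PR alternating, CR
first; PD never generated) and 16 SD nonresponders.

Two further properties make the cohort statistically realistic where the
analysis is sensitive to them:

* **Between-patient variability.** Per-case texture parameters are
  jittered around the class values (lognormal, σ = 0.25, on correlation
  length, skew strength, heterogeneity and noise; Gaussian SD 10 HU on the
  mean). ICC is a ratio of between-case to total variance; a cohort whose
  cases were statistically identical would make that ratio degenerate.
* **Low-contrast background.** Background is constant 45 HU + noise
  (≈15 HU below the tumor), emulating peritumoral soft tissue. Features
  are mask-restricted, but a perturbed observer contour may include a thin
  background shell, and the ROI min–max quantization is sensitive to its
  intensity.

The second observer is emulated by adding a smooth random field (amplitude
= the perturbation magnitude in mm, 3 mm correlation) to the signed
distance of the mask boundary and re-thresholding — correlated local
dilations/erosions whose expected Dice against the original decreases with
magnitude. The default magnitude is 1 mm; magnitudes are calibrated only
to exercise the ICC filter, since no quantitative description of the
clinical inter-observer disagreement is available.

**What the generator does not emulate:** CT anatomy, contrast kinetics,
partial-volume and beam-hardening effects, non-ellipsoidal/infiltrative
tumor shapes, or any relationship between geometry and response. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
calibrated (exact matrix counts, type-I error near nominal, power against
planted effects, monotone ICC behavior) — not that the clinical effect
sizes or reported AUCs are recoverable.

## Problem sizes

The test suite runs reduced cohorts (6–16 cases, 48×48×16 volumes, tumors
6–9 mm) for unit and determinism checks, and study-scale tumor geometry
(default spec, 16 cases) for the ICC behavior checks, where realistic
between-case spread matters. Statistical calibration checks run directly
on sampled feature tables (49 or 37 cases, 200 label permutations, 5–20
model seeds). `scripts/acceptance.py` runs the full default 49-case
cohort end to end.

## Known limitations

* The 214-name inventory is pinned by family counts; the original study's
  full feature list is not public, so individual definitions within each
  family follow the standard literature forms rather than a published
  per-feature table.
* Wrapper selection outside the CV loop inflates internal CV metrics (see
  above); with strongly separable synthetic classes both classifiers
  saturate near accuracy 1.0.
* DeLong p-values and the AUC CI rely on asymptotic normality; at n = 49
  with AUCs near 1 they are approximate.
* The 2D branch depends on the largest-section choice; a contour
  perturbation can move that section by a slice or two, which is the main
  reproducibility cost for 2D features.
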