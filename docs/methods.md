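# Methods

`pathosig` implements a biopsy digital-pathology signature for
predicting poor response (PR) to neoadjuvant chemoradiotherapy (nCRT)
in locally advanced rectal cancer, together with a synthetic histology
generator that makes every stage testable without patient slides.  This
note records the model, the defaults and why they were chosen, the
numerical decisions, and what the synthetic experiments do and do not
demonstrate.

## The pipeline

1. **Tiling.** Pathologist-annotated tumor polygons on a source image
   (nominally ×400 magnification) are cropped to their minimum
   axis-aligned bounding rectangle, downsampled ×2 by block mean
   (→ ×200), and cut into a non-overlapping grid of 512×512 tiles
   anchored at the crop origin.  Partial border tiles are dropped, not
   padded, so every tile honors the 512×512 contract.  Tile selection
   has two modes: `explicit-list` replays a manual (pathologist-style)
   choice; `tissue-fraction` is an automated surrogate keeping tiles
   whose fraction of non-background pixels (luminance ≤ 220 of 255) is
   at least 0.8.
2. **Texture features.** Each tile is converted to luminance
   (0.299 R + 0.587 G + 0.114 B), quantized into G = 64 uniform bins
   over the fixed range [0, 255], and summarized by gray-level
   co-occurrence matrices (GLCMs) at distances {1, 2} pixels and
   directions {0°, 45°, 90°, 135°} (offsets (0,d), (−d,d), (−d,0),
   (−d,−d)), symmetrized and normalized.  Thirteen Haralick statistics
   per GLCM — energy/ASM, contrast, correlation, variance, inverse
   difference moment, sum average, sum variance, sum entropy, entropy,
   difference variance, difference entropy, IMC1, IMC2 — give
   13 × 2 × 4 = **104 features per tile**.
3. **Feature selection.** Features are z-scored with primary-cohort
   statistics and fed to an L1-penalized logistic regression over a
   log-spaced penalty grid; the penalty is chosen by 10-fold
   cross-validated binomial deviance with folds **grouped by patient**
   (all tiles of a patient share a fold) and stratified by label.
   Features with nonzero coefficients at the chosen penalty are
   retained.
4. **Tile classifier.** An RBF-kernel SVM on the selected features,
   hyperparameters grid-searched by stratified 5-fold CV on AUC
   (C ∈ 2^{−3..7}, γ ∈ 2^{−9..1}, exponent step 2), refitted with Platt
   (sigmoid) probability calibration estimated within CV.
5. **Pathology score.** A patient's characteristic is the arithmetic
   mean m of their selected tiles' PR probabilities; a univariable
   logistic regression of outcome on m over the primary cohort defines
   the pathology score s = σ(β₀ + β₁ m).  The transform is strictly
   monotone, so patient ranking (and AUC) is that of m.
6. **Adjustment and evaluation.** A multivariable logistic model
   adjusts the score for age, gender, clinical T and N stage, and CEA
   level (references: male, T3, N0, CEA-normal).  Evaluation covers
   discrimination (ROC/AUC with stratified percentile-bootstrap
   B = 2000 or DeLong CIs; accuracy/sensitivity/specificity/F1 at the
   Youden-optimal primary-cohort threshold, reused on validation),
   calibration (decile calibration curve; Hosmer-Lemeshow χ² with
   g = 10 equal-frequency bins, df = g − 2), and clinical utility
   (decision-curve net benefit over thresholds 0.01–0.99).

### Assumptions worth stating

- **Tile labels are inherited from the patient outcome.**  No
  tile-level ground truth exists; on real data this injects label noise
  by design (not every tumor tile carries response-relevant texture).
- Patient-grouped CV folds for the LASSO prevent the leakage that
  plain tile-level folds would cause via within-patient correlation.
- The cohort split is stratified by outcome; primary size is
  ⌊n · 0.8⌋, so 151 patients split 120 / 31.

## Synthetic data

The generator emulates the study's data conditions at configurable
scale: tiles are fields of randomly oriented, anti-aliased elliptical
nuclei (hematoxylin-purple, ≈(90, 60, 130)) scattered by a homogeneous
Poisson process over an eosin-pink background (≈(230, 200, 220)), with
additive Gaussian speckle; rendering is at 2× supersampling and
block-mean reduction, so nucleus edges have fractional coverage.

Class structure: the PR class differs from non-PR by a nucleus-density
factor (1 + 0.5·effect_size) and 2·effect_size extra gray levels of
speckle.  At effect_size = 0 the classes coincide exactly.  A per-tile
lognormal density jitter (CV 0.15, both classes) stands in for
intra-class biological heterogeneity; without it, tile features
concentrate so tightly over 512² pixels that any nonzero effect is
trivially separable.

Cohort defaults follow the observed study composition: 151 patients,
PR prevalence 59/120 (the primary-dataset rate), 3–6 tiles per patient
(the study selected 667 tiles over 151 patients), covariates sampled
independently from the primary-dataset marginal frequencies (gender
80/120 male; T stage 3/49/68 for T2/T3/T4; N stage 23/77/20; CEA
68/52 normal/abnormal; age ~ N(55.7, 11.1²), clipped to [25, 90]).
Covariates are independent of outcome and of each other — the study
reports only marginals — so the synthetic multivariable model is null
for everything except the pathology score.

Reproducibility: one root seed; per-patient and per-tile RNG
substreams derived by counter (`SeedSequence(seed, spawn_key=...)`),
so any tile regenerates bit-identically in isolation and in any order.

**What the synthetic tests do not show.**  The generator reproduces
second-order texture contrast between classes, not histology: no
stain-deconvolution realism, no gland architecture, no scanner
artifacts, no annotation error, and its tile labels are exactly the
patient labels (no label noise).  Passing the recovery experiments
demonstrates the pipeline's statistical machinery end to end — it says
nothing about discrimination on real rectal-cancer slides.

## Numerical choices

- **Quantization** uses fixed global bins (k = ⌊v·G/256⌋), not
  per-image min–max, so per-tile brightness cannot leak into texture.
- **GLCM**: pairs with either pixel outside the image are excluded;
  counts symmetrized (C + Cᵀ) then normalized.  Natural logs with
  0·ln 0 = 0.  Degenerate single-level GLCM: correlation := 1,
  IMC1 := 0, IMC2 := 0 (the constant-image limit).  Sum variance is
  centered on sum average (modern convention; Haralick's original text
  centers on sum entropy).  Difference variance is the variance of the
  |i−j| distribution.
- **Penalty grid**: 50 log-spaced values from α_max =
  max|Xᵀ(y−ȳ)|/n down two decades.  The floor matters: the feature
  bank contains near-duplicate columns (correlations up to 1−6·10⁻⁸
  between, e.g., contrast and difference variance at the same offset),
  and exact L1 coordinate descent at weak penalties cycles between
  them almost indefinitely.  For the same reason the liblinear
  iteration budget is capped (200); approximate solutions on the
  overfitted end of the path do not affect the CV choice.  Penalty
  rule: minimum mean CV deviance by default; a 1-SE rule is available
  (`rule="1se"`) and yields visibly sparser sets.
- **Zero-selection fallback**: on null data the LASSO may retain no
  features; the pipeline then emits a constant prevalence model (flat
  signature, AUC 0.5 by the tie convention) rather than failing.
- **Perfect separation**: small cohorts with a strong classifier
  separate perfectly and the logistic MLE diverges; `fit_signature`
  falls back to a lightly ridge-penalized fit (penalty 1e-4) with a
  warning.  The score stays monotone in m, so discrimination metrics
  are unaffected.
- **Hosmer-Lemeshow**: χ²_{g−2} calibration applies to probabilities
  fitted on the same data; bins whose variance term vanishes are
  merged with a warning.  Validation cohorts too small for g = 10 get
  a reduced g (≥ 3) in the pipeline report.
- **Chi-square convention**: Yates continuity correction on 2×2
  tables (scipy's default, and the convention that reproduces standard
  published baseline tables); Fisher's exact test when a 2×2 table has
  an expected cell below 5; plain Pearson for larger tables.
- **Block-mean downsampling** (not subsampling): deterministic,
  alias-free; 8-bit outputs round half-to-even.

## Problem sizes used in the recovery experiments

The end-to-end recovery experiment uses 60 patients with 10–20 tiles
of 512² pixels each (~900 tiles) at effect_size 1 and an 80:20
stratified split; held-out patient-level AUC ≥ 0.9 is the qualitative
analogue of the published discrimination (0.930 primary / 0.877
validation).  The null experiment repeats the pipeline at
effect_size 0 across 10 seeds with 60 patients × 4–6 tiles of 128²
pixels — the null distribution of texture is scale-free, so smaller
tiles test the same property at a fraction of the rendering cost — and
checks that the mean held-out AUC lies in [0.35, 0.65].  The
planted-signal experiment (2 informative + 102 noise features, n = 500
tiles, 20 seeds) checks that the selector recovers both informative
features in > 90% of seeds.

## Known limitations

- The identity of the study's 17 selected features is not public; only
  the 104-feature construction and the selection machinery are
  reproducible, not the selected set itself.
- The published AUCs were computed on undeposited slides and cannot be
  reproduced; synthetic recovery is a property check, not a
  replication.
- Fisher's exact test is applied only to 2×2 tables; sparse r×c tables
  fall back to chi-square with a warning.
- The pseudo-WSI generator renders a square field and crops, which is
  wasteful for very elongated images.
- `explicit-list` tile selection replays manual choices but no tooling
  is provided for making them.
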