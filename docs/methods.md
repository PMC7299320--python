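# Methods

This note records the models, parameter choices and numerical conventions
behind `texomri`, and what the synthetic phantom does and does not emulate.

## Phantom model

Each case is a pair of 64×64 float images (16-bit-like dynamic range) with
one circular lesion (radius uniform on 8–13 px) fully inside the frame:

    pre  = B + 1_lesion · T_pre(class)  + ε_pre
    post = B + 1_lesion · (g·B + T_enh(class)) + ε_post

with background level B = 400, enhancement gain g = 1 (so the lesion gains
one background-level of signal after contrast), and i.i.d. Gaussian pixel
noise ε with σ = 20. The lesion textures T are stationary Gaussian random
fields: white noise smoothed by a Gaussian kernel whose σ is the
*correlation length*, rescaled to a target marginal variance, plus a constant
mean shift. The subtraction image post − pre therefore equals the
enhancement component plus independent noise.

Default texture parameters (correlation length px, variance, mean shift):

| field | positive class | negative class |
|---|---|---|
| pre-contrast | (2.0, 3600, 60) | (2.0, 3600, 60) |
| enhancement | (2.4, 3600, 0) | (1.6, 3600, 0) |

Two deliberate consequences:

* **The class contrast is textural, not additive.** The pipeline's own
  μ ± 3σ normalization is affine-invariant within the mask, so any constant
  class mean shift is removed exactly before a single feature is computed.
  A phantom that encoded its class effect as an additive enhancement
  difference would be erased by the pipeline it is meant to exercise. The
  contrast therefore lives in the correlation length of the enhancement
  field, which GLCM/GRLM/DWT features see directly; the
  `separated_config(s)` dial interpolates the negative class's enhancement
  parameters toward the positive class's (s = 0 no contrast, s = 1 default)
  and the median downstream AUC is monotone in s.
* **The phase ordering is built in.** The pre-contrast texture is identical
  across classes (no true pre-contrast effect); the post-contrast image
  carries the enhancement contrast diluted by the equally strong shared
  pre-contrast field; the subtraction image carries it undiluted. Hence
  separation: subtraction > post > pre by construction.

The seed ROI handed to the segmenter is the true lesion circle dilated by a
5 px margin (a 24-gon), standing in for an operator's loose hand-drawn
region.

What the phantom does **not** emulate: pharmacokinetic washin/washout, 3-D
lesion geometry and the "slice of maximum diameter" selection, partial-volume
and bias fields, inter-phase misregistration, and scanner-specific intensity
distributions. Passing tests therefore demonstrate that the pipeline
recovers class structure of this textural kind at these sample sizes — not
clinical performance on real DCE-MRI.

## Delineation

Otsu's threshold is computed on a 256-bin histogram over the ROI's observed
min–max range; the reported threshold is the interior bin edge maximizing
between-class variance, lowest edge on ties (this matches scikit-image up to
its bin-center convention, which the tests pin down). Foreground is *above*
threshold, since lesions enhance. Erosion and dilation both use a disk of
radius 2 by default (the element geometry is a free choice; square is
available). The final mask is intersected with the ROI so dilation cannot
leak outside the operator's region. Failure at any stage (nothing above
threshold, erosion removes everything) raises a diagnostic error rather than
returning an empty mask.

## Quantization

Masked pixels are clipped (not discarded — neighbor geometry must survive)
to [μ − 3σ, μ + 3σ] and floor-mapped onto 2⁸ levels with the top edge
inclusive. σ = 0 ROIs map to the middle level and are flagged degenerate.
Each phase is normalized with its own μ, σ.

## Texture features

GLCMs are accumulated sparsely over pixel pairs whose both ends lie inside
the mask, symmetrized, and normalized; 256 gray levels are used directly
(no rebinning), which on small lesions yields sparse matrices — the sparse
representation makes this exact and cheap. The 19 statistics use natural
logarithms, 0·log 0 = 0, and the single information-measure-of-correlation
variant IMC1. Correlation is defined 0 when either marginal is degenerate.
Feature names carry the raw offset (`S(0,1) CON`); the per-distance
directional mean is `S(d,mean) NAME`. 19 × 4 distances × (4 + 1) = 380.

Run-length matrices trace maximal equal-level runs along 0°/45°/90°/135°,
truncated at mask boundaries; gray levels enter the low/high-gray weights as
level + 1 so level 0 has finite weight. 11 × 4 = 44.

The DWT operates on the mask's bounding box, outside-mask pixels filled with
the masked mean, padded to a multiple of 2⁴ so a 4-level decomposition is
always defined (this padding makes the level-reduction fallback unreachable
in normal use). Periodized orthogonal transforms (haar, db2, sym4) give
exact energy partition (Parseval, asserted to 1e−8). Per level the features
are the three detail-subband energies and the approximation energy, each
normalized by total image energy, plus the approximation mean: 5 × 4 × 3
wavelets = 60.

## Screening

Normality is tested per group with the Lilliefors-corrected KS test (naive
KS against N(x̄, s) is anti-conservative); both groups must pass at α = 0.05
for the pooled-variance *t* branch, otherwise Mann–Whitney (exact when
n₁n₂ ≤ 400 without ties, else the tie- and continuity-corrected normal
approximation). The screen keeps raw *P* < 0.05 — no multiplicity
correction, matching the workflow being reproduced; Benjamini–Hochberg is
available behind a flag. A vectorized implementation of the same gate + tests
(`screen_matrix_fast`, asymptotic rank-sum branch only) is used where
screening repeats inside every cross-validation fold; the tests assert it
matches the per-feature path.

2×2 cohort tables use χ² without continuity correction when all expected
counts are ≥ 5, otherwise Fisher's exact (point-probability, two-sided).

## Selection

The LASSO path minimizes (1/n) Σ logistic loss + λ‖w‖₁ on internally
standardized features, over 100 log-spaced λ spanning 4 decades below
λ_max = max|Xᵀ(y − ȳ)|/n (the KKT boundary of the all-zero solution).
The solver is liblinear coordinate descent (tol 1e−4, seeded); descent down
the grid stops early once the explained-deviance ratio saturates (change
< 1e−5 or ratio > 0.999), the standard path-termination rule, which matters
because radiomic features are massively collinear and near-unpenalized fits
on them are both slow and meaningless. λ is chosen by 10-fold
cross-validated deviance. `lasso_select` defaults to the minimum rule; the
**pipeline** defaults to the one-standard-error rule, a deliberate parsimony
choice: with n = 92 the minimum rule routinely admits 30–80 collinear
features, enough to destabilize any model that estimates per-class
covariances (QDA fits p(p+1)/2 parameters from ~40 samples). The 1-SE rule
keeps the subset small without touching the path itself.

## Classification

LOOCV throughout; features standardized with training-fold statistics only.
LRA is unpenalized maximum likelihood (iteration-capped under separation);
QDA is a hand-rolled Gaussian discriminant with ridge ε·trace(Σ)/p
(ε = 1e−6) added to each class covariance; SVM is RBF with C = 1 and the
1/(p·Var) gamma rule. Scores are class-1 probabilities (LRA, QDA) or signed
margins (SVM).

Two modes: `paper` cross-validates only the classifier (screening and
selection run once on the full cohort, mirroring the sequential workflow
description), `leakage_safe` re-runs both inside every training fold. On
null data paper mode is measurably optimistic (mean LOOCV AUC ≈ 0.6 vs
≈ 0.5 leakage-safe) — this is asserted as a property, and the null-calibration
acceptance check runs leakage-safe, since that is the mode under which
"chance means 0.5" is actually true.

## ROC statistics

AUC is the tie-corrected Mann–Whitney statistic (ties count ½), identical to
the trapezoidal area. Variances and the paired covariance come from DeLong's
structural components; the paired z-test follows. The 95% CI treats the AUC
as a proportion of concordant pairs with effective trial count
n_eff = AUC(1 − AUC)/var_DeLong and takes Clopper–Pearson limits — a
documented approximation of the "binomial exact" construction of the
clinical software this mirrors, isolated in one function, with empirical
coverage ≈ 95–98% at n = 92 (asserted within [90%, 99%]). The operating
point maximizes Youden's J with ties broken toward specificity.

## Problem sizes used in the test suite

The statistical-calibration checks run on scaled null cohorts chosen as the
package's own test design: 48×48 images with lesion radii 7–10 px (the null
properties are size-free), 92 patients for the screening-rate check,
46 patients for the leakage-safe null-AUC check (20 cohorts each), and 500
score-level cohorts of n = 92 for CI coverage. The phase-ordering check runs
the full default 92-patient, 64×64 pipeline.

## Known limitations

* The null screening-retention rate is a heavy-tailed estimator across
  cohorts: features within one cohort are strongly correlated, so single
  cohorts can retain 10–25% of features by chance; only the mean over many
  cohorts is near α.
* The "binomial exact" CI is an approximation (above); it is conservative.
* QDA degrades sharply when the selected subset grows beyond ~15 features at
  n = 92; this is a property of the model, surfaced honestly by the
  pipeline rather than patched.
* SVM decision values are order-invariant only to ~1e−3 (libsvm's SMO
  stopping tolerance).
* DICOM support is single-file read-only; no 3-D volumes, no registration,
  no bias-field correction, no probability calibration.
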