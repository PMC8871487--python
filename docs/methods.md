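# Methods

`radstab` studies how segmentation-outline variability propagates through
radiomic features into survival models. Because the question is about the
*pipeline* — outlines → features → reliability → prediction — the package
ships a synthetic-data generator that plays the role of the imaging cohorts
and of the probabilistic segmentation model, with known ground truth at every
stage. This note records the models, the defaults and why, the numerical
conventions, and what the synthetic setting does and does not establish.

## Lesion phantoms

A lesion is an ellipse (semi-axes `axes_mm`) whose radius is modulated by a
smooth random periodic function (`irregularity` × a low-harmonic Fourier
series), rasterized on a square pixel grid. The interior texture is a
correlated Gaussian random field (mean, SD, correlation length in mm); the
background is an independent noise field. Edge sharpness is controlled by
blending interior and background through a Gaussian-blurred mask
(`boundary_sharpness_mm`); a `(left, right)` pair blurs the two image halves
differently, which is used to test gradient-modulated perturbation. The truth
mask is defined by the noiseless geometry alone, so it is identical across
texture seeds.

Cohorts draw per-patient geometry and texture from population ranges
(defaults: semi-axes 4–14 mm, irregularity 0.05–0.25, texture SD 8–16 HU-like
units for CT-like phantoms, correlation length 2–5 mm, edge blur 0.5–3 mm,
per-patient mean intensity 20–80 over a −40 background). Wide between-patient
*geometry* and *intensity-level* variation combined with a shared *texture*
distribution is deliberate: it makes coarse shape/intensity summaries highly
reliable across outline variants while fine texture statistics are not, which
is the reliability spectrum observed with real inter-rater variability.

## Outline perturbation

Variant outlines threshold the signed Euclidean distance transform of the
source mask at a spatially correlated, zero-mean, unit-SD Gaussian field
scaled by `amplitude_mm`; the largest connected component is kept and holes
are filled. Amplitude 0 reproduces the source mask exactly. Variants whose
Dice overlap with the source falls below `min_dice` (default 0.6) are
redrawn, up to 10 attempts.

With `gradient_modulation` on, the field is multiplied by a weight inversely
related to the image-gradient magnitude *on the source outline*, propagated
along the boundary normal (nearest-outline lookup) so that the whole
displacement corridor of a boundary segment shares its weight. Fuzzy boundary
segments therefore receive systematically larger displacements, emulating
where human raters (and generative segmentation networks) disagree.

Defaults: 100 variants, amplitude 1.0 mm, noise correlation 5 mm, modulation
on. Amplitude was calibrated once, a priori, to a mean variant–source Dice of
≈0.95 — a realistic expert inter-rater level for small lesions — which also
yields a reliability spectrum qualitatively like clinical reports (median
feature ICC ≈ 0.85–0.9, a handful of features above 0.99, a substantial tail
below 0.75). "Manual" raters are k independent low-amplitude perturbations of
the truth (default 4 raters at 0.4 mm for the pipeline; reliability studies
that need a single reference use the truth itself).

## Survival generation

Event times are exponential with rate `baseline_rate · exp(xᵀβ)` where x are
internally z-standardized per-patient features computed from the *truth* mask
and image; censoring is the minimum of an independent exponential
(`censor_rate`) and administrative truncation. β defaults to
{mean intensity: 0.8, area: 0.6, major axis: 0.4} — signal on geometrically
and photometrically stable quantities, so that reliability-based feature
selection can recover predictive power by construction. Because both the
generator and the Cox fitter standardize internally, the fitted standardized
coefficient estimates β directly regardless of feature scale.

## Preprocessing

Square crops are centred on the reference-mask centroid. The box side is the
smallest even pixel count covering mean + 2 SD of the cohort's maximum lesion
diameters (capped at the image size). Exclusions apply in order: volume
(area × slice thickness, thickness default 1 mm) below 30 mm³; mask not fully
contained in the box; multiple connected components in the crop. Only the
frame is excluded, never the patient record. Cropping a *variant* mask at the
box edge can split it; the largest piece is kept.

## Features

Per frame: 16 first-order statistics, 8 2D shape descriptors, and 8 features
from each of GLCM, GLRLM, GLSZM and GLDM (56 total by default; 248 with
wavelets on, since the 48 intensity-based features are recomputed on the four
stationary-wavelet sub-bands). Conventions, stated because they matter and
are not universal:

- Discretization: fixed bin count (default 32) over the in-mask range;
  synthetic intensities have arbitrary scale so a fixed bin width is
  meaningless by default (both available). Constant regions map to level 1.
- GLCM: symmetric, distance 1, four 2D directions, features computed per
  direction then averaged. The direction set makes averaged GLCM/GLRLM
  features exactly invariant under 90° rotations.
- GLSZM zones use 8-connectivity; GLDM uses the Chebyshev-distance-1
  neighbourhood with an equality criterion (α = 0) and dependence size
  j = 1 + number of equal in-mask neighbours.
- Shape: perimeter from the marching-squares half-level contour after two
  passes of a 3-point moving average (the raw polygon overestimates smooth
  boundaries by ~7%; smoothing brings disks within ~1%). Axis lengths use
  the 4·√eigenvalue moment convention; elongation = √(λ_minor/λ_major),
  which equals the semi-axis ratio for an ellipse. Maximum diameter is the
  largest pairwise pixel-centre distance (via the convex hull).
- Kurtosis is reported as excess kurtosis (0 for a Gaussian). Degenerate
  conventions keeping values finite: GLCM correlation of a constant region
  is 1; skewness/kurtosis of a constant region are 0.
- Wavelets: single-level stationary transform, Coiflet-1, sub-bands named
  <row filter><column filter> (LH = low-pass along rows, high-pass along
  columns). Features with any non-finite value are dropped run-wide and
  logged.

## Reliability

ICC(1), the one-way random-effects intraclass correlation
(MSB − MSW)/(MSB + (k−1)·MSW), is computed per feature over a complete
lesions × outlines matrix; lesions missing any outline of the group are
dropped. A fully constant matrix returns 1 with a degeneracy flag rather
than NaN so signature logic stays total. ICC is computed per dataset/modality
tag and never pooled across modalities. Quartiles (Q1 most reliable) split
ties by feature name; remainders go to the outer quartiles first, so 10
features split 3/2/2/3. Signatures use strict thresholds: high ICC > 0.99,
low ICC < 0.75. The manual-vs-automatic comparison assigns quartiles from the
manual table and runs a paired Wilcoxon per quartile.

## Survival modelling

The Cox model maximizes the Breslow partial likelihood by Newton iterations
with step-halving (the penalized log-likelihood trace is exposed and is
non-decreasing by construction), a ridge penalty of 1e-6 for numerical
stability, and convergence at max|score|/n < 1e-8 within 100 iterations.
Features are standardized with training-fold parameters only. Separation and
non-convergence raise errors naming the offending feature.

Cross-validation is five-fold, stratified on one-year survival intervals
(≤1, 1–2, 2–3, >3 years; t = 1.0 falls in the first interval) crossed with
event status; stratum members are shuffled and dealt round-robin with a
rotating starting fold.

Sequential forward selection takes the feature with the best univariate
discrimination first — scored as max(C, 1−C) of the raw feature so that
protective features compete on equal terms — then greedily adds the feature
that most improves the fitted model's training C, stopping below an
improvement of 0.005 or at 5 features. Ties break by feature name.

Signature evaluation fixes the model per fold on the training patients'
*manual*-outline features and varies only the evaluated features across the
101 segmentations of the test fold. This isolates segmentation-induced
C-index spread; `refit_per_variant=True` implements the alternative reading
(refit on each variant's training features). Risk stratification splits at
the median risk score; the boundary score goes to the high-risk group, since
only "below the median" is defined as low risk.

### Two spread summaries

The C-index distribution of a signature has 5 × 101 values. Its pooled SD
mixes two components: fold-to-fold variation (large when test folds are
small — the SE of C on a 10-patient fold is ≈0.1) and segmentation-induced
variation (the quantity of interest). The package therefore also reports the
*per-variant* summary: C averaged over folds for each variant, and the SD of
those 101 means. Averaging over the same folds for every variant cancels the
shared fold component, so this SD isolates outline-driven spread. At clinical
scale (hundreds of patients) the two summaries converge; at the reduced
scales used in the test suite the per-variant SD is the meaningful one, and
the directional claims (high-ICC signature: higher mean C, lower spread) are
asserted on it.

## Statistics

Friedman (a-priori, three matched groups), Wilcoxon signed-rank (zeros
dropped; exact null for ≤25 untied nonzero differences, normal approximation
with continuity correction otherwise), Bartlett for variances, and the
D'Agostino–Pearson K² normality pre-check that selects Wilcoxon over the
paired t-test when normality is rejected. All tests are two-sided; the
pairwise comparisons (high-vs-all, low-vs-all) use a Bonferroni level of
0.05/2. Fully tied Friedman inputs return statistic 0, p = 1 with a flag
instead of the 0/0 tie correction.

## Problem sizes

Defaults are one lesion per patient, 64×64 px at 1 mm spacing, 50 patients ×
(1–4 manual + 100 automatic) outlines, 56 features. The test suite runs the
headline contrast on twenty 50-patient cohorts and the reliability-vs-
amplitude sweep on 10-lesion cohorts; the acceptance script uses a single
100-patient cohort. These sizes were chosen so a full run completes on one
CPU core in minutes while leaving the directional conclusions stable across
seeds.

## What passing tests show — and what they do not

The synthetic cohorts establish internal correctness (oracle equivalence of
every estimator, ground-truth recovery of hazard ratios, exact neutrality at
zero perturbation) and qualitative transfer (reliability decreases with
outline variability; restricting models to high-ICC features raises the mean
and tightens the spread of the C-index across outlines; automatic outlines
diverge from manual ones mostly in the least stable features). They do not
establish clinical effect sizes: phantom textures are stationary Gaussian
fields, not tumour biology; intensity scales are arbitrary; there is no
acquisition/reconstruction variability, no 3D structure, no inter-scanner
effect; and the survival signal is planted on features chosen to be stable.
Absolute C-indices here (≈0.6–0.85) are therefore not comparable to clinical
values; only orderings and directions are.

## Known limitations

- 2D only; slice selection for 3D masks is provided but phantoms are 2D.
- The texture-matrix catalogue is a representative 8-per-family subset, not
  a full standardized catalogue; counts are exposed, not matched to any
  external toolkit.
- ICC confidence intervals and ICC(2,1)/ICC(3,1) variants are out of scope.
- The perturbation simulator produces star-shaped-ish, single-component
  variants; it cannot emulate topology changes (holes, satellites) a real
  rater or network might produce.
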