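# Methods

## Scientific setting

The package quantifies a *radiographic field effect*: the hypothesis that
tissue surrounding a tumor carries texture alterations that decay with
distance, detectable in projection radiographs.  The analysis protocol is:

1. sample 128×128-pixel ROIs from four regions of each image — inside the
   tumor (A), adjacent parenchyma (B), and two distant sites (C, D);
2. extract 45 human-engineered radiomic features and 20 deep
   pseudo-features per ROI;
3. test each feature for a monotone association with the ordinal region
   (0 = tumor, 1 = near, 2 = far; C and D are pooled because the protocol
   treats them as one far region) using Kendall's Tau-b, separately per
   modality, and for mammogram↔specimen agreement using Pearson's rho over
   matched (patient, region) ROI pairs;
4. control each test family (45 radiomic, 20 deep) with Benjamini–Hochberg
   at FDR 0.05.

Because clinical images cannot be redistributed, the package ships a
synthetic phantom whose ground truth makes every stage falsifiable.

## Phantom model

A case is a latent tissue field

  L(x) = baseline + clutter_sd · C(x) + tumor_contrast · T(x) + F(x)

* **Clutter** C is zero-mean, unit-variance Gaussian noise with an
  isotropic power-law spectrum P(f) ∝ f^(−β), synthesized in the Fourier
  domain (white spectrum shaped by f^(−β/2), DC removed).  Default
  β = 2.8, the upper end of the 1/f^(2–3) range typical of mammographic
  parenchyma; clutter_sd defaults to 300 gray levels on the 12-bit scale.
* **Tumor** T is a disc of radius r (default 64 px at the default 1024-px
  frame) with a ~4-px sigmoid edge; contrast defaults to 600 gray levels.
* **Field** F perturbs both intensity and texture with the same
  multiplicative decay w(d) = A·exp(−d/λ), where d is the distance from
  the tumor edge, A = `field_amplitude` and λ = `field_range` (px):
  intensity gains `tumor_contrast`·w(d), and the clutter is blended toward
  a smoother realization (β + `field_beta_shift`) with weight w(d).  A = 0
  switches the field off exactly.

The mammogram is L quantized to `bit_depth` (default 12) bits.  The
specimen radiograph re-renders the *same* latent field at
`specimen_resolution_scale` = 1.4× finer pixel pitch (the 70 µm / 50 µm
ratio of the emulated detectors) via bilinear resampling, adds Gaussian
read noise of `specimen_noise_sd` gray levels, and quantizes.  Pairing is
purely statistical — no geometric deformation — because the downstream
statistic only needs a tunable cross-modality correlation, not
registration.

ROI placement: A is centered on the tumor; B's center sits at
max(2.5 r, 136) px from the tumor center (1.5 radii beyond the edge for
typical radii; the 136-px floor is the smallest distance at which two
128-px patches can avoid overlap); C and D are drawn uniformly in the
annulus [image_size/3, image_size/2 − 66] with rejection sampling until
all patches are disjoint and in-frame, then labeled so that
d(A,C) ≤ d(A,D).  The real protocol gives no pixel distances for the
near/far mammographic ROIs, so these are free choices of the phantom and
are part of its configuration.

## Radiomic features

All 45 features live in a frozen canonical order (`FEATURE_NAMES`);
family-level notes:

* **Fractal (7).**  Box-counting dimension of the mask {pixel > threshold}
  with box sizes 2–32 px (boxes are kept ≤ ¼ of the patch side: counts at
  box sizes comparable to the patch are dominated by finite-size and
  alignment effects and bias the slope).  The base feature thresholds at
  the median; variants 1–5 at the 30/40/50/60/70th percentiles.  Rank
  thresholds make all six invariant to affine gray rescaling.  Empty or
  full masks give NaN.  The Minkowski dimension uses the blanket
  (dilation/erosion) construction with radii 1–5: D = 2 − slope of
  log A(r) vs log r, A(r) = Σ(u_r − b_r)/(2r); a flat patch gives exactly
  2.  The six box variants and the band scheme below are this package's
  concrete interpretation of feature families whose defining formulas are
  spread across the older texture-analysis literature; they are
  configurable interpretation, not canon.
* **Edge frequency (4).**  Mean/max/min/SD of the Sobel gradient magnitude
  (unnormalized 1-2-1 kernels, so a step of height h has max gradient 4h),
  computed over the interior (1-px border excluded).
* **Histogram (8).**  Mean; empirical-CDF thresholds at 95/5/70/30%
  (smallest present gray level whose CDF reaches the quantile); balance
  ratios (95−mean)/(mean−5) and (70−mean)/(mean−30); skewness as the third
  standardized central moment.  Zero denominators and zero variance give
  NaN with a warning.
* **Fourier (2).**  FRMS = sqrt(ΣP)/N over non-DC frequencies of the
  mean-subtracted patch (equals the spatial SD by Parseval — asserted in
  tests); FFMP = power-weighted mean radial frequency in cycles/pixel.
* **NGTDM (2).**  Amadasun–King coarseness and contrast at 64 requantized
  levels, 3×3 neighborhood excluding the center, border excluded.
  Coarseness is capped at 10⁶ for uniform patches (reciprocal guard).
* **Power-law β (8).**  Negative slope of log mean ring power vs log ring
  frequency.  Band k's upper wavenumber shrinks geometrically from the
  full range (64 at 128 px) down to 4 over the eight bands, so β₁ uses the
  whole resolvable spectrum and β₈ only the coarsest structure.
* **GLCM (14).**  Co-occurrence at distance 1 over angles
  {0°, 45°, 90°, 135°}, symmetrized, normalized, 64 equal-width levels
  over the patch's own [min, max] (these parameters are convention, not
  canon, and are exposed as arguments).  The 14 Haralick-family statistics
  use base-2 logs with 0·log 0 = 0; the maximum correlation coefficient is
  the square root of the second-largest eigenvalue of the Q matrix
  restricted to occupied levels.  Single-level matrices give NaN for the
  correlation family.

Degenerate-input policy: NaN + `RuntimeWarning`, never an exception, so a
cohort extraction cannot be aborted by one flat patch.  The correlation
stage drops NaN rows pairwise and shrinks the BH family accordingly.

## Deep pseudo-features

ROIs are min-max scaled to [0, 1], replicated to 3 channels, and passed
through a VGG19-topology convolutional network (16 conv layers, 5 max-pool
stages) implemented in numpy (im2col + BLAS).  Each pooling stage's output
is averaged per channel (average pooling matches the stage-pooling
convention of transfer-learning radiomics; max pooling is available as an
option), giving 64+128+256+512+512 = 1472 features.  Weights are
He-initialized from a seed by default — every structural and statistical
contract here (counts, filtering, PCA geometry, null calibration) is
weight-agnostic — and a pretrained weight file in .npz form can be
supplied for transfer-learning use.

Columns with zero variance, or zero in more than half the rows, are
dropped.  Surviving columns are standardized (activation scales differ by
orders of magnitude across stages) and reduced by PCA to k = 20 scores per
modality; the fit is per modality because the two detectors have different
spectral content, and the stored projection is reapplied to all regions of
that modality.  Component signs are fixed by making each component's
largest-magnitude loading positive, so signed downstream correlations are
reproducible.

## Statistics

Kendall's Tau-b uses the tie-corrected formula with the tie-aware normal
approximation for p (exact enumeration is intractable at n ≈ 100 and the
region variable is massively tied).  Pearson's rho uses the t transform
with n−2 df.  BH is the standard step-up with ≤ at the boundary.  Features
whose statistic is undefined are excluded before BH and reduce the family
size m — conservative for the discovery count; the run log records family
sizes.

## Calibration experiments (and what they do and do not show)

Calibration cohorts use 512-px phantoms with a 32-px tumor (the full
A/B/C/D layout at ⅓-image far distances still fits), 50 patients and 20
replicates per condition, which gives stable fraction estimates in minutes
on one CPU; the reproduction script uses the same sizes.

* **Null calibration.**  The null condition zeroes both the field *and*
  the tumor contrast: region A straddles the tumor disc, so a visible blob
  alone is a genuine region effect, not a null.  Mean BH-flagged radiomic
  fraction must stay ≤ 2× the nominal FDR.
* **Power.**  Strong-field cohorts (A = 1, λ = 80 px) must flag the
  histogram-average feature in ≥ 90% of replicates.
* **Cross-modality dial.**  Pearson rho of histogram average between
  modalities must fall monotonically as specimen read noise rises through
  20 / 200 / 2000 gray.  All levels sit above one quantization step —
  read noise below the quantization floor is not resolvable in the
  rendered integers — and share one latent cohort per seed, isolating the
  noise scale as the only moving part.

What passing these shows: the estimators are unbiased enough to recover
programmed effects and calibrated enough not to invent them, *under the
phantom's assumptions* — stationary Gaussian power-law clutter, isotropic
exponential field decay, noise-only modality differences.  Real
parenchyma is non-Gaussian and non-stationary, tumors are not discs,
ROI placement is manual, and specimen sectioning deforms tissue; none of
that is emulated, so phantom calibration cannot certify effect sizes or
significance patterns on clinical data — only the machinery.

## Known limitations

* Pretrained backbone weights are not bundled; random-weight features are
  structurally identical but not transferable descriptors.
* The 6 box-counting variants and 8 β bands are one defensible reading of
  loosely specified feature families; other readings would change values
  but not the pipeline contracts.
* Tau-b p-values rely on the normal approximation and are inaccurate below
  n ≈ 10 per test.
* The phantom's far-ROI distances are arbitrary (configurable), since the
  emulated protocol specifies none for mammograms.
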