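# Methods

This note documents the models, conventions and numerical choices behind
`radstab`, in the order the pipeline runs them: synthetic cohort →
interpolation-kernel ranking → perturbations → feature extraction →
robustness classification.

## Synthetic CT cohort

Real contrast-enhanced renal CT with expert segmentations is not freely
available at cohort scale, so the package ships a generator
(`radstab.phantom`) that reproduces the *acquisition statistics* of such a
study rather than renal anatomy:

| parameter | default | unit | rationale |
|---|---|---|---|
| in-plane spacing `vs` | U(0.541, 0.957) per case | mm | heterogeneous scan resolutions |
| slice spacing `vz` | 5 | mm | typical abdominal protocol |
| scan noise sigma | U(2.9, 5.9) per case | HU | CT quantum noise range |
| tumour texture | corr. length 1.5 mm, amplitude 30 HU | | heterogeneous lesion |
| kidney texture | corr. length 3.5 mm, amplitude 8 HU | | smooth parenchyma |
| tissue-mean jitter | SD 12 | HU | between-patient enhancement |
| ROI radius | U(6, 9) per case | mm | between-patient lesion size |

Each case is a soft-tissue body ellipsoid on an air background with two
disjoint ROIs.  Tissue texture is a stationary correlated Gaussian random
field — white noise convolved with an isotropic Gaussian kernel of the
stated physical correlation length, normalized to unit variance and scaled
to the amplitude — added to a constant per-case tissue mean.  Additive
Gaussian scan noise is applied last and everything is rounded to integer HU,
as CT convention demands.  ROIs are stacks of lobulated discs whose radius
follows a flattened ellipsoidal axial profile, floored at 55% of the
maximal radius: a true ellipsoid has one-to-two-pixel polar slices that a
single 3x3 erosion pass annihilates, which would make the larger
segmentation-shrink targets unreachable.

Between-case variability (ROI size, tissue mean, texture amplitude and
correlation length) is essential, not cosmetic: the intraclass correlation
compares perturbation-induced within-subject variance against
between-subject variance, and a cohort of near-clones would label every
feature non-robust regardless of the perturbation.

Seeding: one master seed; case *i* uses seed *master + i*; within a case,
geometry, the two texture fields and the scan noise consume four independent
child streams, so a noiseless twin of any case can be regenerated exactly
(used by the noise-calibration tests).

**What the phantom does not emulate** — and hence what passing tests do not
show about real data: anatomy, contrast-phase enhancement gradients,
spatially correlated reconstruction noise, beam hardening, and the wide
body dynamic range of real patients (fat, muscle, bone, contrast).  Two
visible consequences on the synthetic cohort: (i) absolute robust/non-robust
percentages are lower than a real study would find, because synthetic
between-case variance is smaller than between-patient variance — the
identity and inflated-noise controls, not the absolute percentages, are the
meaningful checks; (ii) the kernel ranking can favour linear interpolation
(see below).

## Interpolation kernels and EME-IQ

Resampling uses voxel-centre coordinates ``(i + 1/2) * spacing``; the output
grid spans the same physical extent with ``round(extent/dst)`` samples, so
identity resampling is exact.  In-plane resampling is applied slice-wise and
separably (rows then columns); through-plane resampling is a separate 1D
pass along z, skipped when the target equals the native slice spacing.
Grey levels are rounded to integers once per resampling operation.

* **linear** — two-tap weights, the field's default;
* **Akima cubic Hermite** — `scipy.interpolate.Akima1DInterpolator` applied
  per axis (its slope rule is data-dependent, so no weight matrix exists);
* **Lanczos, a = 3** — three-lobe windowed sinc, taps normalized to unit sum
  so constants are preserved exactly; at integer source positions the kernel
  reduces to a delta, so it interpolates.

All kernels replicate edge values at the borders (queries are clamped to the
source extent).

**EME-IQ.**  A slice is offset by ``1 − min`` so every value is ≥ 1 (HU are
signed and the log ratio needs a positive range), partitioned into
non-overlapping blocks (default 8x8, the usual choice in the EME literature;
trailing partial blocks are dropped), and scored as the block-mean of
``20 log10(Bmax/Bmin)``.  A constant slice scores exactly 0.  Before the
kernel comparison each volume is clamped to the 2.5/97.5 percentiles of its
body region (voxels above −200 HU) — clamping rather than removal keeps the
grid dense.

**Ranking.**  Each case is resampled to the cohort's smallest spacing
(upsample) and largest (downsample) with all three kernels; the highest
slice-averaged score wins the case; the kernel winning the most cases summed
over both directions is selected, ties broken by the fixed order
lanczos > akima > linear.  A case whose native spacing coincides with a grid
target is untouched by that direction's resampling and ties by construction.

*Phantom caveat*: on the synthetic cohort linear tends to win.  The clamped
phantom body spans only a few tens of HU, so the Lanczos ring (under/
overshoot at edges) lowers the slice minimum, inflates the global offset and
deflates every block ratio; on real CT the clamped body range is an order of
magnitude wider and the ringing penalty is negligible next to the sharpness
preserved.  The ranking machinery, not the phantom-specific winner, is the
tested artefact.

## Perturbations

**Noise (N).**  Per-case sigma is estimated slice-wise as the mode of the
local-SD histogram (7x7 windows fully inside the body, 0.1 HU bins; the
slice estimate is the mean of the local SDs inside the modal bin, so a
noiseless image yields exactly 0); the case sigma is the slice mean.  White
Gaussian noise at that sigma is added voxel-wise before re-rounding to
integer HU.  The estimator is a mode-of-local-SD concretization of the
homogeneous-region approach common in CT noise measurement; window size and
bin width are configurable.

**Voxel size (V).**  The 15 combinations of {smallest, median, largest
in-plane spacing} x {1, 2, 3, 4, 5 mm slice spacing}, resampled with the
selected kernel.  Masks follow their volumes onto the new grid by
nearest-neighbour assignment.

**Segmentation (R).**  Slice-wise binary dilation (+10%) or erosion
(−10/−15/−20%) with a 3x3 square structuring element.  Whole passes are
applied while they do not overshoot the target voxel count
``round(N(1+t/100))``; the final pass's boundary shell is subsampled at
random (seeded) so the output count matches the target *exactly*.  Only the
final shell is randomized; the deterministic core is preserved.  Erosion
that would wipe a populated slice while further full passes are still
needed raises an error naming the slice.

**Scenarios.**  29 in total: 1 N, 15 single voxel-size combos, 1 global
scenario pooling all 15, 3 fixed-in-plane scenarios across the z ladder,
5 fixed-z scenarios across the three in-plane spacings, and 4 R targets.
Every scenario includes the original image as one of its k measurements
(k = 1 + number of variants); whether the original belongs in the
measurement set is genuinely ambiguous, and including it is the
configurable default (`original_key` in the classification API).

## Feature extraction

Per ROI and image variant: grey levels outside the ROI's own
[2.5, 97.5] percentile band are discarded, and the surviving min–max range
is quantized into 32 equal-width bins, computed per variant independently
(no shared calibration across variants).  Quantile convention everywhere:
linear interpolation between order statistics.

**First order (13).**  mean, median, skewness, max, mean and median of the
top decile, SD, median absolute deviation, IQR, local coefficient of
variation, uniformity, entropy, kurtosis.  Population (biased) moments;
kurtosis is the non-excess Pearson form (3 for a Gaussian), matching the
convention of the numerical environment most radiomics pipelines grew up
in.  Uniformity and entropy (base-2) are computed on the 32-bin quantized
histogram; everything else on raw post-trim HU.  Zero-variance ROIs return
skewness = kurtosis = 0 so constant phantoms traverse the pipeline.  The
local CV is under-specified in the literature; here it is the ROI mean of
(local SD / |local mean|) over 3x3 in-slice neighbourhoods of kept voxels,
restricted to kept voxels, skipping neighbourhoods with |mean| < 1 HU — a
deliberate, prominently flagged concretization.

**GLCM (19).**  Ordered co-occurrence pairs are counted between kept ROI
voxels at displacement delta x direction — 4 in-plane directions (0°, 45°,
90°, 135°) in 2D, the 13 sign-unique 26-neighbourhood directions in 3D —
summed over directions (pair-count weighting; an equal-weight per-direction
alternative sits behind a config switch), symmetrized by adding the
transpose and normalized.  2D features are computed per slice and averaged
unweighted over slices with at least one valid pair.  Distances delta ∈
{1, 3, 5, 7, 9}.

Formulations are the classical Haralick / Soh–Tsatsoulis / Clausi set, all
base-2 logs, 0·log 0 = 0: autocorrelation, correlation, cluster prominence
and shade, contrast, dissimilarity, energy, entropy, homogeneity
(1/(1+|i−j|) weighting), maximum probability, variance (sum of squares
about the marginal mean), sum average/variance/entropy on the i+j
distribution, difference variance/entropy on the |i−j| distribution,
information measure of correlation 1, and inverse difference /
inverse difference moment, both normalized by the level count.  Two
conventions worth naming because the literature is inconsistent: sum
variance is taken about the *sum average* (not Haralick's historical
sum-entropy typo), and difference variance is the variance of the
difference distribution about its own mean (not the raw second moment).
Correlation of a single-level matrix (zero marginal variance) is reported
as 0.  Every formula is unit-tested against an independent brute-force
evaluation.

The canonical inventory is 13 + 19 x 5 = 108 feature identifiers, counting a
distance-specific GLCM feature once across its 2D and 3D renderings; the
extracted vector carries both renderings (203 values).

## Robustness classification

ICC(1,1) from the one-way random-effects ANOVA:
``ICC = (MSB − MSW) / (MSB + (k−1) MSW)`` with the exact F-pivot 95% CI
(`lower = (F/Fu − 1)/(F/Fu + k − 1)`, `upper = (F·Fl − 1)/(F·Fl + k − 1)`,
`Fu = F_{0.975}(n−1, n(k−1))`, `Fl = F_{0.975}(n(k−1), n−1)`).  Labels:
robust if the CI lower bound ≥ 0.90, non-robust if the upper bound < 0.90,
indeterminate when 0.90 lies strictly inside the CI.  Negative estimates are
reported as-is (the estimator's range extends to −1/(k−1)); labels depend on
the CI only.  Degenerate cases: an all-identical matrix has no defined ICC
and is labelled indeterminate with a flag; zero within-subject variance with
between-subject variance gives ICC = 1, CI [1, 1].  No multiple-testing
correction is applied across the feature x scenario grid.

Cross-distance redundancy: per GLCM feature family, pairwise Pearson
correlation of case-level values between distances, plus a one-way
fixed-effects ANOVA across the five distance groups, significance at
p ≤ 0.001.  On the synthetic cohort the cross-distance correlations are much
lower than on real tissue — the Gaussian random field has a single
correlation scale, so features at different distances decouple faster than
in structured anatomy; another place where the phantom bounds what the
numbers mean.

## Problem sizes and runtime choices

Default driver scale: 20 cases of 88 x 88 x 10 voxels, all 29 scenarios,
both tissues — 840 feature extractions, ~12 k ICC cells — chosen so a full
run completes in a couple of minutes on one core.  The classification stage
pivots the tidy feature table once per feature, not once per cell.  ICC
calibration checks use n = 98, k = 2 and 1000 replicates per true-ICC level:
the binomial Monte-Carlo error of a coverage estimate at a few hundred
replicates (~1.5 percentage points) would be comparable to the width of the
band being checked, so replicates are set high enough that the estimate, not
its noise, is tested.

## Known limitations

* The phantom bounds every real-data claim (see above); absolute r/nr/i
  percentages on synthetic cohorts are systematically lower than published
  patient values.
* The EME-IQ variant (block size, offset convention) and the noise
  estimator concretization are reasonable defaults, flagged as such and
  configurable, not canonical reprints.
* 2D morphology for ROI perturbation is slice-wise by design (the
  structuring element is a pixel-space object); volumetric erosion would
  behave differently at ROI poles.
* DICOM/RTSTRUCT ingestion is out of scope; masks are consumed as aligned
  binary volumes (NIfTI).
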