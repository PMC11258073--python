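# Methods

## The measurement problem

Image noise and vascular attenuation are primary determinants of diagnostic
image quality in coronary CT angiography (CCTA). Both are conventionally
quantified with a region of interest (ROI) in the contrast-filled aortic
root at the level of the left-main (LM) coronary ostium: the ROI mean in
Hounsfield units (HU) is the signal ("attenuation"), the ROI standard
deviation is the noise ("HUsd"), and their quotient is the signal-to-noise
ratio (SNR). `noisekit` automates that measurement and implements the
statistical machinery used to relate it to reader-assessed image quality.

## Pipeline

1. **Resampling** (`volio`). Volumes are resampled to a working grid of
   (0.9, 0.66, 0.66) mm per voxel, axes ordered (z, y, x) with z the axial
   slice index. The 0.9 mm step is assigned to the axial axis, the coarsest
   axis of reconstructed cardiac CT; the assignment is configurable because
   file metadata, not convention, should decide in ambiguous cases. Images
   are interpolated trilinearly, label masks by nearest neighbour; the output
   shape per axis is `round(extent / target)` with ties to even, and
   resampling to the input's own spacing short-circuits to identity.

2. **Segmentation** (`segnet`). A 3D U-Net labels every voxel as background,
   aortic root, LM or proximal RCA. Inference tiles the study with a sliding
   window, averages logits in overlapping regions, and takes the argmax
   (ties resolve to the lowest class code). Postprocessing keeps the largest
   26-connected component per class and fills enclosed cavities against a
   6-connected background, processing classes in the fixed order aorta, LM,
   RCA; the operation is idempotent.

3. **Zone construction** (`roimetrics`). The LM mask is dilated by one voxel
   with a 3×3 in-plane structuring element (no through-slice growth); its
   overlap with the aorta mask is the contact point. The zone centre is the
   median z index of the contact voxels (ties round toward the lower index).
   The zone spans the centre slice ±3 (seven slices); in each slice the
   aorta cross-section is shrunk by 1/3 of its equivalent-circle radius
   `r = sqrt(area/π)`, dropping voxels whose Euclidean distance to the mask
   boundary (computed by distance transform in millimetres, respecting
   anisotropic in-plane spacing) is below `r/3`. Equivalent-circle radius
   was chosen over the maximal inscribed radius because the latter is
   unstable on noisy predicted masks. Slices outside the volume are dropped
   with a warning; an empty LM–aorta intersection raises a typed
   `ContactNotFound` that the study runner records as a failed study rather
   than a crash — the behaviour wanted for anomalous coronary anatomy.

4. **Statistics** (`roimetrics`). Attenuation is the zone mean, noise the
   sample SD (n−1 denominator), SNR their quotient, reported as undefined
   (never infinity) when the noise is exactly zero. A manual comparator
   emulates a reader's single-slice circular ROI (15 mm diameter default).
   Statistics are computed on the working grid the mask lives on; a caller
   can map the zone to the native grid instead, but the default avoids
   resampling the mask a second time.

## Network and training schedule

The U-Net is assembled from a compact numpy layer library written for this
package (`noisekit.nn`): 3×3×3 convolutions (offset-accumulation form of
im2col), instance normalisation, ReLU, 2× max-pooling, nearest-neighbour
upsampling with skip concatenation, a final 1×1×1 convolution, and
hand-derived backward passes verified against brute-force oracles in the
test suite. Dropout (rate 0.5) sits before the last and second-to-last
convolutions; convolution kernels carry L2 weight decay 10⁻³.

Training minimises softmax cross-entropy with the Nadam optimizer. Voxels
carrying the ignore label (255) contribute exactly zero loss and gradient.
Before training, label masks are cleaned: LM/RCA voxels farther than 20 mm
(configurable) from the aorta mask are ignored, as is the one-voxel inner
and outer boundary shell of every structure — neither is a precise
annotation. The learning rate starts at 10⁻⁴ and is halved whenever the
validation loss has not strictly decreased for 5 consecutive epochs;
training stops when it has not decreased for 10. An epoch is a fixed number
of patch iterations. Periodically (every `hardmine_every_epochs`) the model
is run over the full training set; per-case mean loss re-weights which study
a patch comes from and the per-voxel loss map re-weights the patch centre
within the study, concentrating sampling on high-loss regions. The
checkpoint with the highest validation aorta Dice is returned (the aorta is
the class the measurement depends on, and the one whose Dice is reported).

Two scales are expressible through `TrainingConfig`:

| parameter | full-scale default | toy default |
| --- | --- | --- |
| iterations / epoch | 20,000 | 200 |
| hard-mining period | 500 epochs | 5 epochs |
| resolution levels / base width | 4 / 32 | 2 / 8 |
| patch (z, y, x) | (64, 96, 96) | (16, 32, 32) |
| max epochs | until early stop | 10 |

The toy scale exists because this package trains in pure numpy on one CPU;
a 4-level, 32-wide net is not trainable there in reasonable time, and the
phantom segmentation task does not need it. Ten toy epochs take several
minutes and reach validation aorta Dice ≈ 0.9; the thin coronary tubes
(2 mm radius) need a longer schedule than the toy budget provides, so at
desk scale the measurement pipeline is exercised with ground-truth masks
while the network demonstrates the aorta. Patch and batch size are not
dictated by the schedule and were chosen for CPU feasibility.

## The phantom generator

Every input at desk scale is synthetic, with exact ground truth. A phantom
is a vertical contrast-filled cylinder (aortic root, default radius 15 mm,
attenuation 500 HU) in a soft-tissue background (50 HU), with a horizontal
LM tube (radius 2 mm) leaving the wall at a configurable height and an RCA
tube on the opposite side lower down; labels are the noise-free geometry
(aorta takes precedence where tubes overlap, guaranteeing in-plane
LM–aorta adjacency), and i.i.d. Gaussian noise of known SD is added per
voxel. Geometry that does not fit the requested shape (plus a 5-voxel
margin) fails loudly, naming the offending axis. Boundaries are voxelized
exactly by default; an optional Gaussian edge blur emulates partial-volume
softening when smooth boundaries are wanted.

The cohort generator assigns each study one of three quality labels
(fully diagnostic / diagnostic with excluded parts / non-diagnostic, mixed
30 / 64.5 / 5.5%) and draws its injected noise SD and attenuation from
per-label normal distributions. The defaults centre on the group medians
observed in real quality-labelled CCTA cohorts — noise 33.1 / 36.1 / 42.1
HU, attenuation 533.7 / 502.0 / 466.0 HU — with spreads set to IQR/1.349
under the normal model, since no distributional form beyond medians and
IQRs is available; this is an emulation of the published group structure,
not ground truth. For excluded-parts studies, the excluded fraction of the
coronary tree is a rank-preserving transform of `z_noise + ε` with latent
scatter ε ~ N(0, 3.66²), calibrated so the noise–exclusion Spearman
correlation is weak (≈ 0.25), mirroring the weak correlation real cohorts
show; the fraction is capped at 0.4 of a total tree length drawn around
350 mm.

What the phantoms deliberately do **not** model: cardiac anatomy and
motion, beam hardening, spatially correlated CT noise texture, dose. Tests
that pass on phantoms therefore validate the measurement and statistical
machinery — zone geometry, estimator calibration, discrimination given a
known group structure — not robustness to real-world artefacts.

## Statistical layer

Method agreement uses Spearman rank correlation (average ranks on ties,
two-sided p), Bland–Altman bias with 1.96·SD limits of agreement plus a
one-sample test of nonzero bias, and mean absolute difference / mean
absolute relative error with 95% normal-approximation CIs (the manual
measurement is the reference denominator; zero references are excluded with
a count). Group contrasts report median and IQR per quality group with
pairwise Mann–Whitney U tests — exact when both groups are ≤ 20 and
tie-free, otherwise the tie-corrected normal approximation — alongside a
Kolmogorov–Smirnov normality screen (the screen that motivates rank-based
reporting). Unpaired group comparisons use Mann–Whitney throughout; the
paired t-test alternative applies only to paired designs, which these
contrasts are not.

ROC analysis orients the score by a declared direction (higher noise, lower
SNR = positive/non-diagnostic), computes the curve over all thresholds, the
AUC (equal to the concordant-pair fraction with ties counting ½), a 95%
DeLong confidence interval from placement-value variances, and the
Youden-optimal cutoff with its sensitivity and specificity. Youden's index
is used because no other cutoff criterion is standard for this task; DeLong
is the standard nonparametric AUC CI. No multiplicity correction is
applied.

## Numerical choices and degenerate inputs

- Sample SD uses the n−1 denominator everywhere, so automatic, manual and
  oracle computations are comparable by construction.
- SNR with zero noise is `None`, never ∞; records keep `NaN` in CSV.
- Dice of two empty masks is defined as 1.0.
- Equal-size connected components tie-break to the one whose minimum
  (z, y, x) index is lexicographically smallest.
- Median slice index with an even number of contact slices rounds toward
  the lower index.
- HU normalisation for the network is the fixed affine (HU − 250)/250; HU
  is a calibrated scale, so no per-volume statistics are needed and
  inference is deterministic.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configuration and seed give
  bit-identical phantoms, training logs and measurements.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated
phantoms: calibration uses 200 replicates at injected noise 35 HU;
method agreement uses 60 studies; cohort discrimination uses 300-study
cohorts (20 seeds in the test suite, one seed in the script); toy training
uses 8 + 2 studies at the toy configuration above. These sizes were chosen
as the smallest at which the respective statistics are stable.

## Known limitations

- The numpy network trains at toy scale only; the full-scale schedule
  (20,000 iterations/epoch, 4 levels) is expressible but meant for a real
  accelerator-backed reimplementation.
- Phantom noise is white; real CT noise is spatially correlated, so
  real-data SD estimates in small ROIs behave somewhat differently.
- DICOM support is read-only and limited to axis-aligned axial series;
  non-axis-aligned orientations raise rather than reorient.
- The quality labels of synthetic cohorts derive from the injected noise by
  construction, so cohort-level discrimination results on phantoms are a
  consistency check of the machinery, not clinical evidence.
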