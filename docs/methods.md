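# Methods

## Phantom image model

The generator emulates the structure that the downstream estimators assume,
not the physics of a particular scanner.

Each B-scan (depth × lateral) is built as follows. A smooth random surface
profile (sum of four low harmonics, amplitude `surface_profile` px) is placed
around an axial offset of `surface_depth_frac · depth_px`. Above the surface
the image is `noise_floor` plus clipped zero-mean Gaussian noise. Below the
surface the mean intensity follows the single-scattering Beer–Lambert model

    I(z) = I0 · exp(−2 μ z),

with depth `z` measured from the per-column surface and μ in mm⁻¹ (the factor
2 is the round trip of the probe beam). This is deliberately the same model
that the attenuation-coefficient estimator fits, so that estimator is
well-posed on phantoms and its recovery error measures the fit, not a model
mismatch. Speckle is multiplicative unit-mean exponential — the first-order
statistic of fully developed speckle — applied after the mean model;
`speckle_model="none"` disables it for exact-recovery tests.

A lesion is an elliptical footprint in the (lateral, slice) plane centred in
the volume. It nucleates at the onset week with a small seed radius and grows
linearly (`lesion_growth_rate` px/week laterally, `lesion_growth_rate_slices`
slices/week in the out-of-plane direction); the seed radius exists because a
lesion must be present from the onset week on, while a purely linear extent
would be zero exactly at onset. Inside the footprint, down to
`lesion_depth_um` below the surface, the tissue uses `mu_lesion` instead of
`mu_normal`, intensity is multiplied by `hyperreflective_gain` (≥ 1), the
surface is elevated (growing with weeks since onset), and a band-limited
random texture of amplitude `disarray_strength` modulates the signal —
mimicking the hyperreflective, architecturally disordered appearance of
melanoma in OCT. Ground truth (voxel mask, per-slice flags, true surface) is
carried with every volume.

Default desk-scale geometry is 256 × 256 × 16 voxels over the nominal
4 × 4 × 2 mm³ field (full scale 1024 × 813 × 400 is available by
configuration). Growth defaults are chosen so that an induced lesion covers
essentially the whole scanned volume by the cleanly labelled late weeks,
matching fully developed disease in the labelled period; per-subject biology
is emulated by ±10 % jitter of μ, gain, growth rate and surface roughness.
All randomness derives from one master seed through a hierarchical
`SeedSequence` split (cohort → subject → volume → slice), so identical
(spec, seed) inputs are bit-identical.

What the phantoms do *not* contain: hair and gel-bubble artifacts, motion,
confocal/sensitivity roll-off, multiple scattering, or any texture difference
between melanoma and healthy tissue beyond the modelled gain/attenuation/
disarray. Passing tests therefore demonstrate that the pipeline recovers
known structure under its own assumptions — not that it would reach the same
operating numbers on real animal data, where the attenuation baseline in
particular is reported near chance.

## Surface detection and preparation

Surface detection thresholds each A-line at background mean + k·SD (k = 3,
background = top rows), after a depth-wise median-3 filter that suppresses
isolated noise without shifting step edges, then median-filters the detected
indices across 15 A-lines. More than 50 % unusable A-lines is a failure.

Network inputs keep the top half of the axial range (the signal-bearing 512
of 1024 rows at full scale), resample both axes to the target size with
anti-aliased linear interpolation, min–max normalise per image to [0, 1]
(constant images map to zeros; per-image normalisation makes the input
invariant to scanner gain), and replicate the channel three times. ImageNet
mean/SD normalisation is not applied (no pretrained weights are in play);
the hook exists in the config.

## Attenuation baseline

Per usable A-line, ordinary least squares of `log(I + 1e−6)` against physical
depth over [surface, surface + 200 μm]; μ = −slope/2; image summary = median
of per-A-line μ (robust to outlier columns). A `mean_aline` aggregate (fit a
single line to the across-column mean profile) is provided for low-variance
estimation under speckle. Windows truncated by the image bottom are flagged;
under 8 px of window the fit is refused.

The decision threshold maximises Youden's J over midpoints of consecutive
sorted values (plus sentinels), in both directions — whether melanoma raises
or lowers μ is learned, not assumed. Ties prefer higher sensitivity, then the
lower threshold; values exactly on the threshold classify negative. Threshold
selection sees only the training+validation partition, by interface.

## Radiomics baseline

Features are computed per image in the 200 μm sub-surface band. First-order
statistics use raw intensities (kurtosis is Pearson, normal → 3; IQR uses
linear-interpolation quantiles; robust MAD is the mean absolute deviation of
the 10th–90th percentile subset about that subset's mean). GLCM features use
intensities quantised to 32 equal-width levels; the matrix is symmetric,
distance 1, normalised per direction and averaged over 0°/45°/90°/135°.
Degenerate single-level ROIs give joint energy = maximum probability = 1 by
convention.

Selection is two-stage: two-sided Welch t-test gate at α = 0.05, then greedy
mRmR in the MID (difference) variant — relevance MI(f; y) minus mean MI with
already-selected features — with quartile-discretised mutual information.
The classifier is a CART tree (Gini, depth ≤ 5, ≥ 5 samples/leaf); its score
is the leaf positive-class fraction.

## CNN and temporal ranking loss

The network maps an H×W×3 image to one logit; sigmoid(logit) is the melanoma
probability score. Training minimises BCE plus the relative loss at 1:1:

    LossR = (1/N) Σᵢ ReLU(Ŷ1ᵢ − Ŷ2ᵢ),

over batches of same-subject, same-slice-index image pairs ≥ 2 weeks apart
("more than 2 weeks" is read as ≥ 2, configurable). No registration is
attempted between time points. Pairs are drawn from induced subjects
(progression is only defined there) and may span weeks outside the cleanly
labelled training period — LossR consumes no labels — but never test
subjects, which the trainer enforces along with the general rule that no
subject id may appear on both sides of the train/test wall. Each step
computes BCE on a shuffled image batch and LossR on a concurrently sampled
pair batch; gradients are accumulated into one Adam update. With a zero
relative weight the pair machinery is bypassed entirely, so such a run is
step-for-step a plain BCE run under the same seed.

Layers (3×3 same-padded convolution via im2col, non-overlapping max-pooling,
dense) and their backward passes are implemented directly on NumPy arrays and
verified against central-difference gradients. The default `tiny_vgg`
backbone (two conv/ReLU/pool blocks, one hidden dense layer) accepts reduced
inputs; the full 16-layer VGG topology with a single-logit head can be built
by configuration, but pretrained ImageNet weights are not bundled and must be
supplied as a file if wanted.

Early stopping monitors validation accuracy at threshold 0.5 and stops after
5 epochs without improvement. The returned checkpoint has the best validation
accuracy; among equal-accuracy epochs the one with the lower validation BCE
wins (then the earlier). The tie-break matters at desk scale: accuracy
saturates within an epoch or two while scores are still near 0.5, and
keeping the earliest such epoch would freeze an uncalibrated model whose
volume scores could not be read as malignant fractions. Learning rate
defaults to 1e−4 with batch 16; the desk-scale experiments use 1e−3 to reach
score saturation within their small epoch budget.

## Scoring, cross-validation, evaluation

A volume's melanoma probability score is the arithmetic mean of its slice
scores — the fraction of the scanned area judged malignant. Longitudinal
curves report group mean ± SD per week, unsmoothed.

Cross-validation assigns subjects (stratified by group) to five folds; for
each fold the images of the remaining subjects are shuffled and split 9:1
into train and validation. Subject exclusivity is enforced between train+val
and test; the 9:1 split is by image, so train and validation share subjects —
the wall the protocol guarantees is to the test side. ROC sweeps all observed
thresholds; AUC is the trapezoidal area, identical to the normalized
Mann–Whitney U with rank-average ties; confusion matrices use threshold 0.5.
Pooled (summed matrices) and per-fold-mean metrics are both available.

## Class activation maps

The head keeps fully connected layers, so classic CAM (which requires a
global-average-pool head) does not apply; the package computes a
gradient-weighted activation map at the last convolutional block: channel
weights are the spatial means of the positive logit gradients, the map is the
ReLU of the weighted activation sum, bilinearly upsampled and max-normalised
per image (all-zero maps stay zero; volume-wide joint normalisation is
optional for comparable en-face intensity). For a GAP head this reduces to
classic CAM. The en-face view is the per-column maximum over depth, one row
per slice.

## Desk-scale experiment sizes

The standard end-to-end experiment uses 4 induced + 4 control subjects,
weeks 0–6 with onset at week 3, 16 slices/volume at 256 × 256, network inputs
64 × 64, weeks ≥ 5 as the cleanly labelled learning set, a 4-fold
subject-exclusive split (one induced + one control held out), and up to 12
epochs. The ranking-loss ablation uses a smaller standard cohort (3 + 3
subjects, 8 slices at 128 × 128, inputs 32 × 32) with five training seeds per
loss variant on one fixed cohort. These sizes are the package's chosen study
conditions for CPU-scale reproduction; all invariants they exercise are
scale-free.

## Ablation reading

In the ordering-violation measurement, a held-out temporal pair counts as
violated only when the later score drops by more than 0.01; smaller
differences on near-saturated, lesion-free pairs are floating-point ties, and
a strict comparison there measures coin flips rather than ordering. Under the
standard seeded conditions the with-LossR violation rate does not exceed the
without-LossR rate (paired over five seeds). This is a non-degradation check,
not evidence of improvement: across other seeds the difference changes sign,
i.e. the ranking loss neither helps nor hurts measurably at desk scale —
consistent with the marginal effect reported on the original data.

## Known limitations

* The phantom world is easy: lesion contrast is strong, so the texture and
  CNN models saturate and baseline orderings need not match real data.
* The attenuation estimator assumes the generator's own decay model; on real
  tissue (roll-off, heterogeneity, hair) its error would be larger.
* Full-scale VGG16 training is impractical on one CPU; the topology is
  provided, the experiments use `tiny_vgg`.
* Bitwise reproducibility holds for fixed seeds on a fixed BLAS; across
  different BLAS builds only statistical reproducibility is guaranteed.
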