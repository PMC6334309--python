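# Methods

This note records the models, the synthetic data they are exercised on, the
numerical choices, and the limits of what the offline tests establish.

## Pipeline overview

Annotated 3-D volumes → cube VOI per nodule (side = 2× max diameter,
isotropic trilinear resampling) → oblique 2-D sections through the VOI
center, expanded by the dihedral-4 symmetries → per-class WGAN training on
the sections of isolated nodules → classifier pretraining on WGAN samples →
FC re-initialization and fine-tuning on the real sections → case-level
stratified k-fold evaluation (per-class accuracy at threshold 0.5, ROC/AUC).

## The phantom cohort

The generator emulates the statistical contrast a benign/malignant nodule
classifier must exploit, not lung anatomy:

* benign: a near-spherical ellipsoid (largest semi-axis = drawn radius; the
  other axes jittered ×U(0.9, 1.1)) of soft-tissue density (+40 HU) in lung
  background (−800 HU), edge smoothed by a Gaussian of σ = 5 % of the
  diameter;
* malignant: the same core plus 3–8 spicules — radial segments starting at
  the core surface, length U(0.7, 1.3) × 0.6 r, intensity decaying linearly
  to background, stamped as 0.9 mm balls — and, with probability 0.3,
  pleural attachment to a chest-wall plane (attached cases are flagged
  non-isolated and excluded from WGAN training);
* additive Gaussian noise (σ = 20 HU), all intensities clipped to
  [−1024, +400] HU.

Defaults: 64³ voxels at 1 mm, diameters U(8, 16) mm, cohort 27 benign + 33
malignant (20 cases, 10+10, in the tiny preset). No quantitative morphology
statistics of the original clinical cohort are available, so the diameter
and spicule distributions are free parameters of the phantom, not claims
about clinical data. Determinism: each case consumes its PRNG in a fixed
draw order (diameter, center, axis jitter, attachment, spicule count,
directions, lengths, noise), and per-case seeds derive from the master seed
by counter-based `SeedSequence` splitting, so cohorts are identical on any
platform and independent of generation order.

What the phantom does *not* model: reconstruction physics, vessels and
airways, part-solid/ground-glass texture, inter-scanner variation. A
passing pretraining-benefit test therefore shows the *mechanism* works
(GAN-synthesized morphology transfers into useful convolutional features),
not that clinical accuracy would be reproduced.

## Geometry

* VOI side in voxels = nearest odd integer to 2·diameter/resolution (ties
  upward), so the nodule center is exactly the central lattice point and
  the 0° section equals the central axial slice bit-for-bit. Out-of-volume
  samples take air density (−1024), not edge clamping, because pleura-near
  nodules legitimately abut the volume edge. Default VOI resolution 1 mm,
  trilinear interpolation (both configurable; neither is dictated by the
  method itself).
* Oblique sections: the axial plane rotated by the tilt angle about one
  in-plane axis through the center, sampled by trilinear interpolation on a
  square grid with the VOI's side and spacing.
* Orientation scheme: a single-axis grid of 17 angles (−40°…+40°, step 5°,
  including 0°) with 8 dihedral ops cannot yield the reference count of 256
  images per nodule; the two constraints are mutually inconsistent. The default here uses the 16 non-zero angles about *each*
  of the two in-plane axes (32 orientations × 8 ops = 256), preserving that
  angle range and step while reproducing the 256-per-nodule yield exactly; a
  `faithful_text` configuration (17 angles, one axis → 136 per nodule) is
  provided. Rotations/flips are exact lattice operations on the section,
  not 3-D reslices.

## Networks and training

All layers (strided and fractionally strided 5×5 convolutions, batch-norm,
overlapping max-pool, linear, dropout) are implemented in numpy with
hand-written backward passes, validated against central finite differences
in the test suite; training is therefore exactly reproducible from a seed
(no backend nondeterminism).

WGAN (full scale): latent 100, RMSprop lr 5e-5, 1000 epochs, clip c = 0.01,
n_critic = 5, batch 64, channel widths 512/256/128/64 (the DCGAN convention;
only layer count and kernel size are fixed by the method), batch-norm on
every critic convolution layer (a no-batch-norm switch exists). The
critic clips *all* parameters, including batch-norm scales and biases, after
every update, matching the original weight-clipping algorithm. Images enter
WGAN training through a fixed invertible linear map of the HU window
[−1000, +400] to [−1, 1], shared with the classifier.

Classifier: canonical AlexNet interior (conv2–5 widths 256/384/384/256, FC
4096/4096/2), He-initialized conv weights, FC weights Gaussian σ = 0.01
with zero bias (the Caffe convention) at full scale. 256→227 center crop
makes the printed conv1/pool1 arithmetic true. Pretraining hyperparameters are open
choices: SGD momentum 0.9, lr 0.001, 10 epochs by default, logged in every
run manifest. Fine-tuning: FC layers re-initialized,
conv weights transferred, all layers trained by SGD (lr 1e-4, 30 epochs,
momentum 0.9) at full scale. Pretraining mixes the two classes' generated
images in one run with equal counts per class.

## Tiny preset (CPU scale)

All tests run the `tiny` preset: 32×32 images, classifier 3 conv + 2 FC
layers (widths 8/16/16, FC 32), WGAN base width 8, ~400 generator steps at
lr 5e-4 with clip 0.02, pretraining 5 epochs on 128 generated images per
class, fine-tuning 3 epochs at lr 0.001, 20-case cohorts, 3 folds. Two
tiny-scale choices deliberately deviate from the full-scale constants and
are scale-driven, not fidelity-driven:

* clip box 0.02 (not 0.01): with the tiny preset's larger learning rate the
  clipped critic saturates at the box corners within tens of updates and
  its Wasserstein estimate collapses to ~0, starving the generator of
  gradient; widening the box keeps the critic informative over the short
  schedule.
* FC initialization is fan-in-scaled (He) rather than σ = 0.01: at width 32
  a fixed 0.01 std produces logits ~10⁻² and effectively no gradient
  signal, whereas at width 4096 the Caffe constant is appropriate.

## Evaluation

Cases, not images, are the cross-validation unit (augmented views inherit
their case's fold; an audit asserts it every run). Folds are stratified by
class via `StratifiedKFold`. Per-fold WGANs see only that fold's training
cases flagged isolated. Case-level probability = mean over the case's test
views (median and axial-only are available; mean is this package's default
aggregation rule). Threshold 0.5, ties called malignant. ROC/AUC via
threshold sweep and trapezoidal integration (`sklearn.metrics`).

## Known limitations

* The WGAN here is the original weight-clipping variant; gradient-penalty
  and other successors are out of scope.
* The phantom's class contrast (spiculation, pleural attachment) is
  stronger and cleaner than clinical morphology; tiny-preset accuracies are
  not comparable to clinical numbers in either direction.
* At tiny scale the pretraining benefit is a small average effect over
  seeds; individual seeds can tie or invert, which the paired multi-seed
  acceptance check reflects.
* NIfTI support is limited to axis-aligned affines; DICOM series assembly
  is out of scope.
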