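# Methods

## The platform

`roscope` implements an image-based assessment of reactive oxygen species
(ROS) in single microglial cells, built around three stages:

1. **Quantification.** A two-channel confocal z-stack (an actin reporter and
   a fluorogenic ROS dye) is segmented from the actin channel, and five
   ImageJ-convention measures of the ROS channel are computed per cell.
   Treatment groups (CBD vs vehicle control) are compared per challenge
   condition with Welch's two-tailed t-test.
2. **Classification.** Individual 2D optical sections, treated as independent
   training images, are preprocessed to 8-bit 256x256 tiles and fed to a
   small convolutional network that predicts the treatment (binary) or the
   challenge condition (ternary).
3. **Interpretation.** Grad-CAM saliency maps localize the image evidence the
   classifier uses; an edge-saliency fraction summarizes how much of that
   evidence lies near the cell boundary.

Because the original microscopy data are not public, a synthetic-data
generator is a first-class component: it renders labeled two-channel stacks
with exact ground truth (cell mask, noiseless integrated ROS, puncta count)
so that segmentation, measurement, statistics and classification can all be
validated against known answers.

## Synthetic scenes

A scene is one cell in one stack. Geometry: an ellipsoid whose in-plane
outline is perturbed by low-order radial harmonics (orders 2-5, amplitudes up
to 6%), producing the irregular single-cell outlines typical of adherent
microglia. Default calibration is 0.25 um/pixel in XY and 0.5 um z-steps,
with 18-20 slices per stack and 1024x1024-pixel frames; pixels are stored as
16-bit unsigned integers. The cell's z semi-axis is a multiple
(`cell_z_fill`, default 0.8) of the stack depth, so the acquisition crops the
cell in z the way real stacks do.

The **actin channel** is a bright cortical rim (default 1 um wide, found by a
per-slice Euclidean distance transform) over a dimmer cell body — the
outline signal used for segmentation.

The **ROS channel** is a Poisson number of 3D Gaussian puncta with log-normal
amplitudes, placed inside the cell mask according to a per-condition spatial
motif (`peripheral`, `perinuclear`, or `diffuse`), then clipped at the
membrane (ROS is intracellular). Condition baselines multiply the expected
puncta count and the amplitude scale. The CBD effect multiplier `m` scales
the **expected puncta count** of treated cells: ROS reduction manifests as
fewer ROS-positive puncta. This choice (rather than scaling amplitudes) keeps
the mean noiseless integrated ROS exactly proportional to `m` while leaving a
class signal that survives the intensity-destroying preprocessing below —
per-image min-max normalization and histogram equalization erase absolute
intensity, but not object density.

Noise model: optional Poisson shot noise on signal + background, additive
Gaussian read noise, multiplicative per-slice z-attenuation, then clipping
and quantization to 16 bits. `true_integrated_ros` is defined as the sum of
the *quantized noiseless* ROS channel inside the mask, so a noiseless render
reproduces it exactly rather than to quantization error.

The default effect design mirrors the emulated experiment: CBD reduces ROS
under LPS (m = 0.6) and Abeta42 (m = 0.65) but not under GP120 (m = 1.0),
with group sizes of 66-138 cells and distinct spatial motifs per condition.

What the generator does **not** emulate: photobleaching, PSF blur and
deconvolution artifacts, multi-cell fields, cell motion, organelle structure,
and the correlated morphology changes real treatments cause. Passing tests
on synthetic data therefore validate the *pipeline* (its arithmetic,
statistics, and learnability claims), not any biological conclusion.

## Per-cell quantification

Segmentation thresholds the maximum projection of the actin channel (Otsu by
default; a fixed threshold is available for reproducibility), applies
morphological closing (disk radius 2 px), keeps the largest connected
component and fills holes. The resulting 2D footprint defines the cell; the
mask volume broadcasts it across z.

Measures follow ImageJ conventions. By default intensity statistics are
computed on the z-summed projection of the ROS channel inside the footprint:

- `area_um2` = footprint pixels x (pixel size)^2,
- `raw_int_den` = sum of ROS intensities over all masked voxels,
- `mean` = raw_int_den / footprint pixels,
- `max` = maximum of the z-summed masked pixels,
- `int_den` = mean x area_um2.

On the projection the identities `raw_int_den = mean x area_px`,
`int_den = mean x area_um2` and `max >= mean` hold at machine precision. A
`voxel` mode computes mean/max over the 3D voxel set instead (there
`raw_int_den = mean x n_voxels`). An optional background correction
subtracts the per-slice median intensity outside the footprint; it is needed
when estimating treatment-effect ratios, since a camera offset is
treatment-independent and otherwise biases the CBD/control ratio toward 1.

Welch's t statistic is computed from the closed form with
Welch-Satterthwaite degrees of freedom and a two-tailed p-value from
Student's t distribution. Degenerate inputs are defined: two zero-variance
groups with equal means give p = 1, with unequal means p = 0. Significance
stars follow the *, **, *** convention at 0.05 / 0.01 / 0.001. No
multiple-testing correction is applied by default (per-measure p-values are
reported raw); a Holm step-down option exists.

## Preprocessing

Each stack contributes its individual z-slices as independent images (an
18-20x data augmentation). Per slice, in order: min-max normalization
`new = (old - min) / (max - min) * 255`, grayscale collapse (single-channel
fluorescence passes through; RGB collapses by ITU-R 709 luminance), area
interpolation to 256x256 (exact local-mean for integer factors), and classic
CDF histogram equalization
`out(v) = round((cdf(v) - cdf_min) / (N - cdf_min) * 255)`. All rounding is
half-to-even with clipping to [0, 255]. Degenerate conventions: a constant
image normalizes to zeros (logged) and equalizes to itself.

The train/validation/test split is 0.72/0.08/0.20 by largest-remainder
apportionment, stratified by (condition, treatment), seeded. The default
grouping is `by_cell`: all slices of a cell stay in one partition, preventing
leakage of cell identity between training and testing (slices of one cell
share the puncta envelope and, for adjacent slices, the puncta themselves).
A `by_slice` mode reproduces the simpler slice-level split.

## The classifiers

Architecture (fixed by its characteristic dimensions): 256x256 input ->
conv(8 filters, kernel 16, stride 1, no padding) -> ReLU -> dropout 0.20 ->
5x5 max pool (stride 5, floor) -> conv(16 filters, kernel 5) -> ReLU ->
5x5 max pool -> flatten (exactly 8x48x48 into the second convolution and a
1024-long vector after flattening) -> three dense layers -> softmax over 2
(treatment) or 3 (condition) classes. `trace_shapes` recomputes this
arithmetic and is asserted in the tests; any padding would break these
shapes.

Design choices the architecture's dimensions do not determine, and what this package uses:

- **Activation**: ReLU (standard for small CNNs; Grad-CAM assumes
  ReLU-family activations).
- **Hidden dense widths**: 1024 -> 32 -> 16 -> n (configurable). Only the
  1024 flat width and the output width are fixed by the architecture. The narrow head is
  deliberate: at the few-hundred-slice scale this package trains at, a wide
  head (1024 -> 256 -> 64) has enough capacity to memorize the identity of
  the handful of training cells — training accuracy rises while cell-held-out
  accuracy stalls — whereas the narrow head forces the density cue that
  generalizes across cells.
- **Dropout position**: conv -> ReLU -> dropout -> pool ("max pooling
  applied to a dropout layer"); a pool-before-dropout variant is available.
  Pooling over dropped maps injects far less gradient noise than dropping
  pooled maps, which matters at small update budgets.
- **Input scaling**: 8-bit pixels map to zero-centered [-0.5, 0.5]. At the
  fixed learning rate and epoch budget, all-positive inputs measurably slowed
  convergence in scaled-down runs.
- **Initialization**: He-normal, seeded, followed by layer-sequential
  unit-variance (LSUV) rescaling on the first training batch (on by
  default). At a budget of ~90 gradient updates, runs whose random start
  leaves the logits badly scaled never recover; LSUV gives every seed a
  comparably scaled start and markedly reduces run-to-run spread.
- **Softmax**: applied at inference; training uses logits with
  softmax-cross-entropy (mathematically identical, numerically standard).

The runtime is pure NumPy: im2col matrix-multiply convolutions for small
feature maps and an FFT path (circular correlation on the zero-padded frame,
exact for valid correlation) for large ones, hand-derived backward passes,
inverted dropout, and Adam (beta1 0.9, beta2 0.999, eps 1e-8). This makes
every training run bit-reproducible under a seed and exposes the exact
feature-map gradients Grad-CAM needs. FFT and im2col paths agree to
float32 roundoff and both are checked against numerical differentiation.

Training recipe: cross-entropy, Adam at learning rate 1e-4, 10 epochs,
batch size 32, reshuffled each epoch from the run seed; per-epoch train and
validation loss/accuracy are recorded (plus test accuracy when a test set is
supplied, which is what the accuracy curves plot), and the
best-validation-accuracy weights are retained. `overfit_divergence` flags a
run as diverging when validation loss rises over three consecutive
epoch-to-epoch steps while training loss falls.

Evaluation reports accuracy (%), a confusion matrix with rows = true class
and columns = predicted class (for the binary task, true negatives upper
left, true positives lower right; positive = CBD), and ROC/AUC per class
(one-vs-rest with macro averaging for the ternary task; a class absent from
the test set gets an undefined AUC and is flagged).

## Grad-CAM

Gradients of the pre-softmax target-class logit are taken with respect to the
last convolutional layer's feature maps (any conv layer can be requested).
Channel weights are the spatial average of the gradient; the map is
ReLU(sum_k w_k A_k), bilinearly upsampled to the 256x256 input grid and
divided by its maximum. `edge_saliency_fraction` measures the fraction of
total saliency mass inside a morphological band (dilation minus erosion by a
disk, default radius 8 px ~ 3% of the frame) around the cell footprint; it is
invariant to positive rescaling of the map, and an identically zero map is
reported as 0 with a warning.

## Problem sizes used by the test suite and the acceptance script

All empirical checks run at deliberately scaled-down sizes chosen as package
defaults for routine verification:

- **Effect recovery Monte Carlo**: 48-pixel frames, 4 slices, cell radius
  2.2-3.2 um, 80 cells per group, 100 replicates per arm, full
  generate -> segment -> measure -> Welch pipeline per replicate. With the
  LPS-like design (baseline 1.3, m = 0.6) the per-replicate Welch test on
  raw integrated density is expected significant (standardized effect ~2);
  with the GP120-like null (m = 1.0) rejections stay at the nominal 5%.
- **Classifier benchmark** (`roscope.simulate.cnn_benchmark`): 256-pixel
  frames, 20 slices, 10 cells per group = exactly 400 slices, constant
  puncta density 0.27 per um^3 (~3000 per control cell; sigma 0.25 um,
  amplitude sigma 0.2, no z-attenuation, `cell_z_fill` 1.5), dark background
  (5 counts, read noise 2), controlled geometry (radius 19-21 um, outline
  irregularity 0.02, aspect jitter 0.05), m = 0.5. These values make the two
  classes strongly separated at the slice level *after* preprocessing, for
  three reasons established while designing the benchmark: (i) the
  puncta-density contrast is the only cue that survives rank-based
  equalization; (ii) a dark background is required for it to survive (a
  bright noisy background equalizes into salt-and-pepper speckle that drowns
  object density); and (iii) tying puncta count to cell volume and holding
  silhouettes near-identical removes cell-size and cell-identity confounds
  that a ~14-training-cell dataset cannot average away. Training uses the
  standard recipe (batch 32, lr 1e-4, 10 epochs) over three seeds with a
  cell-grouped 72/8/20 split.

## Known limitations

- At the 400-slice benchmark scale the training recipe performs roughly 90
  gradient updates (batch 32), an order of magnitude fewer than a
  several-thousand-image experiment would provide. Cell-held-out test
  accuracy in the mid-80s to mid-90s by epoch 10 is the typical outcome;
  near-perfect accuracy is not reliably reached at this update budget, and
  run-to-run (seed) variability is substantial. The acceptance script
  reports the median over three seeds.
- The per-slice z-augmentation makes adjacent slices of one cell highly
  correlated; the effective sample size is closer to the number of cells
  than the number of slices. The `by_cell` split accounts for this in
  evaluation but cannot create diversity that is not there.
- Synthetic puncta are isotropic Gaussians without organelle structure;
  edge-saliency findings on synthetic data are directional observations
  about the classifier, not biology.
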