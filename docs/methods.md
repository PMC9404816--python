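# Methods

## Problem and model

Triple-label immunofluorescence of post-mortem brain tissue from tauopathy
patients images a neurofibrillary tangle (NFT) in three acquisition channels
(R, G, B), each channel reporting one antibody or dye against a specific
pathological modification of the tau protein.  The biological question is
*colocalization*: which pixels of the tangle core show joint significant
signal in a given subset of channels.  Four binary masks are therefore
defined per image — RG, RB, GB and RGB — and the fraction of image pixels in
each mask quantifies the corresponding biomarker combination.

The segmentation model is a **semi-Siamese U-Net**: a single U-Net
contracting path shared by four independent expanding paths, one per channel
combination.  Compared with a single-decoder U-Net emitting four channels,
each decoder can specialize in its combination while sharing one learned
representation of the tangle.  Architecture (defaults in
`tangleseg.ModelConfig`):

- **Encoder** — `depth` = 5 levels including the bottleneck; each level is two
  same-padded stride-1 convolutions (`kernel_size` = 5, ReLU) with channel
  widths 16/32/64/128/256 (`base_filters` × 2^(level−1)); 2×2 max-pooling and
  dropout (`dropout_rate` = 0.2) between levels.
- **Decoders** — `n_outputs` = 4 parallel paths.  Each level: nearest-neighbour
  ×2 upsampling, concatenation of that decoder's *own copy* of the matching
  encoder feature map, two convolutions, dropout.  Each path ends in a 1×1
  convolution with sigmoid.
- With `n_outputs` = 1 the same builder produces a classical U-Net, used as
  the single-decoder baseline.

The network is implemented directly on numpy with explicit backpropagation
(`tangleseg.nn`): same-padded convolution evaluated as k² shifted BLAS
matmuls, argmax-routed max-pool gradients (first tie wins), inverted dropout,
block-sum upsampling gradients, and Adam with conventional moment defaults.
Gradients of the full network are validated against central finite
differences in the test suite, and the convolution forward pass against
`scipy.ndimage.correlate`.

## Loss, optimization, cross-validation

Training minimizes pixel-mean binary cross-entropy per output, averaged
uniformly over the four outputs (no inter-output weighting; the loss is
defined per mask and the outputs are symmetric).  Probabilities are clipped
to [1e−7, 1−1e−7] before the logarithm.  Optimization uses Adam with
learning rate 5e−4, 50 epochs, mini-batches of 4, per-epoch shuffling under
`shuffle_seed`.

Evaluation uses k-fold cross-validation (k = 5).  The initial weights are
materialized once from `init_seed`, persisted, and reloaded at the start of
every fold, so all folds start from the identical state.  `kfold_split` is an
exact partition: with 97 items the validation sizes are 19/19/19/20/20
(training 78/78/78/77/77).  A uniform 78/19 split in *all five* folds is
arithmetically impossible for a strict partition of 97; the exact partition
was chosen over repeated independent 80/20 draws because it guarantees each
image is validated exactly once.

**Initializer.** The default is standard fan-based Glorot-uniform.  A
fixed-limit uniform(−1, 1) initializer (`init_scheme="uniform_pm1"`) is also
available; it is not the default because ±1 limits on 5×5 kernels produce
pre-activations far outside the sigmoid's useful range and destabilize
training.

**Binarization.** Probability maps are thresholded with a strict `>` at 0.5;
pixels exactly at the threshold are excluded.  Binarization is idempotent.

## Augmentation

Each training fold is expanded exactly fourfold, offline: for every sample
the expanded fold contains the original, one rotated copy (a single angle
drawn uniformly from {90°, 180°, 270°} per image — this is what makes
78 → 312), an elastic deformation of the original, and an elastic deformation
of the rotated copy.  Right-angle rotation of square rasters is a pure index
permutation (lossless, masks stay binary).

Elastic deformation draws one per-pixel displacement field — uniform noise in
[−1, 1] per axis, Gaussian-smoothed with `elastic_sigma` = 4 px, scaled by
`elastic_alpha` = 34 px — and applies it identically to the image (bilinear)
and to all four masks (nearest-neighbour, re-binarized), preserving
registration.  (34, 4) are the classic values from the elastic-distortion
literature; out-of-border lookups replicate the edge so no dark borders are
introduced.  The validation split is never augmented.

## Evaluation metrics

With GT the ground-truth and SR the predicted pixel set:
TP = |GT∩SR|/|GT|, FP = (|GT∪SR|−|GT|)/|GT| = |SR\GT|/|GT|,
DC = 2|GT∩SR|/(|GT|+|SR|), IoU = |GT∩SR|/|GT∪SR|.
TP, DC, IoU ∈ [0, 1]; FP ≥ 0 and may exceed 1 (not clipped).  DC and IoU obey
DC = 2·IoU/(1+IoU) identically.

Conventions for degenerate inputs (which synthetic data can produce): TP and
FP are undefined for empty GT and reported as NaN, excluded from fold means;
DC/IoU are 1.0 when both masks are empty and 0.0 when exactly one is.
Aggregation is two-level: per fold, the unweighted mean over all validation
images × all four outputs; across folds, the mean and *sample* (n−1)
standard deviation of the five fold means.  Per-image averaging (rather than
pooling pixels per fold) is used; masks are compared at the training
resolution (256×256 by default).

## Fluorescence quantification

For each combination the positive pixels of its binary mask are counted and
divided by the raster's own H×W (65,536 for 256×256), reported as a
percentage.  The arithmetic is exact: percentage × total/100 is always the
integer count.  The source may be either model predictions or ground-truth
label files — both are supported because the protocol's output is the
percentage, regardless of which segmentation produced it.  Human-readable
output prints two decimals; CSV stores full precision.

## Synthetic data generator

Real data are restricted clinical images; the generator emulates what the
method needs from them, not their appearance:

- **Tangle cores** as isotropic 2-D Gaussian intensity profiles (σ = radius/2,
  footprint = disc of the stated radius), placed uniformly, overlap allowed —
  real tangles cluster, so no minimum separation is imposed.
- **Partial channel overlap**: each core is bright in each channel with
  probability `channel_presence_probs` (default 0.8 each) and an independent
  peak drawn from `core_intensity_range` (default 0.7–1.0), so the four
  combination masks genuinely differ.
- **Background**: additive Gaussian noise (default σ = 0.05), clipped to
  [0, 1]; the image is then snapped to the 8-bit grid so in-memory pixels
  equal the stored PNG exactly.
- **Ground truth** applies the labelling rule mechanically: a pixel is in
  mask(C) iff it lies in some core footprint and every channel of C strictly
  exceeds `intensity_threshold` (default 0.5 of dynamic range, standing in
  for the experts' "significant intensity" judgement).  Masks are computed
  from the final quantized image, so brute-force re-thresholding reproduces
  them exactly, and mask(RGB) ⊆ mask(RG) ∩ mask(RB) ∩ mask(GB) by
  construction.

Default sizes (6 cores, radii 10–28 px at 256²) give per-combination
ground-truth fractions of a few percent of the image, the same order as real
quantifications.  What the generator does **not** emulate: point-spread
blur and confocal optics, channel bleed-through, antibody-specific
morphology (fibrillar texture, processes), intensity gradients, and
inter-rater label noise.  Passing tests therefore demonstrate that the
pipeline is correct and that the network can learn joint-threshold
colocalization structure — not that it reaches clinical-image accuracy.

## Scaled-down experiments

`tangleseg.experiments.scaled_learning_check` fixes one reduced
configuration that the whole pipeline can run end-to-end in minutes on one
CPU: 30 easy-contrast synthetic images at 64×64 (5 cores, radii 6–14, peaks
0.85–1.0, noise σ = 0.02), `base_filters` = 8 with the full five-level /
four-decoder architecture, an 80/20 holdout (24 train / 6 held out), fourfold
augmentation of the training split, 10 epochs, batch 4, Adam 5e−4.  These
problem sizes are the package's own choice of the smallest configuration on
which learning is clearly demonstrable; the acceptance script
(`scripts/acceptance.py`) reruns it from scratch and reports held-out mean
DC/IoU/TP/FP and the first/final epoch losses, alongside the protocol
arithmetic (fold sizes, fourfold augmentation, parameter counts, the ln 2
closed form of the loss at probability ½, and quantification exactness).

## Numerical choices and edge cases

- float32 throughout training; float64 available for gradient checking.
- Sigmoid input clipped to ±80 to avoid overflow in `exp`; BCE clipping at
  1e−7 bounds the perfect-prediction loss near 1.2e−6.
- Max-pool gradient goes to the first argmax on ties (relevant for flat ReLU
  regions); this is a valid subgradient.
- Mask resizing is nearest-neighbour + re-binarization at 0.5 of range, so
  masks never acquire intermediate values; image resizing is anti-aliased
  bilinear.
- Mask files are written as lossless PNG; the reader also accepts JPEG labels
  and binarizes at 50% of dynamic range, which recovers binary content under
  ±10-gray-level compression noise.
- Empty training sets, empty folds, non-square rotations, non-binary masks
  and indivisible input sizes raise typed errors naming the offending field.

## Known limitations

- CPU-only numpy training: minutes at the reduced scale, but the full
  256×256 / 50-epoch / 97-image protocol would take days; the code path is
  identical, only the problem size differs.
- No learning-rate schedule, early stopping, or batch normalization (none are
  part of the protocol; the architecture diagram shows no normalization
  layers).
- The generator's Gaussian-blob model makes the learning task easier than
  clinical morphology; headline clinical metrics are not reproducible from
  synthetic data and are not claimed.
- Physical pixel size (26.97–134.85 μm fields) is carried only as optional
  metadata; quantification is per-pixel-fraction, not per-μm².
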