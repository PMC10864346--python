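# Methods

## Problem and model

Microscopy images of living cells are often acquired at low light to avoid
phototoxicity, so the images fed to a segmentation network are noisy, dim or
blurred. `aepseg` implements a two-network pipeline that *learns* its own
preprocessing instead of relying on hand-tuned classical filters:

1. **First network** `f1`: a lightweight U-Net-style encoder-decoder with two
   output convolutions. The second convolution produces the C class logits;
   the *first* one produces the penultimate feature maps — `m·C` channels
   (multiplier `m` = 1 by default, so one channel per class).
2. **Translation (AEP)**: each penultimate channel, passed through ReLU then
   sigmoid, is an additive *translation filter*. Adding filter `c` to the
   input `x` yields translated image `x̂_c` that emphasizes structures
   relevant to class `c`. ReLU discards negative activations (which would
   erase object shapes), the sigmoid bounds the filter in (0, 1).
3. **Second network** `f2` (single output convolution) segments each
   translated image independently with shared parameters.
4. **Fusion (AWEL)**: the `S = 1 + m·C` logit maps — `f1`'s own output plus
   one per translated image — are stacked and fused by a point-wise 3D
   convolution: a 1×1×1 kernel, stride 1, padding 0, acting only along the
   source axis, i.e. one trainable scalar weight per source:
   `fused = Σ_i w_i · stack_i`. Fixing all `w_i = 1` gives the plain
   unweighted logit-sum ensemble (the fixed-weight control); freezing the
   fusion off entirely reduces prediction to the mean of `f2`'s outputs.

Training minimizes the sum of softmax cross-entropies over every head,

    Loss = CE(f1 logits) + CE(fused logits) + Σ_c CE(f2 logits on x̂_c),

so the second network's errors backpropagate through the filters into the
first network's trunk: the filters are supervised only by segmentation
labels, never by any high-quality reference image.

### Two readings of the translation equation

The formula for the translated image is ambiguous about where the sigmoid
applies, and the two readings have different ranges:

* `variant="printed"` (default): `x̂_c = x + sigmoid(relu(f'_c))`; each
  translated pixel lies in `[x + 0.5, x + 1)`.
* `variant="text"`: `x̂_c = sigmoid(x + relu(f'_c))`; translated images are
  normalized into (0, 1).

Both are implemented and selectable in `TrainConfig`; every log line and
saved config records which variant is active. All range contracts in the
test suite state the variant they assume.

## Network architecture

The trunk is deliberately lighter than the original U-Net (one convolution
per layer instead of blocks of three), since two networks are trained
simultaneously:

* encoder: 1 input layer (3×3 conv at full resolution) + 6 encoder layers —
  three blocks of two, the first layer of each block downsampling with a
  stride-2 convolution; channels double per block from `base_channels`.
* decoder: 6 decoder layers — three blocks of a 2×2/stride-2
  transposed-convolution layer followed by a 3×3 convolution layer; skip
  connections concatenate encoder features at each resolution.
* every layer is conv → batch norm → ReLU → dropout (rate 0.2 by default).

The distribution of the six encoder layers over blocks and the downsampling
operator are design choices (the architecture description we follow does
not pin them down); they live in `NetworkConfig` (`depth`, `base_channels`,
`dropout_rate`) so other readings remain expressible. Inputs must be
divisible by `2^depth` (8 by default); the shape error names the padding
needed.

Because no deep-learning framework is part of the dependency set, the
package carries its own minimal numpy engine (`aepseg.nn`): im2col + BLAS
matmul convolutions, explicit backward passes, batch normalization with
running statistics, inverted dropout drawing from a caller-owned generator,
and Adam. A finite-difference check against backprop on a 16×16 input (in
float64, relative error < 1e-3) is part of the test suite.

## Training protocol

Images are normalized to [0, 1]; no other preprocessing. Adam with
lr = 1e-3, betas (0.9, 0.999), batch size 16. Cross-entropy is reduced by
the mean over pixels and batch (a sum is recoverable by scaling the
learning rate) so lr is stable across image sizes. k-fold cross-validation
assigns folds by seeded permutation followed by contiguous chunking; fold
sizes differ by at most one. The final-epoch model is used (no early
stopping); best-validation checkpointing is available but off by default.
All randomness — data generation, weight init, shuffling, dropout — fans
out from one top-level seed through named sub-seeds, so identical configs
reproduce identical histories bitwise.

AWEL weights initialize at `1/S` (training starts from an unweighted
average) and carry no bias by default, so the fixed-weight control
(`w_i = 1`, plain sum) is exactly reproducible; a config switch enables the
standard convolution bias. In `awel_mode="off"` the fused head and its loss
term are dropped and prediction uses the unweighted mean of the second
network's outputs (literally the single second-network output when there is
one translated image).

## Synthetic data

The generator emulates multi-cell fields: a seeded Voronoi-like tessellation
of cell centers (Poisson-disk rejection keeps centers separated) whose
region boundaries form closed membranes of configurable thickness; in
3-class mode a nucleus disk is placed strictly inside each cell, its radius
a fraction of the center's clearance from the membrane. Class ids are
0 = cytoplasm, 1 = membrane, 2 = nucleus (3-class) and 0 = background,
1 = membrane (2-class). The image is a rendering of the mask with per-class
base intensities on the 8-bit scale (cytoplasm 160, membrane 70, nucleus
230; background 170) plus Gaussian texture noise (SD 10 by default),
clipped to [0, 255] — i.e. classes are intensity-separable up to noise,
with the realistic class imbalance of thin membranes.

Three pseudo-degradations operate on the 0–255 scale (σ = 100 is only
meaningful there) and clip the result: additive Gaussian noise
(μ = 0, σ = 100), a constant contrast shift (μ = −100, σ = 0), and Gaussian
blur (kernel 5, σ = 0.3·((k−1)·0.5 − 1) + 0.8, mirror borders — the blur σ
and border mode are unstated upstream, so these conventions are recorded in
config and overridable). Note that clipping a σ = 100 field at the 8-bit
bounds shrinks the *observed* SD of a mid-gray image's residual to ≈ 82;
statistical checks therefore address the pre-clip field, exposed as
`synthetic.noise_field`.

What the generator does **not** emulate: optical point-spread functions,
structured illumination artifacts, intensity gradients across the field,
touching nuclei, or annotation noise. Passing tests on this data shows the
*mechanism* works — filters form, translation enhances, fusion weights
adapt, gradients reach every component — not that the accuracy numbers
transfer to real micrographs.

## Evaluation

Per-class IoU and Dice from exact integer confusion counts; the identity
`DSC = 2·IoU/(1+IoU)` holds per class on shared counts and is asserted in
tests. A class absent from both masks (0/0) is excluded from that image's
average — scoring it 0 or 1 would deflate or inflate scores on images
lacking a class. Metrics are computed per image and averaged over the
evaluation set (pooled-pixel aggregation is a flag). Fold aggregation
reports mean ± SD across folds.

Classical baselines (median, Gaussian, bilateral, Sobel magnitude,
Frangi/vesselness; kernels 3 and 9) are applied as preprocessing before the
same plain single-network trainer used for the no-preprocessing control, so
preprocessing is the only variable. Frangi uses scikit-image defaults.

The ablation harness varies exactly one axis at a time — `awel_mode`
(off / fixed / automated), `filter_source` (penultimate / raw / softmax /
argmax first-network output), or `filter_multiplier` (×1…×5) — with shared
fold assignments and seeds across rows, asserted by fold-hash comparison.
Argmax filters are one-hot and treated as constants for gradients (ties
break to the lowest class index); softmax filters are probabilities and are
added to the input directly, without the sigmoid chain.

## Scaled-down benchmark

The repository's end-to-end check trains on 60 generated 3-class fields at
64×64 (48 train / 12 held out under a 5-fold split), base width 8, 30
epochs, three seeds — sizes chosen so the whole study runs on a single CPU
core in minutes while still exercising every pipeline component. At this
scale both the joint pipeline and the plain single-network control reach
high accuracy on the intensity-separable synthetic fields; the test asserts
that training losses fall, that the pipeline's mean test IoU clears 0.55,
and that it lands within a small margin of the control, which mirrors the
method's directionality without asserting full-scale margins (at full scale
the two-network pipeline is reported to overtake the single network after
an order of magnitude more epochs than this benchmark runs).

## Known limitations

* Convergence at 30 epochs is far from the 300-epoch protocol the method
  was designed for; the joint pipeline converges more slowly than a single
  network early in training because the second network chases a
  nonstationary input distribution while the filters form.
* The numpy engine is single-threaded and CPU-bound; it is sized for
  ≤ 128×128 images and base widths ≤ 16, not for production training.
* Batch-norm evaluation statistics are running averages with momentum 0.1;
  with very few steps per epoch they lag the batch statistics early in
  training.
* The synthetic fields make class identity nearly a per-pixel intensity
  decision; absolute scores on them say nothing about real micrographs.
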