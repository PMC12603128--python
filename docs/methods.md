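# Methods

This note documents the model, the data pipelines, and the design choices
made where more than one reasonable construction exists, so results computed
with the package can be interpreted and reproduced precisely.

## Architecture

The network is an encoder–bottleneck–decoder U-Net over single-channel
inputs of size `S × S` (default 128, `S` divisible by 16), with per-pixel
softmax outputs.

**First block.** With `use_inception=True` (default), four parallel branches
process the input at full resolution: a 1×1 convolution (64 filters); a 1×1
reduction (96) followed by a 3×3 convolution (128); a 1×1 reduction (16)
followed by a 5×5 convolution (32); and a 3×3 stride-1 max-pool followed by a
1×1 convolution (32). Branch outputs are concatenated to 256 channels. With
`use_inception=False` the first block is a plain pair of 3×3 convolutions
(64 filters), emulating the baseline ablation. Either way a 2×2 max-pool
follows, which is required for the bottleneck to sit at `S/16`.

**Encoder.** Three further blocks of two 3×3 convolutions (128, 256, 512
filters), each convolution followed by batch normalization and ReLU, each
block by a 2×2 max-pool. Dropout (rate 0.5) is applied after the convolution
pairs of the two deeper encoder blocks and after each bottleneck convolution.

**Bottleneck.** Two 3×3 convolutions with 1024 filters (+BN, ReLU, dropout).
With `use_dual_output=True`, a 1×1 convolution with `n_classes` filters and a
per-pixel softmax produce the auxiliary bottleneck output at `S/16 × S/16`.

**Decoder.** Four stages of: 2×2 transposed convolution with stride 2 to the
stage's filter count (512/256/128/64), concatenation with the matching
encoder skip tensor (the last stage concatenates the 256-channel first-block
output), then two 3×3 convolutions (+BN, ReLU). A final 1×1 convolution with
`n_classes` filters and softmax yields the segmentation map.

### Parameter accounting

Two independent counters must agree for every valid configuration:
`count_parameters_analytic` evaluates the closed forms
(`k²·c_in·c_out + c_out` per convolution; `2c` trainable + `2c` running
statistics per batch-norm; zero for pooling/dropout/softmax) over the layer
plan without building arrays, and `count_parameters_built` sums the realized
network's arrays. The default binary configuration yields 31,475,396 total,
31,463,140 trainable and 12,256 non-trainable parameters. Conventions pinned
by this accounting — they are exactly the set under which the counts above
arise:

- upsampling is a 2×2 transposed convolution with stride 2, bias, ReLU and
  **no** batch normalization (parameter-free upsampling would change the
  trainable count by +1,347,200 in following convolutions);
- batch normalization follows **every** convolution, including all six
  Inception-branch convolutions, but **neither 1×1 output head**;
- the last decoder stage has 64 filters and concatenates the first-block
  output;
- every convolution carries a bias; padding is 'same'; tensors are
  channel-last.

The transposed-conv activation is not dictated by the counts (it is
parameter-neutral); ReLU is used. Dropout placement is likewise
parameter-neutral. Toggling `use_dual_output` changes the count by exactly
`bottleneck_filters · n_classes + n_classes` (2,050 for the binary default).

### Numpy network engine

No GPU framework is used: `spineseg.nn` implements the needed layers with
hand-derived backward passes (convolution via im2col/tensordot, with the
input gradient computed as a convolution against the spatially flipped,
channel-transposed kernel; 2×2 transposed convolution as a per-pixel linear
map onto disjoint 2×2 blocks; batch-norm with the standard training-mode
gradient; max-pool backward by argmax scatter) and Adam
(β₁=0.9, β₂=0.999, ε=1e-7). Batch-norm uses ε=1e-3 and momentum 0.99 for the
running statistics. Weights are He-normal initialized from an explicit seed;
all arrays are float32. Backward passes are verified against central finite
differences in the test suite. ReLU uses the subgradient 0 at exactly 0; a
branch whose pre-activation is identically zero (possible at initialization
in inference mode) therefore receives zero gradient, which is the standard
convention.

## Preprocessing

Volumes (MetaImage via SimpleITK, NIfTI via nibabel, slice axis first) go
through: T1 selection by case-insensitive regex on the series tag (default
substring `t1`); central slice at `floor(depth/2)` (the even-depth convention
must be fixed somewhere; floor is used); min–max rescale to integer [0, 255]
with round-half-up, constant slices mapping to zero; resize to the working
size — bilinear for the image, which is then divided by 255 into [0, 1], and
nearest-neighbor for labels so no new label values can appear; one-hot
encoding of the class-index map plus a bottleneck target built by
nearest-neighbor downsampling of the class map to `S/16` and one-hot encoding.

Nearest-neighbor label resizing is implemented by explicit pixel-center index
mapping (`src = floor((i + 0.5)·in/out)`) rather than a generic interpolator:
the rule is exact, order-free, and independently checkable by a brute-force
loop. Majority-vote pooling for the bottleneck target was rejected for the
same reason (ties would need an arbitrary order-dependent break). The 8-bit
intermediate is kept rather than folded into one rescale so that the [0, 1]
inputs are exactly `x/255` of the stored 8-bit values.

Binary masks use the rule nonzero → foreground. Multiclass work requires a
user-supplied total `LabelMap` (raw code → {0 background, 1 vertebra, 2 disc,
3 canal}); no raw-code default is hard-coded because annotation coding schemes
differ between datasets.

## Losses

For one-hot target `y` and softmax probabilities `ŷ` (clipped to
`[1e-7, 1−1e-7]` before logarithms):

- **BCE** and **focal** (`α(1−p_t)^γ(−log p_t)`, defaults α=0.5, γ=2.0) are
  averaged per scalar entry across *all* channels, so the binary 2-channel
  head and the 4-class head are treated uniformly. For complementary
  softmax channels this equals twice the single-channel mean.
- **Dice** is computed per channel over the whole batch (batch-Dice, not
  per-image), as `1 − (2Σyŷ + s)/(Σy + Σŷ + s)` with smoothing `s = 1`
  added to numerator and denominator (prevents 0/0 on empty classes; a
  both-empty channel contributes loss 0), then averaged over channels.
- **BCE-Dice** and **CCE-Dice** are `λ₁·CE + λ₂·Dice` with λ₁=λ₂=1 by
  default. **CCE** averages `−Σ_c y_c log ŷ_c` over pixels.

Each loss has an analytic gradient with respect to `ŷ` used by the trainer
(chained through the softmax Jacobian), checked against finite differences.

## Metrics

All pixel metrics derive from one additive per-class confusion accumulator,
pooled over the evaluated set (micro pooling; per-image reporting remains
possible by evaluating per image). IoU of a class absent from both maps is
defined as 1; mean IoU averages over classes. For two classes,
precision/recall/F1 are foreground-class values (the clinically meaningful
class); for more classes they are macro averages. Boundaries are foreground
pixels with at least one 4-neighbor that is background or off-image.
Hausdorff distance and ASSD are Euclidean, in pixel units at the working
resolution, reported as means of per-image values; images with an empty
boundary on either side are skipped with a warning.

## Phantoms

`spineseg.phantom` draws a gently curved vertical column of 5–7 (default 6)
bright rounded-rectangle vertebral bodies, darker elliptical discs strictly
between consecutive bodies, and a thin dark canal stripe following the
column posteriorly, over a dark background — the intensity ordering
(bright marrow 0.75, disc 0.45, canal 0.25, background 0.10) mimics
T1-weighted contrast. The rendered image is Gaussian-blurred (σ=0.7 px) and
corrupted with additive Gaussian noise (σ=0.03), while the masks keep the
crisp pre-blur geometry, so ground truth is exact and edges are soft. All
geometry defaults are fractions of the image size; per-structure jitter (8%)
and the column bow are drawn from the sample's explicit seed, and dataset
seeds are spawned from one master seed, so generation is bit-reproducible.
Foreground occupies 17–19% of pixels at defaults, echoing the
background-dominant class balance of spinal MRI.

The phantoms deliberately do **not** model scanner physics (bias fields,
Rician noise, partial-volume effects), pathology, inter-subject anatomy
variation or 3D structure. A model that segments them well has demonstrated
that the architecture, losses, optimizer and evaluation plumbing work
end-to-end — not clinical-grade performance.

## Training protocol

Adam at learning rate 1e-4, batch size 2, 50 epochs by default. The split is
80% training (of which 20% validation) and 20% test, computed on indices
from an explicit seed; the stability harness keeps train/test fixed across
runs while re-sampling validation and re-initializing weights per run seed,
and reports per-run metrics with mean ± sample (n−1) standard deviation.
Both heads receive the same loss with weights (1.0, 1.0) by default — the
combination rule is exposed in config since deep supervision weighting is a
free choice. No early stopping is used (fixed epoch budget). Inference and
evaluation use the final head only.

The end-to-end convergence check trains a quarter-scale replica (64×64
input, encoder 32/64/128, bottleneck 256, Inception scaled by ¼ so its
64-channel output keeps the full model's 2:1 ratio to the next stage) on 80
phantoms for 30 epochs with Dice loss — sized to finish in about three
minutes on one CPU core while leaving a wide margin over the mIoU > 0.8
pass bar (measured runs reach ≈ 0.99).

## Grad-CAM

For dense softmax outputs the class score is defined as the spatial sum of
the chosen class's final softmax channel. Channel weights are the
global-average-pooled gradients of that score with respect to the target
layer's activations (default: the last decoder activation before the 1×1
head); the map is `ReLU(Σ_c w_c A_c)`, bilinearly upsampled to the input
size and min–max normalized to [0, 1], with an all-zero map left all-zero.
The heatmap is invariant to positive rescaling of the weighted sum by
construction of the normalization.

## Known limitations

- The numpy engine targets correctness and reproducibility, not throughput;
  full-scale 128×128 training with the 31.5M-parameter model is possible but
  slow on a CPU (the reduced configuration exists for exactly this reason).
- Batch-Dice and micro-pooled metrics are declared choices; other packages
  sometimes average per image, which changes values on heterogeneous sets.
- Baseline architectures (ResUNet, Attention U-Net, TransUNet) and
  attention-augmented skip connections are out of scope; the plain-first-block
  ablation does not claim to reproduce any published baseline parameter
  count, whose batch-norm placement is not documented.
- 3D segmentation is out of scope: volumes contribute their central slice
  only.
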