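# Methods

## Model

`angioseg` segments coronary vessels in angiographic video by classifying
every pixel of a target frame using a temporal window of 2N+1 consecutive
frames. The input layer is a 3D convolution of kernel size (2N+1)×3×3 with
spatial padding 1, no temporal padding, and stride 1 on all axes; with a
single-channel (grayscale) frame stack this collapses the temporal depth to
1 and emits 16 channels of 2D feature maps. Implementation note: a depth-D
3D convolution over a 1-channel stack with no z-padding is arithmetically
identical to a 2D convolution whose input channels are the D temporal
slices, and it is computed that way. Two consequences are exploited and
tested: N = 0 *is* the 2D single-frame baseline (not an approximation of
it), and any 2D model can be embedded exactly in the 3D-2D parameter space
by zeroing the off-centre temporal slices — so the 2D model's achievable
performance lower-bounds the 3D-2D model's.

The 2D body follows the CE-Net design: a 3×3 fusion convolution (16 → first
encoder width) + 2×2 max-pool (to 1/2 resolution), four residual encoder
stages with the ResNet-34 block counts (3, 4, 6, 3) at widths (64, 128, 256,
512) × `width_multiplier`, a dense-atrous-convolution cascade (dilations 1,
3, 5, then 1×1; each stage ReLU-activated and added residually) and a
residual multi-kernel pooling block (max-pools of kernel 2, 3, 5, 6, each
projected to one channel and upsampled back, concatenated onto the input) at
the bottleneck, then four decoder stages (1×1 reduce → 3×3 stride-2
transposed convolution → 1×1 expand), and a 3×3 conv + 1×1 conv + sigmoid
head. Instance normalization (no running statistics) and ReLU follow every
convolution except the output.

Design choices where the architecture was genuinely open:

* **Skip connections** are additive after channel matching (decoder stage k
  outputs the width of encoder stage k−1 and is summed with it).
* **Fusion width**: the post-fusion 2D convolution outputs the first encoder
  width (64 at multiplier 1). Only the 3D layer's 16 channels are fixed.
* **Resolution accounting**: the stem halves resolution once (pool) and the
  encoders three more times (/16 total), so the fourth decoder already
  restores full resolution; the head therefore upsamples no further.
* **RMP on small bottlenecks**: pooling kernels are clamped to the feature
  map size, so any input size divisible by 32 is valid (e.g. 64 gives a 4×4
  bottleneck).
* **Initialization**: Kaiming-normal convolution weights, zero biases, unit
  instance-norm gains, all drawn from one seeded generator — two networks
  built with the same seed are identical. Optional encoder weights can be
  loaded from an `.npz` (`pretrained_weights`); only convolution kernels
  with matching shapes are taken, since normalization statistics do not
  transfer across normalization flavours. Default is random initialization.

## Training

Loss: `L = (1 − dice) + ρ·Σw²` with a per-image soft dice
`(2Σpy + ε)/(Σp + Σy + ε)` averaged over the batch; ε (`dice_smooth`,
default 1.0) makes the empty-vs-empty case score 1. The dice gradient with
respect to the probability map is closed-form and seeded into the network's
backward pass; the regularizer contributes `2ρw` per parameter. Optimizer is
plain SGD (optional classical momentum, default 0), seeded shuffling of the
pooled windows each epoch, fixed learning rate. Defaults follow the
full-scale recipe (lr 2×10⁻⁴, batch 4, 100 epochs, instance norm); ρ
defaults to 10⁻⁴ (unspecified at full scale; small enough that the dice term
dominates) and optimizer-level weight decay is never applied on top of the
explicit ρ term. Desk-scale runs (the benchmark, the examples) use lr 0.05
with momentum 0.9, because plain SGD at 2×10⁻⁴ is matched to ~10⁴ images ×
100 epochs, not to a few hundred windows; this choice was fixed before the
benchmark was measured and is not tuned per run. Divergence (non-finite
loss) aborts with a diagnostic rather than continuing.

## Data pipeline

Clips are windowed after a hard-cut partition: each clip contributes a
contiguous block of ceil(L/6) frames at its head or tail (seeded fair coin
per clip) as test data, the rest as training data. Ceiling rounding
guarantees every clip at least one test frame. Each subset is then padded
independently by replicating its first and last frame N times, and one
window of depth 2N+1 is extracted per original frame — so window counts sum
exactly to L and no window ever mixes frames across the cut (asserted by
index bookkeeping over L = 7..200 in the tests). Frames are converted to
luminance in [0,1] and bilinearly resized to the network size (default
448 × 448, any multiple of 32 works); labels are resized nearest-neighbour
and re-binarized at >127 (8-bit). Preprocessing happens per frame before
windowing; preprocessing at the target size is exactly idempotent.

## Synthetic angiogram simulator

The simulator emulates the properties of clinical angiographic video that
the model exploits, not its anatomy or physics:

* **Geometry**: a branching tree of smooth (cubic-spline) centerlines rooted
  at an image border; children sprout from a random point on their parent
  with radius tapered by `radius_taper`. Rasterization marks pixel centres
  within `radius − 0.5` of the centerline, so a radius-r stroke is 2r pixels
  wide (verified against a stadium-area oracle).
* **Contrast dynamics**: each branch has an arrival frame (by default
  staggered by tree depth); masks are empty before the earliest arrival and
  grow monotonically for static geometry.
* **Motion**: a global sinusoidal displacement with period ~0.9 s at the
  clip's frame rate (one cardiac cycle), rounded to integer pixels per
  frame; amplitudes below 0.5 px therefore render as static.
* **Noise**: Poisson photon noise (`poisson_scale`, default 60 counts at
  full intensity) followed by Gaussian read-out noise (σ = 0.08), applied to
  frames only.
* **Occlusions**: with probability `occlusion_rate` (default 0.3) per frame,
  one contiguous arc (25–55% of a visible branch's length) is blanked to
  background intensity in the *frame* while the ground-truth mask keeps it.
  Occlusion draws are i.i.d. across frames, so neighbouring frames usually
  reveal what the target frame hides — measurably: the fraction of mask
  pixels that look like vessel in at least one of frames t−1..t+1 exceeds
  the fraction visible in frame t alone.
* **Intensities**: vessels at 0.25 vs background 0.75 (contrast agent
  absorbs X-rays), plus a static coarse clutter field (σ = 0.03).

Everything is a deterministic function of the spec including its seed
(separate named substreams for geometry, motion, occlusion, noise);
identical specs give bit-identical sequences, which the tests assert.

What passing on this data does **not** show: robustness to real anatomy
(foreshortening, crossing vessel *trees*, catheters and ribs), to
non-sinusoidal motion, to detector-specific noise, or to annotation noise in
human labels. The benchmark demonstrates the *mechanism* — temporal fusion
recovering frame-local information loss — not clinical performance.

## Evaluation

Vessel is the positive class. Sensitivity, specificity, accuracy, vessel and
background IOU, and dice are computed from exact pixel tallies; a ratio with
zero denominator is 1 if the class is absent from both masks, else 0.
Reports always carry both aggregations (mean of per-image metrics, and
metrics of pooled counts); per-image mean is the default headline.
Predictions are thresholded at 0.5; optional post-processing deletes
8-connected components smaller than `min_area` (default 64 px at 448×448,
scaled by area — 3 px at 96×96), which can only remove predicted pixels and
never alters surviving components.

## Desk-scale benchmark

`angioseg.benchmark.temporal_benefit` renders 10 clips of 16 frames at
96×96 with occlusion rate 0.3, trains N=1 and N=0 models (width multiplier
0.25, 15 epochs, identical data/split/init seeds) for three repetitions, and
compares held-out vessel IOU. Clip length matters for this comparison: with
16-frame clips the 3-frame test blocks contain windows with two *real*
temporal neighbours, whereas shorter clips leave only boundary windows whose
padding replicates the target frame — which dilutes exactly the information
the temporal layer uses. The clip count is the one axis reduced relative to
a larger study so that the full comparison (six training runs) stays within
minutes on one CPU with the package's NumPy engine (~80 ms per training
sample forward+backward); all sizes are the package's standing study
conditions, not tunable per run. `scripts/acceptance.py` re-runs this
benchmark (two repetitions, for runtime) plus the two exactness probes and
writes the numbers as JSON.

## Numerical engine

The package includes a small reverse-mode autodiff over NumPy float32
arrays. Convolutions are lowered to GEMM via im2col; the transposed
convolution and the data-gradient of the forward convolution share one
adjoint routine, keeping them consistent by construction (an adjoint
identity ⟨convT(x), g⟩ = ⟨x, conv(g)⟩ is tested directly). Max-pooling uses
argmax scatter; instance-norm backward uses the standard normalized-input
formula. All layer gradients are verified against central finite differences
at float32-appropriate tolerances, and the convolution forward against
`scipy.signal.correlate`. Inference runs under a no-tape mode so constant
inputs cost no gradient memory.

## Known limitations

* No data augmentation, learning-rate schedule, or early stopping.
* Training throughput is CPU-bound; full-scale runs (448×448, width 1) are
  out of desk reach — the architecture supports them, the engine is simply
  slow at that size.
* The simulator's motion is a rigid global sinusoid; real coronary motion is
  non-rigid.
* ImageNet-pretrained encoder weights are supported only via a user-supplied
  `.npz` of convolution kernels.
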