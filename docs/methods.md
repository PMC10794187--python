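# Methods

## Problem and pipeline

The package estimates the number of leaves of a rosette plant from a single
top-down RGB image. Two tasks are solved in sequence and trained
independently: binary leaf segmentation, and count regression from the image
concatenated with its (normalized) leaf mask. The segmented channel gives
the counter an explicit figure–ground separation, which matters most where
the background is green or image quality is poor; the RGB channels retain
texture and shading cues the mask lacks. The ablation experiment
(`run_ablation`) quantifies that design directly by training matched
4-channel and 3-channel models on identical seeds and budgets.

## Segmentation model

Encoder stages of (n_convs, width) Conv Blocks — convolution (3×3, no bias)
→ batch normalization → ReLU — each followed by 2×2 max-pooling that records
argmax indices. The decoder mirrors the encoder: index-based unpooling (each
pooled value returns to the exact position it came from; elsewhere zeros)
followed by the stage's Conv Blocks, the last of which steps the width down
to the previous stage's. A final 1×1 convolution with bias and a sigmoid
produce per-pixel leaf probabilities. Training minimizes mean binary
cross-entropy; the gradient is taken through the fused sigmoid+BCE form
(p − y)/N for numerical stability, and the public `bce_loss` clips
probabilities to [1e-7, 1 − 1e-7].

Two scale presets exist. `desk` (64×64, stages (2,8),(2,16)) trains in tens
of seconds on one CPU. `benchmark` (224×224, stages
(2,64),(2,128),(3,256),(3,512),(3,512)) follows the VGG-style five-stage
encoder used at benchmark scale; its exact filter accounting is not pinned
to any published parameter total — fidelity is to the architecture family.

## Threshold normalization layer

`normalize_mask(m, t=0.5)` zeroes every value strictly below t and passes
values ≥ t unchanged (ties kept, since only sub-threshold values are
"unwanted"); an optional `binarize` flag maps kept values to 1. The operator
is idempotent and its output contains no value in (0, t). It is applied to
every predicted mask before the counter consumes it. Ground-truth masks are
binary, so the layer is the identity on them, which keeps the ground-truth
and segmenter-fed training paths interchangeable.

## Counting model

Input is H×W×4 (RGB + mask) or H×W×3 in the image-only ablation mode. Each
stage applies one 1×1 Conv Block with bottleneck width p_s, then three 3×3
Conv Blocks at width w_s, then 2×2 max-pooling; configuration requires
p_s < w_s. The triple-3×3 stack is the parameter-economical stand-in for a
single 5×5 Conv Block at the same width: with the preceding bottleneck the
stage costs fewer trainable parameters whenever p_s ≲ 0.7 w_s, which holds
on every default stage (p_s ≤ w_s/2). The head is global average pooling
and one linear unit with no output activation; predictions are real numbers,
rounded half-away-from-zero and clamped at zero only at evaluation time.

The `benchmark` preset uses four stages (24,48),(48,96),(96,192),(192,416) at
224×224: 4,976,625 trainable parameters (conv weights + batch-norm
scale/shift + linear head), i.e. 5M to the nearest million. The `desk`
preset uses (4,8),(8,16),(16,32) at 64×64 (9,589 parameters).

Training minimizes the smooth L1 (Huber) loss with δ = 1 (configurable)
under Adam. The head bias is initialized to the mean training count, so
optimization starts from the best constant predictor instead of spending
hundreds of Adam steps walking the bias up from zero — with bounded Huber
gradients and lr 1e-3..3e-3 that walk would otherwise dominate the budget.

## Numerical core

No deep-learning framework is used; `leafcount.nn` implements the layers on
NumPy (float32, NCHW) with explicit backpropagation: im2col + BLAS matmul
convolutions, batch normalization (biased batch variance; running statistics
with momentum 0.1, eps 1e-5, used in eval mode), max-pool/unpool via
recorded argmax indices, and Adam with bias correction. Analytic gradients
are verified against central finite differences in float64 in the test
suite. Training is exactly reproducible given the seed: weight
initialization (He), batch shuffling and the simulator all derive their
generators from `numpy.random.SeedSequence` keyed by (seed, stream), and no
global RNG state is touched.

## Synthetic rosette generator

The simulator emulates the regime of the public rosette benchmarks: 3–15
partially overlapping leaves arranged radially around a plant center,
imaged top-down over soil, pot, or green backgrounds. A leaf is a rotated
ellipse: leaf k of a c-leaf plant sits at base angle 2πk/c plus uniform
jitter, displaced radially by a sampled offset, oriented along its radius,
with length/width sampled per leaf and a per-leaf green color. Pixels are
inside a leaf iff the rotated-ellipse quadratic form evaluated at the pixel
center is ≤ 1; the mask is the exact union of leaf interiors and the count
is exact by construction. Rendering adds painter's-order occlusion, a mild
radial shading per leaf, a linear illumination ramp in a random direction,
and additive Gaussian noise (clipped to [0,1]); the mask is unaffected by
illumination and noise. `overlap_level` ∈ [0,1] multiplies angular jitter by
(1 + level) and leaf width by (1 + level/2), pushing neighbors into each
other. Images and masks are written as 8-bit PNG ({0,255} masks) with a CSV
manifest; generation is byte-reproducible from (seed, index) via
per-image `SeedSequence` sub-seeds.

Difficulty presets: `easy` = 3–8 leaves, jitter 0.08 rad, overlap 0.1, soil
background, noise σ 0.01 — leaves rarely merge and color separates
figure from ground; `hard` = 3–15 leaves, jitter 0.25 rad, overlap 0.8,
green background, noise σ 0.03 — heavy occlusion and no color cue.

What the simulator does **not** model: real leaf shapes (serration, petiole,
tip taper), specular highlights, shadows, moss/soil clutter, camera blur,
perspective, or growth-stage correlations between leaf size and count.
Passing the desk-scale tests therefore shows the pipeline learns and the
architecture carries the intended signal; it does not certify benchmark
accuracy on real plant photographs.

## Data plumbing

Images resize by bilinear interpolation at aligned pixel centers
((i + 0.5)·H/H′ − 0.5, edge-clamped); masks resize by nearest-neighbor so
they stay binary. Augmentation is the benchmark set: vertical flip (row
order reversed; the common imaging convention, configurable) and 90°/180°
rotations in both directions, applied identically to image and mask, counts
copied verbatim; augmented copies are materialized on disk. Splitting
assigns round(n·fraction) records to val and test and the remainder to
train via a seeded shuffle — 2010 records at fractions 1410/2010, 300/2010,
300/2010 give exactly 1410/300/300. Augmentation defaults to the training
split only.

## Metrics

Counting: DiC = mean(ĉ − c), AbsDiC = mean|ĉ − c|, MSE, R² = 1 − SS_res/SS_tot
(undefined, and raised, for constant ground truth), percentage agreement =
100 · #{ĉ = c}/n. Metrics are computed on rounded integer predictions by
default; a raw mode exists for MSE/R² sensitivity. Segmentation: pixel
accuracy, IoU and Dice, micro-aggregated (confusion counts pooled over all
pixels before ratios). Conventions chosen for continuity: IoU = Dice = 1
when both masks are empty, 0 when exactly one is; probability masks must be
thresholded (at the normalization layer's 0.5) before mask metrics.

## Desk-scale training budgets

Chosen so the full suite (three seeds per experiment) runs on one CPU in
minutes, and frozen before the acceptance runs: dataset = easy preset,
64×64, 350 images split 200/50/100, generator seed 11; segmenter = desk
config, Adam lr 3e-3, batch 16, 10 epochs; counter = desk config, Adam lr
3e-3, batch 8, 18 epochs with lr × 0.2 at epoch 12, ground-truth masks,
δ = 1. Under these budgets the desk segmenter reaches test IoU ≈ 0.95 and
the combined-input counter ≈ 80–95% agreement (AbsDiC ≈ 0.05–0.2) across
seeds; the image-only counter is consistently worse, reproducing the
direction of the combined-input ablation.

## Design choices where the design was open

- Mask values at exactly the threshold are kept (only "less than" is
  zeroed); `binarize` covers users wanting hard masks.
- The counter's stage count/widths at benchmark scale were set to four
  stages with p_s = w_s/2 (last stage 192→416) so the parameter total lands
  at 5M; the published description fixes the stage pattern but not its depth
  or widths.
- Optimizer settings not pinned by the architecture description (segmenter
  optimizer, learning rates, batch sizes, δ) are exposed in `TrainConfig`
  with the defaults above.
- Counting metrics round predictions before scoring; exact-match agreement
  only makes sense on integers.
- Split remainder goes to train; shuffling is uniform (no stratification by
  count).

## Known limitations

- CPU-bound NumPy training: benchmark-scale (224×224, 5M-parameter)
  training is out of reach here; the `benchmark` presets are provided for
  architecture fidelity and parameter accounting, not for training runs.
- The simulator's ellipse leaves make segmentation easier than real foliage;
  segmentation scores on synthetic data overstate real-data performance.
- Instance-level (per-leaf) segmentation metrics such as best Dice are out
  of scope; the segmenter is strictly binary figure/ground.
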