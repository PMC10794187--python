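# leafcount

Leaf counting for top-down images of rosette plants (Arabidopsis-like
rosettes and komatsuna pot plants). Counting leaves from images is a core
plant-phenotyping measurement — leaf number tracks growth stage and
genotype–environment effects — but it is hard where leaves overlap or the
background is green. This package implements a two-stage CNN pipeline for
that problem, together with the evaluation metrics used by the counting
benchmarks and a procedural rosette simulator, so the whole pipeline can be
trained and tested end-to-end on one CPU with no external data.

The pipeline:

1. **Leaf segmentation** — an encoder–decoder network (SegNet-style: Conv
   Blocks with 2×2 max-pooling whose argmax indices drive the decoder's
   unpooling) maps an H×W×3 image to an H×W×1 leaf-probability mask through
   a sigmoid, trained with binary cross-entropy.
2. **Threshold normalization** — a filter that zeroes every mask value below
   a threshold t = 0.5, removing low-confidence speckle caused by uneven
   background or reflections; values ≥ t pass through unchanged.
3. **Count regression** — the counting network concatenates the RGB image
   with the normalized mask (4 input channels) and applies stages of one 1×1
   Conv Block (a narrow bottleneck, p_s < w_s filters) followed by three 3×3
   Conv Blocks (width w_s) and a 2×2 max-pool; global average pooling and a
   single linear unit output the real-valued count ĉ. A Conv Block is
   convolution (no bias) → batch normalization → ReLU. Training minimizes
   the smooth L1 (Huber) loss

   L(d) = ½d²  for |d| < δ,  δ(|d| − ½δ) otherwise,  d = ĉ − c, δ = 1,

   under Adam. Predictions are rounded half-away-from-zero and clamped at 0.

At benchmark scale (224×224 input, stage widths (24,48), (48,96), (96,192),
(192,416)) the counting network has 4,976,625 trainable parameters (~5M).

Counting metrics: DiC (mean signed error), AbsDiC (mean absolute error),
MSE, R², and percentage agreement (share of images counted exactly right).
Segmentation metrics: pixel accuracy, IoU, Dice.

All networks run on a small NumPy layer library with explicit
backpropagation (`leafcount.nn`) — no GPU or deep-learning framework needed.

## Worked example

`examples/03_train_counter.py` generates 80 synthetic rosettes (32×32,
3–8 leaves), trains a reduced-width counter on ground-truth masks for 30
epochs, and evaluates on the held-out quarter:

```
final train smooth-L1 loss: 0.1642
test DiC=+0.20  AbsDiC=0.30  MSE=0.30  R2=0.896  agreement=70%  (n=20)
```

AbsDiC 0.30 means the prediction is off by 0.3 leaves on average; 70%
agreement means 14 of the 20 test plants were counted exactly right; DiC
near 0 means no systematic over- or under-count. The other examples cover
simulation (`01`), segmentation plus the threshold layer (`02`), the
combined-input-vs-image-only ablation (`04`) and the full
segment→normalize→count pipeline (`05`).

A thin CLI wraps the same functions:

```bash
leafcount simulate --preset desk --out runs/data
leafcount train-seg   --manifest runs/data/manifest.csv --out runs/seg
leafcount train-count --manifest runs/data/manifest.csv --out runs/count
leafcount evaluate    --manifest runs/data/manifest.csv \
    --checkpoint runs/count/counter.npz --split test --out runs/report.json
leafcount ablation    --manifest runs/data/manifest.csv --out runs/ablation.json
```

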