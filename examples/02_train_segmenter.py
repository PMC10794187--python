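"""Train a small encoder-decoder leaf segmenter and apply the threshold layer.

Builds a reduced-width segmenter, trains it briefly on tiny synthetic
rosettes, then shows the effect of the normalization (threshold) layer on
the predicted probability mask: sub-threshold background speckle is zeroed
while confident leaf pixels pass through.
"""

from dataclasses import replace

import numpy as np

import leafcount as lc
from leafcount.sim import EASY
from leafcount.train import TrainConfig

params = replace(EASY, n_images=40, canvas=(32, 32), leaf_length_range=(8.0, 13.0),
                 leaf_width_range=(2.5, 4.5), radial_offset_range=(2.0, 5.0), seed=1)
manifest = lc.generate_dataset(params, "scratch_example_seg")
manifest = lc.split_dataset(manifest, lc.SplitSpec(0.75, 0.125, 0.125, seed=1))

config = lc.SegConfig(input_size=(32, 32), stages=((1, 6), (1, 12)))
model = lc.build_segnet(config, seed=0)
model, history = lc.train_segmenter(model, manifest, TrainConfig(lr=3e-3, batch_size=8,
                                                                 epochs=6, seed=0))
print("per-epoch binary cross-entropy (train):",
      [round(r["train_loss"], 3) for r in history.records])
report = lc.evaluate_segmenter(model, manifest, split="test")
print(f"test accuracy={report.accuracy:.3f} IoU={report.iou:.3f} Dice={report.dice:.3f}")

sample = manifest.load_sample(0)
proba = lc.predict_mask(model, sample.rgb)
cleaned = lc.normalize_mask(proba)
print(f"probability mask: {np.sum((proba > 0) & (proba < 0.5))} pixels below threshold")
print(f"after normalization layer: {np.sum((cleaned > 0) & (cleaned < 0.5))} "
      "(every sub-threshold pixel was zeroed)")
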