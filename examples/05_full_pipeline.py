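"""End-to-end pipeline: segment, normalize, count, evaluate.

Trains the segmenter, feeds its threshold-normalized predictions (not the
ground truth) as the counter's mask channel, and scores the final counts --
the full deployment path in which only RGB images are available at test time.
"""

from dataclasses import replace

import numpy as np

import leafcount as lc
from leafcount.sim import EASY
from leafcount.train import TrainConfig

params = replace(EASY, n_images=100, canvas=(32, 32), leaf_length_range=(8.0, 13.0),
                 leaf_width_range=(2.5, 4.5), radial_offset_range=(2.0, 5.0), seed=9)
manifest = lc.generate_dataset(params, "scratch_example_pipeline")
manifest = lc.split_dataset(manifest, lc.SplitSpec(0.6, 0.15, 0.25, seed=9))

seg = lc.build_segnet(lc.SegConfig(input_size=(32, 32), stages=((1, 6), (1, 12))), seed=0)
seg, _ = lc.train_segmenter(seg, manifest, TrainConfig(lr=3e-3, batch_size=8, epochs=6,
                                                       seed=0))
seg_report = lc.evaluate_segmenter(seg, manifest, split="test")
print(f"segmenter test IoU={seg_report.iou:.3f} Dice={seg_report.dice:.3f}")

config = lc.CountConfig(input_size=(32, 32), input_channels=4, stages=((3, 6), (6, 12)))
cfg = TrainConfig(lr=3e-3, batch_size=8, epochs=15, lr_step=10, seed=0,
                  mask_source="segmenter")
counter = lc.build_count_net(config, seed=0)
counter, _ = lc.train_counter(counter, manifest, cfg, seg_model=seg)

from leafcount.counting import predict_counts_for_split

raw, rounded, truth = predict_counts_for_split(counter, manifest, "test", cfg,
                                               seg_model=seg)
report = lc.count_report(rounded.astype(float), truth.astype(float))
print(f"counting via predicted masks: AbsDiC={report.abs_dic:.2f} "
      f"agreement={report.percentage_agreement:.0f}% (n={report.n})")
print("first five predictions vs truth:",
      list(zip(rounded[:5].tolist(), np.asarray(truth[:5], int).tolist())))
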