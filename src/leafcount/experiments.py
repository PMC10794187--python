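"""Canned experiments tying the modules together.

``run_counting_experiment`` trains one counter and scores it on the test
split; ``run_ablation`` trains matched combined-input (RGB+mask) and
image-only counters on identical seeds and budgets and reports both, the
direct test of what the mask channel buys.
"""

from __future__ import annotations

from dataclasses import replace
from statistics import median

import numpy as np

from .counting import CountConfig, CountModel, build_count_net, predict_counts_for_split, train_counter
from .data import DatasetManifest
from .metrics import CountMetricsReport, count_report
from .segmentation import SegModel
from .train import TrainConfig, TrainHistory


def run_counting_experiment(data: DatasetManifest, config: CountConfig, cfg: TrainConfig,
                            seg_model: SegModel | None = None,
                            ) -> tuple[CountModel, TrainHistory, CountMetricsReport]:
    """Train a counter on the train split and evaluate it on the test split."""
    model = build_count_net(config, seed=cfg.seed)
    model, history = train_counter(model, data, cfg, seg_model=seg_model)
    raw, rounded, y = predict_counts_for_split(model, data, "test", cfg, seg_model=seg_model)
    report = count_report(rounded.astype(np.float64), y.astype(np.float64))
    return model, history, report


def run_ablation(data: DatasetManifest, config4: CountConfig, cfg: TrainConfig,
                 seeds: tuple[int, ...] = (0, 1, 2)) -> dict:
    """Matched combined-input vs image-only comparison over several seeds.

    Returns per-seed test reports for both input modes plus the medians of
    AbsDiC and the combined-minus-image-only difference (negative favors the
    combined input).
    """
    if config4.input_channels != 4:
        raise ValueError("ablation baseline config must be the 4-channel combined model")
    config3 = replace(config4, input_channels=3)
    combined, image_only = [], []
    for seed in seeds:
        run_cfg = replace(cfg, seed=seed)
        _, _, rep4 = run_counting_experiment(data, config4, run_cfg)
        _, _, rep3 = run_counting_experiment(data, config3, run_cfg)
        combined.append(rep4)
        image_only.append(rep3)
    med4 = median(r.abs_dic for r in combined)
    med3 = median(r.abs_dic for r in image_only)
    return {
        "seeds": list(seeds),
        "combined": combined,
        "image_only": image_only,
        "median_abs_dic_combined": med4,
        "median_abs_dic_image_only": med3,
        "abs_dic_difference": med4 - med3,
    }
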