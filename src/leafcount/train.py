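"""Shared training plumbing: configuration, array loading, batching, history."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DatasetManifest, resize_bilinear
from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings shared by the segmenter and the counter.

    ``mask_source`` selects where the counter's mask channel comes from:
    ``ground_truth`` uses annotated masks, ``segmenter`` runs a trained
    segmentation model and feeds its (threshold-normalized) predictions.
    """

    lr: float = 1e-3
    batch_size: int = 16
    epochs: int = 20
    huber_delta: float = 1.0
    seed: int = 0
    mask_source: str = "ground_truth"
    lr_step: int | None = None  # epoch at which lr is multiplied by lr_gamma
    lr_gamma: float = 0.2
    stop_at_train_loss: float | None = None  # early stop once mean epoch loss drops below

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.lr_step is not None and self.lr_step < 1:
            raise ConfigurationError("lr_step must be >= 1 when set")
        if not 0.0 < self.lr_gamma <= 1.0:
            raise ConfigurationError("lr_gamma must be in (0, 1]")
        if self.huber_delta <= 0:
            raise ConfigurationError("huber_delta must be > 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.mask_source not in ("ground_truth", "segmenter"):
            raise ConfigurationError(
                f"mask_source must be 'ground_truth' or 'segmenter', got {self.mask_source!r}")


def load_split(manifest: DatasetManifest, split: str | None,
               size: tuple[int, int] | None = None,
               need_masks: bool = False, need_counts: bool = False):
    """Load one split into NCHW arrays: images (N,3,H,W), masks (N,H,W), counts (N,).

    Masks/counts arrays are None when not requested.
    """
    records = [r for r in manifest.records if split is None or r.split == split]
    if not records:
        raise ValidationError(f"no records in split {split!r}")
    if need_masks:
        missing = [r.image_path for r in records if not r.mask_path]
        if missing:
            raise ValidationError(f"records lacking masks: {missing}")
    if need_counts:
        missing = [r.image_path for r in records if r.count is None]
        if missing:
            raise ValidationError(f"records lacking counts: {missing}")
    imgs, masks, counts = [], [], []
    index = {id(r): i for i, r in enumerate(manifest.records)}
    for r in records:
        sample = manifest.load_sample(index[id(r)])
        if size is not None and sample.rgb.shape[:2] != tuple(size):
            sample = resize_bilinear(sample, size)
        imgs.append(sample.rgb.transpose(2, 0, 1))
        if need_masks:
            masks.append(sample.mask)
        if need_counts:
            counts.append(sample.count)
    x = np.stack(imgs).astype(np.float32)
    m = np.stack(masks).astype(np.float32) if need_masks else None
    y = np.asarray(counts, dtype=np.float32) if need_counts else None
    return x, m, y


def batch_indices(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


@dataclass
class TrainHistory:
    """Per-epoch training log; one record per epoch run."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kw):
        self.records.append(kw)

    def __len__(self):
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path
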