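"""Encoder-decoder leaf segmentation (SegNet-style) and the threshold
normalization layer.

The encoder is a stack of Conv Blocks (conv -> batch norm -> ReLU) with 2x2
max-pooling that records argmax indices; the decoder mirrors the encoder and
upsamples with index-based unpooling, ending in a 1x1 convolution and a
sigmoid, so an H x W x 3 image maps to an H x W x 1 leaf-probability mask.
Training minimizes binary cross-entropy against binary leaf masks.

The normalization layer post-processes a probability mask by zeroing every
value below a threshold (default 0.5), which removes spurious low-confidence
pixels caused by uneven background or reflections while leaving confident
leaf pixels untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .data import DatasetManifest
from .errors import ConfigurationError
from .metrics import mask_report
from .train import TrainConfig, TrainHistory, batch_indices, load_split

#: scale presets: "desk" trains in seconds on one CPU; "benchmark" follows the
#: VGG-style (2,2,3,3,3)-conv encoder at 224x224 used at benchmark scale.
SEG_PRESETS = {
    "desk": {"input_size": (64, 64), "stages": ((2, 8), (2, 16))},
    "benchmark": {"input_size": (224, 224),
                  "stages": ((2, 64), (2, 128), (3, 256), (3, 512), (3, 512))},
}


@dataclass(frozen=True)
class SegConfig:
    """Architecture spec: encoder stages (n_convs, width), mirrored in the decoder."""

    input_size: tuple[int, int] = (64, 64)
    stages: tuple[tuple[int, int], ...] = ((2, 8), (2, 16))

    def __post_init__(self):
        if len(self.stages) < 1:
            raise ConfigurationError("stages must contain at least one stage")
        for n_convs, width in self.stages:
            if n_convs < 1 or width < 1:
                raise ConfigurationError(f"invalid stage spec {(n_convs, width)}")
        h, w = self.input_size
        factor = 2 ** len(self.stages)
        if h % factor or w % factor:
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by 2^{len(self.stages)}")

    @classmethod
    def preset(cls, name: str) -> "SegConfig":
        if name not in SEG_PRESETS:
            raise ConfigurationError(f"unknown preset {name!r}; choose from {list(SEG_PRESETS)}")
        return cls(**SEG_PRESETS[name])


class SegModel:
    """Configured encoder-decoder network with index-based unpooling."""

    def __init__(self, config: SegConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence((abs(int(seed)), 0x5E6)))
        widths = [w for _, w in config.stages]
        self.encoder: list[list[nn.ConvBlock]] = []
        in_c = 3
        for n_convs, width in config.stages:
            blocks = []
            for _ in range(n_convs):
                blocks.append(nn.ConvBlock(in_c, width, 3, rng))
                in_c = width
            self.encoder.append(blocks)
        # decoder mirrors the encoder; the last conv of decoder stage i maps
        # down to the width of stage i-1 (or stays at stage-0 width at the end)
        self.decoder: list[list[nn.ConvBlock]] = []
        for i in range(len(config.stages) - 1, -1, -1):
            n_convs, width = config.stages[i]
            out_width = widths[i - 1] if i > 0 else widths[0]
            blocks = []
            for j in range(n_convs):
                blocks.append(nn.ConvBlock(width, width if j < n_convs - 1 else out_width,
                                           3, rng))
            self.decoder.append(blocks)
        self.head = nn.Conv2d(widths[0], 1, 1, rng, bias=True)
        self._cache = None

    def layers(self):
        for stage in self.encoder:
            yield from stage
        for stage in self.decoder:
            yield from stage
        yield self.head

    def params(self) -> list[nn.Param]:
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def set_training(self, flag: bool) -> None:
        for layer in self.layers():
            layer.set_training(flag)

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 3, H, W) float32 -> logits (N, 1, H, W); caches for backward."""
        h, w = self.config.input_size
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2:] != (h, w):
            raise ValueError(f"expected input (N, 3, {h}, {w}), got {x.shape}")
        indices = []
        for stage in self.encoder:
            for block in stage:
                x = block.forward(x)
            x, idx = nn.MaxPool2d.forward(x)
            indices.append(idx)
        for stage in self.decoder:
            x = nn.MaxUnpool2d.forward(x, indices.pop())
            for block in stage:
                x = block.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        # rebuild the unpool index bookkeeping symmetrically
        idx_stack = self._fwd_indices
        for stage, idx in zip(reversed(self.decoder), self._decoder_indices_rev):
            for block in reversed(stage):
                g = block.backward(g)
            g = nn.MaxUnpool2d.backward(g, idx)
        for stage, idx in zip(reversed(self.encoder), reversed(idx_stack)):
            g = nn.MaxPool2d.backward(g, idx)
            for block in reversed(stage):
                g = block.backward(g)

    # forward_logits above is the inference path; training uses forward_train
    # which keeps the pooling indices needed by backward.
    def forward_train(self, x: np.ndarray) -> np.ndarray:
        h, w = self.config.input_size
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2:] != (h, w):
            raise ValueError(f"expected input (N, 3, {h}, {w}), got {x.shape}")
        indices = []
        for stage in self.encoder:
            for block in stage:
                x = block.forward(x)
            x, idx = nn.MaxPool2d.forward(x)
            indices.append(idx)
        self._fwd_indices = list(indices)
        decoder_indices = []
        for stage in self.decoder:
            idx = indices.pop()
            decoder_indices.append(idx)
            x = nn.MaxUnpool2d.forward(x, idx)
            for block in stage:
                x = block.forward(x)
        # store in the order the decoder consumed them, reversed for backward
        self._decoder_indices_rev = list(reversed(decoder_indices))
        return self.head.forward(x)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Batch inference: (N, 3, H, W) -> probabilities (N, H, W) in (0, 1)."""
        self.set_training(False)
        return nn.sigmoid(self.forward_logits(x))[:, 0]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        stats = {}
        for i, layer in enumerate(self.layers()):
            bn = getattr(layer, "bn", None)
            if bn is not None:
                stats[f"rm{i}"] = bn.running_mean
                stats[f"rv{i}"] = bn.running_var
        np.savez(path, **arrays, **stats)
        sidecar = {"input_size": list(self.config.input_size),
                   "stages": [list(s) for s in self.config.stages]}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        path = Path(path)
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        config = SegConfig(input_size=tuple(sidecar["input_size"]),
                           stages=tuple(tuple(s) for s in sidecar["stages"]))
        model = cls(config)
        with np.load(path) as data:
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"p{i}"]
            for i, layer in enumerate(model.layers()):
                bn = getattr(layer, "bn", None)
                if bn is not None:
                    bn.running_mean[...] = data[f"rm{i}"]
                    bn.running_var[...] = data[f"rv{i}"]
        return model


def build_segnet(config: SegConfig, seed: int = 0) -> SegModel:
    """Instantiate the encoder-decoder segmenter for the given config."""
    return SegModel(config, seed=seed)


def bce_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy over all pixels, with p clipped to [eps, 1-eps]."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    bad = np.setdiff1d(np.unique(target), [0.0, 1.0])
    if bad.size:
        raise ValueError("targets must be binary")
    p = np.clip(pred, eps, 1.0 - eps)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def normalize_mask(mask: np.ndarray, threshold: float = 0.5,
                   binarize: bool = False) -> np.ndarray:
    """Threshold filter: zero every value below ``threshold``; values at or
    above it pass through unchanged (or become 1 with ``binarize``).

    Idempotent, and the output contains no value in the open interval
    (0, threshold).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    mask = np.asarray(mask, dtype=np.float32)
    keep = mask >= threshold
    if binarize:
        return keep.astype(np.float32)
    return np.where(keep, mask, 0.0).astype(np.float32)


def predict_mask(model: SegModel, rgb: np.ndarray) -> np.ndarray:
    """Per-pixel leaf probability for one H x W x 3 image (or an N-batch)."""
    rgb = np.asarray(rgb, dtype=np.float32)
    single = rgb.ndim == 3
    if single:
        rgb = rgb[None]
    if rgb.ndim != 4 or rgb.shape[3] != 3:
        raise ValueError(f"expected H x W x 3 image(s), got shape {rgb.shape}")
    h, w = model.config.input_size
    if rgb.shape[1:3] != (h, w):
        raise ValueError(f"input must be resized to the model size {(h, w)}, got {rgb.shape[1:3]}")
    proba = model.predict_proba(rgb.transpose(0, 3, 1, 2))
    return proba[0] if single else proba


def train_segmenter(model: SegModel, data: DatasetManifest, train_cfg: TrainConfig
                    ) -> tuple[SegModel, TrainHistory]:
    """Optimize binary cross-entropy with Adam; logs per-epoch train/val loss
    and thresholded val accuracy/IoU/Dice. Deterministic given the seed."""
    x_tr, m_tr, _ = load_split(data, "train", size=model.config.input_size, need_masks=True)
    has_val = any(r.split == "val" for r in data.records)
    if has_val:
        x_va, m_va, _ = load_split(data, "val", size=model.config.input_size, need_masks=True)
    rng = np.random.default_rng(np.random.SeedSequence((abs(int(train_cfg.seed)), 0x7A)))
    opt = nn.Adam(model.params(), lr=train_cfg.lr)
    history = TrainHistory()
    for epoch in range(train_cfg.epochs):
        if train_cfg.lr_step is not None and epoch == train_cfg.lr_step:
            opt.lr *= train_cfg.lr_gamma
        model.set_training(True)
        losses = []
        for idx in batch_indices(len(x_tr), train_cfg.batch_size, rng):
            xb = x_tr[idx]
            yb = m_tr[idx][:, None]
            opt.zero_grad()
            logits = model.forward_train(xb)
            p = nn.sigmoid(logits)
            losses.append(bce_loss(p, yb))
            model.backward((p - yb).astype(np.float32) / p.size)
            opt.step()
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if has_val:
            model.set_training(False)
            proba = _predict_in_batches(model, x_va, train_cfg.batch_size)
            row["val_loss"] = bce_loss(proba, m_va)
            pred_bin = (normalize_mask(proba) >= 0.5).astype(np.uint8)
            rep = mask_report(pred_bin, m_va.astype(np.uint8))
            row.update(val_accuracy=rep.accuracy, val_iou=rep.iou, val_dice=rep.dice)
        history.append(**row)
        if train_cfg.stop_at_train_loss is not None \
                and row["train_loss"] < train_cfg.stop_at_train_loss:
            break
    model.set_training(False)
    return model, history


def _predict_in_batches(model: SegModel, x: np.ndarray, batch_size: int) -> np.ndarray:
    out = [model.predict_proba(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(out, axis=0)


def evaluate_segmenter(model: SegModel, data: DatasetManifest, split: str = "test",
                       batch_size: int = 16, threshold: float = 0.5):
    """Threshold the model's probability masks and score them against the
    ground truth of one split (micro-aggregated accuracy/IoU/Dice)."""
    from .train import load_split

    x, m, _ = load_split(data, split, size=model.config.input_size, need_masks=True)
    proba = _predict_in_batches(model, x, batch_size)
    pred = (normalize_mask(proba, threshold) >= threshold).astype(np.uint8)
    return mask_report(pred, m.astype(np.uint8))
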