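"""The leaf-count regression network: combined image+mask input, bottlenecked
Conv-Block stages, and a linear head.

The network concatenates the 3-channel RGB image with its 1-channel
segmented leaf mask (4 channels total; a 3-channel image-only mode exists
for the ablation). Each stage applies one 1x1 Conv Block with a narrow
bottleneck width followed by three 3x3 Conv Blocks at the stage width --
the triple 3x3 stack standing in for a single 5x5 at lower parameter cost --
then a 2x2 max-pool. Global average pooling and a single linear unit (no
output activation) regress the real-valued leaf count, trained with the
smooth L1 (Huber) loss under Adam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .data import DatasetManifest
from .errors import ConfigurationError, ValidationError
from .metrics import count_report
from .segmentation import SegModel, normalize_mask
from .train import TrainConfig, TrainHistory, batch_indices, load_split

#: scale presets. "benchmark" is the benchmark-scale schedule whose trainable
#: parameter total rounds to 5 million at 224x224x4 input; "desk" trains in
#: about a minute on one CPU at 64x64.
COUNT_PRESETS = {
    "desk": {"input_size": (64, 64), "stages": ((4, 8), (8, 16), (16, 32))},
    "benchmark": {"input_size": (224, 224),
                  "stages": ((24, 48), (48, 96), (96, 192), (192, 416))},
}


@dataclass(frozen=True)
class CountConfig:
    """Architecture spec: stages of (bottleneck_width, main_width)."""

    input_size: tuple[int, int] = (64, 64)
    input_channels: int = 4
    stages: tuple[tuple[int, int], ...] = ((4, 8), (8, 16), (16, 32))

    def __post_init__(self):
        if self.input_channels not in (3, 4):
            raise ConfigurationError(
                "input_channels must be 4 (combined) or 3 (image-only ablation)")
        if len(self.stages) < 1:
            raise ConfigurationError("stages must contain at least one stage")
        for p, w in self.stages:
            if p < 1 or w < 1:
                raise ConfigurationError(f"invalid stage widths {(p, w)}")
            if p >= w:
                raise ConfigurationError(
                    f"1x1 must have less filter size than the 3x3 stage width, got {(p, w)}")
        h, w = self.input_size
        factor = 2 ** len(self.stages)
        if h % factor or w % factor:
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by 2^{len(self.stages)}")

    @classmethod
    def preset(cls, name: str, input_channels: int = 4) -> "CountConfig":
        if name not in COUNT_PRESETS:
            raise ConfigurationError(f"unknown preset {name!r}; choose from {list(COUNT_PRESETS)}")
        return cls(input_channels=input_channels, **COUNT_PRESETS[name])


class CountModel:
    """Configured counting network; one real-valued output per sample."""

    def __init__(self, config: CountConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence((abs(int(seed)), 0xC07)))
        self.blocks: list[list[nn.ConvBlock]] = []
        in_c = config.input_channels
        for p, w in config.stages:
            stage = [nn.ConvBlock(in_c, p, 1, rng),
                     nn.ConvBlock(p, w, 3, rng),
                     nn.ConvBlock(w, w, 3, rng),
                     nn.ConvBlock(w, w, 3, rng)]
            self.blocks.append(stage)
            in_c = w
        self.gap = nn.GlobalAvgPool()
        self.head = nn.Linear(in_c, 1, rng)

    def layers(self):
        for stage in self.blocks:
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

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, C, H, W) -> (N,) raw real-valued counts; caches for backward."""
        h, w = self.config.input_size
        if x.ndim != 4 or x.shape[1] != self.config.input_channels or x.shape[2:] != (h, w):
            raise ValueError(
                f"expected input (N, {self.config.input_channels}, {h}, {w}), got {x.shape}")
        self._pool_indices = []
        for stage in self.blocks:
            for block in stage:
                x = block.forward(x)
            x, idx = nn.MaxPool2d.forward(x)
            self._pool_indices.append(idx)
        x = self.gap.forward(x)
        return self.head.forward(x)[:, 0]

    def backward(self, g: np.ndarray) -> None:
        """g: (N,) gradient of the loss w.r.t. the raw outputs."""
        g = self.head.backward(g[:, None])
        g = self.gap.backward(g)
        for stage, idx in zip(reversed(self.blocks), reversed(self._pool_indices)):
            g = nn.MaxPool2d.backward(g, idx)
            for block in reversed(stage):
                g = block.backward(g)

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
                   "input_channels": self.config.input_channels,
                   "stages": [list(s) for s in self.config.stages]}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CountModel":
        path = Path(path)
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        config = CountConfig(input_size=tuple(sidecar["input_size"]),
                             input_channels=sidecar["input_channels"],
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


def build_count_net(config: CountConfig, seed: int = 0) -> CountModel:
    """Instantiate the counting network for the given config."""
    return CountModel(config, seed=seed)


def count_parameters(model) -> int:
    """Total trainable scalars (conv weights, batch-norm scale/shift, linear
    weights/bias) of a counting or segmentation model."""
    return int(sum(p.value.size for p in model.params()))


def smooth_l1(pred, target, delta: float = 1.0) -> float:
    """Mean smooth-L1 (Huber) loss: 0.5 d^2 for |d| < delta, else
    delta (|d| - delta/2), with d = pred - target."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    d = np.abs(pred - target)
    per = np.where(d < delta, 0.5 * d * d, delta * (d - 0.5 * delta))
    return float(np.mean(per))


def smooth_l1_grad(pred: np.ndarray, target: np.ndarray, delta: float = 1.0) -> np.ndarray:
    """d(mean smooth-L1)/d(pred): clipped residual, divided by n."""
    d = pred - target
    return np.clip(d, -delta, delta).astype(np.float32) / d.size


def round_count(raw: float) -> int:
    """Round half away from zero, then clamp below at zero."""
    raw = float(raw)
    if not np.isfinite(raw):
        raise ValueError(f"count prediction must be finite, got {raw}")
    rounded = int(np.sign(raw) * np.floor(abs(raw) + 0.5))
    return max(rounded, 0)


def predict_count(model: CountModel, rgb: np.ndarray, mask: np.ndarray | None = None
                  ) -> float | np.ndarray:
    """Raw (unclamped, unrounded) count prediction for one image or a batch.

    ``rgb`` is H x W x 3 (or N x H x W x 3); ``mask`` is the normalized leaf
    mask H x W, required in combined (4-channel) mode and rejected in
    image-only mode.
    """
    rgb = np.asarray(rgb, dtype=np.float32)
    single = rgb.ndim == 3
    if single:
        rgb = rgb[None]
        if mask is not None:
            mask = np.asarray(mask, dtype=np.float32)[None]
    x = rgb.transpose(0, 3, 1, 2)
    if model.config.input_channels == 4:
        if mask is None:
            raise ValueError("combined-input model requires a mask channel")
        mask = np.asarray(mask, dtype=np.float32)
        if mask.shape != rgb.shape[:3]:
            raise ValueError(f"mask shape {mask.shape} does not match images {rgb.shape[:3]}")
        x = np.concatenate([x, mask[:, None]], axis=1)
    elif mask is not None:
        raise ValueError("image-only model takes no mask input")
    model.set_training(False)
    out = model.forward(x)
    return float(out[0]) if single else out


def _counter_inputs(model: CountModel, x: np.ndarray, masks: np.ndarray | None,
                    seg_model: SegModel | None, batch_size: int) -> np.ndarray:
    """Assemble NCHW input tensors, normalizing the mask channel."""
    if model.config.input_channels == 3:
        return x
    if seg_model is not None:
        proba = np.concatenate(
            [seg_model.predict_proba(x[i:i + batch_size]) for i in range(0, len(x), batch_size)])
        masks = normalize_mask(proba)
    else:
        masks = normalize_mask(masks)
    return np.concatenate([x, masks[:, None]], axis=1)


def train_counter(model: CountModel, data: DatasetManifest, cfg: TrainConfig,
                  seg_model: SegModel | None = None) -> tuple[CountModel, TrainHistory]:
    """Minimize smooth L1 between predicted and true counts with Adam.

    ``cfg.mask_source`` picks ground-truth masks or segmenter predictions for
    the mask channel (always passed through the threshold normalization
    layer). The head bias is initialized to the mean training count so the
    optimizer starts from an unbiased baseline. Deterministic given the seed.
    """
    if cfg.mask_source == "segmenter" and model.config.input_channels == 4 and seg_model is None:
        raise ConfigurationError("mask_source='segmenter' requires a seg_model")
    need_masks = model.config.input_channels == 4 and cfg.mask_source == "ground_truth"
    x_tr, m_tr, y_tr = load_split(data, "train", size=model.config.input_size,
                                  need_masks=need_masks, need_counts=True)
    xin_tr = _counter_inputs(model, x_tr, m_tr,
                             seg_model if cfg.mask_source == "segmenter" else None,
                             cfg.batch_size)
    has_val = any(r.split == "val" for r in data.records)
    if has_val:
        x_va, m_va, y_va = load_split(data, "val", size=model.config.input_size,
                                      need_masks=need_masks, need_counts=True)
        xin_va = _counter_inputs(model, x_va, m_va,
                                 seg_model if cfg.mask_source == "segmenter" else None,
                                 cfg.batch_size)
    model.head.b.value[...] = float(np.mean(y_tr))
    rng = np.random.default_rng(np.random.SeedSequence((abs(int(cfg.seed)), 0xC7)))
    opt = nn.Adam(model.params(), lr=cfg.lr)
    history = TrainHistory()
    for epoch in range(cfg.epochs):
        if cfg.lr_step is not None and epoch == cfg.lr_step:
            opt.lr *= cfg.lr_gamma
        model.set_training(True)
        losses = []
        for idx in batch_indices(len(xin_tr), cfg.batch_size, rng):
            xb, yb = xin_tr[idx], y_tr[idx]
            opt.zero_grad()
            out = model.forward(xb)
            losses.append(smooth_l1(out, yb, cfg.huber_delta))
            model.backward(smooth_l1_grad(out, yb, cfg.huber_delta))
            opt.step()
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if has_val:
            model.set_training(False)
            raw = np.concatenate([model.forward(xin_va[i:i + cfg.batch_size])
                                  for i in range(0, len(xin_va), cfg.batch_size)])
            row["val_loss"] = smooth_l1(raw, y_va, cfg.huber_delta)
            rounded = np.array([round_count(v) for v in raw], dtype=np.float64)
            try:
                rep = count_report(rounded, y_va)
                row.update(val_abs_dic=rep.abs_dic, val_agreement=rep.percentage_agreement)
            except ValueError:
                pass  # constant val counts leave r2 undefined; skip the report
        history.append(**row)
        if cfg.stop_at_train_loss is not None and row["train_loss"] < cfg.stop_at_train_loss:
            break
    model.set_training(False)
    return model, history


def predict_counts_for_split(model: CountModel, data: DatasetManifest, split: str,
                             cfg: TrainConfig, seg_model: SegModel | None = None):
    """Raw and rounded predictions for every record of a split, in order."""
    need_masks = model.config.input_channels == 4 and cfg.mask_source == "ground_truth"
    x, m, y = load_split(data, split, size=model.config.input_size,
                         need_masks=need_masks, need_counts=True)
    xin = _counter_inputs(model, x, m,
                          seg_model if cfg.mask_source == "segmenter" else None,
                          cfg.batch_size)
    model.set_training(False)
    raw = np.concatenate([model.forward(xin[i:i + cfg.batch_size])
                          for i in range(0, len(xin), cfg.batch_size)])
    rounded = np.array([round_count(v) for v in raw])
    return raw, rounded, y
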