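"""Run-level presets and YAML/JSON configuration loading.

A run config has sections ``sim``, ``seg``, ``count`` and ``train`` plus a
global ``seed``. The ``desk`` preset runs the whole pipeline in minutes on
one CPU (64x64 images, 200/50/100 synthetic samples, reduced widths); the
``benchmark`` preset is the full-scale geometry (224x224, full widths).
Precedence: explicit overrides > config file > preset defaults.
"""

from __future__ import annotations

import copy
import json
import hashlib
from dataclasses import replace
from pathlib import Path

import yaml

from .counting import CountConfig
from .errors import ConfigurationError
from .segmentation import SegConfig
from .sim import PRESETS as SIM_PRESETS, SimParams
from .train import TrainConfig

RUN_PRESETS: dict[str, dict] = {
    "desk": {
        "sim": {"preset": "easy", "n_images": 350, "canvas": [64, 64]},
        "split": {"train": 200 / 350, "val": 50 / 350, "test": 100 / 350},
        "seg": {"preset": "desk"},
        "count": {"preset": "desk"},
        "train_seg": {"lr": 3e-3, "batch_size": 16, "epochs": 10},
        "train_count": {"lr": 3e-3, "batch_size": 8, "epochs": 18, "lr_step": 12,
                        "mask_source": "ground_truth"},
        "seed": 0,
    },
    "benchmark": {
        "sim": {"preset": "hard", "n_images": 2010, "canvas": [224, 224]},
        "split": {"train": 1410 / 2010, "val": 300 / 2010, "test": 300 / 2010},
        "seg": {"preset": "benchmark"},
        "count": {"preset": "benchmark"},
        "train_seg": {"lr": 1e-3, "batch_size": 32, "epochs": 60},
        "train_count": {"lr": 1e-3, "batch_size": 32, "epochs": 120,
                        "mask_source": "segmenter"},
        "seed": 0,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_run_config(preset: str = "desk", config_file: str | Path | None = None,
                    overrides: dict | None = None) -> dict:
    """Expand a preset, then layer a YAML/JSON config file and overrides on top."""
    if preset not in RUN_PRESETS:
        raise ConfigurationError(f"unknown preset {preset!r}; choose from {list(RUN_PRESETS)}")
    cfg = copy.deepcopy(RUN_PRESETS[preset])
    if config_file is not None:
        text = Path(config_file).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {config_file} must contain a mapping")
        cfg = _deep_merge(cfg, loaded)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def sim_params_from(cfg: dict, seed: int | None = None) -> SimParams:
    section = dict(cfg.get("sim", {}))
    base = SIM_PRESETS[section.pop("preset")] if "preset" in section else SimParams()
    if "canvas" in section:
        section["canvas"] = tuple(section["canvas"])
    for key in ("count_range", "leaf_length_range", "leaf_width_range", "radial_offset_range"):
        if key in section:
            section[key] = tuple(section[key])
    if seed is not None:
        section["seed"] = seed
    elif "seed" not in section:
        section["seed"] = cfg.get("seed", 0)
    return replace(base, **section)


def seg_config_from(cfg: dict) -> SegConfig:
    section = dict(cfg.get("seg", {}))
    base = SegConfig.preset(section.pop("preset")) if "preset" in section else SegConfig()
    if "input_size" in section:
        section["input_size"] = tuple(section["input_size"])
    if "stages" in section:
        section["stages"] = tuple(tuple(s) for s in section["stages"])
    return replace(base, **section)


def count_config_from(cfg: dict, input_channels: int | None = None) -> CountConfig:
    section = dict(cfg.get("count", {}))
    base = CountConfig.preset(section.pop("preset")) if "preset" in section else CountConfig()
    if "input_size" in section:
        section["input_size"] = tuple(section["input_size"])
    if "stages" in section:
        section["stages"] = tuple(tuple(s) for s in section["stages"])
    if input_channels is not None:
        section["input_channels"] = input_channels
    return replace(base, **section)


def train_config_from(cfg: dict, section_name: str, seed: int | None = None) -> TrainConfig:
    section = dict(cfg.get(section_name, {}))
    if seed is not None:
        section["seed"] = seed
    elif "seed" not in section:
        section["seed"] = cfg.get("seed", 0)
    return TrainConfig(**section)


def config_hash(cfg: dict) -> str:
    """Stable short hash embedded in run artifacts for reconstructability."""
    text = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
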