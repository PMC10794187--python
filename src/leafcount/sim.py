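"""Procedural rosette-plant scenes with exact leaf masks and counts.

A rosette is modelled as ellipse-shaped leaves radiating from a central
point, the top-down geometry of Arabidopsis-like plants and of the komatsuna
pot images used in counting benchmarks. Each leaf k of a c-leaf plant sits
at base angle 2*pi*k/c plus jitter, displaced radially from the plant
center and oriented along its own radius. Backgrounds are procedural soil,
pot, or green textures; a green background and heavy leaf overlap are the
regimes that make real leaf segmentation and counting hard, so both are
reachable through presets.

Coordinate convention: row-major arrays, origin at the top-left corner,
pixel centers at integer (row, col); angles are measured counter-clockwise
from the +col axis (so +angle moves toward smaller row indices).

Determinism: every image derives its RNG from ``SeedSequence((seed, index,
stream))``, so a single (seed, index) pair regenerates a scene and its
rendered bytes exactly, with no global state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

from .data import DatasetManifest, ImageSample, ManifestRecord, write_image, write_mask
from .errors import ConfigurationError

BACKGROUNDS = ("soil", "pot", "green")


@dataclass(frozen=True)
class SimParams:
    """Generator configuration; defaults emulate the 3-15 leaf rosette regime.

    Lengths and widths are full leaf extents in pixels (the ellipse
    semi-axes are half of these). ``overlap_level`` in [0, 1] multiplies the
    angular jitter by (1 + level) and leaf widths by (1 + level/2), pushing
    neighboring leaves into each other.
    """

    n_images: int = 100
    count_range: tuple[int, int] = (3, 15)
    canvas: tuple[int, int] = (64, 64)
    leaf_length_range: tuple[float, float] = (16.0, 26.0)
    leaf_width_range: tuple[float, float] = (5.0, 9.0)
    angular_jitter: float = 0.15
    radial_offset_range: tuple[float, float] = (4.0, 10.0)
    overlap_level: float = 0.3
    background: str = "soil"
    illumination_amplitude: float = 0.2
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_images < 1:
            raise ConfigurationError("n_images must be >= 1")
        cmin, cmax = self.count_range
        if cmin < 0 or cmin > cmax:
            raise ConfigurationError(f"count_range must satisfy 0 <= c_min <= c_max, got {self.count_range}")
        h, w = self.canvas
        if h < 32 or w < 32:
            raise ConfigurationError(f"canvas dims must be >= 32, got {self.canvas}")
        lo_l, hi_l = self.leaf_length_range
        lo_w, hi_w = self.leaf_width_range
        if not (0 < lo_w <= hi_w):
            raise ConfigurationError(f"leaf_width_range must be positive and ordered, got {self.leaf_width_range}")
        if not (0 < lo_l <= hi_l):
            raise ConfigurationError(f"leaf_length_range must be positive and ordered, got {self.leaf_length_range}")
        if lo_l < hi_w:
            raise ConfigurationError("leaf_length_range must dominate leaf_width_range (length >= width)")
        if self.angular_jitter < 0:
            raise ConfigurationError("angular_jitter must be >= 0")
        lo_r, hi_r = self.radial_offset_range
        if lo_r < 0 or lo_r > hi_r:
            raise ConfigurationError(f"radial_offset_range must be ordered and non-negative, got {self.radial_offset_range}")
        if not 0.0 <= self.overlap_level <= 1.0:
            raise ConfigurationError("overlap_level must be in [0, 1]")
        if self.background not in BACKGROUNDS:
            raise ConfigurationError(f"background must be one of {BACKGROUNDS}, got {self.background!r}")
        if not 0.0 <= self.illumination_amplitude <= 1.0:
            raise ConfigurationError("illumination_amplitude must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")


# Difficulty presets: "easy" is low-jitter, low-overlap plants on soil;
# "hard" is heavy overlap on a green background (the regime real counting
# pipelines struggle with).
EASY = SimParams(count_range=(3, 8), angular_jitter=0.08, overlap_level=0.1,
                 background="soil", illumination_amplitude=0.15, noise_sigma=0.01)
HARD = SimParams(count_range=(3, 15), angular_jitter=0.25, overlap_level=0.8,
                 background="green", illumination_amplitude=0.3, noise_sigma=0.03)

PRESETS = {"easy": EASY, "hard": HARD}


@dataclass(frozen=True)
class LeafPrimitive:
    center: tuple[float, float]  # (row, col)
    orientation: float           # radians, CCW from +col axis
    semi_major: float
    semi_minor: float
    color: tuple[float, float, float]

    def __post_init__(self):
        if not (self.semi_major >= self.semi_minor > 0):
            raise ConfigurationError("leaf semi-axes must satisfy semi_major >= semi_minor > 0")


@dataclass(frozen=True)
class RosetteScene:
    leaves: tuple[LeafPrimitive, ...]
    plant_center: tuple[float, float]
    background: str
    count: int
    index: int = 0

    def __post_init__(self):
        if self.count != len(self.leaves):
            raise ConfigurationError("scene count must equal the number of leaves")


def _rng(seed: int, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((abs(int(seed)), int(index), stream)))


def generate_scene(params: SimParams, index: int) -> RosetteScene:
    """Draw one rosette: count ~ U(count_range), leaf k at 2*pi*k/count + jitter."""
    params.validate()
    if not 0 <= index < params.n_images:
        raise ConfigurationError(f"index {index} outside [0, {params.n_images})")
    rng = _rng(params.seed, index, 0)
    cmin, cmax = params.count_range
    count = int(rng.integers(cmin, cmax + 1))
    h, w = params.canvas
    center = (h / 2 + rng.uniform(-0.04, 0.04) * h, w / 2 + rng.uniform(-0.04, 0.04) * w)
    jitter = params.angular_jitter * (1.0 + params.overlap_level)
    width_mult = 1.0 + 0.5 * params.overlap_level
    leaves = []
    for k in range(count):
        base = 2.0 * math.pi * k / count
        ang = base + rng.uniform(-jitter, jitter)
        radius = rng.uniform(*params.radial_offset_range)
        length = rng.uniform(*params.leaf_length_range)
        width = min(rng.uniform(*params.leaf_width_range) * width_mult, length)
        # angles CCW from +col; rows grow downward, hence the -sin term
        leaf_center = (center[0] - radius * math.sin(ang), center[1] + radius * math.cos(ang))
        color = (rng.uniform(0.10, 0.22), rng.uniform(0.45, 0.70), rng.uniform(0.10, 0.22))
        leaves.append(LeafPrimitive(center=leaf_center, orientation=ang,
                                    semi_major=length / 2, semi_minor=width / 2, color=color))
    return RosetteScene(leaves=tuple(leaves), plant_center=center,
                        background=params.background, count=count, index=index)


def leaf_interior(leaf: LeafPrimitive, shape: tuple[int, int]) -> np.ndarray:
    """Boolean grid: pixel (r, c) is inside iff the rotated-ellipse form <= 1
    at the pixel center."""
    h, w = shape
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    dr = rows - leaf.center[0]
    dc = cols - leaf.center[1]
    ct, st = math.cos(leaf.orientation), math.sin(leaf.orientation)
    # project onto the leaf axes (angle CCW from +col, rows downward)
    u = dc * ct - dr * st
    v = dc * st + dr * ct
    return (u / leaf.semi_major) ** 2 + (v / leaf.semi_minor) ** 2 <= 1.0


def _background(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    h, w = params.canvas
    tex = ndi.gaussian_filter(rng.standard_normal((h, w)), sigma=2.0)
    tex /= max(np.abs(tex).max(), 1e-9)
    if params.background == "soil":
        base = np.array([0.36, 0.26, 0.16])
        img = base[None, None, :] + 0.08 * tex[:, :, None]
    elif params.background == "green":
        base = np.array([0.22, 0.38, 0.18])
        img = base[None, None, :] + 0.10 * tex[:, :, None]
    else:  # pot: dark disc on gray
        img = np.full((h, w, 3), 0.55) + 0.04 * tex[:, :, None]
        rr = np.arange(h)[:, None] - h / 2
        cc = np.arange(w)[None, :] - w / 2
        disc = rr ** 2 + cc ** 2 <= (0.45 * min(h, w)) ** 2
        img[disc] = np.array([0.16, 0.14, 0.13]) + 0.05 * tex[disc, None]
    return np.clip(img, 0.0, 1.0)


def render_scene(scene: RosetteScene, params: SimParams) -> ImageSample:
    """Rasterize a scene: background, painter's-order leaves, illumination,
    noise; the mask is the exact union of leaf interiors."""
    params.validate()
    h, w = params.canvas
    rng = _rng(params.seed, scene.index, 1)
    rgb = _background(params, rng)
    mask = np.zeros((h, w), dtype=np.uint8)
    for k, leaf in enumerate(scene.leaves):
        inside = leaf_interior(leaf, (h, w))
        if not inside.any():
            warnings.warn(f"leaf {k} lies fully outside the canvas; clipped (count unchanged)",
                          stacklevel=2)
            continue
        shade = 1.0 - 0.25 * ((np.arange(h)[:, None] - leaf.center[0]) ** 2
                              + (np.arange(w)[None, :] - leaf.center[1]) ** 2) ** 0.5 \
            / max(leaf.semi_major, 1e-9)
        shade = np.clip(shade, 0.6, 1.0)
        for ch in range(3):
            plane = rgb[:, :, ch]
            plane[inside] = leaf.color[ch] * shade[inside]
        mask[inside] = 1
    if params.illumination_amplitude > 0:
        phi = rng.uniform(0, 2 * math.pi)
        ramp = (math.cos(phi) * (np.arange(w)[None, :] - w / 2)
                + math.sin(phi) * (np.arange(h)[:, None] - h / 2)) / (max(h, w) / 2)
        rgb = rgb * (1.0 + params.illumination_amplitude * ramp[:, :, None])
    if params.noise_sigma > 0:
        rgb = rgb + rng.normal(0.0, params.noise_sigma, size=rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0).astype(np.float32)
    return ImageSample(rgb=rgb, mask=mask, count=scene.count, source="sim")


def generate_dataset(params: SimParams, out_dir: str | Path) -> DatasetManifest:
    """Write n_images image/mask PNG pairs plus a CSV manifest.

    Re-running with identical params reproduces byte-identical files.
    """
    params.validate()
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as e:
        raise OSError(f"output directory {out_dir} is not writable: {e}") from e
    records = []
    for i in range(params.n_images):
        scene = generate_scene(params, i)
        sample = render_scene(scene, params)
        img_rel = f"image_{i:05d}.png"
        mask_rel = f"mask_{i:05d}.png"
        write_image(out_dir / img_rel, sample.rgb)
        write_mask(out_dir / mask_rel, sample.mask)
        records.append(ManifestRecord(image_path=img_rel, mask_path=mask_rel,
                                      count=sample.count, source="sim", split="unassigned"))
    manifest = DatasetManifest(out_dir, records)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest
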