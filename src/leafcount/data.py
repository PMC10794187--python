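"""Dataset plumbing: image samples, CSV manifests, resizing, augmentation, splits.

Images are RGB float arrays in [0, 1] (H, W, 3); masks are binary uint8
(H, W) with values in {0, 1}. On disk both are 8-bit PNG, masks stored as
{0, 255}. A manifest is a CSV with header
``image_path,mask_path,count,source,split`` whose paths are relative to the
manifest's root directory.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from PIL import Image

from .errors import ValidationError

MANIFEST_COLUMNS = ["image_path", "mask_path", "count", "source", "split"]
SPLITS = ("train", "val", "test", "unassigned")


@dataclass
class ImageSample:
    """One plant image with optional leaf mask and leaf-count annotation."""

    rgb: np.ndarray
    mask: np.ndarray | None = None
    count: int | None = None
    source: str = "unknown"
    split: str = "unassigned"

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb, dtype=np.float32)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValidationError(f"rgb must be H x W x 3, got shape {self.rgb.shape}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.rgb.shape[:2]:
                raise ValidationError(
                    f"mask shape {self.mask.shape} does not match image {self.rgb.shape[:2]}")
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValidationError("mask values must be in {0, 1}")
            self.mask = self.mask.astype(np.uint8)
        if self.count is not None and self.count < 0:
            raise ValidationError("count must be non-negative")


@dataclass(frozen=True)
class ManifestRecord:
    image_path: str
    mask_path: str | None = None
    count: int | None = None
    source: str = "unknown"
    split: str = "unassigned"


@dataclass
class DatasetManifest:
    """Ordered collection of sample records, serialized as CSV."""

    root: Path
    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self):
        self.root = Path(self.root)
        paths = [r.image_path for r in self.records]
        if len(set(paths)) != len(paths):
            dupes = sorted({p for p in paths if paths.count(p) > 1})
            raise ValidationError(f"duplicate image paths in manifest: {dupes}")
        for r in self.records:
            if r.count is not None and r.count < 0:
                raise ValidationError(f"negative count for {r.image_path}")

    def __len__(self):
        return len(self.records)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(self.root, [r for r in self.records if r.split == split])

    def to_csv(self, path: str | os.PathLike) -> Path:
        df = pd.DataFrame(
            [
                {
                    "image_path": r.image_path,
                    "mask_path": r.mask_path or "",
                    "count": "" if r.count is None else int(r.count),
                    "source": r.source,
                    "split": r.split,
                }
                for r in self.records
            ],
            columns=MANIFEST_COLUMNS,
        )
        path = Path(path)
        df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | os.PathLike, root: str | os.PathLike | None = None
                 ) -> "DatasetManifest":
        path = Path(path)
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"manifest {path} missing columns {missing}")
        records = [
            ManifestRecord(
                image_path=row.image_path,
                mask_path=row.mask_path or None,
                count=int(row.count) if row.count != "" else None,
                source=row.source or "unknown",
                split=row.split or "unassigned",
            )
            for row in df.itertuples()
        ]
        return cls(Path(root) if root is not None else path.parent, records)

    def load_sample(self, i: int) -> ImageSample:
        r = self.records[i]
        rgb = read_image(self.root / r.image_path)
        mask = read_mask(self.root / r.mask_path) if r.mask_path else None
        return ImageSample(rgb=rgb, mask=mask, count=r.count, source=r.source, split=r.split)


def read_image(path: str | os.PathLike) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float32)
    return arr / 255.0


def read_mask(path: str | os.PathLike) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr >= 128).astype(np.uint8)


def write_image(path: str | os.PathLike, rgb: np.ndarray) -> None:
    arr = np.clip(np.asarray(rgb, dtype=np.float64) * 255.0, 0, 255)
    Image.fromarray(np.round(arr).astype(np.uint8), mode="RGB").save(path)


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255, mode="L").save(path)


# ---------------------------------------------------------------------------
# Resizing

def _resize_plane(img: np.ndarray, th: int, tw: int, order: int) -> np.ndarray:
    """Resample one plane at target pixel centers with edge clamping."""
    h, w = img.shape
    rows = (np.arange(th) + 0.5) * h / th - 0.5
    cols = (np.arange(tw) + 0.5) * w / tw - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndi.map_coordinates(img, [rr, cc], order=order, mode="nearest")


def resize_bilinear(sample: ImageSample, target: tuple[int, int]) -> ImageSample:
    """Bilinear-resample the image; the mask follows by nearest-neighbor.

    Target coordinates map to source coordinates through aligned pixel
    centers, (i + 0.5) * H / H' - 0.5, clamped at the edges, so an identity
    resize reproduces the input exactly and masks stay binary.
    """
    th, tw = target
    if th < 1 or tw < 1:
        raise ValueError(f"target size must be positive, got {target}")
    if (th, tw) == sample.rgb.shape[:2]:
        return replace(sample)
    rgb = np.stack(
        [_resize_plane(sample.rgb[:, :, c], th, tw, order=1) for c in range(3)], axis=2
    ).astype(np.float32)
    mask = None
    if sample.mask is not None:
        mask = _resize_plane(sample.mask.astype(np.float32), th, tw, order=0)
        mask = (mask > 0.5).astype(np.uint8)
    return ImageSample(rgb=np.clip(rgb, 0.0, 1.0), mask=mask, count=sample.count,
                       source=sample.source, split=sample.split)


# ---------------------------------------------------------------------------
# Augmentation

class AugmentationOp(enum.Enum):
    VFLIP = "vflip"
    ROT90CW = "rot90cw"
    ROT90CCW = "rot90ccw"
    ROT180 = "rot180"


def _transform(arr: np.ndarray, op: AugmentationOp) -> np.ndarray:
    # VFLIP mirrors about the horizontal axis (row order reversed).
    if op is AugmentationOp.VFLIP:
        return arr[::-1].copy()
    if op is AugmentationOp.ROT90CW:
        return np.rot90(arr, k=-1, axes=(0, 1)).copy()
    if op is AugmentationOp.ROT90CCW:
        return np.rot90(arr, k=1, axes=(0, 1)).copy()
    if op is AugmentationOp.ROT180:
        return np.rot90(arr, k=2, axes=(0, 1)).copy()
    raise ValueError(f"unknown augmentation op: {op!r}")


def apply_augmentation(sample: ImageSample, op: AugmentationOp) -> ImageSample:
    """Apply the same flip/rotation to image and mask; the count is unchanged."""
    if not isinstance(op, AugmentationOp):
        raise ValueError(f"unknown augmentation op: {op!r}")
    rgb = _transform(sample.rgb, op)
    mask = _transform(sample.mask, op) if sample.mask is not None else None
    return ImageSample(rgb=rgb, mask=mask, count=sample.count,
                       source=sample.source, split=sample.split)


def expand_with_augmentation(manifest: DatasetManifest, k_per_image: int,
                             seed: int) -> DatasetManifest:
    """Materialize k flipped/rotated copies per image next to the originals.

    Ops are drawn uniformly with the stated seed; counts and split labels are
    copied verbatim. Augmented files are named ``<stem>_aug<j>.png``.
    """
    if k_per_image < 0:
        raise ValueError("k_per_image must be >= 0")
    if k_per_image == 0:
        return DatasetManifest(manifest.root, list(manifest.records))
    rng = np.random.default_rng(np.random.SeedSequence((abs(int(seed)), 0xA06)))
    ops = list(AugmentationOp)
    new_records = list(manifest.records)
    for i, r in enumerate(manifest.records):
        sample = manifest.load_sample(i)
        for j in range(k_per_image):
            op = ops[int(rng.integers(len(ops)))]
            aug = apply_augmentation(sample, op)
            stem = Path(r.image_path)
            img_rel = str(stem.with_name(f"{stem.stem}_aug{j}.png"))
            write_image(manifest.root / img_rel, aug.rgb)
            mask_rel = None
            if r.mask_path:
                mstem = Path(r.mask_path)
                mask_rel = str(mstem.with_name(f"{mstem.stem}_aug{j}.png"))
                write_mask(manifest.root / mask_rel, aug.mask)
            new_records.append(ManifestRecord(img_rel, mask_rel, r.count, r.source, r.split))
    return DatasetManifest(manifest.root, new_records)


# ---------------------------------------------------------------------------
# Splitting and merging

@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test fractions (must sum to 1) plus a shuffle seed."""

    train: float
    val: float
    test: float
    seed: int = 0

    def __post_init__(self):
        for name in ("train", "val", "test"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {name}={f} outside [0, 1]")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_dataset(manifest: DatasetManifest, spec: SplitSpec) -> DatasetManifest:
    """Assign every record to exactly one split by a seeded shuffle.

    Validation and test sizes are round(n * fraction); the remainder goes to
    train (so 2010 records at fractions 1410/2010, 300/2010, 300/2010 give
    exactly 1410/300/300).
    """
    n = len(manifest)
    if n == 0:
        raise ValueError("cannot split an empty manifest")
    n_val = int(round(n * spec.val))
    n_test = int(round(n * spec.test))
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ValueError("val/test fractions leave no room for train")
    rng = np.random.default_rng(np.random.SeedSequence((abs(int(spec.seed)), 0x5B11)))
    order = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[order[:n_train]] = "train"
    labels[order[n_train:n_train + n_val]] = "val"
    labels[order[n_train + n_val:]] = "test"
    records = [replace_record(r, split=labels[i]) for i, r in enumerate(manifest.records)]
    return DatasetManifest(manifest.root, records)


def replace_record(r: ManifestRecord, **kw) -> ManifestRecord:
    d = {"image_path": r.image_path, "mask_path": r.mask_path, "count": r.count,
         "source": r.source, "split": r.split}
    d.update(kw)
    return ManifestRecord(**d)


def merge_manifests(a: DatasetManifest, b: DatasetManifest) -> DatasetManifest:
    """Concatenate two manifests, re-rooting paths at their common ancestor."""
    if len(b) == 0:
        return DatasetManifest(a.root, list(a.records))
    if len(a) == 0:
        return DatasetManifest(b.root, list(b.records))
    root = Path(os.path.commonpath([str(a.root.resolve()), str(b.root.resolve())]))

    def rebase(m: DatasetManifest) -> list[ManifestRecord]:
        out = []
        for r in m.records:
            img = os.path.relpath(m.root.resolve() / r.image_path, root)
            msk = os.path.relpath(m.root.resolve() / r.mask_path, root) if r.mask_path else None
            out.append(replace_record(r, image_path=img, mask_path=msk))
        return out

    ra, rb = rebase(a), rebase(b)
    dup = sorted({r.image_path for r in ra} & {r.image_path for r in rb})
    if dup:
        raise ValidationError(f"duplicate image paths across manifests: {dup}")
    return DatasetManifest(root, ra + rb)
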