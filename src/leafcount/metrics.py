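"""Counting and segmentation evaluation metrics.

Counting metrics (on paired integer predictions/ground truths):
DiC (mean signed difference), AbsDiC (mean absolute difference), MSE,
R-squared, and percentage agreement (exact matches, in percent).
Segmentation metrics (on binary masks): pixel accuracy, IoU (Jaccard) and
the Dice score. Mask metrics are micro-aggregated: confusion counts are
pooled over all pixels of all images before the ratios are taken.

Empty-mask conventions: IoU and Dice are 1 when both masks are empty and 0
when exactly one is (the continuous limits).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DatasetManifest, read_mask
from .errors import ValidationError


def _check_pair(pred, gt):
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {gt.shape}")
    if pred.size == 0:
        raise ValueError("empty prediction/ground-truth vectors")
    return pred.ravel(), gt.ravel()


def dic(pred, gt) -> float:
    """Mean signed difference in count, pred - gt (0 is unbiased)."""
    p, g = _check_pair(pred, gt)
    return float(np.mean(p - g))


def abs_dic(pred, gt) -> float:
    """Mean absolute difference in count."""
    p, g = _check_pair(pred, gt)
    return float(np.mean(np.abs(p - g)))


def mse_count(pred, gt) -> float:
    """Mean squared count error."""
    p, g = _check_pair(pred, gt)
    return float(np.mean((p - g) ** 2))


def r2(pred, gt) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    Undefined (raises) when the ground truth is constant.
    """
    p, g = _check_pair(pred, gt)
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r2 is undefined for constant ground truth")
    return float(1.0 - np.sum((g - p) ** 2) / ss_tot)


def percentage_agreement(pred, gt) -> float:
    """Percentage of samples whose predicted count equals the ground truth."""
    p, g = _check_pair(pred, gt)
    return float(100.0 * np.mean(p == g))


def _check_masks(pred_mask, gt_mask):
    p = np.asarray(pred_mask)
    g = np.asarray(gt_mask)
    if p.shape != g.shape:
        raise ValueError(f"mask shape mismatch: {p.shape} vs {g.shape}")
    for name, m in (("pred", p), ("gt", g)):
        if not np.all(np.isin(np.unique(m), (0, 1))):
            raise ValueError(f"{name} mask is not binary; threshold probabilities first")
    return p.astype(bool), g.astype(bool)


def pixel_accuracy(pred_mask, gt_mask) -> float:
    """Fraction of pixels on which the two masks agree."""
    p, g = _check_masks(pred_mask, gt_mask)
    return float(np.mean(p == g))


def iou(pred_mask, gt_mask) -> float:
    """Intersection over union; defined as 1 when both masks are empty."""
    p, g = _check_masks(pred_mask, gt_mask)
    union = np.sum(p | g)
    if union == 0:
        return 1.0
    return float(np.sum(p & g) / union)


def dice(pred_mask, gt_mask) -> float:
    """Dice score 2|A∩B| / (|A|+|B|); defined as 1 when both masks are empty."""
    p, g = _check_masks(pred_mask, gt_mask)
    denom = int(np.sum(p)) + int(np.sum(g))
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(p & g) / denom)


@dataclass(frozen=True)
class CountMetricsReport:
    dic: float
    abs_dic: float
    mse: float
    r2: float
    percentage_agreement: float
    n: int

    def __post_init__(self):
        if self.abs_dic + 1e-12 < abs(self.dic):
            raise ValidationError("AbsDiC must dominate |DiC|")
        if self.mse + 1e-9 < self.dic ** 2:
            raise ValidationError("MSE must dominate DiC^2")

    def to_json(self, path=None, **extra) -> str:
        payload = {"task": "counting", **asdict(self), **extra}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class SegMetricsReport:
    accuracy: float
    iou: float
    dice: float
    n_pixels: int

    def to_json(self, path=None, **extra) -> str:
        payload = {"task": "segmentation", **asdict(self), **extra}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def count_report(pred, gt) -> CountMetricsReport:
    """Aggregate all counting metrics for paired prediction/ground-truth vectors."""
    p, g = _check_pair(pred, gt)
    return CountMetricsReport(
        dic=dic(p, g), abs_dic=abs_dic(p, g), mse=mse_count(p, g),
        r2=r2(p, g), percentage_agreement=percentage_agreement(p, g), n=int(p.size))


def mask_report(pred_masks, gt_masks) -> SegMetricsReport:
    """Micro-aggregated mask metrics over an iterable of mask pairs."""
    tp = fp = fn = tn = 0
    for pm, gm in zip(pred_masks, gt_masks):
        p, g = _check_masks(pm, gm)
        tp += int(np.sum(p & g))
        fp += int(np.sum(p & ~g))
        fn += int(np.sum(~p & g))
        tn += int(np.sum(~p & ~g))
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("no pixels to evaluate")
    union = tp + fp + fn
    return SegMetricsReport(
        accuracy=(tp + tn) / total,
        iou=1.0 if union == 0 else tp / union,
        dice=1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn),
        n_pixels=total)


def evaluate_counts(predictions_csv: str | Path, manifest: DatasetManifest,
                    split: str | None = None, rounded: bool = True) -> CountMetricsReport:
    """Score a predictions CSV (image_path,raw_prediction,rounded_count)
    against a manifest's ground-truth counts."""
    from .counting import round_count

    df = pd.read_csv(predictions_csv)
    if "image_path" not in df.columns:
        raise ValidationError("predictions CSV must have an image_path column")
    pred_by_path = dict(zip(df["image_path"], df["raw_prediction"]))
    records = [r for r in manifest.records if split is None or r.split == split]
    missing = [r.image_path for r in records if r.image_path not in pred_by_path]
    if missing:
        raise ValidationError(f"no prediction for manifest records: {missing}")
    no_count = [r.image_path for r in records if r.count is None]
    if no_count:
        raise ValidationError(f"manifest records without counts: {no_count}")
    gt = np.array([r.count for r in records], dtype=np.float64)
    raw = np.array([pred_by_path[r.image_path] for r in records], dtype=np.float64)
    pred = np.array([round_count(v) for v in raw], dtype=np.float64) if rounded else raw
    return count_report(pred, gt)


def evaluate_masks(mask_dir: str | Path, manifest: DatasetManifest,
                   split: str | None = None) -> SegMetricsReport:
    """Score predicted mask PNGs (named after each record's image file)
    against the manifest's ground-truth masks."""
    mask_dir = Path(mask_dir)
    records = [r for r in manifest.records if split is None or r.split == split]
    unmatched = [r.image_path for r in records
                 if not (mask_dir / Path(r.image_path).name).exists()]
    if unmatched:
        raise ValidationError(f"no predicted mask for manifest records: {unmatched}")
    no_gt = [r.image_path for r in records if not r.mask_path]
    if no_gt:
        raise ValidationError(f"manifest records without ground-truth masks: {no_gt}")
    preds = (read_mask(mask_dir / Path(r.image_path).name) for r in records)
    gts = (read_mask(manifest.root / r.mask_path) for r in records)
    return mask_report(preds, gts)
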