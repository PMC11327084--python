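"""Dice loss, segmentation metrics, grouped validation means and overlays.

The training loss is the soft Dice loss over all N pixels,

    DiceLoss(p, t) = 1 - (2 * sum_i p_i t_i + eps) / (sum_i p_i^2 + sum_i t_i^2 + eps),

with a small smoothing constant guarding the empty-mask 0/0 case.
Evaluation metrics (Dice, IoU, pixel accuracy, precision) are derived from
per-image confusion counts on predictions binarised at 0.5, averaged
unweighted over the background and foreground classes for the "m"-prefixed
variants, and aggregated across a validation set by the grouped mean:
scores are partitioned in order into groups of ten, each group is averaged,
and the group averages are averaged — damping the influence of occasional
outlier images.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, as_tensor

logger = logging.getLogger(__name__)

SMOOTH_EPS = 1e-6

# Fig-style confusion overlay colours (RGB)
TP_COLOR = (128, 0, 128)  # purple
FN_COLOR = (255, 255, 0)  # yellow
FP_COLOR = (0, 255, 0)  # green


def _check_binary(t: np.ndarray) -> None:
    if not np.isin(t, (0, 1)).all():
        raise ValueError("mask must be binary (values in {0, 1})")


def dice_loss(p, t, eps: float = SMOOTH_EPS) -> Tensor:
    """Soft Dice loss; differentiable in ``p`` when it is a graph tensor."""
    p = as_tensor(p)
    t = as_tensor(t)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    _check_binary(t.data)
    num = 2.0 * (p * t).sum() + eps
    den = (p * p).sum() + (t * t).sum() + eps
    return 1.0 - num / den


def dice_coefficient(pred: np.ndarray, t: np.ndarray) -> float:
    """Hard Dice 2TP / (2TP + FP + FN) of a binary prediction."""
    c = confusion(pred, t)
    den = 2 * c.tp + c.fp + c.fn
    return 1.0 if den == 0 else 2 * c.tp / den


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, t: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts of a binary prediction against a binary mask."""
    pred = np.asarray(pred)
    t = np.asarray(t)
    if pred.shape != t.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {t.shape}")
    _check_binary(pred)
    _check_binary(t)
    p = pred.astype(bool)
    g = t.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        fp=int(np.count_nonzero(p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
        tn=int(np.count_nonzero(~p & ~g)),
    )


def _safe_ratio(num: int, den: int, class_present: bool, what: str) -> float:
    if den == 0:
        # class absent from both prediction and truth counts as perfect
        if not class_present:
            return 1.0
        logger.debug("empty denominator for %s with class present; scoring 0", what)
        return 0.0
    return num / den


def class_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Per-class IoU / pixel accuracy (recall) / precision for both classes.

    The background class uses the complementary counts (TN as its TP etc.).
    """
    out = {}
    for cls, (tp, fp, fn) in {
        "foreground": (c.tp, c.fp, c.fn),
        "background": (c.tn, c.fn, c.fp),
    }.items():
        present = (tp + fn + fp) > 0  # class occurs in prediction or truth
        out[f"iou_{cls}"] = _safe_ratio(tp, tp + fp + fn, present, f"IoU {cls}")
        out[f"pa_{cls}"] = _safe_ratio(tp, tp + fn, present, f"PA {cls}")
        out[f"precision_{cls}"] = _safe_ratio(tp, tp + fp, present, f"precision {cls}")
    return out


def image_metrics(pred: np.ndarray, t: np.ndarray) -> dict[str, float]:
    """Dice plus class-averaged metrics (percent) for one image."""
    c = confusion(pred, t)
    m = class_metrics(c)
    den = 2 * c.tp + c.fp + c.fn
    dice = 1.0 if den == 0 else 2 * c.tp / den
    return {
        "dice": dice,
        "miou": 100.0 * (m["iou_foreground"] + m["iou_background"]) / 2,
        "mpa": 100.0 * (m["pa_foreground"] + m["pa_background"]) / 2,
        "mprecision": 100.0
        * (m["precision_foreground"] + m["precision_background"]) / 2,
    }


def grouped_mean(scores, group_size: int = 10) -> float:
    """Mean of group means over ordered groups of ``group_size`` scores.

    A partial final group is kept and averaged as its own group.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("grouped_mean needs at least one score")
    groups = [scores[i : i + group_size] for i in range(0, len(scores), group_size)]
    return float(np.mean([np.mean(g) for g in groups]))


@dataclass
class MetricsReport:
    """Validation summary: grouped means of per-image metrics."""

    dice: float
    miou: float
    mpa: float
    mprecision: float
    group_size: int
    n_images: int
    per_image: list[dict] = field(default_factory=list)

    @staticmethod
    def from_per_image(per_image: list[dict], group_size: int = 10) -> "MetricsReport":
        return MetricsReport(
            dice=grouped_mean([m["dice"] for m in per_image], group_size),
            miou=grouped_mean([m["miou"] for m in per_image], group_size),
            mpa=grouped_mean([m["mpa"] for m in per_image], group_size),
            mprecision=grouped_mean([m["mprecision"] for m in per_image], group_size),
            group_size=group_size,
            n_images=len(per_image),
            per_image=per_image,
        )

    def summary(self) -> dict[str, float]:
        return {
            "dice": self.dice,
            "miou": self.miou,
            "mpa": self.mpa,
            "mprecision": self.mprecision,
        }

    def to_json(self, path) -> None:
        payload = self.summary() | {
            "group_size": self.group_size,
            "n_images": self.n_images,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path) -> None:
        """Dump per-image metrics; the grouped means are recomputable from it."""
        if not self.per_image:
            raise ValueError("report has no per-image rows")
        fields = list(self.per_image[0].keys())
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            writer.writerows(self.per_image)


def overlay(pred: np.ndarray, t: np.ndarray, image: np.ndarray) -> np.ndarray:
    """Colour-coded confusion overlay on a grayscale image (uint8 RGB).

    True positives purple, false negatives yellow, false positives green;
    true negatives show the underlying image.
    """
    pred = np.asarray(pred)
    t = np.asarray(t)
    if pred.shape != t.shape or image.shape[:2] != t.shape:
        raise ValueError("overlay inputs must share the spatial shape")
    _check_binary(pred)
    _check_binary(t)
    gray = np.asarray(image, dtype=np.float64)
    if gray.ndim == 3:
        gray = gray.mean(axis=2)
    if gray.max() <= 1.0:
        gray = gray * 255.0
    rgb = np.repeat(gray.astype(np.uint8)[:, :, None], 3, axis=2)
    p = pred.astype(bool)
    g = t.astype(bool)
    rgb[p & g] = TP_COLOR
    rgb[~p & g] = FN_COLOR
    rgb[p & ~g] = FP_COLOR
    return rgb
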