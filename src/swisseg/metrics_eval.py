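"""Pixel-level segmentation metrics: per-class IoU, mIoU, micro precision /
recall / F1, and the merged-weed IoU used to judge weeding-operation value.

All metrics are derived from a full K x K pixel confusion matrix accumulated
over non-ignored pixels, so class-merging metrics (Weed IoU) remain exact:
confusions *between* two weed species count as true positives of the merged
weed category.

Conventions (reported in every TSV/JSON output):
- mIoU averages IoU over classes present in ground truth or prediction;
  classes absent from both are excluded from the mean. Reported both with and
  without the background class.
- Precision/Recall/F1 are micro-averaged over foreground classes only
  (background excluded), matching the weed-detection reading of the metrics.
- Values are percentages in [0, 100]; a zero denominator yields 0 with a
  warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClassMap",
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "miou",
    "micro_prf",
    "weed_iou",
    "compute_report",
]

IGNORE = 255


@dataclass
class ClassMap:
    """Dense id -> (name, role) table; roles are background / crop / weed."""

    names: list
    roles: list

    def __post_init__(self):
        if len(self.names) != len(self.roles):
            raise ValueError("names and roles must have equal length")
        if self.roles.count("background") != 1 or self.roles[0] != "background":
            raise ValueError("exactly one background class required, at id 0")
        for r in self.roles:
            if r not in ("background", "crop", "weed"):
                raise ValueError(f"unknown class role {r!r}")

    @property
    def n_classes(self) -> int:
        return len(self.names)

    @property
    def weed_ids(self) -> list:
        return [i for i, r in enumerate(self.roles) if r == "weed"]

    @property
    def foreground_ids(self) -> list:
        return [i for i, r in enumerate(self.roles) if r != "background"]

    @classmethod
    def default(cls, n_weeds: int = 2) -> "ClassMap":
        names = ["background", "crop"] + [f"weed_{i + 1}" for i in range(n_weeds)]
        roles = ["background", "crop"] + ["weed"] * n_weeds
        return cls(names=names, roles=roles)


@dataclass
class ConfusionCounts:
    """Full pixel confusion matrix; rows = ground truth, cols = prediction."""

    matrix: np.ndarray  # (K, K) int64

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def fp(self) -> np.ndarray:
        return self.matrix.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.matrix.sum(axis=1) - self.tp

    @property
    def n_pixels(self) -> int:
        return int(self.matrix.sum())

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.matrix + other.matrix)


def confusion_counts(pred, gt, n_classes: int) -> ConfusionCounts:
    """Accumulate the confusion matrix over non-ignored pixels."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    valid = gt != IGNORE
    p, g = pred[valid].astype(np.int64), gt[valid].astype(np.int64)
    if p.size and (p.min() < 0 or p.max() >= n_classes):
        raise ValueError("prediction contains ids outside [0, n_classes)")
    if g.size and (g.min() < 0 or g.max() >= n_classes):
        raise ValueError("ground truth contains ids outside [0, n_classes)")
    m = np.bincount(g * n_classes + p, minlength=n_classes * n_classes)
    return ConfusionCounts(m.reshape(n_classes, n_classes))


def _iou_from_tfpn(tp, fp, fn):
    denom = tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, tp / np.maximum(denom, 1), np.nan)


def miou(counts: ConfusionCounts, include_background: bool = True) -> float:
    """Mean IoU (percent) over classes present in gt or prediction."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    ious = _iou_from_tfpn(tp.astype(float), fp.astype(float), fn.astype(float))
    if not include_background:
        ious = ious[1:]
    ious = ious[~np.isnan(ious)]
    if ious.size == 0:
        raise ValueError("no evaluable class: every class absent from gt and prediction")
    return float(ious.mean() * 100.0)


def per_class_iou(counts: ConfusionCounts) -> np.ndarray:
    """IoU per class in percent; NaN for classes absent from both."""
    return _iou_from_tfpn(counts.tp.astype(float), counts.fp.astype(float),
                          counts.fn.astype(float)) * 100.0


def micro_prf(counts: ConfusionCounts, foreground_ids=None) -> tuple:
    """Micro precision, recall, F1 (percent) over the given class ids.

    Defaults to all non-zero (foreground) classes.
    """
    if foreground_ids is None:
        foreground_ids = list(range(1, counts.n_classes))
    ids = np.asarray(foreground_ids, dtype=int)
    tp = float(counts.tp[ids].sum())
    fp = float(counts.fp[ids].sum())
    fn = float(counts.fn[ids].sum())

    def _safe(num, den, name):
        if den == 0:
            warnings.warn(f"{name}: zero denominator, reporting 0", stacklevel=3)
            return 0.0
        return num / den

    precision = _safe(tp, tp + fp, "precision")
    recall = _safe(tp, tp + fn, "recall")
    f1 = _safe(2 * precision * recall, precision + recall, "f1")
    return precision * 100.0, recall * 100.0, f1 * 100.0


def weed_iou(counts: ConfusionCounts, class_map: ClassMap) -> float:
    """IoU (percent) of the union of all weed classes.

    Cross-species confusions inside the weed group count as true positives of
    the merged category — exactly the pixel-level class merge.
    """
    weed_ids = class_map.weed_ids
    if not weed_ids:
        raise ValueError("class map declares no weed class")
    w = np.asarray(weed_ids, dtype=int)
    m = counts.matrix
    tp = float(m[np.ix_(w, w)].sum())
    fn = float(m[w, :].sum() - m[np.ix_(w, w)].sum())
    fp = float(m[:, w].sum() - m[np.ix_(w, w)].sum())
    denom = tp + fp + fn
    if denom == 0:
        warnings.warn("weed_iou: weed class absent from gt and prediction", stacklevel=2)
        return 0.0
    return tp / denom * 100.0


@dataclass
class MetricsReport:
    """Headline metrics plus the per-class breakdown, all in percent."""

    miou: float
    miou_foreground: float
    precision: float
    recall: float
    f1: float
    weed_iou: float
    per_class_iou: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "miou": self.miou,
            "miou_foreground": self.miou_foreground,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "weed_iou": self.weed_iou,
            "per_class_iou": self.per_class_iou,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for k, v in self.to_dict().items():
                if k == "per_class_iou":
                    for cname, ciou in v.items():
                        fh.write(f"iou_{cname}\t{ciou:.4f}\n")
                else:
                    fh.write(f"{k}\t{v:.4f}\n")


def compute_report(counts: ConfusionCounts, class_map: ClassMap) -> MetricsReport:
    """Assemble the full report from an accumulated confusion matrix."""
    p, r, f1 = micro_prf(counts, class_map.foreground_ids)
    per_cls = per_class_iou(counts)
    return MetricsReport(
        miou=miou(counts, include_background=True),
        miou_foreground=miou(counts, include_background=False),
        precision=p,
        recall=r,
        f1=f1,
        weed_iou=weed_iou(counts, class_map),
        per_class_iou={class_map.names[i]: float(per_cls[i])
                       for i in range(class_map.n_classes)
                       if not np.isnan(per_cls[i])},
    )
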