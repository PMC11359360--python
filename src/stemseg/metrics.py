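"""Confusion accounting and the evaluation suite: mIoU, mP, mR, mF1, speed.

All four quality metrics derive from per-class true-positive/false-positive/
false-negative counts accumulated over the whole dataset (micro over points),
then averaged over classes (macro) and reported as percentages:

    IoU_c = TP / (TP + FP + FN)      P_c = TP / (TP + FP)
    R_c   = TP / (TP + FN)           F1_c = 2 P R / (P + R)

A class with no predicted and no true points (TP+FP+FN = 0) is excluded from
the means with a warning — degenerate early-growth clouds may lack stem
points entirely. Speed is the reciprocal of the mean per-cloud inference
time, in clouds per second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EvalCounts", "MetricReport", "confusion", "miou", "mp", "mr",
           "mf1", "speed", "report"]


@dataclass
class EvalCounts:
    """Per-class TP/FP/FN counts; additive across clouds and batches."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @classmethod
    def zeros(cls, n_classes: int) -> "EvalCounts":
        z = lambda: np.zeros(n_classes, dtype=np.int64)
        return cls(z(), z(), z())

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn)


def confusion(pred: np.ndarray, true: np.ndarray, n_classes: int = 2) -> EvalCounts:
    """Exact per-class counts from hard label arrays of equal length."""
    pred = np.asarray(pred).ravel()
    true = np.asarray(true).ravel()
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: pred {pred.shape} vs true {true.shape}")
    if pred.size and (pred.min() < 0 or pred.max() >= n_classes
                      or true.min() < 0 or true.max() >= n_classes):
        raise ValueError("labels out of range")
    cm = np.bincount(true * n_classes + pred, minlength=n_classes**2
                     ).reshape(n_classes, n_classes)
    tp = np.diag(cm).copy()
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    return EvalCounts(tp, fp, fn)


def _macro(counts: EvalCounts, numer, denom) -> float:
    active = (counts.tp + counts.fp + counts.fn) > 0
    if not active.all():
        warnings.warn(
            f"excluding {int((~active).sum())} empty class(es) from the mean",
            stacklevel=3)
    if not active.any():
        raise ValueError("no class has any points")
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = numer(counts) / denom(counts)
    vals = np.where(np.isfinite(vals), vals, 0.0)
    return float(vals[active].mean() * 100.0)


def miou(counts: EvalCounts) -> float:
    """Mean intersection-over-union, percent."""
    return _macro(counts, lambda c: c.tp,
                  lambda c: c.tp + c.fp + c.fn)


def mp(counts: EvalCounts) -> float:
    """Mean precision, percent."""
    return _macro(counts, lambda c: c.tp, lambda c: c.tp + c.fp)


def mr(counts: EvalCounts) -> float:
    """Mean recall, percent."""
    return _macro(counts, lambda c: c.tp, lambda c: c.tp + c.fn)


def mf1(counts: EvalCounts) -> float:
    """Mean F1 (harmonic mean of per-class precision and recall), percent."""
    active = (counts.tp + counts.fp + counts.fn) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts.tp / (counts.tp + counts.fp)
        r = counts.tp / (counts.tp + counts.fn)
        f1 = 2 * p * r / (p + r)
    f1 = np.where(np.isfinite(f1), f1, 0.0)
    if not active.any():
        raise ValueError("no class has any points")
    return float(f1[active].mean() * 100.0)


def speed(total_time: float, n_clouds: int) -> float:
    """Clouds segmented per second: 1 / (mean per-cloud time)."""
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    return n_clouds / total_time


@dataclass
class MetricReport:
    """The evaluation table: four percentages plus optional speed."""

    miou: float
    mp: float
    mr: float
    mf1: float
    speed: float | None = None
    per_class: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {"mIoU": round(self.miou, 1), "mP": round(self.mp, 1),
               "mR": round(self.mr, 1), "mF1": round(self.mf1, 1)}
        if self.speed is not None:
            out["Speed"] = self.speed
        return out


def report(counts: EvalCounts, total_time: float | None = None,
           n_clouds: int | None = None,
           class_names=("other", "stem")) -> MetricReport:
    """Assemble the full metric report from accumulated counts."""
    per_class = {}
    for c, name in enumerate(class_names[: counts.n_classes]):
        denom = counts.tp[c] + counts.fp[c] + counts.fn[c]
        per_class[name] = {
            "iou": float(counts.tp[c] / denom * 100.0) if denom else float("nan"),
            "tp": int(counts.tp[c]), "fp": int(counts.fp[c]),
            "fn": int(counts.fn[c]),
        }
    spd = (speed(total_time, n_clouds)
           if total_time is not None and n_clouds else None)
    return MetricReport(miou=miou(counts), mp=mp(counts), mr=mr(counts),
                        mf1=mf1(counts), speed=spd, per_class=per_class)
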