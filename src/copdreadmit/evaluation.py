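"""Confusion statistics, Matthews correlation, ROC/AUC, threshold search.

The system's crisp output is a risk score in [0, 1]; turning it into a
label requires a cutoff.  Following the original workflow the cutoff is
chosen by sweeping a dense threshold grid and maximizing the Matthews
correlation coefficient (Mcc), a balanced statistic in [-1, 1] that
behaves well under class imbalance:

    Mcc = (TN*TP - FN*FP) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the conventional value 0 when any denominator factor vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics

READMIT_LABEL = "The patient will be readmitted within 90 days"
NO_READMIT_LABEL = "The patient will not be readmitted within 90 days"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 if the denominator vanishes."""
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return (tn * tp - fn * fp) / np.sqrt(denom)


def confusion_at_threshold(scores: Sequence[float], labels: Sequence[int],
                           threshold: float) -> ConfusionCounts:
    """Counts under the decision rule: positive iff score >= threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pred = s >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))), tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))), fn=int(np.sum(~pred & (y == 1))))


def roc_curve(scores: Sequence[float], labels: Sequence[int]
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC points (fpr, tpr, thresholds) and trapezoidal AUC."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both outcome classes")
    fpr, tpr, thr = _skmetrics.roc_curve(y, np.asarray(scores, dtype=float))
    return fpr, tpr, thr, float(_skmetrics.auc(fpr, tpr))


def optimize_threshold(scores: Sequence[float], labels: Sequence[int],
                       grid_step: float = 0.001) -> tuple[float, float]:
    """Mcc-maximizing cutoff over a uniform grid on [0, 1].

    Returns (threshold, mcc); ties take the smallest threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("threshold optimization requires both classes")
    n_steps = int(round(1.0 / grid_step))
    grid = np.linspace(0.0, 1.0, n_steps + 1)

    pred = s[None, :] >= grid[:, None]
    pos = (y == 1)
    tp = (pred & pos).sum(axis=1).astype(float)
    fp = (pred & ~pos).sum(axis=1).astype(float)
    fn = pos.sum() - tp
    tn = (~pos).sum() - fp
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, (tn * tp - fn * fp) / np.sqrt(denom), 0.0)
    best = int(np.argmax(vals))  # first occurrence = smallest threshold
    return float(grid[best]), float(vals[best])


def mcc_curve(scores: Sequence[float], labels: Sequence[int],
              grid_step: float = 0.001) -> tuple[np.ndarray, np.ndarray]:
    """Mcc at every grid threshold (for cutoff-selection plots)."""
    n_steps = int(round(1.0 / grid_step))
    grid = np.linspace(0.0, 1.0, n_steps + 1)
    vals = np.array([mcc(confusion_at_threshold(scores, labels, t)) for t in grid])
    return grid, vals


@dataclass
class EvaluationReport:
    """Test-set performance of the full two-level system."""

    n: int
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_thresholds: np.ndarray
    threshold_grid: np.ndarray
    mcc_values: np.ndarray
    optimal_threshold: float
    mcc_at_optimum: float
    confusion: ConfusionCounts
    sensitivity: float
    specificity: float
    labels_at_optimum: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "auc": self.auc,
            "roc": {"fpr": self.roc_fpr.tolist(), "tpr": self.roc_tpr.tolist(),
                    "thresholds": self.roc_thresholds.tolist()},
            "optimal_threshold": self.optimal_threshold,
            "mcc_at_optimum": self.mcc_at_optimum,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": {"tp": self.confusion.tp, "tn": self.confusion.tn,
                          "fp": self.confusion.fp, "fn": self.confusion.fn},
        }


def evaluate_scores(scores: Sequence[float], labels: Sequence[int],
                    grid_step: float = 0.001) -> EvaluationReport:
    """Full report for a scored patient set: ROC, AUC, Mcc-optimal cutoff."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    fpr, tpr, thr, auc = roc_curve(s, y)
    grid, vals = mcc_curve(s, y, grid_step=grid_step)
    best = int(np.argmax(vals))
    t_opt, mcc_opt = float(grid[best]), float(vals[best])
    conf = confusion_at_threshold(s, y, t_opt)
    label_strings = [READMIT_LABEL if v >= t_opt else NO_READMIT_LABEL for v in s]
    return EvaluationReport(
        n=len(s), auc=auc, roc_fpr=fpr, roc_tpr=tpr, roc_thresholds=thr,
        threshold_grid=grid, mcc_values=vals,
        optimal_threshold=t_opt, mcc_at_optimum=mcc_opt, confusion=conf,
        sensitivity=conf.sensitivity, specificity=conf.specificity,
        labels_at_optimum=label_strings)
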