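"""Classification and reconstruction metrics.

Confusion-matrix scalars (sensitivity, specificity, precision, accuracy,
F1), rank-based AUROC, and image RMSE/SSIM.  All fractions are kept
internal in [0, 1]; conversion to percent happens only at the reporting
layer.  Metrics with a zero denominator are reported as ``None``
(explicitly undefined), never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity
from sklearn.metrics import roc_auc_score

from .errors import InputError

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion_counts",
    "metrics_from_confusion",
    "roc_auc",
    "image_rmse",
    "image_ssim",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; the positive class is nystagmus (1)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Scalar metrics as fractions; ``None`` marks an undefined metric."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    accuracy: float | None
    f1: float | None
    auroc: float | None = None

    def as_percent(self) -> dict:
        return {k: (None if v is None else 100.0 * v)
                for k, v in asdict(self).items()}


def confusion_counts(pred_labels, true_labels) -> ConfusionMatrix:
    """Tally TP/FP/TN/FN for binary labels."""
    p = np.asarray(pred_labels)
    t = np.asarray(true_labels)
    if p.shape != t.shape:
        raise InputError("prediction/truth length mismatch")
    if not (np.isin(p, (0, 1)).all() and np.isin(t, (0, 1)).all()):
        raise InputError("labels must be binary 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((p == 1) & (t == 1))),
        fp=int(np.sum((p == 1) & (t == 0))),
        tn=int(np.sum((p == 0) & (t == 0))),
        fn=int(np.sum((p == 0) & (t == 1))))


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricReport:
    """Standard scalar metrics from confusion counts.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    precision = tp/(tp+fp), accuracy = (tp+tn)/total and F1 is the
    harmonic mean of precision and sensitivity.
    """
    if cm.total == 0:
        raise InputError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    acc = (cm.tp + cm.tn) / cm.total
    if prec is None or sens is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricReport(sensitivity=sens, specificity=spec, precision=prec,
                        accuracy=acc, f1=f1)


def roc_auc(scores, true_labels) -> float:
    """Rank-based (Mann-Whitney) AUROC with midrank tie handling."""
    t = np.asarray(true_labels)
    if len(np.unique(t)) < 2:
        raise InputError("AUROC requires both classes")
    return float(roc_auc_score(t, np.asarray(scores, dtype=np.float64)))


def image_rmse(a, b) -> float:
    """Root mean squared pixel difference (0-255 intensity scale)."""
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    if x.shape != y.shape:
        raise InputError("image shapes differ")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def image_ssim(a, b, data_range: float = 255.0) -> float:
    """Mean local structural similarity with the standard constants.

    11x11 Gaussian window (sigma 1.5), K1 = 0.01, K2 = 0.03.
    """
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    if x.shape != y.shape:
        raise InputError("image shapes differ")
    return float(structural_similarity(
        x, y, data_range=data_range, gaussian_weights=True, sigma=1.5,
        win_size=11, use_sample_covariance=False, K1=0.01, K2=0.03))
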