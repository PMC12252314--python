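"""1D-CNN nystagmus detection on torsion-angle time series.

Fixed-length windows of torsion angles (default 3 samples = 0.3 s at
10 Hz) are classified as normal vs. nystagmus by a nine-layer 1D-CNN:
three blocks of three convolutions each (32, 64 and 128 channels), max
pooling after the first two blocks, global average pooling after the
third, then fully connected layers of 1024 and 2 units whose normalised
output is the nystagmus probability.  A probability >= 0.5 is called
positive.  Training minimises binary cross-entropy with Adam and stops
early once the loss has failed to improve on its running best by at least
5% for three consecutive epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .errors import ConfigurationError, InputError

__all__ = [
    "DetectorConfig",
    "WindowBatch",
    "NystagmusDetector",
    "DetectorTrainResult",
    "make_windows",
    "concat_batches",
    "classify",
    "early_stop_check",
    "train_detector",
    "sweep_window_sizes",
]


@dataclass
class DetectorConfig:
    """Architecture and training settings of the window classifier."""

    window_size: int = 3
    channels: tuple = (32, 64, 128)
    kernel: int = 3
    fc_widths: tuple = (1024, 2)
    threshold: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 30
    early_stop_rel_improve: float = 0.05
    early_stop_patience: int = 3
    val_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.window_size < 2:
            raise ConfigurationError("window_size must be >= 2")
        if not (0.0 < self.threshold < 1.0):
            raise ConfigurationError("threshold must be in (0, 1)")
        if self.fc_widths[-1] != 2:
            raise ConfigurationError("final FC layer must have 2 units")


@dataclass
class WindowBatch:
    """Angle windows with labels and the id of their source series."""

    windows: np.ndarray        # (n, window_size) degrees
    labels: np.ndarray         # (n,) 0/1
    series_ids: np.ndarray     # (n,) int, for leakage-free splits

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        self.series_ids = np.asarray(self.series_ids, dtype=int)
        if self.windows.ndim != 2 or len(self.labels) != len(self.windows):
            raise InputError("inconsistent window batch")
        if np.isnan(self.windows).any():
            raise InputError("windows contain missing values")

    def __len__(self):
        return len(self.windows)


def make_windows(series, label: int, window_size: int,
                 series_id: int = 0) -> WindowBatch:
    """Cut a torsion series into non-overlapping windows.

    The remainder that does not fill a window is dropped; every window
    inherits the series label.  ``series`` may be a plain array, a
    ``LabeledSeries`` or a ``TorsionSeries``.
    """
    angles = getattr(series, "angles_deg", None)
    if angles is None:
        angles = getattr(series, "angles", series)
    angles = np.asarray(angles, dtype=np.float64)
    if window_size < 2:
        raise ConfigurationError("window_size must be >= 2")
    if len(angles) < window_size:
        raise InputError("series shorter than one window")
    m = len(angles) // window_size
    w = angles[:m * window_size].reshape(m, window_size)
    return WindowBatch(windows=w, labels=np.full(m, int(label)),
                       series_ids=np.full(m, int(series_id)))


def concat_batches(batches) -> WindowBatch:
    return WindowBatch(
        windows=np.concatenate([b.windows for b in batches]),
        labels=np.concatenate([b.labels for b in batches]),
        series_ids=np.concatenate([b.series_ids for b in batches]))


class NystagmusDetector(nn.Module):
    """Three 1D-conv blocks + FC head producing a nystagmus probability."""

    def __init__(self, cfg: DetectorConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        k = cfg.kernel
        self.blocks = []
        cin = 1
        for c in cfg.channels:
            block = [nn.Conv1d(cin, c, k, rng),
                     nn.Conv1d(c, c, k, rng),
                     nn.Conv1d(c, c, k, rng)]
            self.blocks.append(block)
            cin = c
        self.fc1 = nn.Linear(cfg.channels[-1], cfg.fc_widths[0], rng)
        self.fc2 = nn.Linear(cfg.fc_widths[0], cfg.fc_widths[1], rng)

    def forward(self, windows: np.ndarray | nn.Tensor) -> nn.Tensor:
        """Probability of nystagmus per window, in [0, 1]."""
        x = windows if isinstance(windows, nn.Tensor) else nn.Tensor(
            np.asarray(windows, np.float32))
        if x.ndim != 2 or x.shape[1] != self.cfg.window_size:
            raise InputError(
                f"expected (n, {self.cfg.window_size}) windows, "
                f"got {x.shape}")
        n = x.shape[0]
        x = x.reshape(n, 1, self.cfg.window_size)
        for bi, block in enumerate(self.blocks):
            for conv in block:
                x = nn.relu(conv(x))
            if bi < len(self.blocks) - 1:
                x = nn.maxpool1d(x)
            else:
                x = nn.global_avg_pool1d(x)
        x = nn.relu(self.fc1(x))
        logits = self.fc2(x)
        probs = nn.softmax(logits, axis=-1)
        return probs[:, 1]

    def predict_proba(self, windows: np.ndarray,
                      batch_size: int = 1024) -> np.ndarray:
        out = []
        with nn.no_grad():
            for i in range(0, len(windows), batch_size):
                out.append(self.forward(windows[i:i + batch_size])
                           .data.astype(np.float64))
        return np.concatenate(out) if out else np.empty(0)


def classify(probability, threshold: float = 0.5) -> np.ndarray:
    """Binary call: positive (1) iff probability >= threshold."""
    p = np.asarray(probability, dtype=np.float64)
    if (p < 0).any() or (p > 1).any():
        raise InputError("probabilities must be in [0, 1]")
    return (p >= threshold).astype(int)


def early_stop_check(loss_history, rel_improve: float = 0.05,
                     patience: int = 3) -> bool:
    """True iff each of the last ``patience`` epochs improved on the best
    loss seen before it by less than ``rel_improve`` (relative)."""
    h = list(loss_history)
    if len(h) == 0:
        raise InputError("empty loss history")
    if len(h) < patience + 1:
        return False
    for i in range(len(h) - patience, len(h)):
        best_before = min(h[:i])
        denom = abs(best_before) if best_before != 0 else 1.0
        if (best_before - h[i]) / denom >= rel_improve:
            return False
    return True


@dataclass
class DetectorTrainResult:
    model: NystagmusDetector
    train_loss: list
    val_loss: list
    val_mask: np.ndarray      # boolean mask into the input batch
    stopped_early: bool


def _split_by_series(batch: WindowBatch, val_fraction: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Boolean validation mask; whole series go to one side of the split."""
    val_mask = np.zeros(len(batch), dtype=bool)
    for cls in np.unique(batch.labels):
        ids = np.unique(batch.series_ids[batch.labels == cls])
        ids = rng.permutation(ids)
        n_val = max(1, int(round(val_fraction * len(ids)))) \
            if len(ids) > 1 else 0
        val_ids = set(ids[:n_val].tolist())
        val_mask |= np.isin(batch.series_ids, list(val_ids)) \
            & (batch.labels == cls)
    return val_mask


def train_detector(data: WindowBatch,
                   cfg: DetectorConfig) -> DetectorTrainResult:
    """Train the window classifier with a leakage-free series-level split.

    Requires both classes; minimises binary cross-entropy with Adam and
    stops at ``max_epochs`` or when ``early_stop_check`` fires on the
    training-loss history.  Reproducible per seed.
    """
    if len(np.unique(data.labels)) < 2:
        raise ConfigurationError("training data must contain both classes")
    if data.windows.shape[1] != cfg.window_size:
        raise ConfigurationError("window size of data and config differ")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xDE7]))
    val_mask = _split_by_series(data, cfg.val_fraction, rng)

    xtr = data.windows[~val_mask].astype(np.float32)
    ytr = data.labels[~val_mask].astype(np.float64)
    xva = data.windows[val_mask].astype(np.float32)
    yva = data.labels[val_mask].astype(np.float64)

    model = NystagmusDetector(cfg)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    train_hist: list[float] = []
    val_hist: list[float] = []
    stopped = False
    n = len(xtr)

    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(n)
        tot = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            p = model.forward(xtr[idx])
            loss = nn.binary_cross_entropy(p, ytr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot += loss.item() * len(idx)
        train_hist.append(tot / n)
        if len(xva):
            pv = model.predict_proba(xva)
            pv = np.clip(pv, 1e-7, 1 - 1e-7)
            val_hist.append(float(-np.mean(
                yva * np.log(pv) + (1 - yva) * np.log(1 - pv))))
        if early_stop_check(train_hist, cfg.early_stop_rel_improve,
                            cfg.early_stop_patience):
            stopped = True
            break
    return DetectorTrainResult(model=model, train_loss=train_hist,
                               val_loss=val_hist, val_mask=val_mask,
                               stopped_early=stopped)


def sweep_window_sizes(series_list, labels, sizes,
                       cfg_template: DetectorConfig | None = None,
                       sample_rate: float = 10.0) -> pd.DataFrame:
    """Train one detector per window size on identical series-level splits.

    Returns one row per size with recall, specificity, precision,
    accuracy, F1 and AUROC (all percentages except AUROC) measured on the
    held-out series.
    """
    from .evaluation import confusion_counts, metrics_from_confusion, roc_auc

    cfg_template = cfg_template or DetectorConfig()
    rows = []
    for size in sizes:
        cfg = DetectorConfig(**{**vars(cfg_template), "window_size": size})
        batches = [make_windows(s, labels[i], size, series_id=i)
                   for i, s in enumerate(series_list)
                   if len(np.atleast_1d(getattr(s, "angles", s))) >= size]
        data = concat_batches(batches)
        res = train_detector(data, cfg)
        xva = data.windows[res.val_mask]
        yva = data.labels[res.val_mask]
        p = res.model.predict_proba(xva)
        pred = classify(p, cfg.threshold)
        cm = confusion_counts(pred, yva)
        rep = metrics_from_confusion(cm)

        def pct(v):
            return np.nan if v is None else 100.0 * v

        rows.append({
            "window_size": size,
            "input_time_s": size / sample_rate,
            "recall": pct(rep.sensitivity),
            "specificity": pct(rep.specificity),
            "precision": pct(rep.precision),
            "accuracy": pct(rep.accuracy),
            "f1": pct(rep.f1),
            "auroc": roc_auc(p, yva),
        })
    return pd.DataFrame(rows)
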