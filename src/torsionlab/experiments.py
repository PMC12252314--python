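"""Reference desk-scale experiments.

These functions wire the synthetic generator, the preprocessing chain and
the two models into the package's standard benchmark experiments:

* :func:`torsion_recovery_experiment` — train a reduced Torsion
  Transformer on ~2,000 synthetic rotation samples and measure held-out
  angle error, the predict-zero baseline, and rotation equivariance;
* :func:`detection_experiment` — train the window-3 detector on 200
  synthetic series per class and measure held-out AUROC and the
  confusion-matrix scalars;
* :func:`decoder_quality` — reconstruction RMSE/SSIM of the trained
  Decoder on held-out samples.

Every function takes one integer seed; all internal randomness is derived
from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detector import (DetectorConfig, classify, concat_batches,
                       make_windows, train_detector)
from .evaluation import (confusion_counts, image_rmse, image_ssim,
                         metrics_from_confusion, roc_auc)
from .preprocess import (RotationSample, boxes_from_frames,
                         make_rotation_samples, rotate_box)
from .synthetic import (SceneParams, WaveformParams, generate_waveform,
                        render_sequence)
from .torsion_model import (TorsionNetConfig, TorsionTransformer,
                            retained_for_eval, train_torsion_transformer)
from . import nn

__all__ = [
    "TorsionRecoveryResult",
    "DetectionResult",
    "make_rotation_dataset",
    "torsion_recovery_experiment",
    "equivariance_slope",
    "decoder_quality",
    "detection_experiment",
]


def make_rotation_dataset(seed: int, n_scenes: int = 6,
                          triples_per_scene: int = 400,
                          noise_sd: float = 2.0) -> list[RotationSample]:
    """Render canonical-pose sequences and build rotation samples.

    Each scene contributes ``triples_per_scene`` three-frame samples taken
    from a near-zero-torsion sequence (0.05 deg jitter), so the unrotated
    pose defines the zero-torsion reference.
    """
    ss = np.random.SeedSequence([seed, 0xD5])
    rngs = [np.random.default_rng(c) for c in ss.spawn(n_scenes)]
    samples: list[RotationSample] = []
    for rng in rngs:
        scene = SceneParams(texture_seed=int(rng.integers(2**31 - 1)),
                            noise_sd=noise_sd)
        wf = WaveformParams(label="normal", drift_amplitude=0.0,
                            noise_sd=0.05,
                            duration=3 * triples_per_scene / 10.0)
        series = generate_waveform(wf, seed=int(rng.integers(2**31 - 1)))
        seq = render_sequence(series, scene, frames_per_sample=1)
        boxes = boxes_from_frames(seq.frames, seq.masks, strategy="oracle")
        samples.extend(make_rotation_samples(
            boxes, len(boxes) // 3, seed=int(rng.integers(2**31 - 1))))
    return samples


@dataclass
class TorsionRecoveryResult:
    model: TorsionTransformer
    val_samples: list
    val_mae_deg: float
    untrained_mae_deg: float
    baseline_mae_deg: float        # always-predict-zero on the val targets
    equivariance_slope: float
    history: object


def equivariance_slope(model: TorsionTransformer, stacks: np.ndarray,
                       thetas=(-10.0, -5.0, 5.0, 10.0)) -> float:
    """Least-squares slope of estimate(rotate(b, t)) - estimate(b) vs t.

    Averaged over the given box stacks; a rotation-equivariant estimator
    with the package's sign convention has slope 1.
    """
    thetas = np.asarray(thetas, dtype=np.float64)
    base = model.predict_angles(stacks)
    num = den = 0.0
    for t in thetas:
        rot = np.stack([[rotate_box(f, float(t)) for f in s]
                        for s in stacks])
        delta = model.predict_angles(rot) - base
        num += float(np.sum(t * delta))
        den += float(len(stacks) * t * t)
    return num / den


def torsion_recovery_experiment(seed: int = 0, n_train: int = 2000,
                                n_val: int = 300, n_scenes: int = 6,
                                max_epochs: int = 3,
                                log=None) -> TorsionRecoveryResult:
    """The angle-recovery benchmark at reduced (CPU) scale."""
    samples = make_rotation_dataset(seed, n_scenes=n_scenes,
                                    triples_per_scene=-(-(
                                        n_train + n_val) // n_scenes) + 2)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    order = rng.permutation(len(samples))
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train:n_train + n_val]]

    cfg = TorsionNetConfig.small(max_epochs=max_epochs, batch_size=64,
                                 seed=seed)
    vrot = np.stack([s.rotated for s in val])
    vthetas = np.array([s.theta_gt for s in val])

    untrained = TorsionTransformer(cfg)
    untrained_mae = float(np.mean(np.abs(
        untrained.predict_angles(vrot) - vthetas)))

    model, history = train_torsion_transformer(train, cfg, val, log=log)
    val_mae = history.val_mae_deg[-1]
    baseline = float(np.mean(np.abs(vthetas)))

    eq_stacks = np.stack([s.original for s in val[:8]])
    slope = equivariance_slope(model, eq_stacks)
    return TorsionRecoveryResult(model=model, val_samples=val,
                                 val_mae_deg=val_mae,
                                 untrained_mae_deg=untrained_mae,
                                 baseline_mae_deg=baseline,
                                 equivariance_slope=slope,
                                 history=history)


def decoder_quality(model: TorsionTransformer, samples,
                    max_samples: int = 100) -> dict:
    """Mean reconstruction RMSE (8-bit scale) and SSIM on held-out samples.

    The Decoder is evaluated with the nearest anchor and its two grid
    neighbours retained.
    """
    rmses, ssims = [], []
    for s in samples[:max_samples]:
        retained = retained_for_eval(model.cfg.grid,
                                     np.array([s.theta_gt]))
        with nn.no_grad():
            recon = model.decoder_forward(
                nn.Tensor(s.original[None].astype(np.float32)), retained)
        rec = np.clip(recon.data[0], 0, 1) * 255.0
        gt = s.rotated * 255.0
        for k in range(3):
            rmses.append(image_rmse(rec[k], gt[k]))
            ssims.append(image_ssim(rec[k], gt[k]))
    return {"rmse": float(np.mean(rmses)), "ssim": float(np.mean(ssims))}


@dataclass
class DetectionResult:
    auroc: float
    metrics: object            # MetricReport on the held-out windows
    result: object             # DetectorTrainResult
    sweep: object | None


def detection_experiment(seed: int = 0, n_per_class: int = 200,
                         window_size: int = 3, duration: float = 10.0,
                         max_epochs: int = 30,
                         run_sweep: bool = False,
                         sweep_sizes=range(2, 10),
                         sweep_series_per_class: int = 60) -> DetectionResult:
    """Detector benchmark: default waveform parameters, series-level split."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBEA7]))
    series = []
    for label in ("normal", "nystagmus"):
        for _ in range(n_per_class):
            series.append(generate_waveform(
                WaveformParams(label=label, duration=duration),
                seed=int(rng.integers(2**31 - 1))))
    batches = [make_windows(s, s.label, window_size, series_id=i)
               for i, s in enumerate(series)]
    data = concat_batches(batches)
    cfg = DetectorConfig(window_size=window_size, max_epochs=max_epochs,
                         seed=seed)
    res = train_detector(data, cfg)

    xva = data.windows[res.val_mask]
    yva = data.labels[res.val_mask]
    probs = res.model.predict_proba(xva)
    auroc = roc_auc(probs, yva)
    rep = metrics_from_confusion(
        confusion_counts(classify(probs, cfg.threshold), yva))

    sweep = None
    if run_sweep:
        from .detector import sweep_window_sizes

        sub = series[:sweep_series_per_class] \
            + series[n_per_class:n_per_class + sweep_series_per_class]
        labels = [s.label for s in sub]
        sweep = sweep_window_sizes(
            sub, labels, list(sweep_sizes),
            DetectorConfig(window_size=window_size, max_epochs=10,
                           seed=seed))
    return DetectionResult(auroc=auroc, metrics=rep, result=res, sweep=sweep)
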