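"""End-to-end orchestration: simulate -> preprocess -> train the torsion
estimator -> estimate torsion series -> train the detector -> detect ->
evaluate.

A :class:`PipelineConfig` (strict schema, unknown keys rejected, every
stochastic stage carries an explicit seed) drives :func:`run_pipeline`,
which writes every intermediate artifact plus a ``manifest.json`` holding
the config hash, seeds, package version and per-stage wall time.
Re-running with the same config reproduces all deterministic artifacts;
only the recorded timings differ.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .detector import (DetectorConfig, classify, concat_batches,
                       make_windows, train_detector)
from .errors import ConfigurationError
from .evaluation import confusion_counts, metrics_from_confusion, roc_auc
from .preprocess import boxes_from_frames, make_rotation_samples
from .synthetic import (LabeledSeries, SceneParams, WaveformParams,
                        generate_waveform, render_sequence)
from .torsion_model import (TorsionNetConfig, estimate_series,
                            save_checkpoint, train_torsion_transformer)
from . import io as tio

logger = logging.getLogger("torsionlab")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SceneSection(_Strict):
    image_size: int = 224
    pupil_radius: float = 28.0
    iris_radius: float = 88.0
    texture_harmonics: int = 6
    noise_sd: float = 2.0
    occluder_fraction: float = 0.0


class WaveformSection(_Strict):
    duration: float = 10.0
    sample_rate: float = 10.0
    noise_sd: float = 0.3
    drift_amplitude: float = 1.0
    slow_fast_ratio: float = 0.9


class PreprocessSection(_Strict):
    strategy: str = "oracle"
    enhance: bool = False


class TorsionSection(_Strict):
    n_scenes: int = 4
    n_train_samples: int = 400
    n_val_samples: int = 100
    angle_sampler: str = "uniform_continuous"
    network: str = "small"          # "small" or "full"
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 4


class DetectorSection(_Strict):
    n_series_per_class: int = 40
    window_size: int = 3
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 20


class EvalSection(_Strict):
    n_series_per_class: int = 2
    duration: float = 5.0


class SeedsSection(_Strict):
    simulate: int = Field(...)
    torsion: int = Field(...)
    detector: int = Field(...)


class PipelineConfig(_Strict):
    scene: SceneSection = SceneSection()
    waveform: WaveformSection = WaveformSection()
    preprocess: PreprocessSection = PreprocessSection()
    torsion: TorsionSection = TorsionSection()
    detector: DetectorSection = DetectorSection()
    evaluation: EvalSection = EvalSection()
    seeds: SeedsSection


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _scene(cfg: PipelineConfig, texture_seed: int) -> SceneParams:
    s = cfg.scene
    return SceneParams(image_size=s.image_size, pupil_radius=s.pupil_radius,
                       iris_radius=s.iris_radius, texture_seed=texture_seed,
                       texture_harmonics=s.texture_harmonics,
                       noise_sd=s.noise_sd,
                       occluder_fraction=s.occluder_fraction)


def _torsion_net_config(cfg: PipelineConfig) -> TorsionNetConfig:
    t = cfg.torsion
    kw = dict(learning_rate=t.learning_rate, batch_size=t.batch_size,
              max_epochs=t.max_epochs, seed=cfg.seeds.torsion)
    if t.network == "small":
        return TorsionNetConfig.small(**kw)
    if t.network == "full":
        return TorsionNetConfig(**kw)
    raise ConfigurationError(f"unknown network size {t.network!r}")


def make_training_samples(cfg: PipelineConfig):
    """Render canonical-pose frame stacks and build rotation samples.

    The training sequences are rendered at near-zero torsion (tiny jitter
    only), so the trained Finder reports torsion relative to the upright
    texture pose.  Samples never straddle scene boundaries.
    """
    t = cfg.torsion
    total = t.n_train_samples + t.n_val_samples
    per_scene = -(-total // t.n_scenes)      # ceil
    rng = np.random.default_rng(np.random.SeedSequence(
        [cfg.seeds.simulate, 0x51]))
    samples = []
    for i in range(t.n_scenes):
        scene = _scene(cfg, texture_seed=int(rng.integers(0, 2**31 - 1)))
        wf = WaveformParams(label="normal", drift_amplitude=0.0,
                            noise_sd=0.05,
                            duration=3 * per_scene / cfg.waveform.sample_rate,
                            sample_rate=cfg.waveform.sample_rate)
        series = generate_waveform(wf, seed=int(rng.integers(0, 2**31 - 1)))
        seq = render_sequence(series, scene, frames_per_sample=1)
        boxes = boxes_from_frames(seq.frames, seq.masks,
                                  strategy=cfg.preprocess.strategy,
                                  enhance=cfg.preprocess.enhance,
                                  log=logger.debug)
        samples.extend(make_rotation_samples(
            boxes, len(boxes) // 3, angle_sampler=t.angle_sampler,
            seed=int(rng.integers(0, 2**31 - 1))))
    if len(samples) < total:
        raise ConfigurationError(
            f"only {len(samples)} samples survived preprocessing, "
            f"{total} requested")
    order = rng.permutation(len(samples))
    train = [samples[j] for j in order[:t.n_train_samples]]
    val = [samples[j] for j in order[t.n_train_samples:total]]
    return train, val


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute every stage in order; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    artifacts: list[str] = []

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    # 1. simulate + preprocess training data -------------------------------
    name = stage("simulate_preprocess")
    train_samples, val_samples = make_training_samples(config)
    boxes = np.concatenate(
        [s.original for s in train_samples[:10]])   # preview artifact
    tio.write_boxes(boxes, out / "boxes_preview.npz",
                    {"n_train": len(train_samples),
                     "n_val": len(val_samples),
                     "seed": config.seeds.simulate})
    artifacts.append("boxes_preview.npz")
    done(name)

    # 2. train the torsion estimator ---------------------------------------
    name = stage("train_torsion")
    net_cfg = _torsion_net_config(config)
    model, history = train_torsion_transformer(
        train_samples, net_cfg, val_samples, log=logger.info)
    save_checkpoint(model, out / "torsion_ckpt.npz")
    pd.DataFrame({
        "decoder_loss": history.decoder_loss,
        "finder_loss": history.finder_loss,
        "total_loss": history.total_loss,
        "val_mae_deg": history.val_mae_deg,
    }).to_csv(out / "torsion_history.csv", index=False)
    artifacts += ["torsion_ckpt.npz", "torsion_history.csv"]
    done(name)

    # 3. render evaluation videos and estimate their torsion ---------------
    name = stage("estimate")
    w = config.waveform
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seeds.simulate, 0xE7A]))
    est_dir = out / "estimated"
    est_dir.mkdir(exist_ok=True)
    estimated: list[tuple[LabeledSeries, int]] = []
    for label in ("normal", "nystagmus"):
        for j in range(config.evaluation.n_series_per_class):
            wf = WaveformParams(label=label,
                                duration=config.evaluation.duration,
                                sample_rate=w.sample_rate,
                                noise_sd=w.noise_sd,
                                drift_amplitude=w.drift_amplitude,
                                slow_fast_ratio=w.slow_fast_ratio)
            series = generate_waveform(
                wf, seed=int(rng.integers(0, 2**31 - 1)))
            scene = _scene(config,
                           texture_seed=int(rng.integers(0, 2**31 - 1)))
            seq = render_sequence(series, scene, frames_per_sample=3)
            bx = boxes_from_frames(seq.frames, seq.masks,
                                   strategy=config.preprocess.strategy,
                                   enhance=config.preprocess.enhance,
                                   log=logger.debug)
            ts = estimate_series(bx, model)
            est = LabeledSeries(angles=ts.angles_deg, label=series.label,
                                seed=series.seed,
                                sample_rate=1.0 / (ts.times_s[1] - ts.times_s[0])
                                if len(ts.times_s) > 1 else w.sample_rate)
            tio.write_series(est, est_dir / f"{label}_{j:03d}.csv")
            estimated.append((est, series.label))
    artifacts.append("estimated/")
    done(name)

    # 4. train the detector on generated waveforms -------------------------
    name = stage("train_detector")
    d = config.detector
    det_cfg = DetectorConfig(window_size=d.window_size,
                             learning_rate=d.learning_rate,
                             batch_size=d.batch_size,
                             max_epochs=d.max_epochs,
                             seed=config.seeds.detector)
    srng = np.random.default_rng(np.random.SeedSequence(
        [config.seeds.detector, 0x3E]))
    batches = []
    sid = 0
    for label in ("normal", "nystagmus"):
        for _ in range(d.n_series_per_class):
            wf = WaveformParams(label=label, duration=w.duration,
                                sample_rate=w.sample_rate,
                                noise_sd=w.noise_sd,
                                drift_amplitude=w.drift_amplitude,
                                slow_fast_ratio=w.slow_fast_ratio)
            s = generate_waveform(wf, seed=int(srng.integers(0, 2**31 - 1)))
            batches.append(make_windows(s, s.label, d.window_size,
                                        series_id=sid))
            sid += 1
    data = concat_batches(batches)
    res = train_detector(data, det_cfg)
    np.savez_compressed(out / "detector_ckpt.npz",
                        **res.model.state_arrays())
    artifacts.append("detector_ckpt.npz")
    done(name)

    # 5. detect on the estimated series and evaluate -----------------------
    name = stage("detect_evaluate")
    win, labels = [], []
    for est, label in estimated:
        if len(est.angles) >= d.window_size:
            b = make_windows(est, label, d.window_size)
            win.append(b.windows)
            labels.append(b.labels)
    windows = np.concatenate(win)
    truth = np.concatenate(labels)
    probs = res.model.predict_proba(windows)
    pred = classify(probs, det_cfg.threshold)
    pd.DataFrame({"window_start_s": d.window_size / w.sample_rate
                  * np.arange(len(probs)),
                  "probability": probs,
                  "label": pred}).to_csv(out / "calls.csv", index=False)
    cm = confusion_counts(pred, truth)
    rep = metrics_from_confusion(cm)
    metrics = {
        "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "fractions": {k: v for k, v in rep.__dict__.items()},
        "percent": rep.as_percent(),
        "auroc": (roc_auc(probs, truth)
                  if len(np.unique(truth)) == 2 else None),
        "final_val_mae_deg": history.val_mae_deg[-1],
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    artifacts += ["calls.csv", "metrics.json"]
    done(name)

    # manifest -------------------------------------------------------------
    cfg_json = json.dumps(config.model_dump(), sort_keys=True)
    manifest = {
        "config": config.model_dump(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seeds": config.seeds.model_dump(),
        "version": __version__,
        "stage_seconds": timings,
        "artifacts": artifacts,
        "metrics": metrics,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
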