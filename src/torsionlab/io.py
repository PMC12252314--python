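"""File formats: PNG frames, torsion-series CSV with JSON sidecar, box
archives and model checkpoints."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import InputError
from .synthetic import LabeledSeries, WaveformParams

__all__ = [
    "write_frames",
    "read_frames",
    "write_series",
    "read_series",
    "write_boxes",
    "read_boxes",
]


def write_frames(frames: np.ndarray, out_dir, masks: np.ndarray | None = None,
                 prefix: str = "frame") -> list[Path]:
    """Write a (T, H, W) uint8 stack as PNGs (masks alongside if given)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out / f"{prefix}_{i:05d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
        if masks is not None:
            iio.imwrite(out / f"{prefix}_{i:05d}_mask.png",
                        (np.asarray(masks[i], bool) * 255).astype(np.uint8))
    return paths


def read_frames(in_dir, prefix: str = "frame"):
    """Read frames written by :func:`write_frames` (masks if present)."""
    paths = sorted(Path(in_dir).glob(f"{prefix}_[0-9]*.png"))
    paths = [p for p in paths if not p.stem.endswith("_mask")]
    if not paths:
        raise InputError(f"no frames found in {in_dir}")
    frames = np.stack([iio.imread(p) for p in paths])
    mask_paths = [p.with_name(p.stem + "_mask.png") for p in paths]
    masks = None
    if all(p.exists() for p in mask_paths):
        masks = np.stack([iio.imread(p) > 0 for p in mask_paths])
    return frames, masks


def write_series(series: LabeledSeries, csv_path,
                 params: WaveformParams | None = None) -> None:
    """Series as CSV (time_s, angle_deg) plus a {label, seed, params} sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": series.times_s,
                  "angle_deg": series.angles}).to_csv(csv_path, index=False)
    side = {"label": int(series.label), "seed": int(series.seed),
            "sample_rate": series.sample_rate,
            "params": None if params is None else asdict(params)}
    csv_path.with_suffix(".json").write_text(json.dumps(side, indent=2))


def read_series(csv_path) -> LabeledSeries:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if not {"time_s", "angle_deg"} <= set(df.columns):
        raise InputError("series CSV needs time_s and angle_deg columns")
    side_path = csv_path.with_suffix(".json")
    label, seed, rate = 0, -1, 10.0
    if side_path.exists():
        side = json.loads(side_path.read_text())
        label = int(side.get("label", 0))
        seed = int(side.get("seed", -1))
        rate = float(side.get("sample_rate", 10.0))
    elif len(df) > 1:
        rate = 1.0 / float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
    return LabeledSeries(angles=df["angle_deg"].to_numpy(float),
                         label=label, seed=seed, sample_rate=rate)


def write_boxes(boxes, npz_path, manifest: dict | None = None) -> None:
    """Iris boxes as one (T, 64, 64) array plus a JSON manifest."""
    from .preprocess import IrisBox

    arr = np.stack([b.pixels if isinstance(b, IrisBox) else np.asarray(b)
                    for b in boxes]).astype(np.float32)
    npz_path = Path(npz_path)
    np.savez_compressed(npz_path, boxes=arr)
    if manifest is not None:
        npz_path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def read_boxes(npz_path) -> np.ndarray:
    with np.load(npz_path) as z:
        return z["boxes"]
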