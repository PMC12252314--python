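"""The Torsion Transformer: anchor-based self-supervised torsion estimation.

The model learns continuous iris torsion from mechanically generated
rotation pairs.  It has two heads sharing a bank of 31 learnable 64x64
"anchor" matrices, one per angle on the -15..+15 degree grid:

* the **Decoder** receives the unrotated 3-frame iris-box stack, runs each
  frame through its own skip-connection block, merges the three 31-channel
  feature stacks, applies the anchor matrices of 3 retained branches
  (block-level dropout over the 31 branches) and reconstructs the rotated
  stack; it is supervised with a mean-squared-error loss.
* the **Finder** receives a 3-frame stack and regresses its rotation angle:
  a conv layer lifts the stack to 31 channels, each channel is mixed by the
  corresponding shared anchor matrix, further convs condense to a 32x32x4
  map, and a 2-layer fully connected head produces 31 logits whose softmax
  expectation over the grid angles is the predicted angle (so predictions
  are always inside [-15, 15]).  It is supervised with a Huber loss
  (delta = 1).

The total training loss is the unweighted sum of the two, so gradients
from both heads flow into the shared anchor bank.  During training the
Finder sees the rotated stack and the unrotated training pose defines the
zero-torsion reference; at inference it maps any 3-frame window of iris
boxes to one torsion angle (one value per 0.1 s at 30 fps).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .errors import ConfigurationError, InputError, TrainingError
from .preprocess import RotationSample

__all__ = [
    "AngleGrid",
    "angle_grid",
    "TorsionNetConfig",
    "TrainHistory",
    "TorsionSeries",
    "TorsionTransformer",
    "decoder_loss",
    "finder_loss",
    "total_loss",
    "softmax_expectation",
    "train_torsion_transformer",
    "estimate_series",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class AngleGrid:
    """Inclusive angle grid; 31 one-degree steps over +-15 at defaults."""

    min_deg: float = -15.0
    max_deg: float = 15.0
    step_deg: float = 1.0

    def __post_init__(self):
        if self.step_deg <= 0:
            raise ConfigurationError("step_deg must be > 0")
        span = self.max_deg - self.min_deg
        n = span / self.step_deg
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("(max - min) must be divisible by step")

    @property
    def angles(self) -> np.ndarray:
        n = int(round((self.max_deg - self.min_deg) / self.step_deg)) + 1
        return self.min_deg + self.step_deg * np.arange(n)

    def __len__(self) -> int:
        return len(self.angles)

    def nearest_index(self, theta) -> np.ndarray:
        idx = np.rint((np.asarray(theta) - self.min_deg) / self.step_deg)
        return np.clip(idx, 0, len(self) - 1).astype(int)


def angle_grid(min_deg: float = -15.0, max_deg: float = 15.0,
               step_deg: float = 1.0) -> AngleGrid:
    return AngleGrid(min_deg, max_deg, step_deg)


@dataclass
class TorsionNetConfig:
    """Architecture and training hyperparameters.

    Defaults follow the full-size network: skip-block convs of 16 and 64
    filters, a post-concatenation pair of 16 and 31 filters, an anchor
    block of 16/64/1 filters, a Finder condensation of 3, 12 and 4 filters
    and a 1024-wide fully connected layer.  ``small()`` returns a reduced
    configuration suitable for CPU-scale experiments.
    """

    grid: AngleGrid = field(default_factory=AngleGrid)
    retained_anchors: int = 3
    skip_channels: tuple = (16, 64)
    post_concat_channels: tuple = (16, 31)
    anchor_block_filters: tuple = (16, 64, 1)
    finder_channels: tuple = (3, 12, 4)
    fc_widths: tuple = (1024, 31)
    per_anchor_blocks: bool = False
    huber_delta: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 15
    seed: int = 0

    def __post_init__(self):
        n = len(self.grid)
        if self.retained_anchors > n:
            raise ConfigurationError("retained_anchors exceeds anchor count")
        if self.huber_delta <= 0:
            raise ConfigurationError("huber_delta must be > 0")
        if self.post_concat_channels[-1] != n:
            raise ConfigurationError(
                "last post-concat channel count must equal the grid length")
        if self.fc_widths[-1] != n:
            raise ConfigurationError(
                "final FC width must equal the grid length")
        if self.anchor_block_filters[-1] != 1:
            raise ConfigurationError("anchor block must end in 1 filter")

    @classmethod
    def small(cls, **kw) -> "TorsionNetConfig":
        """Reduced network for desk-scale CPU training."""
        kw.setdefault("skip_channels", (4, 8))
        kw.setdefault("post_concat_channels", (4, 31))
        kw.setdefault("anchor_block_filters", (4, 8, 1))
        kw.setdefault("fc_widths", (256, 31))
        return cls(**kw)


@dataclass
class TrainHistory:
    """Per-epoch losses and validation angle error.

    ``total_loss`` equals ``decoder_loss + finder_loss`` per epoch within
    floating tolerance.
    """

    decoder_loss: list = field(default_factory=list)
    finder_loss: list = field(default_factory=list)
    total_loss: list = field(default_factory=list)
    val_mae_deg: list = field(default_factory=list)


@dataclass
class TorsionSeries:
    """Time-ordered torsion angles (degrees), one per 3-frame window."""

    times_s: np.ndarray
    angles_deg: np.ndarray


# ---- losses (public scalar forms) ---------------------------------------

def decoder_loss(recon: np.ndarray, gt: np.ndarray) -> float:
    """Mean squared error over all pixels of the 3-frame stacks."""
    a, b = np.asarray(recon, np.float64), np.asarray(gt, np.float64)
    if a.shape != b.shape:
        raise InputError("reconstruction and ground truth differ in shape")
    return float(np.mean((a - b) ** 2))


def finder_loss(theta_pred, theta_gt, delta: float = 1.0) -> float:
    """Mean Huber loss between predicted and target angles (degrees)."""
    if delta <= 0:
        raise ConfigurationError("delta must be > 0")
    e = np.asarray(theta_gt, np.float64) - np.asarray(theta_pred, np.float64)
    small = np.abs(e) <= delta
    per = np.where(small, 0.5 * e * e, delta * np.abs(e) - 0.5 * delta ** 2)
    return float(np.mean(per))


def total_loss(dec: float, fin: float) -> float:
    """Unweighted sum of the two objectives."""
    return float(dec) + float(fin)


def softmax_expectation(logits: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Continuous angle prediction: softmax-weighted mean of grid angles."""
    z = np.asarray(logits, np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=-1, keepdims=True)
    return p @ np.asarray(angles, np.float64)


# ---- the network ---------------------------------------------------------

class _SkipBlock(nn.Module):
    """Per-frame skip-connection block: 64x64x1 -> 64x64x31 features."""

    def __init__(self, cfg: TorsionNetConfig, rng):
        c1, c2 = cfg.skip_channels
        p1, p2 = cfg.post_concat_channels
        self.conv1 = nn.Conv2d(1, c1, 3, rng)
        self.conv2 = nn.Conv2d(c1, c2, 3, rng)
        self.conv3 = nn.Conv2d(c2, 1, 3, rng)
        self.conv4 = nn.Conv2d(2, p1, 3, rng)
        self.conv5 = nn.Conv2d(p1, p2, 3, rng)

    def __call__(self, frame: nn.Tensor) -> nn.Tensor:
        # frame is channels-last (N, 64, 64, 1)
        x = nn.relu(self.conv1(frame))
        x = nn.relu(self.conv2(x))
        x = nn.relu(self.conv3(x))
        x = nn.concat([x, frame], axis=3)     # skip connection -> 64x64x2
        x = nn.relu(self.conv4(x))
        return self.conv5(x)


class _AnchorConvBlock(nn.Module):
    def __init__(self, cfg: TorsionNetConfig, rng):
        f1, f2, f3 = cfg.anchor_block_filters
        self.conv1 = nn.Conv2d(1, f1, 3, rng)
        self.conv2 = nn.Conv2d(f1, f2, 3, rng)
        self.conv3 = nn.Conv2d(f2, f3, 3, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        x = nn.relu(self.conv1(x))
        x = nn.relu(self.conv2(x))
        return self.conv3(x)


class TorsionTransformer(nn.Module):
    """Decoder + Finder with a shared bank of per-angle anchor matrices."""

    def __init__(self, cfg: TorsionNetConfig):
        self.cfg = cfg
        self.angles = cfg.grid.angles.astype(np.float32)
        n_anchors = len(cfg.grid)
        rng = np.random.default_rng(cfg.seed)

        self.skip_blocks = [_SkipBlock(cfg, rng) for _ in range(3)]

        # anchors start near the identity so every branch initially passes
        # its feature slice through unchanged
        eye = np.eye(64, dtype=np.float32)[None].repeat(n_anchors, axis=0)
        noise = rng.normal(0, 0.01, size=eye.shape).astype(np.float32)
        self.anchors = nn.Tensor(eye + noise, requires_grad=True)

        if cfg.per_anchor_blocks:
            self.anchor_blocks = [_AnchorConvBlock(cfg, rng)
                                  for _ in range(n_anchors)]
        else:
            self.anchor_blocks = [_AnchorConvBlock(cfg, rng)]

        fc0, fc1 = cfg.finder_channels[0], cfg.finder_channels[1]
        fc2 = cfg.finder_channels[2]
        self.f_in = nn.Conv2d(3, n_anchors, 3, rng)
        self.f_c1 = nn.Conv2d(n_anchors, fc0, 3, rng)
        self.f_c2 = nn.Conv2d(fc0, fc1, 3, rng)
        self.f_c3 = nn.Conv2d(fc1, fc2, 3, rng)
        self.fc1 = nn.Linear(32 * 32 * fc2, cfg.fc_widths[0], rng)
        self.fc2 = nn.Linear(cfg.fc_widths[0], cfg.fc_widths[1], rng)

    # ---- decoder path ----------------------------------------------------
    def skip_block_forward(self, frame: nn.Tensor, block: int) -> nn.Tensor:
        """One 64x64x1 frame (channels last) -> 64x64x31 feature stack."""
        if frame.shape[1:] != (64, 64, 1):
            raise InputError("skip block expects (N, 64, 64, 1) frames")
        return self.skip_blocks[block](frame)

    def merged_features(self, stack: nn.Tensor) -> nn.Tensor:
        """Element-wise sum of the three per-frame skip-block outputs.

        ``stack`` is (N, 3, 64, 64); the result is channels-last
        (N, 64, 64, 31).
        """
        outs = [self.skip_block_forward(
            stack[:, k].reshape(stack.shape[0], 64, 64, 1), k)
            for k in range(3)]
        return outs[0] + outs[1] + outs[2]

    def _anchor_block_apply(self, prods: nn.Tensor,
                            retained: np.ndarray) -> nn.Tensor:
        """Run the retained products (N, K, 64, 64) through anchor blocks."""
        n, k = retained.shape
        flat = prods.reshape(n * k, 64, 64, 1)
        if not self.cfg.per_anchor_blocks:
            out = self.anchor_blocks[0](flat)
            return out.reshape(n, k, 64, 64)
        # group the (sample, slot) pairs by anchor id, process each group
        # through its own block, then restore the original order
        flat_ids = retained.reshape(-1)
        pieces, order = [], []
        for a in np.unique(flat_ids):
            pos = np.nonzero(flat_ids == a)[0]
            pieces.append(self.anchor_blocks[int(a)](flat[pos]))
            order.append(pos)
        order = np.concatenate(order)
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        return nn.concat(pieces, axis=0)[inv].reshape(n, k, 64, 64)

    def decoder_forward(self, stack: nn.Tensor,
                        retained: np.ndarray) -> nn.Tensor:
        """Reconstruct the rotated stack through the retained anchor branches.

        ``retained`` is (N, K) integer anchor indices (K = 3 by default);
        the K output maps stack depth-wise in anchor-index order.
        """
        retained = np.asarray(retained, dtype=int)
        if retained.ndim == 1:
            retained = np.broadcast_to(retained, (stack.shape[0],
                                                  len(retained))).copy()
        if (np.sort(retained, axis=1)[:, :-1]
                == np.sort(retained, axis=1)[:, 1:]).any():
            raise ConfigurationError("retained anchor indices must be distinct")
        merged = self.merged_features(stack)                  # (N,64,64,31)
        slices = nn.gather_channels_last(merged, retained)    # (N,K,64,64)
        mats = nn.gather_rows(self.anchors, retained)         # (N,K,64,64)
        prods = nn.matmul(slices, mats)
        return self._anchor_block_apply(prods, retained)

    # ---- finder path -----------------------------------------------------
    def finder_forward(self, stack: nn.Tensor):
        """Map a 3-frame stack (N, 3, 64, 64) to (logits, predicted angle)."""
        x = nn.transpose(stack, (0, 2, 3, 1))                 # (N,64,64,3)
        x = nn.relu(self.f_in(x))                             # (N,64,64,31)
        x = nn.transpose(x, (0, 3, 1, 2))
        x = nn.matmul(x, self.anchors)                        # shared anchors
        x = nn.transpose(x, (0, 2, 3, 1))
        x = nn.relu(self.f_c1(x))
        x = nn.relu(self.f_c2(x))
        x = nn.maxpool2d(x)
        x = nn.relu(self.f_c3(x))                             # (N,32,32,4)
        n = x.shape[0]
        x = x.reshape(n, -1)
        x = nn.relu(self.fc1(x))
        logits = self.fc2(x)
        probs = nn.softmax(logits, axis=-1)
        theta = nn.matmul(probs, nn.Tensor(self.angles[:, None])).reshape(n)
        return logits, theta

    def predict_angles(self, stacks: np.ndarray,
                       batch_size: int = 64) -> np.ndarray:
        """Finder inference on an (M, 3, 64, 64) array of stacks."""
        out = []
        with nn.no_grad():
            for i in range(0, len(stacks), batch_size):
                _, th = self.finder_forward(
                    nn.Tensor(stacks[i:i + batch_size]))
                out.append(th.data.astype(np.float64))
        return np.concatenate(out) if out else np.empty(0)


def _retained_for_training(grid: AngleGrid, thetas: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Nearest anchor to each target plus 2 random distinct others."""
    n_anchors = len(grid)
    nearest = grid.nearest_index(thetas)
    out = np.empty((len(thetas), 3), dtype=int)
    for i, nz in enumerate(nearest):
        others = rng.choice(n_anchors - 1, size=2, replace=False)
        others = others + (others >= nz)      # skip the nearest index
        sel = np.sort(np.concatenate([[nz], others]))
        out[i] = sel
    return out


def retained_for_eval(grid: AngleGrid, thetas: np.ndarray) -> np.ndarray:
    """Nearest anchor and its two grid neighbours (evaluation rule)."""
    n = len(grid)
    nearest = grid.nearest_index(thetas)
    center = np.clip(nearest, 1, n - 2)
    return np.stack([center - 1, center, center + 1], axis=1)


def _stacks(samples: list[RotationSample]):
    orig = np.stack([s.original for s in samples]).astype(np.float32)
    rot = np.stack([s.rotated for s in samples]).astype(np.float32)
    thetas = np.array([s.theta_gt for s in samples], dtype=np.float64)
    return orig, rot, thetas


def train_torsion_transformer(train_samples: list[RotationSample],
                              cfg: TorsionNetConfig,
                              val_samples: list[RotationSample] | None = None,
                              log=None):
    """Joint Decoder+Finder training with Adam on the summed loss.

    Per step the Decoder reconstructs the rotated stack through 3 retained
    anchor branches (nearest-to-target plus 2 random, seeded) and the
    Finder regresses the rotation angle of the rotated stack; all
    parameters including the shared anchor bank receive gradient from both
    losses.  Returns ``(model, TrainHistory)``; identical configs and
    seeds give identical histories.
    """
    if not train_samples:
        raise ConfigurationError("no training samples")
    model = TorsionTransformer(cfg)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    ss = np.random.SeedSequence([cfg.seed, 0x70A])
    rng = np.random.default_rng(ss)

    orig, rot, thetas = _stacks(train_samples)
    if val_samples:
        vorig, vrot, vthetas = _stacks(val_samples)
    history = TrainHistory()
    n = len(train_samples)

    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(n)
        dec_sum = fin_sum = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            xb = nn.Tensor(orig[idx])
            rb = nn.Tensor(rot[idx])
            tb = thetas[idx]

            retained = _retained_for_training(cfg.grid, tb, rng)
            recon = model.decoder_forward(xb, retained)
            diff = recon - rb
            dec = (diff * diff).mean()

            _, theta_hat = model.finder_forward(rb)
            fin = nn.huber(theta_hat, tb, cfg.huber_delta)

            loss = dec + fin
            if not np.isfinite(loss.data):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: "
                    f"decoder={dec.item()}, finder={fin.item()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            dec_sum += dec.item() * len(idx)
            fin_sum += fin.item() * len(idx)

        history.decoder_loss.append(dec_sum / n)
        history.finder_loss.append(fin_sum / n)
        history.total_loss.append(dec_sum / n + fin_sum / n)
        if val_samples:
            pred = model.predict_angles(vrot)
            mae = float(np.mean(np.abs(pred - vthetas)))
        else:
            mae = float("nan")
        history.val_mae_deg.append(mae)
        if log is not None:
            log(f"epoch {epoch + 1}/{cfg.max_epochs}: "
                f"decoder {history.decoder_loss[-1]:.5f}, "
                f"finder {history.finder_loss[-1]:.4f}, val MAE {mae:.3f} deg")
    return model, history


def estimate_series(frames, model: TorsionTransformer,
                    dt_s: float = 0.1) -> TorsionSeries:
    """One torsion angle per non-overlapping 3-frame window.

    ``frames`` is a sequence of 64x64 iris boxes (arrays or ``IrisBox``);
    trailing frames that do not fill a triple are dropped.  Timestamps are
    spaced ``dt_s`` apart (0.1 s for 30 fps input).
    """
    from .preprocess import IrisBox

    arrs = [f.pixels if isinstance(f, IrisBox) else np.asarray(f, np.float32)
            for f in frames]
    if len(arrs) < 3:
        raise InputError("need at least 3 frames")
    m = len(arrs) // 3
    stacks = np.stack([np.stack(arrs[3 * i:3 * i + 3]) for i in range(m)])
    angles = model.predict_angles(stacks)
    return TorsionSeries(times_s=dt_s * np.arange(m), angles_deg=angles)


# ---- checkpoints ---------------------------------------------------------

def _cfg_to_json(cfg: TorsionNetConfig) -> str:
    d = asdict(cfg)
    d["grid"] = {"min_deg": cfg.grid.min_deg, "max_deg": cfg.grid.max_deg,
                 "step_deg": cfg.grid.step_deg}
    return json.dumps(d)


def _cfg_from_json(s: str) -> TorsionNetConfig:
    d = json.loads(s)
    d["grid"] = AngleGrid(**d["grid"])
    for k in ("skip_channels", "post_concat_channels", "anchor_block_filters",
              "finder_channels", "fc_widths"):
        d[k] = tuple(d[k])
    return TorsionNetConfig(**d)


def save_checkpoint(model: TorsionTransformer, path) -> None:
    arrays = model.state_arrays()
    np.savez_compressed(path, __config__=_cfg_to_json(model.cfg),
                        __kind__="torsion_transformer", **arrays)


def load_checkpoint(path) -> TorsionTransformer:
    with np.load(path, allow_pickle=False) as z:
        if str(z["__kind__"]) != "torsion_transformer":
            raise InputError("not a torsion-transformer checkpoint")
        cfg = _cfg_from_json(str(z["__config__"]))
        model = TorsionTransformer(cfg)
        model.load_state_arrays(
            {k: z[k] for k in z.files if not k.startswith("__")})
    return model
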