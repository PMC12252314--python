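"""Synthetic eye frames and torsion-angle waveforms with known ground truth.

Real videonystagmography (VNG) recordings are clinical data and cannot be
redistributed, so this module provides the two signals every downstream
stage needs, with exact labels:

* eye frames: a dark pupil disk inside a textured iris annulus on a bright
  sclera.  The iris texture is a seeded sum of angular harmonics modulated
  by a radial window, plus seeded polar speckle, so it has non-trivial
  angular structure and a unique rotational-registration optimum.  A frame
  rendered at torsion angle ``theta`` shows the same texture rotated about
  the pupil centre.
* torsion waveforms: the nystagmus class is a sawtooth beat (linear
  slow-phase drift, fast reset) with amplitude in the pathologic 5-15
  degree range; the normal class is a low-amplitude sinusoidal drift.
  Both carry additive Gaussian noise and a binary label.

Sign convention (package-wide): a positive angle rotates displayed image
content counterclockwise, with the image origin at the top-left, x to the
right and y down.  The renderer, ``preprocess.rotate_box`` and the
waveforms all share this convention.

All randomness flows through explicit integer seeds; rendering is a pure
function of (scene, theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ConfigurationError

__all__ = [
    "SceneParams",
    "WaveformParams",
    "LabeledSeries",
    "RenderedSequence",
    "render_eye_frame",
    "generate_waveform",
    "render_sequence",
]

# base intensities on the 8-bit scale
_SCLERA = 200.0
_PUPIL = 25.0
_IRIS_BASE = 120.0
_EYELID = 185.0
_HARMONIC_SPAN = 38.0   # total amplitude budget of the angular harmonics
_SPECKLE_SD = 16.0
_SPECKLE_NR = 20        # radial bins of the polar speckle field
_SPECKLE_NA = 180       # angular bins (2 degrees)


@dataclass(frozen=True)
class SceneParams:
    """Geometry and texture of one synthetic eye."""

    image_size: int = 224
    pupil_radius: float = 28.0
    iris_radius: float = 88.0
    texture_seed: int = 0
    texture_harmonics: int = 6
    noise_sd: float = 0.0
    occluder_fraction: float = 0.0

    def __post_init__(self):
        if not (0 < self.pupil_radius < self.iris_radius < self.image_size / 2):
            raise ConfigurationError(
                "require 0 < pupil_radius < iris_radius < image_size/2, got "
                f"{self.pupil_radius}, {self.iris_radius}, {self.image_size}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (0.0 <= self.occluder_fraction <= 0.5):
            raise ConfigurationError("occluder_fraction must be in [0, 0.5]")
        if not (2 <= self.texture_harmonics <= 12):
            raise ConfigurationError("texture_harmonics must be in [2, 12]")


@dataclass(frozen=True)
class WaveformParams:
    """Parameters of a labelled torsion-angle time series.

    ``amplitude`` (nystagmus, peak-to-peak of the slow-phase ramp, degrees)
    and ``beat_frequency`` (Hz) may be ``None``, in which case they are
    drawn per series from the pathologic ranges [5, 15] deg and [1, 3] Hz.
    ``slow_fast_ratio`` is the fraction of each beat spent in the slow
    phase.  The normal class is a sinusoidal drift of peak amplitude
    ``drift_amplitude`` at ``drift_frequency`` Hz.
    """

    label: str = "nystagmus"
    duration: float = 10.0
    sample_rate: float = 10.0
    amplitude: float | None = None
    beat_frequency: float | None = None
    slow_fast_ratio: float = 0.9
    noise_sd: float = 0.3
    drift_amplitude: float = 1.0
    drift_frequency: float = 0.2

    def __post_init__(self):
        if self.label not in ("normal", "nystagmus"):
            raise ConfigurationError("label must be 'normal' or 'nystagmus'")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be > 0")
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")
        if self.amplitude is not None and not (0 <= self.amplitude <= 15):
            raise ConfigurationError("amplitude must be in [0, 15] degrees")
        if not (0.5 < self.slow_fast_ratio < 1.0):
            raise ConfigurationError("slow_fast_ratio must be in (0.5, 1)")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ConfigurationError("noise_sd/drift_amplitude must be >= 0")


@dataclass
class LabeledSeries:
    """Torsion angles (degrees) with a binary label (1 = nystagmus)."""

    angles: np.ndarray
    label: int
    seed: int
    sample_rate: float = 10.0

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.angles)) / self.sample_rate


@dataclass
class RenderedSequence:
    """Frames rendered along a torsion series, with oracle masks."""

    frames: np.ndarray        # (T, H, W) uint8
    masks: np.ndarray         # (T, H, W) bool
    angles: np.ndarray        # (T,) degrees, per-frame ground truth
    series: LabeledSeries
    frames_per_sample: int


class _SceneCache:
    """Per-scene geometry and texture parameters (scenes are frozen/hashable)."""

    def __init__(self, scene: SceneParams):
        n = scene.image_size
        c = (n - 1) / 2.0
        yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
        dx, dy = xx - c, yy - c
        r = np.hypot(dx, dy)
        self.annulus = (r >= scene.pupil_radius) & (r <= scene.iris_radius)
        self.pupil = r < scene.pupil_radius
        # one-pixel soft transitions at the region edges (optical blur);
        # alpha = 1 inside the iris annulus, 0 outside
        self.alpha_ann = (np.clip(r - scene.pupil_radius + 0.5, 0, 1)
                          * np.clip(scene.iris_radius - r + 0.5, 0, 1)
                          )[self.annulus]
        self.alpha_pupil_edge = np.clip(
            scene.pupil_radius - r + 0.5, 0, 1)[self.annulus]
        # negate dy so the angle increases counterclockwise as displayed
        self.a_ann = np.arctan2(-dy, dx)[self.annulus]
        u = (r[self.annulus] - scene.pupil_radius) / (
            scene.iris_radius - scene.pupil_radius)
        self.u_ann = np.clip(u, 0.0, 1.0)
        self.window = 0.35 + 0.65 * np.sin(np.pi * self.u_ann)
        self.ri = np.clip(self.u_ann * (_SPECKLE_NR - 1), 0, _SPECKLE_NR - 1)

        rng = np.random.default_rng(scene.texture_seed)
        self.orders = rng.choice(np.arange(2, 13),
                                 size=scene.texture_harmonics, replace=False)
        self.phases = rng.uniform(0, 2 * np.pi, size=scene.texture_harmonics)
        amps = rng.uniform(0.5, 1.0, size=scene.texture_harmonics)
        self.amps = amps * (_HARMONIC_SPAN / amps.sum())
        self.speckle = rng.normal(0.0, 1.0, size=(_SPECKLE_NR, _SPECKLE_NA))

        self.occluded = None
        if scene.occluder_fraction > 0:
            ys = np.nonzero(self.annulus)[0]
            cut = np.quantile(ys, scene.occluder_fraction)
            rows = np.arange(n)[:, None] <= cut
            self.occluded = rows & self.annulus


_SCENE_CACHE: dict = {}


def _get_cache(scene: SceneParams) -> "_SceneCache":
    cache = _SCENE_CACHE.get(scene)
    if cache is None:
        cache = _SCENE_CACHE[scene] = _SceneCache(scene)
        if len(_SCENE_CACHE) > 32:
            _SCENE_CACHE.pop(next(iter(_SCENE_CACHE)))
    return cache


def _texture_values(cache: _SceneCache, a: np.ndarray) -> np.ndarray:
    """Iris intensity of the unrotated pattern at annulus angles ``a``."""
    tex = np.full_like(a, _IRIS_BASE)
    for m, ph, amp in zip(cache.orders, cache.phases, cache.amps):
        tex += amp * np.cos(m * a + ph) * cache.window
    ai = (np.mod(a, 2 * np.pi) / (2 * np.pi)) * _SPECKLE_NA
    spk = map_coordinates(cache.speckle, [cache.ri, ai],
                          order=1, mode="grid-wrap")
    tex += _SPECKLE_SD * cache.window * spk
    return tex


def render_eye_frame(scene: SceneParams, theta: float):
    """Render one eye frame at torsion angle ``theta`` (degrees).

    Returns ``(image, oracle_mask, theta)`` where ``image`` is a uint8
    (H, W) raster and ``oracle_mask`` is True exactly on the visible iris
    annulus.  Identical inputs reproduce bit-identical outputs.
    """
    if abs(theta) > 15 + 1e-9:
        raise ConfigurationError("|theta| must be <= 15 degrees")
    cache = _get_cache(scene)

    # positive theta rotates content counterclockwise: the pixel at display
    # angle alpha shows the unrotated texture at alpha - theta
    tex = _texture_values(cache, cache.a_ann - np.deg2rad(theta))

    img = np.full((scene.image_size, scene.image_size), _SCLERA)
    img[cache.pupil] = _PUPIL
    # blend the annulus texture over its neighbours at the 1 px edge bands
    base = (_PUPIL * cache.alpha_pupil_edge
            + _SCLERA * (1.0 - cache.alpha_pupil_edge
                         - cache.alpha_ann).clip(0, 1))
    img[cache.annulus] = cache.alpha_ann * tex + base

    mask = cache.annulus.copy()
    if cache.occluded is not None:
        img[cache.occluded] = _EYELID
        mask &= ~cache.occluded

    if scene.noise_sd > 0:
        ss = np.random.SeedSequence(
            [scene.texture_seed, abs(int(round(theta * 1e6))),
             int(theta < 0), 0x6E5])
        nrng = np.random.default_rng(ss)
        img = img + nrng.normal(0.0, scene.noise_sd, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask, float(theta)


def generate_waveform(params: WaveformParams, seed: int) -> LabeledSeries:
    """Generate one labelled torsion series.

    Nystagmus: sawtooth beats — a linear slow-phase ramp spanning
    ``amplitude`` degrees peak-to-peak followed by a fast reset — plus
    Gaussian noise.  Normal: sinusoidal drift plus Gaussian noise.  Angles
    are clipped to +-15 degrees.  Same (params, seed) -> identical series.
    """
    rng = np.random.default_rng(seed)
    n = int(round(params.duration * params.sample_rate))
    t = np.arange(n) / params.sample_rate

    if params.label == "nystagmus":
        amp = (params.amplitude if params.amplitude is not None
               else rng.uniform(5.0, 15.0))
        freq = (params.beat_frequency if params.beat_frequency is not None
                else rng.uniform(1.0, 3.0))
        r = params.slow_fast_ratio
        # phase offset of one sample step so the sampling grid straddles the
        # reset rather than landing on the beat boundary
        phase = np.mod(freq * t + freq / params.sample_rate, 1.0)
        ramp = -amp / 2 + amp * phase / r
        reset = amp / 2 - amp * (phase - r) / (1.0 - r)
        angles = np.where(phase < r, ramp, reset)
        label = 1
    else:
        angles = params.drift_amplitude * np.sin(
            2 * np.pi * params.drift_frequency * t + rng.uniform(0, 2 * np.pi))
        label = 0

    if params.noise_sd > 0:
        angles = angles + rng.normal(0.0, params.noise_sd, size=n)
    angles = np.clip(angles, -15.0, 15.0)
    return LabeledSeries(angles=angles.astype(np.float64), label=label,
                         seed=int(seed), sample_rate=params.sample_rate)


def render_sequence(series: LabeledSeries, scene: SceneParams,
                    frames_per_sample: int = 3) -> RenderedSequence:
    """Render a frame stack along a torsion series.

    Frame ``t * frames_per_sample + k`` is rendered at the angle linearly
    interpolated between series samples ``t`` and ``t + 1`` (the final
    sample is held).  A 10 Hz series with the default 3 frames per sample
    emulates 30 fps video.
    """
    if frames_per_sample < 1:
        raise ConfigurationError("frames_per_sample must be >= 1")
    s = np.asarray(series.angles, dtype=np.float64)
    n = len(s)
    idx = np.arange(n * frames_per_sample) / frames_per_sample
    angles = np.interp(idx, np.arange(n), s)

    frames = np.empty((len(angles), scene.image_size, scene.image_size),
                      dtype=np.uint8)
    masks = np.empty(frames.shape, dtype=bool)
    for i, th in enumerate(angles):
        frames[i], masks[i], _ = render_eye_frame(scene, float(th))
    return RenderedSequence(frames=frames, masks=masks, angles=angles,
                            series=series, frames_per_sample=frames_per_sample)


def scene_to_dict(scene: SceneParams) -> dict:
    return asdict(scene)


def waveform_to_dict(params: WaveformParams) -> dict:
    return asdict(params)
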