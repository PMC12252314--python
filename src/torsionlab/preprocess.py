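"""Frame preprocessing: contrast enhancement, iris segmentation, bounding-box
normalisation, and rotation-pair construction for self-supervised training.

The pipeline mirrors standard VNG preprocessing: CLAHE on the luminance
channel, pixel-wise iris segmentation, a crop at the mask's minimum
enclosing circle rescaled so the iris diameter is exactly 64 px, and
randomly rotated original/rotated training pairs on the +-15 degree range.

Segmentation is a pluggable strategy.  A production system would slot a
pretrained segmentation network in here; this package ships an ``oracle``
strategy (the renderer's ground-truth mask, for the synthetic pipeline),
a ``classical`` strategy (multi-Otsu thresholding + largest connected
component + annulus fit) and an ``external`` strategy (mask files produced
elsewhere).  Frames whose segmentation fails raise ``SegmentationError``
carrying the frame index so callers can drop and log them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import imageio.v3 as iio
import shapely
from shapely.geometry import MultiPoint
from skimage import color, exposure, measure, morphology
from skimage.transform import resize, rotate

from .errors import ConfigurationError, InputError, SegmentationError

__all__ = [
    "IrisMask",
    "IrisBox",
    "RotationSample",
    "enhance_contrast",
    "segment_iris",
    "extract_iris_box",
    "rotate_box",
    "make_rotation_samples",
    "boxes_from_frames",
]

BOX_SIZE = 64


@dataclass
class IrisMask:
    """Binary iris mask aligned to its source image."""

    mask: np.ndarray
    source_shape: tuple

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.source_shape):
            raise InputError("mask shape differs from source shape")
        if not self.mask.any():
            raise InputError("mask has no foreground pixels")


@dataclass
class IrisBox:
    """64x64 unit-scaled iris crop; the atomic model input.

    The minimum enclosing circle of the segmentation mask maps to the
    inscribed circle of the box.
    """

    pixels: np.ndarray           # (64, 64) float32 in [0, 1]
    center: tuple                # (x, y) in source-image coordinates
    diameter_src: float          # enclosing-circle diameter in source pixels

    def __post_init__(self):
        if self.pixels.shape != (BOX_SIZE, BOX_SIZE):
            raise InputError("iris box must be 64x64")


@dataclass
class RotationSample:
    """Self-supervised training triple.

    ``original`` is a stack of 3 consecutive iris boxes, ``rotated`` is the
    same stack with every frame rotated by ``theta_gt`` degrees.  The
    rotated stack is the reconstruction target; ``theta_gt`` is the
    regression target.
    """

    original: np.ndarray         # (3, 64, 64) float32
    theta_gt: float
    rotated: np.ndarray          # (3, 64, 64) float32


def _to_unit(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype == np.uint8:
        return img.astype(np.float32) / 255.0
    return img.astype(np.float32)


def enhance_contrast(image: np.ndarray, clip_limit: float = 0.02,
                     tile_grid: int = 8) -> np.ndarray:
    """CLAHE on the luminance channel.

    RGB images are converted to LAB, equalized on L and converted back;
    grayscale images are treated as the luminance channel directly.  The
    output keeps the input shape and the 8-bit range.  ``clip_limit`` is
    the normalised clip limit of ``skimage.exposure.equalize_adapthist``
    (0.02 roughly corresponds to the common OpenCV setting of 2.0 on an
    8x8 tile grid).
    """
    img = np.asarray(image)
    if img.size == 0:
        raise InputError("empty image")
    kernel = tuple(max(1, s // tile_grid) for s in img.shape[:2])
    if img.ndim == 2:
        g = img.astype(np.float64)
        g = g / 255.0 if img.dtype == np.uint8 else g
        eq = exposure.equalize_adapthist(g, kernel_size=kernel,
                                         clip_limit=clip_limit)
        return np.clip(np.rint(eq * 255.0), 0, 255).astype(np.uint8)
    if img.ndim == 3 and img.shape[2] == 3:
        rgbf = img.astype(np.float64)
        rgbf = rgbf / 255.0 if img.dtype == np.uint8 else rgbf
        lab = color.rgb2lab(rgbf)
        ln = exposure.equalize_adapthist(lab[..., 0] / 100.0,
                                         kernel_size=kernel,
                                         clip_limit=clip_limit)
        lab[..., 0] = ln * 100.0
        out = color.lab2rgb(lab)
        return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
    raise InputError(f"unsupported image shape {img.shape}")


def _classical_mask(gray: np.ndarray, frame_index: int | None) -> np.ndarray:
    """Multi-Otsu band threshold + largest component + annulus fit."""
    from skimage.filters import threshold_multiotsu

    if np.ptp(gray) == 0:
        raise SegmentationError("flat image, no iris found", frame_index)
    try:
        t1, t2 = threshold_multiotsu(gray, classes=3)
    except ValueError as exc:
        raise SegmentationError(f"thresholding failed: {exc}", frame_index)
    band = (gray >= t1) & (gray < t2)
    band = morphology.remove_small_objects(band, max_size=63)
    if not band.any():
        raise SegmentationError("no mid-intensity band", frame_index)
    labels = measure.label(band)
    props = measure.regionprops(labels)
    largest = max(props, key=lambda p: p.area)
    comp = labels == largest.label

    cy, cx = largest.centroid
    yy, xx = np.nonzero(comp)
    rr = np.hypot(yy - cy, xx - cx)
    r_in, r_out = np.percentile(rr, [1.0, 99.0])
    gy, gx = np.mgrid[0:gray.shape[0], 0:gray.shape[1]]
    rad = np.hypot(gy - cy, gx - cx)
    annulus = (rad >= r_in) & (rad <= r_out)
    if not annulus.any():
        raise SegmentationError("degenerate annulus fit", frame_index)
    return annulus


def segment_iris(image: np.ndarray, strategy: str = "classical", *,
                 oracle_mask: np.ndarray | None = None,
                 mask_path=None, frame_index: int | None = None) -> IrisMask:
    """Segment the iris annulus.

    ``oracle`` returns the supplied ground-truth mask unchanged (synthetic
    pipeline); ``external`` loads a binary PNG from ``mask_path``;
    ``classical`` thresholds the mid-intensity band, keeps the largest
    connected component and fits an annulus to it.
    """
    img = np.asarray(image)
    gray = img if img.ndim == 2 else color.rgb2gray(img)
    if strategy == "oracle":
        if oracle_mask is None:
            raise ConfigurationError("oracle strategy requires oracle_mask")
        return IrisMask(np.asarray(oracle_mask, dtype=bool), gray.shape)
    if strategy == "external":
        if mask_path is None:
            raise ConfigurationError("external strategy requires mask_path")
        m = iio.imread(mask_path)
        if m.ndim == 3:
            m = m[..., 0]
        return IrisMask(m > 0, gray.shape)
    if strategy == "classical":
        g = gray.astype(np.float64)
        return IrisMask(_classical_mask(g, frame_index), gray.shape)
    raise ConfigurationError(f"unknown segmentation strategy {strategy!r}")


def _min_enclosing_circle(mask: np.ndarray):
    """Centre (x, y) and radius of the minimum enclosing circle of the mask."""
    from scipy.ndimage import binary_erosion

    boundary = mask & ~binary_erosion(mask)
    yy, xx = np.nonzero(boundary if boundary.any() else mask)
    pts = MultiPoint(np.column_stack([xx, yy]))
    radius = float(shapely.minimum_bounding_radius(pts))
    center = shapely.minimum_bounding_circle(pts).centroid
    return (float(center.x), float(center.y)), radius


def extract_iris_box(image: np.ndarray, mask: IrisMask) -> IrisBox:
    """Crop at the mask's minimum enclosing circle and rescale to 64 px.

    The circumscribing square of the circle is cropped (zero padded where
    it leaves the image) and bilinearly rescaled so the circle diameter is
    exactly 64 pixels.
    """
    img = _to_unit(image)
    if img.ndim == 3:
        img = color.rgb2gray(img).astype(np.float32)
    (cx, cy), r = _min_enclosing_circle(mask.mask)

    side = max(2, int(round(2 * r)))
    x0 = int(round(cx - r))
    y0 = int(round(cy - r))
    crop = np.zeros((side, side), dtype=np.float32)
    sy0, sy1 = max(0, y0), min(img.shape[0], y0 + side)
    sx0, sx1 = max(0, x0), min(img.shape[1], x0 + side)
    if sy1 > sy0 and sx1 > sx0:
        crop[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = img[sy0:sy1, sx0:sx1]

    if side != BOX_SIZE:
        # smooth before downscaling so fine iris speckle does not alias
        crop = resize(crop, (BOX_SIZE, BOX_SIZE), order=1,
                      preserve_range=True, anti_aliasing=side > BOX_SIZE)
    return IrisBox(pixels=crop.astype(np.float32), center=(cx, cy),
                   diameter_src=2 * r)


def rotate_box(box_pixels: np.ndarray, theta: float) -> np.ndarray:
    """Rotate a 64x64 box about its centre (bilinear, zero fill).

    Positive ``theta`` rotates content counterclockwise as displayed
    (origin top-left, x right, y down) — the package-wide convention.
    """
    box = np.asarray(box_pixels, dtype=np.float32)
    if theta == 0:
        return box.copy()
    out = rotate(box.astype(np.float64), float(theta), resize=False, order=1,
                 mode="constant", cval=0.0, preserve_range=True)
    return out.astype(np.float32)


def make_rotation_samples(boxes, n_samples: int,
                          angle_sampler: str = "uniform_continuous",
                          seed: int = 0) -> list[RotationSample]:
    """Build self-supervised rotation samples from consecutive iris boxes.

    Boxes are grouped into non-overlapping stride-3 triples; one rotation
    angle is drawn per sample and applied to all three frames.
    """
    arrs = [b.pixels if isinstance(b, IrisBox) else np.asarray(b, np.float32)
            for b in boxes]
    if len(arrs) < 3:
        raise ConfigurationError("need at least 3 boxes")
    n_triples = len(arrs) // 3
    if n_samples > n_triples:
        raise ConfigurationError(
            f"{n_samples} samples requested but only {n_triples} triples")
    rng = np.random.default_rng(seed)
    if angle_sampler == "uniform_continuous":
        thetas = rng.uniform(-15.0, 15.0, size=n_samples)
    elif angle_sampler == "grid_1deg":
        thetas = rng.integers(-15, 16, size=n_samples).astype(np.float64)
    else:
        raise ConfigurationError(f"unknown angle_sampler {angle_sampler!r}")

    samples = []
    for i in range(n_samples):
        stack = np.stack(arrs[3 * i:3 * i + 3])
        rot = np.stack([rotate_box(f, float(thetas[i])) for f in stack])
        samples.append(RotationSample(original=stack,
                                      theta_gt=float(thetas[i]), rotated=rot))
    return samples


def boxes_from_frames(frames: np.ndarray, masks: np.ndarray | None = None,
                      strategy: str = "oracle", enhance: bool = False,
                      log=None) -> list[IrisBox]:
    """Segment and crop every frame of a stack; failed frames are dropped.

    Convenience wrapper used by the pipeline: applies optional CLAHE, then
    ``segment_iris`` and ``extract_iris_box`` per frame.  Frames raising
    ``SegmentationError`` are skipped (and reported through ``log``).
    """
    out: list[IrisBox] = []
    for i, frame in enumerate(frames):
        img = enhance_contrast(frame) if enhance else frame
        try:
            m = segment_iris(
                img, strategy,
                oracle_mask=None if masks is None else masks[i],
                frame_index=i)
            out.append(extract_iris_box(img, m))
        except SegmentationError as exc:
            if log is not None:
                log(f"frame {i}: segmentation failed ({exc}); dropped")
    return out
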