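"""Image conditioning: range normalization, polarity check, CLAHE, pyramids.

The chain mirrors a standard radiograph-preparation recipe: raw intensities
are min-max rescaled to the 8-bit range, photometric polarity is checked so
that dense structures render bright on a dark background, local contrast is
enhanced with CLAHE, and the image is resampled to an ordered set of square
working resolutions. Augmentation (horizontal flip + small rotation) and
ImageNet-style channel standardization prepare arrays for model input.

Conventions: images are row-major 2-D arrays, origin top-left, 0-based
indices; every operation except :func:`build_scale_pyramid` preserves the
input dimensions.
"""

from __future__ import annotations

import numpy as np
from skimage import exposure, transform

from .records import ImageRecord, ScalePyramid

__all__ = [
    "ImageRecord",
    "ScalePyramid",
    "normalize_pixels",
    "detect_and_invert",
    "apply_clahe",
    "build_scale_pyramid",
    "augment",
    "standardize",
    "destandardize",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
]

#: Conventional ImageNet channel statistics (RGB order); grayscale input is
#: replicated across the three channels before standardization.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float64)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float64)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def normalize_pixels(pixels: np.ndarray) -> np.ndarray:
    """Affine min-max rescale onto [0, 255], rounded half-up to uint8.

    A constant image maps to all zeros (the rescale is undefined there and
    zero is the conventional background).
    """
    p = np.asarray(pixels, dtype=np.float64)
    if not np.all(np.isfinite(p)):
        raise ValueError("pixels must be finite")
    lo, hi = p.min(), p.max()
    if hi == lo:
        return np.zeros(p.shape, dtype=np.uint8)
    scaled = (p - lo) * (255.0 / (hi - lo))
    return _round_half_up(scaled).astype(np.uint8)


def detect_and_invert(
    pixels: np.ndarray, margin: float = 20.0, border_fraction: float = 0.1
) -> tuple[np.ndarray, bool]:
    """Flip photometric polarity when the border is brighter than the center.

    Radiograph background is air, which images dark in standard polarity; a
    bright border frame is the signature of an inverted image. The rule
    compares the mean of a ``border_fraction``-wide frame against the mean of
    the central half-size region and flips (255 - p) when the border exceeds
    the center by more than ``margin`` intensity levels. Idempotent: a
    flipped image has a dark border and is never flipped again.
    """
    p = np.asarray(pixels, dtype=np.float64)
    h, w = p.shape
    bh = max(1, int(round(h * border_fraction)))
    bw = max(1, int(round(w * border_fraction)))
    frame = np.ones((h, w), dtype=bool)
    frame[bh : h - bh, bw : w - bw] = False
    ch0, ch1 = h // 4, h - h // 4
    cw0, cw1 = w // 4, w - w // 4
    center = p[ch0:ch1, cw0:cw1]
    inverted = bool(p[frame].mean() - center.mean() > margin)
    out = (255.0 - p) if inverted else p
    return out.astype(pixels.dtype if np.issubdtype(pixels.dtype, np.integer) else np.uint8), inverted


def apply_clahe(
    pixels: np.ndarray,
    clip_limit: float = 2.0,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit image.

    ``clip_limit`` follows the common convention where the per-bin clip count
    is ``clip_limit * tile_pixels / nbins`` (so 2.0 is a gentle default); it
    is converted to the normalized clip fraction of the underlying
    implementation. ``tile_grid`` is (rows, cols) of contextual tiles.
    """
    p = np.asarray(pixels)
    h, w = p.shape
    tr, tc = tile_grid
    if tr > h or tc > w or tr < 1 or tc < 1:
        raise ValueError(f"tile grid {tile_grid} invalid for image {p.shape}")
    if p.min() == p.max():  # constant image: equalization is a no-op
        return p.astype(np.uint8)
    kernel = (max(1, h // tr), max(1, w // tc))
    clip_norm = float(np.clip(clip_limit / 256.0, 1e-4, 1.0))
    out = exposure.equalize_adapthist(
        p.astype(np.uint8), kernel_size=kernel, clip_limit=clip_norm, nbins=256
    )
    return _round_half_up(out * 255.0).astype(np.uint8)


def build_scale_pyramid(
    record: ImageRecord | np.ndarray, resolutions: list[int]
) -> ScalePyramid:
    """Resample a square image to each resolution, anti-aliased on downsampling."""
    if isinstance(record, ImageRecord):
        pixels, image_id = record.pixels, record.image_id
    else:
        pixels, image_id = np.asarray(record), ""
    if not resolutions or list(resolutions) != sorted(set(resolutions)):
        raise ValueError("resolutions must be a nonempty strictly increasing list")
    if pixels.shape[0] != pixels.shape[1]:
        raise ValueError("pyramid construction expects a square source image")
    levels: dict[int, np.ndarray] = {}
    for r in resolutions:
        if r == pixels.shape[0]:
            levels[r] = pixels.astype(np.uint8)
            continue
        out = transform.resize(
            pixels.astype(np.float64),
            (r, r),
            order=1,
            anti_aliasing=r < pixels.shape[0],
            preserve_range=True,
        )
        levels[r] = np.clip(_round_half_up(out), 0, 255).astype(np.uint8)
    return ScalePyramid(image_id=image_id, levels=levels)


def augment(
    pixels: np.ndarray, seed: int, max_angle: float = 15.0
) -> np.ndarray:
    """Random horizontal flip (p=0.5) and uniform rotation in [-15, +15] degrees.

    Deterministic under ``seed``; rotation uses reflection padding and keeps
    the image size.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(pixels, dtype=np.float64)
    if rng.random() < 0.5:
        p = p[:, ::-1]
    angle = rng.uniform(-max_angle, max_angle)
    out = transform.rotate(p, angle, resize=False, mode="reflect", preserve_range=True)
    return np.clip(_round_half_up(out), 0, 255).astype(np.uint8)


def standardize(pixels01: np.ndarray) -> np.ndarray:
    """ImageNet channel standardization of a [0, 1] grayscale image.

    The single channel is replicated to 3 and each channel is transformed as
    (p - mean) / std. Returns a float64 array of shape (3, H, W).
    """
    p = np.asarray(pixels01, dtype=np.float64)
    stacked = np.repeat(p[None, :, :], 3, axis=0)
    return (stacked - IMAGENET_MEAN[:, None, None]) / IMAGENET_STD[:, None, None]


def destandardize(channels: np.ndarray) -> np.ndarray:
    """Inverse of :func:`standardize`; returns the mean over channels in [0, 1]."""
    c = np.asarray(channels, dtype=np.float64)
    back = c * IMAGENET_STD[:, None, None] + IMAGENET_MEAN[:, None, None]
    return back.mean(axis=0)
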