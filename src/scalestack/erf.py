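"""Effective receptive field (ERF) estimation by averaged squared input
gradients.

The theoretical receptive field of a unit is the input region geometrically
connected to it; the *effective* receptive field — the region whose pixels
materially influence the unit — is usually much smaller. It is estimated by
running a trained model in evaluation mode, backpropagating one gradient per
image from the center pixel of the final convolutional layer, squaring the
gradients (positive and negative contributions would otherwise cancel), and
averaging over images and channels, i.e. an uncentered sample variance of
the input sensitivity. Optionally large random translations of the inputs
are added so the estimate is not tied to one image alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .nn import Conv2D, Sequential

__all__ = ["ERFMap", "erf_map", "erf_summary", "theoretical_receptive_field",
           "save_erf_map"]


@dataclass
class ERFMap:
    """Nonnegative sensitivity map, same size as the input image."""

    values: np.ndarray
    model_tag: str
    n_images: int
    n_channels: int
    squared: bool = True

    def __post_init__(self) -> None:
        if self.squared and (self.values < 0).any():
            raise ValueError("squared ERF map must be nonnegative")


def theoretical_receptive_field(
    model: Sequential, out_pos: tuple[int, int], input_shape: tuple[int, int]
) -> tuple[int, int, int, int]:
    """Input-coordinate box (r0, r1, c0, c1), inclusive, geometrically
    connected to ``out_pos`` of the final convolutional layer."""
    convs = [l for l in model.layers if isinstance(l, Conv2D)]
    r0 = r1 = out_pos[0]
    c0 = c1 = out_pos[1]
    for conv in reversed(convs):
        k, s, p = conv.kernel, conv.stride, conv.pad
        r0 = r0 * s - p
        c0 = c0 * s - p
        r1 = r1 * s - p + k - 1
        c1 = c1 * s - p + k - 1
    h, w = input_shape
    return max(r0, 0), min(r1, h - 1), max(c0, 0), min(c1, w - 1)


def _translate(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift with reflection padding, preserving shape."""
    h, w = img.shape[-2:]
    pad_y, pad_x = abs(dy), abs(dx)
    pads = [(0, 0)] * (img.ndim - 2) + [(pad_y, pad_y), (pad_x, pad_x)]
    padded = np.pad(img, pads, mode="reflect")
    return padded[..., pad_y + dy : pad_y + dy + h, pad_x + dx : pad_x + dx + w]


def erf_map(
    model: Sequential,
    images: np.ndarray,
    translate: bool = False,
    seed: int = 0,
    squared: bool = True,
    model_tag: str = "model",
) -> ERFMap:
    """Estimate the ERF of the final conv layer's center unit.

    ``images`` is (N, C, H, W), conditioned as in training. For each image
    and each final-layer channel the input gradient of the center activation
    is computed, squared elementwise (unless ``squared=False``, which
    averages the signed gradients for comparison), summed over input
    channels, and averaged over images x channels. With ``translate`` each
    image is first shifted by uniform integer offsets up to +-25% of the
    side, with reflection padding.
    """
    x = np.asarray(images, dtype=np.float32)
    if x.ndim != 4:
        raise ValueError("images must be (N, C, H, W)")
    last = model.last_conv_index()
    n_channels = model.layers[last].out_ch
    h, w = x.shape[2], x.shape[3]
    if translate:
        rng = np.random.default_rng(seed)
        m_y, m_x = h // 4, w // 4
        x = np.stack(
            [_translate(im, int(rng.integers(-m_y, m_y + 1)),
                        int(rng.integers(-m_x, m_x + 1))) for im in x]
        )
    acc = np.zeros((h, w), dtype=np.float64)
    for c in range(n_channels):
        g = model.activation_input_gradient(x, last, c)  # (N, C, H, W)
        g = np.asarray(g, dtype=np.float64)
        if squared:
            acc += (g**2).sum(axis=1).sum(axis=0)
        else:
            acc += g.sum(axis=1).sum(axis=0)
    acc /= x.shape[0] * n_channels
    return ERFMap(acc, model_tag, x.shape[0], n_channels, squared=squared)


def erf_summary(erf: ERFMap, level: float = 0.5) -> dict:
    """Effective area/radius at a fraction-of-peak level.

    Area counts pixels whose value is >= ``level`` x peak; the effective
    radius is that of the equal-area disk. Reported in pixels and as a
    fraction of the image side.
    """
    v = np.abs(erf.values) if not erf.squared else erf.values
    peak = float(v.max())
    if peak == 0.0:
        raise ValueError("all-zero ERF map has no summary")
    area = int((v >= level * peak).sum())
    radius = float(np.sqrt(area / np.pi))
    side = erf.values.shape[0]
    return {
        "level": level,
        "area_px": area,
        "radius_px": radius,
        "radius_fraction": radius / side,
        "area_fraction": area / (side * erf.values.shape[1]),
        "peak": peak,
    }


def save_erf_map(erf: ERFMap, out_dir: str | Path, name: str = "erf") -> Path:
    """Write the peak-normalized map as 16-bit PNG plus the raw values as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    v = erf.values
    peak = v.max() if v.max() > 0 else 1.0
    png = (np.clip(v / peak, 0, 1) * 65535).astype(np.uint16)
    Image.fromarray(png).save(out / f"{name}.png")
    pd.DataFrame(v).to_csv(out / f"{name}.csv", index=False, header=False)
    return out
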