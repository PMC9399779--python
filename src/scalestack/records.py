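"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageRecord:
    """One 8-bit grayscale image with an identifier and a binary label vector.

    ``pixels`` is a 2-D uint8 array (row-major, origin top-left, 0-based
    indices). ``labels`` holds one 0/1 entry per configured finding; it may be
    empty for images that exist only as pixel data (e.g. denoising inputs).
    """

    image_id: str
    pixels: np.ndarray
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        self.labels = np.asarray(self.labels, dtype=np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ScalePyramid:
    """The same image resampled at an ordered list of square resolutions.

    ``levels`` maps resolution (pixels per side) to the resampled uint8 image;
    iteration order is strictly increasing resolution.
    """

    image_id: str
    levels: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        res = list(self.levels)
        if res != sorted(res) or len(set(res)) != len(res):
            raise ValueError("pyramid resolutions must be strictly increasing")
        for r, img in self.levels.items():
            if img.shape != (r, r):
                raise ValueError(f"level {r} is not {r}x{r}")

    @property
    def resolutions(self) -> list[int]:
        return list(self.levels)
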