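"""RGBA image container plus PNG round-trip via Pillow."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

__all__ = ["Image", "write_png", "read_png"]


@dataclass
class Image:
    """8-bit RGBA raster; ``pixels`` has shape (height, width, 4)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 4:
            raise ValueError(f"expected (H, W, 4) RGBA array, got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image dimensions must be >= 1")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @classmethod
    def filled(cls, width: int, height: int, rgba: tuple[int, int, int, int]) -> "Image":
        px = np.empty((height, width, 4), dtype=np.uint8)
        px[:] = rgba
        return cls(px)


def write_png(image: Image, path: str | Path) -> None:
    """Write a standard RGBA PNG, preserving the alpha channel."""
    PILImage.fromarray(image.pixels, mode="RGBA").save(str(path), format="PNG")


def read_png(path: str | Path) -> Image:
    with PILImage.open(str(path)) as im:
        return Image(np.asarray(im.convert("RGBA")))
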