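"""Calibrated raster containers shared across the pipeline.

Pixel convention: arrays are indexed (row, col), 0-based, pixel centers
at integer coordinates; physical position in mm is ``px * spacing``.
Pixel spacing is stored per axis as (row_mm, col_mm) so anisotropic
resizes keep physical lengths exact; a scalar spacing is accepted and
broadcast to both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def as_spacing(spacing) -> tuple[float, float]:
    """Normalize a scalar or (row, col) pair of mm/px spacings."""
    if np.isscalar(spacing):
        s = float(spacing)
        pair = (s, s)
    else:
        pair = (float(spacing[0]), float(spacing[1]))
    if pair[0] <= 0 or pair[1] <= 0:
        raise ValueError(f"pixel spacing must be positive, got {pair}")
    return pair


@dataclass
class UltrasoundImage:
    """A 2-D grayscale ultrasound-like raster with physical calibration."""

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    image_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("image contains negative values")
        self.pixel_spacing_mm = as_spacing(self.pixel_spacing_mm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CanalMask:
    """Binary segmentation raster aligned to an :class:`UltrasoundImage`."""

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    image_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.pixels.shape}")
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {vals[:10]}")
        self.pixels = self.pixels.astype(np.uint8)
        self.pixel_spacing_mm = as_spacing(self.pixel_spacing_mm)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
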