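"""Shared containers for slides, masks and class labels.

Class conventions used throughout the package:

* pixel label 0 = background / normal tissue, 1 = Bowen's disease (BD),
  2 = seborrheic keratosis (SK);
* section-level classes are the strings ``"Normal"``, ``"BD"``, ``"SK"``
  and ``"SK_with_BD_focus"`` (an SK section carrying a small BD-like
  focus, emulating irritated SK / collision tumors).

Physical scale is carried as microns per pixel (``mpp``); at the 10x
magnification emulated here 1 um = 1 px, i.e. ``mpp = 1.0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABEL_BACKGROUND = 0
LABEL_BD = 1
LABEL_SK = 2

CLASS_NORMAL = "Normal"
CLASS_BD = "BD"
CLASS_SK = "SK"
CLASS_SK_WITH_BD_FOCUS = "SK_with_BD_focus"
SECTION_CLASSES = (CLASS_NORMAL, CLASS_BD, CLASS_SK, CLASS_SK_WITH_BD_FOCUS)


@dataclass
class SlideImage:
    """RGB raster (H, W, 3) uint8 plus its physical scale in um/px."""

    pixels: np.ndarray
    mpp: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("SlideImage expects an (H, W, 3) RGB array")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LabelMask:
    """Integer class mask aligned with a slide (0/1/2)."""

    labels: np.ndarray
    mpp: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("LabelMask expects a 2-D integer array")

    def class_area_mm2(self, label: int) -> float:
        """Area of one class in mm^2 (pixel count x mpp^2 / 1e6)."""
        n = int(np.count_nonzero(self.labels == label))
        return n * self.mpp * self.mpp / 1e6


def pixels_to_mm2(n_pixels: int | float, mpp: float) -> float:
    """Convert a pixel count at scale ``mpp`` um/px into mm^2."""
    return float(n_pixels) * mpp * mpp / 1e6


def mm2_to_pixels(area_mm2: float, mpp: float) -> float:
    """Convert an area in mm^2 into an (unrounded) pixel count at ``mpp``."""
    return area_mm2 * 1e6 / (mpp * mpp)


@dataclass
class SectionTruth:
    """Ground truth for one generated tissue section."""

    section_id: int
    class_label: str
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), 0-based half-open
    footprint: np.ndarray = field(repr=False)  # bool, cropped to bbox
    area_bd_mm2: float = 0.0
    area_sk_mm2: float = 0.0

    @property
    def footprint_area_px(self) -> int:
        return int(np.count_nonzero(self.footprint))
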