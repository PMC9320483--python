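"""Tissue/background separation, section extraction, and tile planning.

Tiles are planned in physical units: by default 1024 um x 1024 um with at
least 300 um overlap between adjacent tiles on each axis, converted to
pixels through the slide's microns-per-pixel value (1 um = 1 px at the
emulated 10x magnification).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color as skcolor
from skimage import filters, morphology

from .core import SlideImage, mm2_to_pixels, pixels_to_mm2

__all__ = [
    "TissueMask",
    "Section",
    "TilingConfig",
    "TileCoord",
    "TissueDetectionConfig",
    "detect_tissue",
    "extract_sections",
    "plan_tiles",
    "read_tile",
    "tile_plan_to_frame",
]


@dataclass
class TissueMask:
    mask: np.ndarray  # bool, same H x W as the slide
    mpp: float = 1.0


@dataclass
class Section:
    """One connected tissue piece — the unit of diagnosis."""

    section_id: int
    mask: np.ndarray = field(repr=False)  # bool, full-slide frame
    bbox: tuple[int, int, int, int]       # (r0, c0, r1, c1), half-open
    area_mm2: float = 0.0
    mpp: float = 1.0


@dataclass(frozen=True)
class TissueDetectionConfig:
    """Knobs of the classic-filter tissue detector.

    ``morph_disc_um`` drives an opening-then-closing disc; holes smaller
    than ``fill_holes_mm2`` are filled.
    """

    saturation_weight: float = 1.0
    morph_disc_um: float = 16.0  # disc diameter for opening/closing
    fill_holes_mm2: float = 0.01
    min_dynamic_range: float = 0.02  # below this the slide is called blank


@dataclass(frozen=True)
class TilingConfig:
    tile_size_um: float = 1024.0
    min_overlap_um: float = 300.0
    mpp: float = 1.0

    def __post_init__(self) -> None:
        if not self.tile_size_um > self.min_overlap_um >= 0:
            raise ValueError("need tile_size_um > min_overlap_um >= 0")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")

    @property
    def tile_px(self) -> int:
        return int(round(self.tile_size_um / self.mpp))

    @property
    def overlap_px(self) -> int:
        return int(np.ceil(self.min_overlap_um / self.mpp))


@dataclass(frozen=True)
class TileCoord:
    x0: int  # column of the top-left corner, 0-based
    y0: int  # row
    side_px: int
    section_id: int


def detect_tissue(image: SlideImage,
                  config: TissueDetectionConfig = TissueDetectionConfig()) -> TissueMask:
    """Binary tissue mask via darkness+saturation score, Otsu threshold,
    opening-then-closing with a disc, and small-hole filling.

    A slide whose score channel is nearly constant (blank glass) yields an
    empty mask rather than an Otsu artifact.
    """
    rgb = image.pixels.astype(np.float64) / 255.0
    gray = skcolor.rgb2gray(rgb)
    sat = skcolor.rgb2hsv(rgb)[..., 1]
    score = (1.0 - gray) + config.saturation_weight * sat
    if score.max() - score.min() < config.min_dynamic_range:
        return TissueMask(np.zeros(image.shape, dtype=bool), mpp=image.mpp)
    t = filters.threshold_otsu(score)
    mask = score > t
    r = max(1, int(round(config.morph_disc_um / image.mpp / 2)))
    disc = morphology.disk(r)
    mask = morphology.closing(morphology.opening(mask, disc), disc)
    max_hole = int(mm2_to_pixels(config.fill_holes_mm2, image.mpp))
    mask = morphology.remove_small_holes(mask, max_size=max_hole)
    return TissueMask(mask, mpp=image.mpp)


def extract_sections(mask: TissueMask, min_section_area_mm2: float = 0.2) -> list[Section]:
    """8-connected components above the area floor, largest first."""
    lab, _ = ndimage.label(mask.mask, structure=np.ones((3, 3), dtype=int))
    out: list[Section] = []
    slices = ndimage.find_objects(lab)
    for i, sl in enumerate(slices, start=1):
        comp = lab[sl] == i
        area = pixels_to_mm2(int(comp.sum()), mask.mpp)
        if area <= min_section_area_mm2:
            continue
        full = np.zeros_like(mask.mask)
        full[sl] = comp
        bbox = (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)
        out.append(Section(section_id=0, mask=full, bbox=bbox,
                           area_mm2=area, mpp=mask.mpp))
    out.sort(key=lambda s: -s.area_mm2)
    for i, s in enumerate(out):
        s.section_id = i
    return out


def _axis_positions(start: int, extent: int, tile: int, overlap: int,
                    limit: int) -> list[int]:
    """Minimal count of tile origins covering [start, start+extent) with
    pairwise overlap >= ``overlap`` px, clamped into [0, limit - tile]."""
    if extent <= tile:
        n = 1
    else:
        n = int(np.ceil((extent - overlap) / (tile - overlap)))
    if n == 1:
        pos = [start + (extent - tile) // 2]
    else:
        q = (extent - tile) / (n - 1)
        pos = [start + int(np.floor(i * q)) for i in range(n)]
    lo, hi = 0, max(limit - tile, 0)
    return [min(max(p, lo), hi) for p in pos]


def plan_tiles(section: Section, cfg: TilingConfig) -> list[TileCoord]:
    """Plan the minimal overlapping tile grid covering a section.

    Tiles are laid from the section bounding box with a uniform (rounded)
    stride, clamped inside the slide; tiles that do not intersect the
    tissue mask are dropped.  A slide smaller than one tile yields a
    single (to-be-padded) tile.
    """
    r0, c0, r1, c1 = section.bbox
    if r1 <= r0 or c1 <= c0:
        raise ValueError("empty section bounding box")
    t, o = cfg.tile_px, cfg.overlap_px
    h, w = section.mask.shape
    xs = _axis_positions(c0, c1 - c0, t, o, w)
    ys = _axis_positions(r0, r1 - r0, t, o, h)
    tiles = []
    for y in ys:
        for x in xs:
            window = section.mask[max(y, 0):y + t, max(x, 0):x + t]
            if window.any():
                tiles.append(TileCoord(x0=x, y0=y, side_px=t,
                                       section_id=section.section_id))
    return tiles


def read_tile(image: np.ndarray, coord: TileCoord) -> np.ndarray:
    """Extract a tile, reflect-padding any part outside the raster."""
    t = coord.side_px
    h, w = image.shape[:2]
    y0, x0 = coord.y0, coord.x0
    ys0, xs0 = max(y0, 0), max(x0, 0)
    ys1, xs1 = min(y0 + t, h), min(x0 + t, w)
    patch = image[ys0:ys1, xs0:xs1]
    pad = ((ys0 - y0, (y0 + t) - ys1), (xs0 - x0, (x0 + t) - xs1))
    if image.ndim == 3:
        pad = pad + ((0, 0),)
    if any(p > 0 for pair in pad for p in pair):
        patch = np.pad(patch, pad, mode="reflect")
    return patch


def tile_plan_to_frame(slide_path: str, tiles: list[TileCoord]) -> pd.DataFrame:
    """Exportable tile plan (CSV layout: slide, section, x0, y0, side)."""
    return pd.DataFrame(
        [{"slide_path": slide_path, "section_id": t.section_id,
          "x0": t.x0, "y0": t.y0, "side_px": t.side_px} for t in tiles])
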