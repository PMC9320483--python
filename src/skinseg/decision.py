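"""Section-level diagnosis from stitched probability heat maps.

Tile heat maps are averaged into a section heat map (1/8 input
resolution), smoothed with grayscale morphology, thresholded per class
and converted to areas in mm^2.  The diagnostic call then follows the
decision cascade — BD if its area reaches delta1, else SK if its area
reaches delta2, else Normal — optionally tightened by the relative-area
rule: BD additionally requires

    r = 100 * area(BD) / (area(BD) + area(SK)) >= 20,

which re-labels sections whose BD component is a small fraction of the
lesion (the irritated-SK pattern) as SK.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology

from .core import pixels_to_mm2
from .model import TileHeatMap
from .tissue import Section

__all__ = [
    "SectionHeatMap",
    "DecisionParams",
    "SectionCall",
    "stitch_heatmaps",
    "postprocess",
    "binarize_and_area",
    "relative_area",
    "classify_section",
    "call_section",
]

CALL_BD = "BD"
CALL_SK = "SK"
CALL_NORMAL = "Normal"

_STRIDE = 8


@dataclass
class SectionHeatMap:
    """Two-channel probability raster over a section bbox at 1/8 scale."""

    probs: np.ndarray  # (2, h, w) float32 in [0, 1]; 0 = BD, 1 = SK
    section_id: int
    bbox: tuple[int, int, int, int]  # slide-frame bbox (full resolution)
    mpp_out: float                   # um per output pixel (= 8 x slide mpp)


@dataclass(frozen=True)
class DecisionParams:
    """Operating point of the section classifier (defaults per the
    calibrated clinical operating point: thresholds 0.5/0.6, minimum
    areas delta1 = 0.0256 mm^2, delta2 = 0.0333 mm^2, r cutoff 20%)."""

    threshold_bd: float = 0.5
    threshold_sk: float = 0.6
    min_area_bd_mm2: float = 0.0256
    min_area_sk_mm2: float = 0.0333
    relative_area_cutoff: float = 20.0
    mode: str = "cascade"  # "cascade" or "relative_area"

    def __post_init__(self) -> None:
        for t in (self.threshold_bd, self.threshold_sk):
            if not 0.0 <= t <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")
        if self.min_area_bd_mm2 < 0 or self.min_area_sk_mm2 < 0:
            raise ValueError("minimum areas must be >= 0")
        if not 0.0 <= self.relative_area_cutoff <= 100.0:
            raise ValueError("relative-area cutoff must lie in [0, 100]")
        if self.mode not in ("cascade", "relative_area"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SectionCall:
    section_id: int
    area_bd_mm2: float
    area_sk_mm2: float
    r_percent: float
    label: str


def stitch_heatmaps(tile_maps: list[TileHeatMap], section: Section,
                    combine: str = "mean") -> SectionHeatMap:
    """Combine overlapping tile heat maps over the section bbox.

    Each output pixel is the mean (or max) of every tile prediction that
    covers it; pixels outside the tissue mask are zeroed.  Tissue output
    pixels covered by no tile raise ``ValueError``.
    """
    if combine not in ("mean", "max"):
        raise ValueError("combine must be 'mean' or 'max'")
    r0, c0, r1, c1 = section.bbox
    hi, wi = r1 - r0, c1 - c0
    # accumulate at input resolution (tile origins are arbitrary pixels,
    # so only the input grid aligns tiles exactly), then block-reduce x8
    acc = np.zeros((2, hi, wi), dtype=np.float32)
    cnt = np.zeros((hi, wi), dtype=np.int32)
    for tm in tile_maps:
        side_in = tm.probs.shape[1] * _STRIDE
        up = np.repeat(np.repeat(tm.probs, _STRIDE, axis=1), _STRIDE, axis=2)
        ys, xs = tm.coord.y0 - r0, tm.coord.x0 - c0
        ye, xe = ys + side_in, xs + side_in
        cys, cxs = max(ys, 0), max(xs, 0)
        cye, cxe = min(ye, hi), min(xe, wi)
        if cye <= cys or cxe <= cxs:
            continue
        sub = up[:, cys - ys:cye - ys, cxs - xs:cxe - xs]
        if combine == "mean":
            acc[:, cys:cye, cxs:cxe] += sub
        else:
            acc[:, cys:cye, cxs:cxe] = np.maximum(acc[:, cys:cye, cxs:cxe], sub)
        cnt[cys:cye, cxs:cxe] += 1

    tissue = section.mask[r0:r1, c0:c1]
    if np.any(tissue & (cnt == 0)):
        raise ValueError("tissue pixels left uncovered by the tile plan")
    if combine == "mean":
        full = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    else:
        full = acc
    full[:, ~tissue] = 0.0

    h = -(-hi // _STRIDE)
    w = -(-wi // _STRIDE)
    pad_h, pad_w = h * _STRIDE - hi, w * _STRIDE - wi
    full = np.pad(full, ((0, 0), (0, pad_h), (0, pad_w)))
    covered = np.pad(tissue & (cnt > 0), ((0, pad_h), (0, pad_w)))
    blocks = full.reshape(2, h, _STRIDE, w, _STRIDE)
    nblk = covered.reshape(h, _STRIDE, w, _STRIDE).sum(axis=(1, 3))
    out = np.divide(blocks.sum(axis=(2, 4)), nblk,
                    out=np.zeros((2, h, w), dtype=np.float32),
                    where=nblk > 0)
    return SectionHeatMap(probs=out.astype(np.float32),
                          section_id=section.section_id, bbox=section.bbox,
                          mpp_out=_STRIDE * section.mpp)


def postprocess(hmap: SectionHeatMap, disc_radius: int = 2) -> SectionHeatMap:
    """Grayscale morphological opening then closing per channel.

    Removes isolated speckles smaller than the disc and fills matching
    dips; the open-close filter is idempotent, so applying it twice
    equals applying it once.  Values stay within [0, 1].
    """
    disc = morphology.disk(disc_radius)
    out = np.empty_like(hmap.probs)
    for c in range(hmap.probs.shape[0]):
        o = morphology.opening(hmap.probs[c], disc)
        out[c] = morphology.closing(o, disc)
    return SectionHeatMap(probs=out, section_id=hmap.section_id,
                          bbox=hmap.bbox, mpp_out=hmap.mpp_out)


def binarize_and_area(channel: np.ndarray, threshold: float,
                      mpp_out: float) -> float:
    """Area (mm^2) of the pixels at or above the probability threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    n = int(np.count_nonzero(channel >= threshold))
    return pixels_to_mm2(n, mpp_out)


def relative_area(area_bd: float, area_sk: float) -> float:
    """Relative BD share r = 100 * BD / (BD + SK), as a percentage.

    Defined as 0 when no lesional area was found at all.
    """
    if area_bd < 0 or area_sk < 0:
        raise ValueError("areas must be non-negative")
    total = area_bd + area_sk
    if total == 0:
        return 0.0
    return 100.0 * area_bd / total


def classify_section(area_bd: float, area_sk: float,
                     params: DecisionParams,
                     section_id: int = 0) -> SectionCall:
    """Apply the decision cascade (optionally with the relative-area rule).

    cascade:        BD iff area_bd >= delta1; else SK iff area_sk >= delta2.
    relative_area:  BD additionally requires r >= cutoff; a BD-sized area
                    failing the r test is re-labelled SK when either area
                    criterion holds, the irritated-SK reading.
    """
    r = relative_area(area_bd, area_sk)
    bd_size_ok = area_bd >= params.min_area_bd_mm2
    sk_size_ok = area_sk >= params.min_area_sk_mm2
    if params.mode == "cascade":
        if bd_size_ok:
            label = CALL_BD
        elif sk_size_ok:
            label = CALL_SK
        else:
            label = CALL_NORMAL
    else:
        if bd_size_ok and r >= params.relative_area_cutoff:
            label = CALL_BD
        elif sk_size_ok or bd_size_ok:
            label = CALL_SK
        else:
            label = CALL_NORMAL
    return SectionCall(section_id=section_id, area_bd_mm2=area_bd,
                       area_sk_mm2=area_sk, r_percent=r, label=label)


def call_section(hmap: SectionHeatMap, params: DecisionParams,
                 disc_radius: int = 2) -> SectionCall:
    """Post-process a stitched section heat map, measure per-class areas
    at the per-class thresholds, and emit the final call."""
    pp = postprocess(hmap, disc_radius=disc_radius)
    area_bd = binarize_and_area(pp.probs[0], params.threshold_bd, pp.mpp_out)
    area_sk = binarize_and_area(pp.probs[1], params.threshold_sk, pp.mpp_out)
    return classify_section(area_bd, area_sk, params,
                            section_id=hmap.section_id)
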