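"""Seeded pseudo-histology slide generator with exact ground truth.

Slides emulate multi-section H&E scans at 10x (1 um = 1 px by default):
a near-white background carries connected "tissue" blobs of correlated
pink/purple texture.  Lesions are painted inside the tissue with
class-specific texture statistics — bright round keratin-like dots for
seborrheic keratosis (SK), darker elongated streaks for Bowen's disease
(BD) — whose contrast is scaled by a ``separability`` knob in (0, 1].
``SK_with_BD_focus`` sections additionally embed a small BD blob inside
the SK lesion, standing in for irritated SK and collision tumors.

Every quantity is derived from a single integer seed, so a fixed spec
reproduces bit-identical images, masks and truths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import color as skcolor

from .core import (
    CLASS_BD,
    CLASS_NORMAL,
    CLASS_SK,
    LABEL_BD,
    LABEL_SK,
    SECTION_CLASSES,
    LabelMask,
    SectionTruth,
    SlideImage,
    mm2_to_pixels,
    pixels_to_mm2,
)

__all__ = [
    "StyleParams",
    "SectionRequest",
    "SyntheticSlideSpec",
    "PlacementError",
    "generate_slide",
    "generate_cohort",
    "apply_style_shift",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "slide_path", "mask_path", "mpp", "section_id", "class",
    "true_bd_area_mm2", "true_sk_area_mm2", "split",
]

# Base palette (RGB, uint8 scale): light/dense H&E-like tissue tones.
_TISSUE_LIGHT = np.array([236.0, 205.0, 218.0])
_TISSUE_DENSE = np.array([196.0, 142.0, 178.0])
_LESION_TONE = np.array([172.0, 110.0, 158.0])
_SK_DOT_COLOR = np.array([250.0, 238.0, 196.0])
_BD_STREAK_COLOR = np.array([96.0, 48.0, 112.0])
_BACKGROUND_LEVEL = 246.0


class PlacementError(RuntimeError):
    """Raised when requested sections cannot be placed on the canvas."""


@dataclass(frozen=True)
class StyleParams:
    """Bounded photometric style shift emulating scanner/lab variation.

    The identity parameters (all defaults) leave pixels unchanged.
    """

    hue_shift: float = 0.0          # fraction of the hue circle, [-0.5, 0.5]
    saturation_shift: float = 0.0   # additive in HSV saturation, [-1, 1]
    brightness: float = 1.0         # multiplicative, [0, 2]
    contrast: float = 1.0           # multiplicative about mid-gray, [0, 2]
    background_tint: tuple[float, float, float] = (0.0, 0.0, 0.0)  # additive RGB
    noise_level: float = 0.0        # Gaussian sigma in 8-bit units, [0, 30]

    def __post_init__(self) -> None:
        if not (-0.5 <= self.hue_shift <= 0.5 and -1 <= self.saturation_shift <= 1):
            raise ValueError("hue/saturation shift out of bounds")
        if not (0 <= self.brightness <= 2 and 0 <= self.contrast <= 2):
            raise ValueError("brightness/contrast out of bounds")
        if self.noise_level < 0 or self.noise_level > 30:
            raise ValueError("noise_level out of bounds")

    @property
    def is_identity(self) -> bool:
        return (self.hue_shift == 0 and self.saturation_shift == 0
                and self.brightness == 1 and self.contrast == 1
                and tuple(self.background_tint) == (0.0, 0.0, 0.0)
                and self.noise_level == 0)

    def inverted_hue(self) -> "StyleParams":
        return replace(self, hue_shift=-self.hue_shift)


@dataclass(frozen=True)
class SectionRequest:
    """One requested tissue section: class, lesion size, difficulty."""

    class_label: str
    lesion_area_mm2: float = 0.02
    separability: float = 1.0
    bd_focus_fraction: float = 0.05  # SK_with_BD_focus only

    def __post_init__(self) -> None:
        if self.class_label not in SECTION_CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}")
        if not (0.0 < self.separability <= 1.0):
            raise ValueError("separability must be in (0, 1]")
        if self.lesion_area_mm2 < 0:
            raise ValueError("lesion area must be >= 0")


@dataclass(frozen=True)
class SyntheticSlideSpec:
    canvas_size_px: tuple[int, int] = (512, 512)  # (width, height)
    mpp: float = 1.0
    section_specs: tuple[SectionRequest, ...] = ()
    style: StyleParams = field(default_factory=StyleParams)
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.canvas_size_px
        if w <= 0 or h <= 0 or self.mpp <= 0:
            raise ValueError("canvas size and mpp must be positive")

    @property
    def n_sections(self) -> int:
        return len(self.section_specs)


def _radial_blob(area_px: float, rng: np.random.Generator,
                 irregularity: float = 0.18) -> tuple[np.ndarray, float]:
    """Rasterize a smooth star-convex blob with the requested pixel area.

    Returns (bool mask cropped to its bbox, max radius in px).  The blob
    boundary is r(theta) = R * (1 + sum_k a_k cos(k theta + phi_k)); R is
    solved from the requested area via the exact polar-area integral, so
    discretisation is the only error source (well under 10%).
    """
    ks = np.arange(2, 6)
    amps = rng.uniform(0.0, irregularity, size=ks.size)
    phis = rng.uniform(0.0, 2 * np.pi, size=ks.size)
    theta = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    shape = 1.0 + np.sum(amps[:, None] * np.cos(ks[:, None] * theta + phis[:, None]), axis=0)
    # area = 0.5 * R^2 * integral(shape^2)
    unit_area = 0.5 * np.trapezoid(np.append(shape, shape[0]) ** 2,
                                   dx=2 * np.pi / theta.size)
    radius = float(np.sqrt(max(area_px, 1.0) / unit_area))
    rmax = radius * float(shape.max())
    half = int(np.ceil(rmax)) + 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    ang = np.arctan2(yy, xx) % (2 * np.pi)
    r_bound = np.interp(ang, np.append(theta, 2 * np.pi), np.append(shape, shape[0]))
    mask = np.hypot(yy, xx) <= radius * r_bound
    return mask, rmax


def _paste(dest: np.ndarray, mask: np.ndarray, center: tuple[int, int]) -> None:
    """OR a cropped bool mask into ``dest`` centred at (row, col)."""
    h, w = mask.shape
    r0 = center[0] - h // 2
    c0 = center[1] - w // 2
    dest[r0:r0 + h, c0:c0 + w] |= mask


def _correlated_field(shape: tuple[int, int], rng: np.random.Generator,
                      sigma: float) -> np.ndarray:
    """Low-pass filtered Gaussian noise rescaled to [0, 1]."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def generate_slide(spec: SyntheticSlideSpec) -> tuple[SlideImage, LabelMask, list[SectionTruth]]:
    """Render one slide: image, pixel labels and per-section ground truth.

    Sections are placed on a jittered grid; if a requested lesion cannot
    fit the canvas a :class:`PlacementError` is raised.  Deterministic for
    a fixed spec (seed included).
    """
    width, height = spec.canvas_size_px
    rng = np.random.default_rng(spec.seed)

    img = np.full((height, width, 3), _BACKGROUND_LEVEL, dtype=np.float64)
    img += rng.normal(0.0, 1.5, size=img.shape)
    labels = np.zeros((height, width), dtype=np.uint8)
    truths: list[SectionTruth] = []

    n = spec.n_sections
    if n > 0:
        # grid layout: ceil(sqrt(n)) cells per side, one section per cell
        cells = int(np.ceil(np.sqrt(n)))
        cell_h, cell_w = height // cells, width // cells
        order = [(i // cells, i % cells) for i in range(n)]
        for sid, (req, (gr, gc)) in enumerate(zip(spec.section_specs, order)):
            lesion_px = mm2_to_pixels(req.lesion_area_mm2, spec.mpp)
            foot_px = max(lesion_px * 2.0, 2500.0)
            foot_mask, rmax = _radial_blob(foot_px, rng)
            margin = int(np.ceil(rmax)) + 6
            if 2 * margin >= min(cell_h, cell_w):
                raise PlacementError(
                    f"section {sid}: footprint radius {rmax:.0f} px does not fit "
                    f"a {cell_w}x{cell_h} px cell")
            cy = gr * cell_h + int(rng.integers(margin, cell_h - margin))
            cx = gc * cell_w + int(rng.integers(margin, cell_w - margin))

            section_mask = np.zeros((height, width), dtype=bool)
            _paste(section_mask, foot_mask, (cy, cx))

            if req.class_label != CLASS_NORMAL and req.lesion_area_mm2 > 0:
                les_mask, les_rmax = _radial_blob(lesion_px, rng)
                # keep the lesion comfortably inside the footprint
                max_off = max(rmax - les_rmax - 4, 0.0)
                off = rng.uniform(-max_off / 2, max_off / 2, size=2)
                lc = (cy + int(off[0]), cx + int(off[1]))
                lesion_full = np.zeros((height, width), dtype=bool)
                _paste(lesion_full, les_mask, lc)
                section_mask |= ndimage.binary_dilation(lesion_full, iterations=4)
                if req.class_label == CLASS_BD:
                    labels[lesion_full] = LABEL_BD
                elif req.class_label == CLASS_SK:
                    labels[lesion_full] = LABEL_SK
                else:  # SK with a small BD focus inside the SK region
                    labels[lesion_full] = LABEL_SK
                    focus_px = lesion_px * req.bd_focus_fraction
                    f_mask, f_rmax = _radial_blob(focus_px, rng)
                    foff = max(les_rmax - f_rmax - 3, 0.0)
                    fo = rng.uniform(-foff / 2, foff / 2, size=2)
                    focus_full = np.zeros((height, width), dtype=bool)
                    _paste(focus_full, f_mask, (lc[0] + int(fo[0]), lc[1] + int(fo[1])))
                    focus_full &= lesion_full
                    labels[focus_full] = LABEL_BD

            rows = np.any(section_mask, axis=1).nonzero()[0]
            cols = np.any(section_mask, axis=0).nonzero()[0]
            bbox = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
            sec_labels = np.where(section_mask, labels, 0)
            truths.append(SectionTruth(
                section_id=sid,
                class_label=req.class_label,
                bbox=bbox,
                footprint=section_mask[bbox[0]:bbox[2], bbox[1]:bbox[3]].copy(),
                area_bd_mm2=pixels_to_mm2(np.count_nonzero(sec_labels == LABEL_BD), spec.mpp),
                area_sk_mm2=pixels_to_mm2(np.count_nonzero(sec_labels == LABEL_SK), spec.mpp),
            ))
            _render_section(img, section_mask, labels, rng,
                            separability=req.separability)

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    slide = SlideImage(pixels, mpp=spec.mpp)
    if not spec.style.is_identity:
        slide = apply_style_shift(slide, spec.style,
                                  seed=int(rng.integers(0, 2**31 - 1)))
    return slide, LabelMask(labels, mpp=spec.mpp), truths


def _render_section(img: np.ndarray, section_mask: np.ndarray,
                    labels: np.ndarray, rng: np.random.Generator,
                    separability: float) -> None:
    """Paint tissue texture and class-specific lesion features in place."""
    rows = np.any(section_mask, axis=1).nonzero()[0]
    cols = np.any(section_mask, axis=0).nonzero()[0]
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    m = section_mask[sl]
    sub = img[sl]
    lab = labels[sl]

    base = _correlated_field(m.shape, rng, sigma=4.0)[..., None]
    tissue = _TISSUE_LIGHT + (_TISSUE_DENSE - _TISSUE_LIGHT) * base
    tissue = tissue + rng.normal(0.0, 3.0, size=tissue.shape)
    sub[m] = tissue[m]

    lesion = (lab > 0) & m
    if not lesion.any():
        return
    # both lesion classes share a denser epithelial tone
    tone_w = 0.25 + 0.35 * separability
    sub[lesion] = (1 - tone_w) * sub[lesion] + tone_w * _LESION_TONE

    sk = lab == LABEL_SK
    if sk.any():
        # horn-pseudocyst-like bright dots, density fixed, contrast ~ separability
        dots = np.zeros(m.shape, dtype=bool)
        n_dots = max(1, int(np.count_nonzero(sk) / 900))
        idx = np.flatnonzero(sk)
        picks = rng.choice(idx, size=min(n_dots, idx.size), replace=False)
        yy, xx = np.unravel_index(picks, m.shape)
        radii = rng.uniform(2.0, 4.5, size=picks.size)
        gy, gx = np.mgrid[0:m.shape[0], 0:m.shape[1]]
        for y, x, r in zip(yy, xx, radii):
            y0, y1 = max(0, int(y - r - 1)), int(y + r + 2)
            x0, x1 = max(0, int(x - r - 1)), int(x + r + 2)
            patch = (gy[y0:y1, x0:x1] - y) ** 2 + (gx[y0:y1, x0:x1] - x) ** 2 <= r * r
            dots[y0:y1, x0:x1] |= patch
        dots &= sk
        w = 0.85 * separability
        sub[dots] = (1 - w) * sub[dots] + w * _SK_DOT_COLOR

    bd = lab == LABEL_BD
    if bd.any():
        # anisotropically smoothed noise -> elongated dark streaks
        ang = rng.uniform(0, np.pi)
        f = rng.standard_normal(m.shape)
        f = ndimage.gaussian_filter(ndimage.rotate(
            ndimage.gaussian_filter(ndimage.rotate(f, np.degrees(ang), reshape=False,
                                                   order=1, mode="reflect"),
                                    sigma=(0.8, 5.0)),
            -np.degrees(ang), reshape=False, order=1, mode="reflect"), 0.5)
        thr = np.quantile(f[bd], 0.72) if np.count_nonzero(bd) > 8 else np.inf
        streaks = (f > thr) & bd
        w = 0.85 * separability
        sub[streaks] = (1 - w) * sub[streaks] + w * _BD_STREAK_COLOR


def apply_style_shift(image: SlideImage, style: StyleParams,
                      seed: int = 0) -> SlideImage:
    """Photometric-only restyling; geometry and any label masks untouched.

    Identity parameters return a bit-identical copy (no HSV round trip is
    performed unless a hue/saturation shift is requested).
    """
    x = image.pixels.astype(np.float64)
    if style.hue_shift != 0 or style.saturation_shift != 0:
        hsv = skcolor.rgb2hsv(x / 255.0)
        hsv[..., 0] = (hsv[..., 0] + style.hue_shift) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] + style.saturation_shift, 0, 1)
        x = skcolor.hsv2rgb(hsv) * 255.0
    if style.brightness != 1.0:
        x = x * style.brightness
    if style.contrast != 1.0:
        x = (x - 127.5) * style.contrast + 127.5
    tint = np.asarray(style.background_tint, dtype=np.float64)
    if np.any(tint != 0):
        x = x + tint
    if style.noise_level > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, style.noise_level, size=x.shape)
    return SlideImage(np.clip(np.round(x), 0, 255).astype(np.uint8), mpp=image.mpp)


def _class_counts(n: int, class_mix: dict[str, float]) -> list[str]:
    """Largest-remainder apportionment of ``n`` slides over the mix."""
    items = [(c, p) for c, p in class_mix.items() if p > 0]
    total = sum(p for _, p in items)
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("class mix proportions must sum to 1")
    raw = [(c, n * p) for c, p in items]
    counts = {c: int(np.floor(v)) for c, v in raw}
    short = n - sum(counts.values())
    for c, _ in sorted(raw, key=lambda cv: cv[1] - np.floor(cv[1]), reverse=True)[:short]:
        counts[c] += 1
    out: list[str] = []
    for c, _ in items:
        out.extend([c] * counts[c])
    return out


def generate_cohort(n_slides: int, class_mix: dict[str, float],
                    style: StyleParams, seed: int, outdir: str | Path,
                    *, canvas_size_px: tuple[int, int] = (512, 512),
                    mpp: float = 1.0, sections_per_slide: int = 1,
                    lesion_area_range_mm2: tuple[float, float] = (0.015, 0.035),
                    separability: float = 1.0,
                    split_label: str = "train") -> pd.DataFrame:
    """Write a cohort of slides + masks + manifest CSV; return the manifest.

    Class counts follow ``class_mix`` up to rounding (largest remainder);
    every section of a slide shares the slide's class.  The manifest has
    one row per section with the true per-class areas in mm^2.
    """
    if n_slides < 0:
        raise ValueError("n_slides must be >= 0")
    for c in class_mix:
        if c not in SECTION_CLASSES:
            raise ValueError(f"unknown class {c!r} in mix")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    assignment = _class_counts(n_slides, class_mix)
    rng.shuffle(assignment)

    rows = []
    for i, cls in enumerate(assignment):
        reqs = tuple(
            SectionRequest(
                class_label=cls,
                lesion_area_mm2=float(rng.uniform(*lesion_area_range_mm2)),
                separability=separability,
            )
            for _ in range(sections_per_slide)
        )
        spec = SyntheticSlideSpec(
            canvas_size_px=canvas_size_px, mpp=mpp, section_specs=reqs,
            style=style, seed=int(rng.integers(0, 2**31 - 1)))
        slide, mask, truths = generate_slide(spec)
        slide_path = outdir / f"slide_{split_label}_{i:03d}.png"
        mask_path = outdir / f"mask_{split_label}_{i:03d}.png"
        Image.fromarray(slide.pixels).save(slide_path)
        Image.fromarray(mask.labels).save(mask_path)
        for t in truths:
            rows.append({
                "slide_path": str(slide_path), "mask_path": str(mask_path),
                "mpp": mpp, "section_id": t.section_id, "class": t.class_label,
                "true_bd_area_mm2": t.area_bd_mm2,
                "true_sk_area_mm2": t.area_sk_mm2, "split": split_label,
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(outdir / f"manifest_{split_label}.csv", index=False)
    return manifest
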