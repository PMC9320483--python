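"""End-to-end orchestration: cohort -> tiles -> model -> calls -> metrics.

This module glues the stages together behind plain functions so the CLI
stays thin: build a training tile set from a cohort manifest, train the
network, predict and stitch per-section heat maps, calibrate the two
operating-point hyper-parameters per call, emit section calls and the
evaluation table, and render probability-as-transparency overlays.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .calibration import (
    CalibrationResult,
    calibrate_call,
    evaluate_calls,
    section_score,
)
from .core import (
    CLASS_BD,
    CLASS_NORMAL,
    CLASS_SK,
    CLASS_SK_WITH_BD_FOCUS,
    LABEL_BD,
    LABEL_SK,
    LabelMask,
    SlideImage,
)
from .decision import DecisionParams, SectionHeatMap, postprocess, stitch_heatmaps
from .model import (
    ModelState,
    NetworkConfig,
    SegNet,
    TileDataset,
    TrainingConfig,
    predict_tiles,
)
from .tissue import (
    Section,
    TilingConfig,
    TissueDetectionConfig,
    detect_tissue,
    extract_sections,
    plan_tiles,
    read_tile,
)

__all__ = [
    "PipelineConfig",
    "load_manifest",
    "build_tile_dataset",
    "predict_slide",
    "predict_cohort",
    "calibrate_cohort",
    "evaluate_cohort",
    "render_overlay",
    "truth_label_for_section",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Single serializable config for a reproducible desk-scale run."""

    seed: int = 0
    # synthetic cohort
    n_train_slides: int = 30
    n_test_slides: int = 20
    class_mix: dict = field(default_factory=lambda: {CLASS_BD: 0.5, CLASS_SK: 0.5})
    separability: float = 0.9
    canvas_size_px: tuple[int, int] = (512, 512)
    mpp: float = 1.0
    # tiling / tissue
    tile_size_um: float = 256.0
    min_overlap_um: float = 75.0
    min_section_area_mm2: float = 0.005
    # model / training
    preset: str = "small"
    epochs: int = 8
    learning_rate: float = 1e-3
    batch_size: int = 8
    gamma: float = 2.0
    # decision
    decision: DecisionParams = field(default_factory=DecisionParams)

    def tiling(self) -> TilingConfig:
        return TilingConfig(tile_size_um=self.tile_size_um,
                            min_overlap_um=self.min_overlap_um, mpp=self.mpp)

    def network(self) -> NetworkConfig:
        return NetworkConfig(input_side=int(round(self.tile_size_um / self.mpp)),
                             preset=self.preset, seed=self.seed)

    def training(self) -> TrainingConfig:
        return TrainingConfig(gamma=self.gamma, learning_rate=self.learning_rate,
                              batch_size=self.batch_size, epochs=self.epochs,
                              seed=self.seed)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["canvas_size_px"] = list(self.canvas_size_px)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "canvas_size_px" in d:
            d["canvas_size_px"] = tuple(d["canvas_size_px"])
        if isinstance(d.get("decision"), dict):
            d["decision"] = DecisionParams(**d["decision"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def load_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _load_slide(row: pd.Series) -> tuple[SlideImage, LabelMask]:
    img = np.asarray(Image.open(row["slide_path"]).convert("RGB"))
    lab = np.asarray(Image.open(row["mask_path"]))
    mpp = float(row["mpp"])
    return SlideImage(img, mpp=mpp), LabelMask(lab, mpp=mpp)


def build_tile_dataset(manifest: pd.DataFrame, tiling: TilingConfig,
                       min_section_area_mm2: float = 0.005,
                       tissue_cfg: TissueDetectionConfig = TissueDetectionConfig(),
                       ) -> TileDataset:
    """Tile every slide of a manifest into a training dataset."""
    tiles, labels, slide_ids = [], [], []
    for slide_path, group in manifest.groupby("slide_path", sort=True):
        slide, mask = _load_slide(group.iloc[0])
        tmask = detect_tissue(slide, tissue_cfg)
        for sec in extract_sections(tmask, min_section_area_mm2):
            for coord in plan_tiles(sec, tiling):
                tiles.append(read_tile(slide.pixels, coord))
                labels.append(read_tile(mask.labels, coord))
                slide_ids.append(str(slide_path))
    if not tiles:
        raise ValueError("no tiles produced from manifest")
    return TileDataset(tiles=np.stack(tiles), labels=np.stack(labels),
                       slide_ids=np.asarray(slide_ids, dtype=object))


def predict_slide(net: SegNet, slide: SlideImage, tiling: TilingConfig,
                  min_section_area_mm2: float = 0.005,
                  tissue_cfg: TissueDetectionConfig = TissueDetectionConfig(),
                  batch: int = 8,
                  postprocess_maps: bool = True,
                  disc_radius: int = 2,
                  ) -> list[tuple[Section, SectionHeatMap]]:
    """Full inference on one slide: tissue, sections, tiles, stitch.

    Returned heat maps are post-processed (open-close) unless disabled.
    """
    tmask = detect_tissue(slide, tissue_cfg)
    out = []
    for sec in extract_sections(tmask, min_section_area_mm2):
        coords = plan_tiles(sec, tiling)
        stack = np.stack([read_tile(slide.pixels, c) for c in coords])
        tile_maps = predict_tiles(net, stack, coords, batch=batch)
        hmap = stitch_heatmaps(tile_maps, sec)
        if postprocess_maps:
            hmap = postprocess(hmap, disc_radius=disc_radius)
        out.append((sec, hmap))
    return out


def truth_label_for_section(section: Section, mask: LabelMask) -> str:
    """Section-level ground truth derived from the pixel label mask.

    BD-only lesions -> BD; SK-only -> SK; both (the generator's
    SK-with-BD-focus pattern) -> SK_with_BD_focus; none -> Normal.
    """
    labs = mask.labels[section.mask]
    has_bd = bool(np.any(labs == LABEL_BD))
    has_sk = bool(np.any(labs == LABEL_SK))
    if has_bd and has_sk:
        return CLASS_SK_WITH_BD_FOCUS
    if has_bd:
        return CLASS_BD
    if has_sk:
        return CLASS_SK
    return CLASS_NORMAL


def predict_cohort(net: SegNet, manifest: pd.DataFrame, tiling: TilingConfig,
                   min_section_area_mm2: float = 0.005,
                   ) -> pd.DataFrame:
    """Predict every slide; one row per detected section.

    Columns: slide_path, section_id, truth (from the mask), and the
    stitched post-processed heat map object (column ``heatmap``).
    """
    rows = []
    for slide_path, group in manifest.groupby("slide_path", sort=True):
        slide, mask = _load_slide(group.iloc[0])
        for sec, hmap in predict_slide(net, slide, tiling, min_section_area_mm2):
            rows.append({"slide_path": str(slide_path),
                         "section_id": sec.section_id,
                         "truth": truth_label_for_section(sec, mask),
                         "heatmap": hmap})
    return pd.DataFrame(rows)


def calibrate_cohort(pred: pd.DataFrame,
                     candidate_areas_mm2: np.ndarray | None = None,
                     threshold_grid: np.ndarray | None = None,
                     ) -> tuple[DecisionParams, list[CalibrationResult]]:
    """Run the two line searches on a predicted cohort.

    "BD vs. all" (channel 0, beta=2) sets threshold_bd/delta1 and
    "SK vs. Normal" (channel 1, beta=1) sets threshold_sk/delta2.
    """
    hmaps = list(pred["heatmap"])
    truth = list(pred["truth"])
    bd_truth = np.array([t == CLASS_BD for t in truth], dtype=bool)
    # SK call is calibrated against Normal sections when the cohort has
    # them (the clinical protocol); otherwise against everything non-SK.
    sk_subset = [i for i, t in enumerate(truth) if t != CLASS_BD]
    sk_truth = np.array([truth[i] in (CLASS_SK, CLASS_SK_WITH_BD_FOCUS)
                         for i in sk_subset], dtype=bool)
    sk_name = "SK vs Normal"
    if sk_truth.all() or not sk_truth.any():
        sk_subset = list(range(len(truth)))
        sk_truth = np.array([t in (CLASS_SK, CLASS_SK_WITH_BD_FOCUS)
                             for t in truth], dtype=bool)
        sk_name = "SK vs all"
    res_bd = calibrate_call(hmaps, bd_truth, channel=0, beta=2.0,
                            call_name="BD vs all",
                            candidate_areas_mm2=candidate_areas_mm2,
                            threshold_grid=threshold_grid)
    res_sk = calibrate_call([hmaps[i] for i in sk_subset], sk_truth,
                            channel=1, beta=1.0, call_name=sk_name,
                            candidate_areas_mm2=candidate_areas_mm2,
                            threshold_grid=threshold_grid)
    params = DecisionParams(threshold_bd=res_bd.threshold,
                            threshold_sk=res_sk.threshold,
                            min_area_bd_mm2=res_bd.min_area_mm2,
                            min_area_sk_mm2=res_sk.min_area_mm2)
    return params, [res_bd, res_sk]


def section_calls(pred: pd.DataFrame, params: DecisionParams) -> pd.DataFrame:
    """Apply the decision rule to every predicted section (maps are
    already post-processed, so areas are measured directly)."""
    from .decision import binarize_and_area, classify_section

    rows = []
    for _, r in pred.iterrows():
        h = r["heatmap"]
        area_bd = binarize_and_area(h.probs[0], params.threshold_bd, h.mpp_out)
        area_sk = binarize_and_area(h.probs[1], params.threshold_sk, h.mpp_out)
        call = classify_section(area_bd, area_sk, params, section_id=h.section_id)
        rows.append({"slide_path": r["slide_path"], "section_id": r["section_id"],
                     "truth": r["truth"], "area_bd_mm2": call.area_bd_mm2,
                     "area_sk_mm2": call.area_sk_mm2, "r_percent": call.r_percent,
                     "label": call.label, "mode": params.mode})
    return pd.DataFrame(rows)


def evaluate_cohort(pred: pd.DataFrame, params: DecisionParams,
                    call_specs: list[str] | None = None) -> pd.DataFrame:
    """Metrics table (AUC / sensitivity / specificity) per call spec."""
    calls = section_calls(pred, params)
    truth = list(calls["truth"])
    specs = call_specs or ["BD vs all", "BD vs SK", "SK vs Normal"]
    rows = []
    for spec in specs:
        if spec.startswith("BD"):
            positive = (calls["label"] == "BD").to_numpy()
            scores = np.array([section_score(h, params.min_area_bd_mm2, 0)
                               for h in pred["heatmap"]])
        else:
            positive = (calls["label"] == "SK").to_numpy()
            scores = np.array([section_score(h, params.min_area_sk_mm2, 1)
                               for h in pred["heatmap"]])
        rows.append(evaluate_calls(positive, truth, spec, scores=scores))
    return pd.DataFrame(rows)


_PALETTE = {0: (255, 255, 0), 1: (255, 165, 0)}  # BD yellow, SK orange


def render_overlay(image: SlideImage, heatmaps: list[SectionHeatMap],
                   palette: dict[int, tuple[int, int, int]] | None = None,
                   ) -> np.ndarray:
    """RGBA overlay at slide resolution: per-pixel alpha = probability.

    Heat maps are upsampled 8x nearest-neighbour (keeping the output
    stride's block structure visible); where both classes predict, the
    stronger one wins the pixel.  Zero probability is fully transparent.
    """
    palette = palette or _PALETTE
    h, w = image.shape
    out = np.zeros((h, w, 4), dtype=np.uint8)
    for hm in heatmaps:
        r0, c0, r1, c1 = hm.bbox
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise ValueError("heat map geometry exceeds the slide")
        up = np.repeat(np.repeat(hm.probs, 8, axis=1), 8, axis=2)
        up = up[:, :r1 - r0, :c1 - c0]
        winner = np.argmax(up, axis=0)
        alpha = np.max(up, axis=0)
        block = out[r0:r1, c0:c1]
        for ch, color in palette.items():
            sel = (winner == ch) & (alpha > 0)
            block[sel, 0] = color[0]
            block[sel, 1] = color[1]
            block[sel, 2] = color[2]
        block[..., 3] = np.maximum(block[..., 3],
                                   np.round(alpha * 255).astype(np.uint8))
    return out
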