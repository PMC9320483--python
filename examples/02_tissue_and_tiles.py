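"""Tissue detection and overlapping tile planning in physical units.

Detects tissue on a generated slide, extracts connected sections, and
plans 256 um tiles with >= 75 um overlap (the desk-scale analogue of
1024 um tiles with >= 300 um overlap), printing the resulting grid.
"""

from skinseg import (
    SectionRequest,
    SyntheticSlideSpec,
    TilingConfig,
    detect_tissue,
    extract_sections,
    generate_slide,
    plan_tiles,
)

slide, _, truths = generate_slide(SyntheticSlideSpec(
    section_specs=(SectionRequest("BD", lesion_area_mm2=0.04),), seed=11))

tissue = detect_tissue(slide)
sections = extract_sections(tissue, min_section_area_mm2=0.005)
print(f"{len(sections)} tissue section(s); detected area "
      f"{sections[0].area_mm2:.4f} mm^2 vs generated "
      f"{truths[0].footprint_area_px / 1e6:.4f} mm^2")

cfg = TilingConfig(tile_size_um=256, min_overlap_um=75, mpp=slide.mpp)
tiles = plan_tiles(sections[0], cfg)
print(f"{len(tiles)} tiles of {cfg.tile_px} px:")
for t in tiles:
    print(f"  tile at (x={t.x0}, y={t.y0})")
# Every tissue pixel lies in at least one tile and adjacent tiles
# overlap by at least 75 um on each axis.
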