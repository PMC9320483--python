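"""Generate a synthetic multi-section slide and inspect its ground truth.

Builds one pseudo-histology slide carrying a Bowen's-disease (BD) section
and an SK section with a small BD-like focus (the irritated-SK
confounder), then prints the per-section true lesion areas in mm^2.
"""

from skinseg import SectionRequest, SyntheticSlideSpec, generate_slide

spec = SyntheticSlideSpec(
    canvas_size_px=(768, 768),
    mpp=1.0,  # 10x magnification convention: 1 um = 1 px
    section_specs=(
        SectionRequest("BD", lesion_area_mm2=0.0256),
        SectionRequest("SK_with_BD_focus", lesion_area_mm2=0.03),
    ),
    seed=7,
)
slide, mask, truths = generate_slide(spec)

print(f"slide {slide.shape[1]}x{slide.shape[0]} px at {slide.mpp} um/px")
for t in truths:
    print(f"section {t.section_id}: class={t.class_label:18s} "
          f"BD={t.area_bd_mm2:.4f} mm^2  SK={t.area_sk_mm2:.4f} mm^2  "
          f"bbox={t.bbox}")
# The BD area of section 0 should sit within 10% of the requested
# 0.0256 mm^2 (the delta1 operating area); section 1 splits its lesion
# into a ~95% SK body and a ~5% BD focus.
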