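"""Render a probability-as-transparency overlay for one slide.

Predicts per-section heat maps with a quickly trained model and writes an
RGBA PNG in which BD probability is yellow, SK probability is orange, and
the alpha channel equals the predicted probability (0 = transparent).
"""

import tempfile
from pathlib import Path

import numpy as np
from PIL import Image

from skinseg import (
    NetworkConfig,
    StyleParams,
    TilingConfig,
    TrainingConfig,
    build_network,
    generate_cohort,
    train,
)
from skinseg.core import SlideImage
from skinseg.pipeline import build_tile_dataset, predict_slide, render_overlay

tiling = TilingConfig(tile_size_um=256, min_overlap_um=75)
with tempfile.TemporaryDirectory() as td:
    manifest = generate_cohort(10, {"BD": 0.5, "SK": 0.5}, StyleParams(),
                               seed=42, outdir=td, separability=1.0)
    dataset = build_tile_dataset(manifest, tiling, 0.005)
    net = build_network(NetworkConfig(input_side=256, preset="small", seed=0))
    state, _ = train(dataset, net, TrainingConfig(learning_rate=1e-3, epochs=8,
                                                  batch_size=8, seed=0))
    slide_path = manifest["slide_path"].iloc[0]
    slide = SlideImage(np.asarray(Image.open(slide_path).convert("RGB")))
    maps = [h for _, h in predict_slide(state.make_network(), slide, tiling, 0.005)]

rgba = render_overlay(slide, maps)
out = Path("overlay_example.png")
Image.fromarray(rgba, mode="RGBA").save(out)
opaque = (rgba[..., 3] > 128).mean()
print(f"wrote {out}: {rgba.shape[1]}x{rgba.shape[0]} RGBA, "
      f"{opaque:.1%} of pixels more than half opaque")
# Overlaid on the slide image, the opaque yellow/orange regions mark the
# model's confident BD/SK predictions at 8 px block resolution.
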