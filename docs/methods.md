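# Methods

This note documents the models, procedures and numerical choices behind
`skinseg`, and what the synthetic experiments can and cannot show.

## Problem setting

A slide carries one or more connected tissue sections; the diagnostic
unit is the section, whose call is one of {BD, SK, Normal}. Pixel labels
are 0 = background/normal tissue, 1 = BD, 2 = SK. All geometry is
carried in physical units through the microns-per-pixel value `mpp`; the
10× convention used throughout is 1 µm = 1 px, so areas in mm² are
`pixels · mpp² / 10⁶`.

## Tissue detection and tiling

Tissue is separated from the near-white glass background by a score
channel `(1 − gray) + saturation`, a global Otsu threshold, grayscale
opening-then-closing with a disc (default diameter 16 µm) and filling of
holes below 0.01 mm². A slide whose score channel is nearly constant
(dynamic range < 0.02) is treated as blank rather than Otsu-thresholded.
Sections are 8-connected components above `min_section_area_mm2`
(default 0.2 mm² at clinical scale; the desk-scale configs use
0.005 mm² to match the generator's small sections), ordered by
descending area.

Tiles of side `T` (default 1024 µm) are planned per section with minimum
pairwise overlap `O` (default 300 µm): along each bbox axis of extent
`E`, the tile count is the minimal `n = ceil((E−O)/(T−O))` and origins
are `floor(i·(E−T)/(n−1))` from the bbox corner, which guarantees full
coverage and overlap ≥ O because `(E−T)/(n−1) ≤ T−O`. Tiles are clamped
into the slide; a slide smaller than one tile yields a single tile that
is reflection-padded at extraction time. Tiles that do not intersect the
tissue mask are dropped.

## Network

The segmentation model is an encoder–decoder with an asymmetric,
truncated decoder: the encoder contracts by 32× (1024 → 32 px at the
bottleneck) and the decoder performs only two 2× bilinear up-samplings,
so the two output probability maps (BD, SK) live at 1/8 input
resolution — one output pixel per 8×8 px region. The decoder blocks are
{bilinear 2× up-sample → concatenate the encoder skip at 1/16 (then
1/8) resolution → 3×3 conv + ReLU}, finished by a 1×1 conv to 2
channels. Per-channel *independent* sigmoids are used rather than a
softmax because the two heat maps are separate detectors and one lesion
can genuinely contain both classes (collision tumors).

Two encoder presets share this topology:

* `paper` — ResNet34-style: 7-conv stem (here a 3×3/2 conv), then
  residual stages of 3/4/6/3 basic blocks with widths 64/128/256/512 and
  strides 2 at each stage entry;
* `small` — a plain five-level conv net with widths 16/32/64/128/128,
  one stride-2 conv plus one stride-1 conv per level, sized so CPU
  training on 256 px tiles takes minutes.

All layers (im2col convolution, ReLU, bilinear up-sampling and its
adjoint, Adam) are implemented in numpy with analytic gradients; the
backward pass was verified against central finite differences.
Weights use He-uniform initialisation from the config seed; there is no
pretrained initialisation.

## Training

The loss is the focal loss `FL(p_t) = −(1−p_t)^γ log(p_t)` with γ = 2,
averaged over pixels and channels, computed on sigmoid outputs clamped
to `[1e−7, 1−1e−7]`; at γ = 0 it reduces exactly to binary cross-entropy
(asserted in tests). Targets at 1/8 resolution are block-*any*
down-sampled label masks: an output pixel is positive when any covered
input pixel carries the class, matching the output pixel's receptive
footprint. The optimiser is Adam with standard moments; the paper-scale
default learning rate is 1e-4, while the desk-scale preset uses 1e-3
because a from-scratch ~10⁵-parameter network sees only ~10³ gradient
steps in these short runs.

Tiles are split into train/validation at the *slide* level (default
80/20, greedy accumulation of shuffled slides until the row share
reaches the fraction), so no slide contributes to both parts.
Augmentation is paired and seeded: geometric transforms (rot90, flips,
optional elastic deformation) hit tile and mask identically (mask
nearest-neighbour), photometric jitter (brightness/contrast, per-channel
colour scale, Gaussian noise, optional blur) hits the tile only. Elastic
deformation is available but off by default in the desk-scale runs for
cost. After every epoch the aggregate IoU (pooled intersection/union
over tiles and both channels, empty/empty defined as 1) is computed on
both splits and the best-validation-IoU weights are returned.

## Stitching, post-processing, decision

Overlapping tile predictions are combined by the arithmetic mean (max is
available via config; mean was chosen for smoothness at tile seams).
Because tile origins are arbitrary pixels, accumulation happens at input
resolution — each tile map is up-sampled 8× nearest-neighbour, averaged
per pixel over the covering tiles, zeroed outside the tissue mask — and
then block-averaged back to the 1/8 grid over the covered tissue pixels
of each block. Any tissue pixel covered by no tile is an error.

Section maps are smoothed per channel by grayscale opening then closing
with a disc of radius 2 output pixels (16 µm); this open–close filter is
idempotent and keeps values in [0, 1]. Areas are measured on the
post-processed maps: `area = #{p ≥ threshold} · mpp_out² / 10⁶` with
`mpp_out = 8·mpp`.

The cascade labels a section BD iff `area(BD) ≥ δ₁`, else SK iff
`area(SK) ≥ δ₂`, else Normal (priority BD > SK > Normal). In
relative-area mode the BD call additionally requires
`r = 100·area(BD)/(area(BD)+area(SK)) ≥ 20`; a section passing the δ₁
size test but failing the r test is re-labelled SK — that pattern (a
small BD component inside a large SK lesion) is exactly the irritated-SK
reading the rule exists for. `r` at 0/0 is defined as 0. By
construction relative-area mode never makes more BD calls than the
cascade.

## Calibration and metrics

The per-section continuous score that the ROC sweep varies is the
largest threshold `t` at which the positive area still reaches the
minimum area; computationally it is the k-th largest probability of the
post-processed channel with `k = ceil(min_area in output px)`. This
makes "compute TPR/FPR for every threshold" well-defined and reduces to
the binary call at the selected operating point: *positive at threshold
t ⇔ score ≥ t*.

Calibration runs two line searches per call ("BD vs all" on channel 0,
"SK vs Normal" on channel 1 — falling back to "SK vs all" when the
cohort has no Normal sections):

1. minimum area over a default grid of 20 log-spaced values in
   [0.001, 0.1] mm², maximising ROC AUC, ties resolved to the *smaller*
   area;
2. threshold over a default 0.05-step grid, maximising F_β (β = 2 for
   BD, β = 1 for SK), ties resolved to the *larger* threshold
   (favouring specificity).

ROC curves and trapezoidal AUC come from scikit-learn; AUC with ties
follows the mid-rank convention and is asserted equal (to 1e-12) to an
O(n²) pairwise-concordance oracle in the tests. TPR = TP/(TP+FN) equals
sensitivity and FPR = FP/(FP+TN) equals 1 − specificity; evaluation
subsets per call ("BD vs SK" drops Normal sections, the irritated-SK
variants select SK subsets, etc.) are encoded in `CALL_SPECS`, with
`SK_with_BD_focus` counting as SK ground truth in every BD-vs-* call.

## Synthetic slides

The generator is a stand-in for clinical cohorts, not a histology
simulator. Tissue sections are smooth star-convex blobs
`r(θ) = R·(1 + Σ aₖ cos(kθ+φₖ))` whose radius is solved from the exact
polar-area integral, so requested lesion areas are met to well within
10%; base tissue texture is low-pass-filtered Gaussian noise mapped to
an H&E-like pink/purple ramp. Class-specific features are bright round
dots for SK (density fixed at ~1 per 900 px², radii 2–4.5 px) and
anisotropically smoothed dark streaks for BD; a `separability` knob in
(0, 1] scales both the lesion tone and the feature contrast, so at low
values lesions approach plain tissue. `SK_with_BD_focus` sections embed
a BD blob of 5% of the lesion area inside the SK region. Style shifts
(hue/saturation, brightness/contrast, tint, noise) are photometric only
and leave masks untouched; their magnitudes are free choices since
between-center stain variation has no published parametrisation.
Everything derives from one integer seed and is bit-reproducible.

Desk-scale study conditions: 512×512 px slides at mpp = 1, one section
per slide, lesion areas drawn uniformly from 0.015–0.035 mm², tissue
footprint about twice the lesion, 256 px tiles with ≥ 75 µm overlap
(the 1024/300 geometry scaled by 4), small preset, ≤ 10 epochs, batch 8.
The headline experiment uses 30 training and 20 test slides at
separability 0.9 and reports held-out BD-vs-SK AUC over 3 seeds.

What passing these tests shows: the pipeline's geometry, statistics and
decision logic are correct, and the training loop can learn textures
that differ in second-order statistics. What it does not show:
performance on real H&E slides — nuclei-level morphology, staining
artifacts, pen marks, folds, and the full difficulty of irritated SK are
all outside the generator's scope.

## Numerical choices and edge cases

* Focal-loss clamp 1e−7; float32 parameters and activations.
* IoU of two empty masks is 1; ROC requires both classes and raises
  otherwise; F_β at precision = recall = 0 is 0.
* Blank slides give empty tissue masks (no Otsu on constant input);
  empty specs give blank slides, empty masks, empty truth lists.
* A requested lesion that cannot fit its canvas cell raises a
  placement error rather than silently shrinking.
* The decision sub-case `area(BD) ≥ δ₁, r < 20, area(SK) < δ₂` is
  labelled SK (the irritated-SK reading); it is nearly empty in practice
  because r < 20 forces `area(SK) > 4·area(BD) ≥ 4δ₁`.
* Overlay rendering up-samples heat maps 8× nearest-neighbour, keeping
  the output stride's block structure visible; where both channels are
  positive the stronger one colours the pixel.

## Known limitations

* No pyramidal/vendor slide formats; plain PNG/TIFF rasters only.
* The numpy training loop is single-device and unbatched across
  processes; paper-scale training (40 epochs, effective batch 256 on
  gigapixel cohorts) is out of reach and out of scope.
* Calibration assumes at least one section of each truth class in the
  calibration cohort.
* The generator's irritated-SK emulation (a clean BD focus inside SK)
  is easier than real inflammation; specificity numbers on it should
  not be read as clinical estimates.
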