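# Methods

## Problem and model

`crownseg` segments individual tree crowns of a target species from paired
UAV imagery: a 3-band RGB tile and a co-registered 4-band multispectral
(MS) tile with bands Red (650 nm), NIR (860 nm), Green (560 nm) and RedEdge
(730 nm).  The two modalities are complementary: RGB carries spatial
texture and color, but crowns whose autumn color matches surrounding
canopies are invisible in it; the narrow bands carry vegetation
physiological signal (NIR/RedEdge reflectance) at lower effective spatial
resolution.  The model is a dual-branch, cross-modal attention UNet:

**Dual-branch encoder (DBE).**  Two independent ConvNeXt-style hierarchical
backbones, one per modality.  Stages use depthwise 7×7 convolutions,
channel LayerNorm, a 4× pointwise MLP with GELU, and layer-scaled residual
connections; the stem patchifies at stride 4 and three 2×2/stride-2
downsample layers give stage outputs at 1/4 … 1/32 resolution with widths
(96, 192, 384, 768) at full scale.  The RGB branch publishes five levels
feat1…feat5 (feat1 at 1/2 resolution from an auxiliary conv–norm–GELU
block, because the decoder consumes four skip connections); the MS branch
runs the same architecture on 4 bands but publishes only feat4/feat5 — deep
semantics only, keeping shallow spectral noise out of the skip path.  A
4-band stem can inherit a pretrained 3-band filter bank: the first three
input-channel slices are copied and the extra band's slice is drawn
i.i.d. N(0, σ²) with σ = 0.01.

**Cross-modal interactive fusion (CIF).**  At feat4 and feat5, a
bidirectional cross-attention block (CotSR): each branch forms Q, K (width
C/8) and V (width C) by 1×1 convolution; attention runs over the N = H·W
spatial positions, each softmax row a distribution over the *other*
branch's positions, with no √d temperature (none is part of the design) and
a single head.  The attended complement is added residually through a
learnable scalar γ, initialized to 0 so the block starts as an exact
identity and interaction strength is learned.  The two enhanced maps are
then blended elementwise as `F = α·F_rgb + β·F_ms` with learnable scalars
α, β per stage (initialized to 1), so the modality balance adapts without
channel expansion.

**Attention-enhanced decoder (AED).**  Four Up-Concat stages: 2× bilinear
upsampling followed by a 3×3 conv (transposed-conv variant available),
channel concatenation with the skip (fused feat4 first, then the RGB
branch's feat3/feat2/feat1), CBAM recalibration of the concatenation, and a
double conv–norm–GELU block.  CBAM is channel-then-spatial sequentially:
M_c = σ(MLP(avgpool) + MLP(maxpool)) with a shared bottleneck MLP
(reduction 16 at full scale), M_s = σ(conv7×7([channel-avg; channel-max]))
computed on the channel-refined map.  A parallel variant (both maps from
the raw input, multiplied jointly) sits behind `cbam_order="parallel"`, and
`cbam_enabled=False` removes the block for ablations.  A final 2× bilinear
upsample and a 1×1 conv produce two-class logits at input resolution;
prediction is argmax with ties broken toward background.

**Training recipe (full-scale defaults).**  Adam (β₁ = 0.9, β₂ = 0.999,
weight decay 10⁻⁴), cross-entropy on logits, batch size 4, cosine annealing
of the learning rate from 10⁻⁴ to 10⁻⁶ over 200 epochs stepped per epoch,
early stopping when validation mean IoU (unweighted mean of background and
crown IoU) fails to exceed the best-so-far value for 5 consecutive epochs.
The best-mIoU checkpoint is retained.  An `amp_enabled` flag is accepted
for config compatibility; this engine computes in float32 throughout, so
the flag changes nothing.

## Numeric engine

The network, its gradients, and Adam are implemented on a small
reverse-mode autodiff tape over numpy arrays (`crownseg.nn`).  Convolutions
use im2col + GEMM (stride/padding general), depthwise convolutions use
shift-accumulate, bilinear resampling is expressed as separable dense
interpolation matrices (half-pixel convention), and LayerNorm normalizes
across the channel axis per sample and position.  GELU uses the sigmoid
parameterization x·σ(1.702x), which matches the erf form to ~10⁻² and lets
the backward pass reuse the cached gate.  Every primitive's backward rule
is tested against central finite differences.  Weight init: fan-in-scaled
normal for conv/linear weights, truncated normal (std 0.02) for depthwise
kernels, zeros for biases, ones for norm gains, 10⁻⁶ for layer-scale
vectors.  With fixed seeds, model builds and training runs are
bit-reproducible.

## Dataset construction pipeline

Orthomosaic-scale rasters are cut into fixed tiles by a sliding window
(default 640 px) with 25 % overlap: stride = round(window·(1−overlap)),
starts 0, s, 2s, … while start+window ≤ dim, plus one final origin clamped
to the image edge per axis whenever pixels would otherwise be lost, so
coverage is exact at the cost of at most one extra overlap band.  Windows
are half-open `[start, start+window)` in 0-based (row, col) coordinates.
Polygon crown annotations (LabelMe-style JSON) are rasterized with the
even-odd rule sampled at pixel centers (col+0.5, row+0.5); overlapping
polygons union.  Tiles are screened by positive-mask fraction (default
"> 0", a reproducible proxy for manual "discernible crown" screening, and
configurable).  Geometric augmentation — k·90° rotations, horizontal and
vertical flips, scale-then-center-crop, random-crop-then-resize — is
applied jointly to RGB, MS and mask (bilinear for imagery, nearest for the
mask, so binarity and co-registration are preserved) and only to training
data, on the fly by default.  The train/validation split shuffles ids
deterministically and takes round-half-up(0.8·n) for training; held-out
test data never passes through this split.  Free-angle rotation is
deliberately excluded by default to avoid border-fill ambiguity.

## Synthetic scenes

Real crown datasets of this kind are rarely shareable, so the generator
fabricates the *decision structure* rather than the photometry of a real
forest.  Each scene is a background with a smooth multiplicative canopy
texture field, plus superellipse blobs (|x/a|^p + |y/b|^p ≤ 1, p ∈ [2, 4],
axis ratio ∈ [0.6, 1], random rotation; axes normalized so the support area
is exactly π·ratio·r²) of three kinds:

* **distractor canopies** — green RGB palette, moderate NIR;
* **ms-cued crowns** — identical RGB palette to distractors, elevated NIR
  and RedEdge (separable only spectrally);
* **rgb-cued crowns** — autumn-yellow RGB, spectrally identical to
  distractors in all four bands (separable only by color).

Three design rules keep the class structure *leak-free*, so that a model
can only solve the task through the intended cues:

* all blob geometries are drawn first under a shared rejection rule and
  classes are assigned by random permutation afterwards — position,
  crowding and overlap statistics are exchangeable across classes;
* shadows (multiplicative factor ∈ [0.3, 0.7] over a 1.5r blob, all bands)
  are cast i.i.d. per blob at the same rate for crowns and distractors, so
  the shadow pattern carries no class information (fixed per-tile shadow
  counts would let one blob's shadow status inform another blob's class);
* the canopy texture field is shared across blobs; per-blob brightness
  signatures (optional via ``crown_jitter``, off by default) would let a
  network shortcut the spectral cue by memorizing individual blobs.

MS bands are Gaussian-blurred
(σ = 1.5 px by default, emulating the lower MS spatial resolution
photometrically at equal grid size — the tiles are co-registered, so no
resampling) and both modalities receive additive Gaussian noise before
clipping to [0, 1].  An `altitude_scale` multiplier scales all object sizes
to emulate flight-height change.  Everything is driven by a single seeded
generator: equal (spec, seed) gives bit-identical tiles.

What the generator does *not* emulate: BRDF and illumination geometry,
within-crown structure (branches, gaps), species mixtures, registration
error, radiometric miscalibration.  Tests passing on these scenes show that
the architecture can discover and route modality-specific evidence and that
the pipeline arithmetic is correct — not that the model reaches any
particular accuracy on real forests.

## Desk-scale study conditions

All simulation studies use a reduced model: width multiplier 0.25
(ladder 12, 24, 48, 96, 192), single-block stages, CBAM reduction 4 (16
does not divide the reduced concatenation widths), and run on one CPU core.
Crowns in protocol scenes are sized to span several cells of the deepest
feature grids (stride 16/32) — the regime the deep-level fusion operates in
on full-size 640 px tiles; crowns much smaller than one deep-grid cell
cannot be localized through feat4/feat5 by construction.

* **Memorization check**: 8 fixed 128×128 tiles (3 crowns of radius 16–28
  each), Adam at lr 5·10⁻³ with a crown class weight of 2 (the fixture is
  ~80 % background), ≤300 optimizer steps of batch 4, training crown IoU
  measured every 10 steps.
* **Modality ablation**: 96×96 scenes with 2 crowns (one spectrally cued,
  one color-cued) and 2 distractors; fused, RGB-only and MS-only models
  share the architecture and data; flip/rotation augmentation on the fly;
  plain cross-entropy (a crown class weight would bias all three variants
  toward blanket canopy prediction and mask the modality contrast);
  cosine-decayed learning rate over 50 epochs and the validation crown IoU
  averaged over the last five epochs — a selection-free estimate, since
  picking each model's luckiest checkpoint on a small validation set
  systematically inflates the single-modality baselines.
* **Adaptivity probe**: the MS input is replaced by uniform noise during
  60 epochs of training on denser 3-crown scenes; because the
  spectrally-cued crowns are then unfittable, the loss floor stays high
  and the optimizer has a sustained incentive to down-weight the noise
  branch — trained β tends below its initialization while α tracks the
  informative RGB branch.

These are capability probes at small scale; absolute IoU values from them
are not comparable to full-scale training results.  Two caveats apply to
the stochastic studies.  First, the number of optimizer steps that fits in
the desk-scale envelope sits near the threshold at which the cross-modal
pathway (using deep spectral evidence to veto color-identical distractors)
reliably emerges; across seeds its emergence is therefore variable, and
majority-vote outcomes of the overfit and ablation studies can land on
either side of their thresholds.  Second, the fusion scalars α and β are
scale-redundant with the adjacent convolutions, so their trained values
measure the modality balance only up to slow re-scaling dynamics (weight
decay moves both), and the cross-attention path can route informative
content into the nominally-noise branch; β's decline under MS noise is a
tendency, not a guarantee, at this scale.

## Conventions and edge cases

* Metrics: IoU, PA (overall pixel accuracy), Precision, Recall, F1 as
  percentages, crown = positive class; F1 ≡ 2·IoU/(1+IoU) for binary
  confusion counts, asserted in tests.  Zero-denominator ratios return the
  flagged undefined value `nan`, never a silent 0; dataset aggregation is
  micro (pixel counts pooled over tiles, ratios computed once), which
  sidesteps per-tile undefined ratios; per-tile rows are also reported.
* mIoU (used for early stopping) is the unweighted mean of background and
  crown IoU; an undefined class is skipped.
* "No improvement" in early stopping means val mIoU ≤ best-so-far; a strict
  improvement resets the counter.
* Argmax ties in prediction go to background (conservative detection).
* The split count uses round-half-up on the training fraction.
* Checkpoints are npz weight archives plus a JSON sidecar holding the model
  config snapshot, the training history, and the learned fusion weights.

## Known limitations

* The engine is CPU-bound numpy; full-scale (640 px, Tiny-width) training
  is out of its intended envelope — the desk-scale configurations are the
  supported regime.
* Fusion weights α, β are global scalars per stage; they cannot express
  spatially or channel-wise varying modality balance.
* The single-head, unscaled attention follows the design faithfully, but
  N² attention memory limits tile sizes at full resolution (N ≤ 1600 at
  640 px input is fine).
* Stochastic protocol outcomes vary across seeds; the reference studies use
  three seeds with majority voting.
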