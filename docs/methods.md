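# Methods

## The scoring model

The pipeline estimates the PD-L1 Tumour Proportion Score

TPS% = 100 · n⁺ / (n⁺ + n⁻),

where n⁺ and n⁻ are the counts of PD-L1-positive and PD-L1-negative
*intact* (viable) tumour cells inside a pathologist-annotated region of
interest (ROI). The ROI is tiled into fixed-size patches (256 px default),
each tile is segmented into a three-class label mask (0 background,
1 positive tumour cell, 2 negative tumour cell), cells are counted per
tile by connected components, tallies are summed over tiles, and the ratio
is applied to the sum. A case whose ROI yields no tumour cells is reported
as "no viable tumour", never as a score; the 0/0 case is an explicit error
(`NoTumourCellsError`), not a NaN.

Tiling-then-summing means a cell that straddles a tile boundary would be
counted once per tile it touches. This double-count risk is inherent to
per-tile aggregation; the synthetic generator's `forbid_tile_straddle`
option removes it for testing, which is how the tiling-additivity checks
are exact.

## Segmentation network

A U-Net-style encoder–decoder maps an RGB patch to per-pixel class
probabilities (softmax over three classes).

* **Full variant** — residual encoder in the ResNet-34 pattern: 7×7 stem
  convolution to 64 feature maps at stride 2, 2×2 max-pool, residual
  stages of 3/4/6/3 blocks at 64/128/256/512 channels, and a 3×3 widening
  convolution to a 1024-channel bottleneck at 1/32 resolution (8×8 for a
  256 px patch). The decoder upsamples with 2×2 transpose convolutions,
  concatenating the encoder skip of matching resolution after each step.
* **Reduced variant** — same topology at desk scale (3×3 stem to 16 maps,
  one block per stage at 32/64/128, bottleneck at 1/8 resolution), used
  for CPU training in tests and the acceptance run.

Input spatial dimensions must be divisible by 32 for both variants;
non-conforming inputs are rejected rather than silently padded, keeping
image/mask pixel correspondence exact.

All layers (convolution, transpose convolution, group normalisation,
max-pooling, ReLU, Adam) are implemented in numpy with explicit
backpropagation (`pdl1tps.nn`); layer gradients are verified against
central differences in the test suite. Group normalisation is used rather
than batch normalisation because training uses mini-batches of 8, too few
for stable batch statistics; it also makes convergence insensitive to
initialisation, which matters for the short training runs exercised here.

The output head is a three-class softmax. A pixel is assigned the
foreground class of higher probability when that probability reaches the
mask threshold (default 0.5), otherwise background; an exact tie between
the foreground classes resolves to the positive class — a deterministic,
documented rule for an event of essentially zero measure.

### Training defaults

| parameter | default | note |
|---|---|---|
| optimizer | Adam (β₁ 0.9, β₂ 0.999) | |
| learning rate | 1e-4 | full-scale recipe; the desk-scale benchmark uses 1e-3, the standard Adam step for its ~125-update budget |
| epochs | 100 | full-scale; 5 in the desk-scale benchmark |
| batch size | 8 | |
| class weights | (0.4, 0.9, 0.9) | background down-weighted against the rarer tumour-cell classes |
| augmentation | rotation ≤ 30°, horizontal/vertical flips at p = 0.5 | identical transform applied to image and mask; mask resampled nearest-neighbour so labels stay in {0,1,2} |
| input scaling | [0,255] → [0,1] | |
| mask threshold | 0.5 | |

The weighted cross-entropy is the mean over pixels of w[t]·(−log p[t]);
probabilities are clamped at 1e-12 so the loss is always finite, and with
unit weights it reduces to plain cross-entropy (asserted against an
independent computation in the tests). Training is fully seeded —
shuffling, augmentation and initialisation derive from one seed — so a
given (data, config) pair reproduces its loss trace bit-for-bit.

An option to load pretrained encoder weights exists as a hook but no
weight file is bundled; the default is He initialisation.

## Cell counting

`label_cells` groups same-class pixels into cells by dilating the class's
binary mask with a Chebyshev-radius-4 structuring element, labelling the
dilation with 4-connectivity, and assigning original pixels the label of
their dilated component. Fragments of one cell within four pixels of each
other therefore count once. Chebyshev (square structuring element) is the
natural raster dilation; radius and connectivity are both configurable.
The implementation (scipy dilation + labelling) is checked exactly against
an independent brute-force dilation + flood-fill oracle in the tests.

An optional `min_size_px` gate (default 0, i.e. off) drops components
smaller than an intact cell. The desk-scale benchmark sets it to 8 px:
the smallest generated tumour cell (3 px semi-major axis) covers ~12
pixels, so sub-8 px components are segmentation specks, and counting them
as cells would corrupt the TPS denominator. At full scale the appropriate
value depends on magnification and should be calibrated per deployment.

ROI handling: polygons arrive as GeoJSON (QuPath-style, 0-based pixel
coordinates, y down). A pixel belongs to the ROI when the polygon contains
its centre (x+0.5, y+0.5). Pixels outside the polygon, or in the padding
of partial edge tiles, are marked invalid and excluded from counting via a
validity mask — the image itself is never mutated.

## Evaluation levels

* **Pixel** — 3×3 confusion matrix; accuracy over all pixels; one-vs-rest
  sensitivity and specificity per class. A class absent from the ground
  truth has undefined sensitivity, reported as NaN and excluded from the
  macro means. Macro averages cover the two tumour-cell classes only,
  since background dominates every patch and would mask foreground
  behaviour; per-class values are always emitted alongside.
* **Object** — cells extracted from both masks with the same radius-4
  rule; greedy one-to-one matching by descending pixel overlap (ties by
  smaller object index), any positive overlap qualifying by default, with
  an optional IoU threshold. Empty prediction against non-empty ground
  truth reports precision 0 and is flagged degenerate rather than hidden.
* **Patient** — Pearson correlation of paired case scores (Spearman also
  emitted), plus interval concordance under either the three clinical
  categories or a routing band scheme. A constant score vector makes
  correlation undefined: reported as NaN with a warning, concordance still
  computed.

## Clinical routing

Scores map to five half-open bands, [0,1) / [1,5) / [5,40) / [40,60) /
[60,100], the last closed at 100. The two "unconfident" bands (1–5 and
40–60) require manual pathologist scoring before a case can finalise; the
others auto-report pending confirmation. Band edges are configurable; 5
and 60 are used as the exclusive upper review edges. The unconfident-high
band deliberately straddles the 50% cut-off: the band triggers review,
while the clinical category always follows the final — possibly
pathologist-entered — score. Finalised records carry a provenance flag
(`algorithm`, `pathologist_confirmed`, `pathologist_overridden`).

## Synthetic data: what it does and does not emulate

The generator emulates the *colour and layout* structure that the
segmentation and counting stages depend on: a pale eosin-like background,
DAB-brown positive cells, haematoxylin-blue negative cells, elliptical
cell shapes with random eccentricity (≤2) and orientation, Gaussian sensor
noise, and macrophage-like distractors — smaller, darker DAB-stained
objects always labelled background, standing in for the PD-L1-positive
non-tumour cells that "hug" tumour clusters and confound scoring.

Placement is rejection sampling with a minimum Chebyshev gap between cell
envelopes (1000 attempts per cell before an explicit `PlacementError`;
never silent truncation). A gap above twice the merge radius guarantees
the counter can never fuse two generated cells, which is what makes the
generator's tally an exact ground truth. With `forbid_tile_straddle`,
centres are sampled at least radius+1 inside tile interiors so per-tile
counting is exactly additive.

Deliberately not modelled: tissue texture and stroma, nuclear chromatin,
membrane-vs-cytoplasm staining patterns, stain variation between
laboratories and scanners, necrosis, overlapping or touching cells.
Passing tests on this data therefore demonstrates that the pipeline's
*mechanics* (segmentation learnability, counting, aggregation, routing)
compose correctly — not that the shipped network would segment real
slides, which requires training on expert-annotated tissue.

Cohorts are stratified over the clinical categories by largest-remainder
rounding of the requested proportions; within a case, the positive-cell
count is drawn uniformly from the integer range realising the assigned
category, and positives are scattered uniformly over the patches.

## Desk-scale benchmark sizes

The end-to-end validation (`pdl1tps.validation.desk_scale_benchmark`, also
run by `scripts/acceptance.py`) uses 64×64 px patches with 3–5 px cell
radii and a 10 px minimum gap — the smallest gap that still guarantees
merge-free counting, letting up to five objects pack into a patch: 200
training patches, 5 epochs, 40 held-out patches for pixel accuracy, and a
20-case cohort (proportions 0.2/0.4/0.4 over the three categories, 4
patches per case, 3–4 cells per patch) for TPS agreement. These sizes keep
a full run to a few minutes on one core while exercising every stage.

## Known limitations

* The per-tile summation counts straddling cells once per tile (see
  above); real deployments should either overlap-merge detections across
  tile borders or accept the small inflation.
* Cells touching or overlapping each other are not separated (no
  watershed); the generator never produces them, real tissue does.
* The numpy network trains at CPU scale only; the full 1024-bottleneck
  variant is forward-complete and shape-tested but not trained here.
* TPS granularity on small synthetic cases is coarse (12–16 cells/case →
  ~7-point steps), which bounds how finely case-level agreement can be
  measured at desk scale.
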