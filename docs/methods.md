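# Methods

This note documents the models, algorithms and numerical choices in
`cervitrace`, module by module, including the places where the design
was genuinely open and what the synthetic test bed does and does not
establish about clinical data.

## Phantoms: the synthetic test bed

Clinical midsagittal cervix frames show a bright glandular band
surrounding a darker endocervical canal on a speckled background.  The
phantom generator reproduces exactly those three features and nothing
more:

* **Centerline** — a parametric curve r(t), t ∈ [0,1], one of:
  straight segment, circular arc through three points (circumcircle;
  the sweep direction is chosen so the middle control point lies on
  the traversed arc), quadratic or cubic Bézier.  Chord length is
  ‖r(1) − r(0)‖; arc length is ∫₀¹ ‖r′(t)‖ dt evaluated with adaptive
  Gauss–Kronrod quadrature on the closed-form derivative (tolerance
  1e-10, far below every downstream use).  These analytic values are
  the ground truth the calipers are judged against.
* **Rasters** — pixels are (row, col), 0-based, centers at integer
  coordinates, position in mm = px × spacing (per axis after
  anisotropic resize).  The mask is every pixel within
  `canal_halfwidth_mm` of the centerline (distances via a KD-tree
  against a dense polyline sampled at ≥ 4 points per pixel); the image
  intensity is 0.18 in the canal, 0.85 in the glandular band
  (`gland_band_mm` thick), background mean 0.45, softened by a 1 px
  Gaussian and multiplied by spatially-correlated Rayleigh speckle
  (mean 1, configurable strength).  No beam physics, shadowing or
  anatomy beyond the band — the generator's purpose is geometric
  fidelity, not visual realism, so segmentation results on phantoms
  bound what the architecture *can* learn, not what it *will* achieve
  on clinical frames.
* **Validation** — control points (and the densely sampled curve,
  which matters for circular arcs that bulge beyond their control
  points) must stay inside the field of view with a glandular-band
  margin; violations name the nearest control point.  Identical spec
  and seed give bit-identical rasters.

Default raster 256 rows × 512 cols (the model's input grid), with a
64×128 "tiny" preset used throughout the CPU-scale tests.

### Cohort generator

The screening-statistics layer needs per-subject lengths and outcomes
at realistic effect sizes.  Group-wise normal models (mean ± SD in mm)
default to a first-trimester pattern in which the chord-based methods
barely separate outcome groups while the traced arc does:

| method | term | sPTB 32–36 wk | sPTB <32 wk |
|---|---|---|---|
| single-line | 33.6 ± 3.6 | 33.2 ± 3.5 | 33.4 ± 1.2 |
| two-line | 36.9 ± 4.6 | 36.6 ± 4.5 | 35.4 ± 2.8 |
| AI-line | 43.3 ± 9.2 | 38.9 ± 6.9 | 37.3 ± 1.9 |

Every subject must satisfy arc ≥ chords, but a joint normal with that
hard constraint cannot keep all marginals normal.  The resolution is
structural: the two chords are exact correlated normals (shared latent
factor, ρ = 0.8 — the same cervix measured twice), and the arc is
`max(single, two) + E` with E ≥ 0 gamma-distributed, its two
parameters calibrated from Clark's (1961) moments of the maximum of
two correlated normals so the arc's mean and SD match the requested
model.  When a group requests an arc SD *smaller* than the SD of the
chord maximum (the <32-week group), the arc is instead a rank-based
quantile map of the chord maximum onto the target normal, floored at
the chord maximum.  Empirically all nine group moments land within
2% of the requested values at n = 10,000 while the ordering holds
exactly.  Draws are truncated at > 5 mm (never binding at the default
parameters).  Adjustment covariates (age, BMI, parity, prior preterm
birth or cervical surgery) are drawn independently of outcome, so a
correctly calibrated logistic regression should find them null.

## Segmentation network

A U-Net whose encoder is a ResNet-style backbone:

* **Stem**: BN → pad → 7×7 stride-2 conv → ReLU → pad → 3×3 stride-2
  max-pool → 3×3 stride-1 padded max-pool.  The second, stride-1 pool
  honours the two pooling steps of the block diagram without a third
  spatial halving; a config flag (`double_stem_pool`) removes it.  The
  stem conv output (at half resolution) doubles as the last skip
  source.
* **Encoder**: four stages of 1 CONV block + k Identity blocks,
  k = [2, 3, 5, 3].  CONV block: BN, ReLU, 3×3 conv, BN, ReLU, padded
  3×3 pool (stride 1 in stage 1, else 2), 3×3 conv, BN, ReLU, plus a
  1×1 shortcut conv (matching stride) applied to the first ReLU output
  and added to the final ReLU output.  Identity block: the same
  without pool/shortcut, the first ReLU output added directly.
* **Decoder**: BN → ReLU, then four Upsample Block_1 units
  (2×2-stride-2 transposed conv → ReLU → concatenate skip → 3×3 conv →
  ReLU) with skips from stages 3, 2, 1 and the stem conv, and one
  Upsample Block_2 (transposed conv → ReLU → 3×3 conv → sigmoid).

Spatial accounting: two halvings in the stem and one in each of
stages 2–4 make five, hence the divisible-by-32 input constraint, and
the decoder's five doublings restore the input grid exactly.  An
alternative reading with two stride-2 stem pools cannot satisfy both
that constraint and the stated skip wiring (the last skip's shapes
would disagree), which is why the stem above is the default.

Filter counts are not part of the published layout; the default is the
ResNet convention (`base_channels` 64 doubling per stage,
multipliers [1, 2, 4, 8]), fully configurable, with
`ModelConfig.tiny()` (64×128, base 8) for CPU work.  Initialization is
He-uniform from a seeded generator — two builds from the same config
are bit-identical.  Binarization threshold 0.5 with ties mapping to 1.
A structure report (ordered layer list with shapes and skip wiring) is
exportable as JSON and asserted in tests.

The network, its training loop and Adam are implemented on a compact
numpy reverse-mode autodiff kit (`cervitrace.nn`): conv2d via
im2col + GEMM, non-overlapping (kernel = stride) transposed conv via
einsum, max-pool with cached argmax, batch norm (momentum 0.9,
eps 1e-5) with running statistics.  Every backward pass is checked
against central finite differences in `tests/test_nn.py`; the training
loss is a single fused node with a closed-form gradient.

## Objectives

* BCE and log-Dice as printed above; predictions are clipped to
  [1e-7, 1 − 1e-7] before logarithms (configurable) and the clip is
  respected by the gradient.  The smoothing constant defaults to 1.0
  and keeps the empty-vs-empty case finite.  The combined loss uses
  unit weights; both weights are configurable.
* Dice coefficient 2TP/(2TP+FP+FN), defined as 1.0 when both masks
  are empty (0/0 otherwise).
* SSIM is computed globally — single window, whole-image means, SDs
  and covariance — with c₁ = (0.01 L)², c₂ = (0.03 L)².  A
  non-overlapping windowed mean-SSIM is available behind
  `ssim_windowed` but is not the default.  The raw value is reported:
  anti-correlated images give a negative index even though the
  quantity is usually quoted in [0, 1]; clamping would hide real
  disagreement.

## Trainer

75/15/10 split realized as floor(n·0.15) validation and floor(n·0.10)
test after a seeded shuffle, remainder to training — identical sizes
to a 90/10 split followed by carving 15/90 of the training pool into
validation.  Resizing is bilinear for images, nearest-neighbour for
masks, with per-axis spacing rescaled so physical lengths survive.
Augmentation emits per source pair the (optionally border-cropped)
original, its horizontal mirror, and one random rotation (±15°) +
scaling (0.9–1.1) copy about the image center, masks transformed
identically — 3× expansion with both flags on, applied after
splitting and to the training pool only so no augmented twin straddles
the train/validation boundary.  Training is mini-batch Adam
(batch 32, lr 1e-3) on the combined loss; early stopping monitors the
*training* loss by default (a flag switches to validation loss, the
more conventional choice), with patience 50 and min_delta 0 as
defaults; the best-loss parameters are restored.  "Accuracy" in the
history is pixel accuracy at threshold 0.5.

Desk-scale study conditions used in the tests: 200 tiny phantoms,
75/15/10 split, flip-augmented training pool, batch 32, ≤ 40 epochs,
all seeds fixed.  This reaches held-out Dice ≈ 0.97 in about five
minutes on one CPU; the suite asserts ≥ 0.90.

## Caliper

`extract_trace` keeps the largest connected component (flagging how
many were present), skeletonizes it, builds the 8-connected skeleton
graph (diagonal weight √2) and takes the geodesically farthest pair of
degree-1 endpoints as the os ends — which prunes side spurs without a
heuristic — then the shortest path between them.  Skeleton ends are
biased: erosion leaves them short of the os on wide canals, and on
very narrow canals they can poke into the rounded end cap.  Both are
corrected against the Euclidean distance transform: each end is
retracted to the local medial-ridge level and then advanced along its
tangent while the ridge level holds (tolerance 0.6 px; beyond the os
the transform falls with unit slope, so ends land within about half a
pixel of the os).  Interior points are then smoothed by a centred
moving average whose window spans ≈ 1.2 mm of trace (odd point count,
minimum 3, endpoints pinned; an integer overrides, 1 disables).  A
fixed point-count window would cover less physical length at finer
spacing and stall convergence; the physical window keeps the
arc-length error strictly decreasing as the pixel spacing halves
(0.4 → 0.2 → 0.1 mm on the semicircle benchmark) and below 2% of the
analytic arc everywhere tested (worst case ≈ 1.5% over 200 random
phantoms).

Measurements on the shared trace: single-line = endpoint chord;
two-line = chords joined at the trace point of maximum perpendicular
distance from that chord ("greatest curvature" operationalized
robustly for discrete skeletons; ties resolve toward the internal-os
end); AI-line = polyline arc length.  All three are invariant to
trace reversal, so the internal/external labelling — not decidable
from a mask alone; the trace is canonicalized leftmost-column-first —
is cosmetic.  The ordering ai ≥ two ≥ single − ε (ε = one pixel
diagonal) is asserted on construction of every measurement.

## Screening statistics

* **MoM** — CL divided by the reference-population median; the whole
  cohort is the default reference ("term_only" is a flag; no
  gestational-age adjustment is applied since the cohort spans only
  11–14 weeks).
* **Group tests** — Shapiro–Wilk per group; Student t for term vs
  each preterm group and vs pooled preterm; one-way ANOVA with post
  hoc pairwise t tests.  Raw p-values, no multiplicity correction.
* **AUROC** — Mann–Whitney with midrank tie handling; variance and
  confidence intervals by DeLong's structural components
  (normal approximation, truncated to [0, 1]); two methods on the same
  subjects are compared with the paired DeLong test (the covariance of
  the placement values enters the variance of the difference).  The
  test suite checks the AUROC against an exhaustive pairwise count and
  the 95% CI for 93–97% empirical coverage over 1000 simulations.
  Risk scores are negated lengths (shorter cervix ⇒ higher risk).
* **Logistic regression** — statsmodels maximum likelihood, outcome
  on CL plus age, BMI, parity and prior preterm birth/cervical
  surgery; constant covariate columns are an error rather than a
  silent drop, as is non-convergence (separation).
* **Power** — closed-form two-sided two-sample normal approximation,
  Φ(λ − z) + Φ(−λ − z) with λ = |δ|/(σ√(1/n₁+1/n₂)); at δ = 0 it
  returns α by construction.

## Pipeline, I/O, CLI

One YAML config with a single global seed drives the stages
phantom → train → segment → measure → evaluate; unknown keys are
rejected before any computation, every run writes its resolved config
and a log, and failures leave a FAILED marker naming the stage.
Images are 16-bit TIFF (floats scaled to 0–65535), masks 0/255 PNG
(any other value is a read error listing the offenders), and pixel
spacing is mandatory on read — explicit argument or a
`<file>.spacing.json` sidecar — because assuming 1 mm/px would corrupt
every length.  Cohorts are plain CSV.  The CLI is a thin wrapper; the
library API is the primary surface.

## Known limitations

* Phantom realism is schematic by design; no claim is made about
  segmentation accuracy on clinical frames, scanner artifacts or
  operator variability.
* SSIM is single-window per the printed formula; spatially local
  structure differences average out.
* The caliper assumes one dominant open curve; masks that are closed
  loops are an error, and heavily fragmented predictions are reduced
  to their largest component with only a flag raised.
* The cohort generator's <32-week arc model is a quantile map rather
  than an independent draw (see above); its within-group rank
  correlation with the chord methods is therefore 1 in that group.
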