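# Methods

This note records the models, conventions and design choices behind
`tasselkit`, in the order a reader meets them in the pipeline.

## Coordinate and box conventions

All boxes are axis-aligned, 0-based and half-open: `[xmin, xmax) ×
[ymin, ymax)`, origin at the top-left, y downward. An integer-coordinate
box therefore covers exactly `(xmax−xmin)·(ymax−ymin)` pixels, which makes
IoU identical to a lattice pixel-counting computation (a property the test
suite checks against an exhaustive oracle). PASCAL VOC XML as written by
LabelImg stores 1-based *inclusive* coordinates; the reader converts with
`xmin ← xmin−1`, `xmax ← xmax` so widths are preserved, and the writer
inverts this exactly. VOC files never state their convention; treating
them as 1-based inclusive is the LabelImg convention and is locked in by
round-trip tests.

## Detection matching

Matching is greedy in descending score order (ties: input order).
Each retained detection is assigned to the ground truth with maximal IoU
(ties: lowest index); the assignment is *independent of the threshold*,
which is only then used to decide TP versus FP. Consequences worth
knowing:

* a ground truth is matched iff any detection naming it as best overlap
  clears the threshold — so lowering the IoU threshold can only grow TP
  (monotonicity, property-tested);
* duplicate detections of a matched ground truth are FPs under the
  default policy and `DUP_DROPPED` under the customized one. Dropped
  detections appear in *no* count: not in the precision denominator, not
  in the PR curve. This is the only reading of "ignore the duplicate"
  under which the worked 5-ground-truth/8-detection scenario scores
  4 TP / 1 FP, and switching the policy to `drop` can then never lower
  precision nor change recall (property-tested);
* detections below the protocol's `min_score` are tagged `BELOW_SCORE`
  and are likewise invisible to every count. The default protocol uses
  `min_score = 0` so that all eight detections of the worked scenario
  enter the default computation, reproducing precision 1/8.

Metrics with an empty denominator are reported as `None` ("not defined"),
never 0 — a silent 0 would distort aggregate reports for images with no
ground truth or no detections.

Average precision uses the all-points interpolation (monotone precision
envelope integrated over recall). The cumulative AP variant sometimes
quoted alongside this protocol family is underspecified, so no AP value is
treated as a reference number here; AP is provided as a convenience
summary only.

### Aggregation across images

Micro-averaging (pool TP/FP/FN over images, then form the ratios) is the
default because it is insensitive to images with few ground truths and
satisfies an exact invariant: pooled metrics equal the metrics of the
disjoint union of all images (unit-tested). Macro averages (mean of
per-image ratios over images where they are defined) are reported
alongside, since published aggregate figures do not always state which
average was used.

## Tiling and patch grids

Frames are tiled without overlap at 1000 px (a 3000×4000 frame gives a
3×4 grid; remainders are dropped). Patches are 128 px. Since 1000 is not
a multiple of 128, the patch grid's last row/column is, by default,
shifted *flush* with the border (offsets 0, 128, …, 768, 872 — eight per
axis, 64 per subimage), so the union of patches covers every pixel and no
canopy pixel escapes classification; the alternative `drop` mode leaves
the 104-px remainder strip uncovered. A pixel covered by several patches
stays colored if any covering patch is positive — the recall-favouring
convention, chosen because in this application a missed tassel is costlier
than a false alarm.

Positive training patches are centered on their annotation (translated,
never shrunk, when the window would overflow), maximizing tassel
visibility with minimal background. Negative patches are sampled only
from frames known to contain no tassels at all; requesting negatives from
an annotated frame is an error, protecting label purity.

## The reference patch classifier

The production-scale classifier for this problem is a transfer-learned
CNN; `tasselkit` keeps that behind a contract (train / score / threshold)
and ships a reference implementation that is honest about what it is: ten
fixed features and a logistic decision layer, deterministic given its
seed, with the decision threshold fixed at 0.5 (a recall-prioritized
threshold is exposed on the model object but off by default).

Features: per-channel mean and standard deviation (6); the fraction of
pixels whose luminance exceeds its 9×9 local mean by more than 8 gray
levels — thin bright structures survive this residual, smooth canopy does
not; the count (log1p) and mean eccentricity of the connected components
of that mask, after discarding components under 5 px (sensor-style speckle
otherwise contributes on the order of a thousand one-pixel components per
patch and drowns both statistics); and the maximum per-component excess of
red chromaticity `R/(R+G+B)` over the patch mean. The chromaticity
feature carries the key domain fact that tassels are yellow-green while
canopy and leaf veins are green: it is illumination-invariant, and taking
the maximum over components keeps one small tassel visible among many
veins. Without it, a linear model leans on raw channel means, which fail
for tassels in locally dark regions of the canopy. Eccentricity is
computed from per-component second moments (vectorized over all
components); it agrees with `skimage.regionprops` to 1e-9, which a unit
test asserts.

The train/test split is seeded, per-patch and stratified by class,
80 % / 20 % (counts within ±1 per class). Splitting by patch rather than
by source frame slightly flatters held-out numbers when several patches
come from one frame; at the synthetic scales used here each frame
contributes at most 15 positives.

## Synthetic scenes

`generate_field` renders: a base green canopy (default RGB (62, 112, 48))
modulated by smooth and per-pixel multiplicative noise (amplitude 0.14);
bright thin leaf-vein streaks (250 per megapixel, +22 % brightness along
an anti-aliased stroke) as deliberate tassel look-alikes; and tassels as
branched anti-aliased strokes (stem 20–60 px, 3–7 branches over a ±55°
spread, stroke width 1–3 px) in a yellow-green (168, 178, 96) blended at
opacity 0.6 — bright enough to see, low-contrast enough that detection is
not trivial. Each ground-truth box is the drawn structure's bounding box
dilated by 2 px; placement retries until no two boxes overlap more than
half of the smaller box. Everything derives from one `numpy` generator
seeded by the config, so identical configs give identical bytes.

The default scene is a full 3000×4000 frame with 180 tassels; the test
suite and the end-to-end command use a 1000×1000 / 15-tassel
configuration (`FieldConfig.test_scale()`), which keeps the whole suite
under half a minute while exercising the same code paths; one test renders
the full-scale frame.

What the generator does *not* emulate: perspective and stitching
artifacts, motion blur, soil/shadow background classes, grouped
annotations covering several tassels (off by default; turning it on would
change no metric contract), and the intra-class variety of real tassels.
Passing tests therefore demonstrate correctness of the pipeline and
protocol machinery and sanity of the reference classifier — not field
accuracy on real imagery, for which the pluggable classifier contract
exists.

### The worked evaluation fixture

The 5-ground-truth / 8-detection scenario is stored as hand-constructed
coordinates satisfying the documented constraints: the lowest-scored
detection overlaps one ground truth at IoU 2/3 (a 20-px shift of a
100-px box); six detections overlap theirs at IoU 57/143 ≈ 0.399 (43-px
shifts), forming duplicate pairs on two ground truths; one detection
overlaps nothing; one ground truth is reached by no detection. Published
sources for this scenario print verdicts and scores but no coordinates,
so only the verdict pattern — not the geometry — is meaningful; the
constraints are re-asserted with the package's own IoU every time the
fixture is built.

## Numerical choices and degenerate inputs

* Zero-area boxes are rejected at construction; empty detection or
  ground-truth lists are legal everywhere and produce well-defined counts.
* IoU ties among ground truths resolve to the lowest index; score ties in
  matching order resolve to input order (both choices arbitrary but
  frozen and tested, so results are permutation-stable for distinct
  scores).
* Grayscale uses Rec. 601 luminance (0.299 R + 0.587 G + 0.114 B), rounded
  half-up.
* Detection CSV scores are serialized at 6 decimals; round-trips are exact
  at that precision.
* The logistic layer uses lbfgs with standardized features; with ~10
  features and hundreds of patches the fit is deterministic and takes
  milliseconds.

## Known limitations

The reference classifier is linear on ten engineered features: it
saturates quickly and will not transfer to real imagery — it exists so the
full pipeline is testable and as a baseline for plugged-in models.
Patch-level localization is as coarse as the 128-px grid; the pipeline
deliberately does not merge adjacent positive patches into object
instances or count tassels. Dataset-level accuracies reported for
GPU-trained models on proprietary UAV imagery are out of reach of this
repository and are not claimed; the acceptance script reproduces their
*arithmetic* (the F1 of stated operating points, the worked scenario's
precision/recall, the tiling geometry) rather than their dataset values.
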