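# Methods

## Fragment sizing

A kernel fragment is an outline polygon in image coordinates (origin
top-left, y down, 1 unit = 1 pixel). Its sieve-relevant size is the
shorter side of the minimum-area enclosing rotated rectangle. The
rectangle is computed by rotating calipers: the minimum-area enclosing
rectangle of a convex polygon has a side flush with a hull edge, so the
implementation takes the convex hull (monotone chain, collinear points
dropped) and minimises the projected-extent product over hull-edge
orientations. The result is parameterised with `side_a >= side_b` and
the angle of `side_a` in [0, 180), removing the four-fold symmetry of
rectangle parameterisations. Tests verify the area against a
multi-resolution brute-force angle sweep and against an independent
geometry library, and verify rigid-motion invariance of the minor axis
at 1e-6 relative tolerance.

Box-only detections cannot support a rotated fit; they are sized by the
shorter side of the axis-aligned box, which over-estimates size for
obliquely oriented fragments (the rotated minor axis never exceeds it).

Pixel lengths convert to millimetres through the camera scale, default
20 px/mm (0.05 mm per pixel), overridable per image — the default
matches a fixed-geometry acquisition rig, but the pipeline is agnostic.

A caveat worth knowing: for nearly isotropic shapes the *orientation*
of the minimum-area rectangle is unstable, and its shorter side can
exceed the shape's minimal width by 10 % or more (an oblique, more
square rectangle can have smaller area than the one aligned with the
minimal-width direction). This is a property of the sizing rule itself,
not of the implementation; it is immaterial for elongated fragments.

## Mask IoU

Polygon overlap is scored on the integer pixel grid: a pixel belongs to
a mask when its centre lies inside the polygon, matching
instance-segmentation benchmark practice. The discretisation error is
bounded in tests against exact polygon-clipping overlap (within 0.02 on
100-pixel-scale shapes). Degenerate requests — IoU of two empty
rasters, or of two zero-area boxes — raise rather than return 0/0.

## Detection matching and metrics

Detections are matched greedily in descending score order; each claims
the so-far-unclaimed annotation with the highest IoU when that IoU
reaches the threshold (default 0.5), otherwise it is a false positive;
unclaimed annotations are false negatives. Score ties are broken by
higher best-IoU, then stable input order. This is the VOC-style rule:
one true positive per annotation, surplus overlapping detections count
against precision. Greedy matching is not globally optimal in
principle — a high-scoring detection can claim an annotation that a
later detection needed — but on random scenes it attains the exhaustive
one-to-one optimum (verified over hundreds of enumerated small cases);
adversarial stacked-overlap configurations where it drops a TP exist
and are accepted as the cost of the standard sweep semantics.

Precision, recall and F1 are reported as percentages over all
detections at or above a configurable score threshold (default: none).
Degenerate conventions: precision 0/0 → 0; recall with no ground truth
is undefined and flagged, never silently 0. AP is the 11-point
interpolated average precision over a dataset-wide ranked sweep (pooled
detections, per-image matching state), so it is invariant under
strictly monotone score transforms.

## KPS conventions

KPS = 100 · n_below / n_total with a *strict* `<` at the 4.75 mm
threshold: a fragment measuring exactly the sieve aperture counts as
not processed. Sequence KPS pools all instances of a processor-gap
sequence before taking the percentage — pooling is sample-size-weighted,
unlike averaging per-image percentages, and both behaviours are pinned
by tests. Detections enter KPS at or above a confidence threshold
(default 0.5, configurable and recorded in every report). A sequence
with zero scoreable instances yields a flagged missing value, never 0.
The per-model summary is the mean absolute gap to the annotation KPS
across sequences.

## Correlation analysis

Model KPS columns are compared to the annotation column with: the
sample Pearson r; a two-tailed p from the exact t distribution
(t = r·√(df/(1−r²)), df = n−2 — at n = 17 the normal approximation
would be noticeably off); explained variance 100·r²; and an OLS line.
Normality of both samples is checked with Shapiro–Wilk (Royston's
approximation, 3 ≤ n ≤ 5000); because normality is an assumption of the
Pearson analysis, the report refuses to quote r when either sample is
rejected at α = 0.05 unless forced. The Shapiro–Wilk implementation is
cross-checked in tests against values frozen from R's `shapiro.test`,
and Pearson p-values against an independent reference implementation at
1e-8.

The embedded 17-sequence per-PG KPS table is stored to one decimal, as
published. Recomputed summary statistics are therefore compared to
published values at printed precision: ±0.1 percentage points for the
error row, ±0.01 for r and W, and ±0.5 percentage points for r² (the
squared statistic amplifies the input rounding). Within those bands all
eight model columns reproduce.

## Synthetic data generator

The generator emulates the statistical structure the analysis rests on,
not the photographs. Each sequence has a processor gap; fragment
minor-axis sizes (mm) are lognormal — the standard right-skewed family
for comminution products — with location increasing in the gap (median
1.9 + 0.45·pg mm by default, σ = 0.35 ln-mm) so that wider gaps yield
larger fragments and lower KPS. A helper solves the location for a
prescribed below-threshold probability, giving datasets whose expected
annotation KPS is known analytically.

Fragment outlines are convex tangent polygons circumscribing a sampled
ellipse (minor diameter = the sampled size, aspect ratio uniform in
[1.6, 2.6], orientation uniform, 22–28 vertices, tangency points placed
exactly at both minor-axis endpoints). With this construction the
polygon's minimal width equals the sampled minor diameter exactly, and
for these aspect ratios and vertex counts the minimum-area rectangle
provably stays flush with the minor-axis slab, so the measured minor
axis recovers the sampled one to machine precision — the tests assert
recovery within 2 %. Lower aspect ratios or coarser polygonisation
would break this: near-circular fragments hit the orientation
instability described above, which is why the defaults are elongated
and finely polygonised.

The simulated detector drops each fragment with a fixed miss
probability, jitters surviving vertices with iid Gaussian noise
(re-convexified and clipped to the image), adds Poisson clutter with
its own size law, and scores each detection as
base − penalty·(1 − IoU-to-source) + noise, clamped to [0, 1] — so
scores correlate with localisation quality as a trained network's
confidences loosely do. All randomness flows from one seed through
per-sequence spawned generators; identical configuration reproduces
identical datasets and byte-identical reports.

What the generator does *not* emulate: photometry, stover background,
occlusion and touching-fragment ambiguity, annotator disagreement, or
any empirical size distribution of real silage (none is published).
Passing recovery tests therefore shows the pipeline is internally
consistent and unbiased under its own assumptions, not that any
particular detector will reach a given accuracy on real images.

Problem sizes in tests and the acceptance script are chosen to keep
binomial error bars tight relative to the 3-standard-error acceptance
bands at desk scale: ≥ 500 instances for KPS recovery, ≥ 1000 for
recall recovery, 17 sequences (matching the published analysis) for
correlation runs.

## Input handling

Datasets interchange as COCO-style JSON (polygon `segmentation`,
`bbox` in x,y,w,h; per-image `px_per_mm`, `pg`, `year`), converted to
corner-based boxes internally; the round-trip is tested field by field.
Instances are validated on read (≥3-vertex polygons, in-bounds
coordinates, scores in [0, 1]) with errors naming the offending
annotation id. Train/test splitting is uniform at random by image,
never by instance, to avoid leakage.

## Known limitations

- Greedy matching can differ from the optimal assignment in adversarial
  overlap stacks (see above).
- Mask IoU is rasterised; sub-pixel slivers may rasterise to nothing
  and raise the undefined-IoU error rather than returning 0.
- Multi-part (disconnected) segmentations are not supported.
- The published per-PG table is stored at printed precision, so
  statistics recomputed from it inherit that rounding; the headline
  error-row value recomputes to 2.76 where the published summary prints
  2.7, consistent with the source having averaged unrounded KPS values.
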