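# silagekps

Kernel-fragmentation quality analysis for maize silage from object
recognition output.

When a forage harvester chops maize, its two mill rolls must crack the
kernels so cattle can digest the starch. The lab standard for judging
this — the Corn Silage Processing Score — sieves a dried sample and asks
what fraction passes a 4.75 mm screen; it takes days. An image-based
shortcut is to outline each kernel fragment in photos of the harvested
silage (by hand, or with a trained detector or instance-segmentation
network) and score the outlines directly. This package implements that
scoring pipeline and the statistics used to validate it, for anyone
building or evaluating such a detector:

- **Sizing.** Each fragment polygon is enclosed in its minimum-area
  rotated rectangle (rotating calipers over the convex hull); the
  rectangle's shorter side is the fragment's *minor axis* — the length
  that governs sieve passage. Box-only detections use the shorter side
  of the axis-aligned box instead. Pixels convert to mm via the camera
  scale (default 20 px/mm, i.e. 95 px = 4.75 mm).
- **Kernel Processing Score (KPS).** For a sequence of images taken at
  one processor-gap (PG) setting, KPS = 100 · |{minor axis < 4.75 mm}| / n,
  pooling every fragment in the sequence. A fragment at exactly 4.75 mm
  counts as *not* processed.
- **Detection evaluation.** Greedy IoU-0.5 matching of detections to
  annotations (highest score first, each annotation claimed once), then
  precision = TP/(TP+FP), recall = TP/P, F1 = 2TP/(2TP+FP+FN), and the
  PASCAL-VOC 11-point interpolated average precision
  AP = (1/11) Σ_{r∈{0,0.1,…,1}} max_{r̃≥r} p(r̃).
- **Correlation analysis.** Model KPS vs annotation KPS across PG
  sequences: Shapiro–Wilk normality on both samples, Pearson r with a
  two-tailed p from the exact t transform t = r·√(df/(1−r²)), df = n−2,
  explained variance 100·r², and an OLS fit. With 17 sequences this is
  the r(15) analysis.
- **Synthetic data.** Because the original field images are not public,
  a generator produces annotation sequences with a PG-dependent
  lognormal minor-axis law and a simulated detector with tunable miss
  rate, clutter rate, localisation jitter and IoU-correlated scores, so
  the whole pipeline is testable end to end against known rates.

A published 17-sequence per-PG KPS table (eight detector variants plus
hand annotations) ships with the package and doubles as an executable
regression suite.

## Worked example

Recompute the published summary statistics from the embedded per-PG
table:

```
$ silagekps reproduce-published --outdir out/ --no-plots
rfcn_2015    avg|err|  6.7  r(15) 0.54  r^2  29.7%
mnc_2015     avg|err|  5.3  r(15) 0.60  r^2  36.2%
rfcn_2016    avg|err|  3.8  r(15) 0.77  r^2  59.4%
mnc_2016     avg|err|  4.6  r(15) 0.74  r^2  54.4%
rfcn_2017    avg|err|  3.3  r(15) 0.81  r^2  64.8%
mnc_2017     avg|err|  6.3  r(15) 0.69  r^2  48.1%
rfcn_151617  avg|err|  2.8  r(15) 0.88  r^2  77.6%
mnc_151617   avg|err|  7.2  r(15) 0.63  r^2  39.9%
all recomputed values match the published ones at printed precision
```

Each row is one trained model variant (bounding-box `rfcn_*` or
instance-segmentation `mnc_*`, trained on one harvest year or the
combined `151617` set). `avg|err|` is the mean absolute gap between the
model's per-sequence KPS and the annotation KPS in percentage points —
the combined-years box detector tracks hand annotations to within 2.8
points on average. `r(15)` is the Pearson correlation of model KPS with
annotation KPS over the 17 sequences; its square is the share of
annotation-KPS variance the model explains (77.6 % for the best model).
The command exits nonzero if any recomputed value drifts from the
published one beyond printed precision.

The same analysis for a single model, from any KPS table CSV:

```
$ silagekps correlate --kps-table src/silagekps/data/kps_by_pg.csv \
      --model rfcn_151617 --out corr.csv
r(15) = 0.88, p = 3e-06, r^2 = 77.6%
```

Or fully synthetic, end to end (generate → detect → evaluate → KPS →
correlate):

```
$ silagekps end-to-end --seed 0 --outdir out/e2e
$ silagekps simulate --seed 0 --out-annotations ann.json --out-detections det.json
$ silagekps evaluate --annotations ann.json --detections det.json --mode box --out report.csv
$ silagekps kps --detections det.json --mode rotated --group-by pg --out kps.csv
```

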