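# Methods

This note records the model implemented by `marrowcyto`, every numerical
convention, the scope and limits of the synthetic data generator, and the
design decisions a reader needs to interpret the test suite.

## 1. Object taxonomy

19 classes (`taxonomy.CLASS_NAMES`), indexed 0–18 everywhere. Three nested
subsets:

* **NDC classes (12)** — neutrophil, metamyelocyte, myelocyte, promyelocyte,
  blast, erythroblast, lymphocyte, monocyte, plasma cell, eosinophil,
  basophil, megakaryocyte. These enter the nucleated differential count and
  the convergence feature vector.
* **BM_ME numerator (6)** — blast, promyelocyte, myelocyte, metamyelocyte,
  neutrophil, eosinophil; denominator is the erythroblast count. The ratio is
  reported as `None` (undefined) when no erythroblast was counted, never
  coerced to 0 or infinity.
* **Evaluated classes (16)** — all classes except basophil, mast cell and
  "other", which are too rare (or too heterogeneous) for stable per-class AP.

The published description lists the NDC/chi-square classes once with
megakaryocyte and once (in a different section) with mast cell in its place;
we follow the Methods-section list (megakaryocyte included, mast cell not),
which also matches the printed feature-vector size of 12.

## 2. Pipeline stages and conventions

**Grid.** 15 rows × 20 columns; the tile for cell (r, c) is centered at
((c+0.5)·W/cols, (r+0.5)·H/rows), rounded, then clamped (never padded) into
the slide. Tiles are 512×512 px.

**Boxes.** 0-based, half-open pixel intervals [x0, x1) × [y0, y1). YOLO text
files use the normalized-center dialect `class cx cy w h`; reader and writer
are exact inverses up to float rounding, and the reader reports the 1-based
line number of any malformed line.

**Matching.** Greedy Pascal-VOC style: detections below the confidence
threshold are discarded; the rest are visited in descending confidence (ties
by input order) and each takes the unmatched same-class annotation with the
highest IoU ≥ 0.5 (IoU ties by lowest annotation index). One-to-one:
a second detection of an already-matched object is a false positive.

**Operating points.** Localization is correct at IoU ≥ 0.5. Precision,
recall, F1 and the HCT counts use class probability ≥ 0.75. AP sweeps all
confidences.

**AP@0.5.** 11-point interpolation: AP = (1/11) Σₖ p_interp(k/10) with
p_interp(r) = max precision at any achieved recall ≥ r, and 0 if recall r is
never reached. Detections of one class are pooled over all tiles and ranked
globally; matching is per-tile. Classes absent from the ground truth are
excluded from mAP (AP undefined), not scored zero.

**Log-average miss rate.** Geometric mean of miss rates sampled at the 9 FPPI
points 10^(−2+k/4), k = 0..8. Step-function sampling: at each point, the miss
rate of the largest achieved FPPI ≤ the point; 1.0 if none; rates clamped to
≥ 1e-10 before the log.

**Binary ROI metrics.** Accuracy, precision, recall, specificity, NPV from
the confusion counts; any metric with a zero denominator is `None`. ROC AUC
is the rank statistic (ties averaged), delegated to scikit-learn.

**Chi-square distance.** χ̃²(x, y) = ½ Σ (xᵢ−yᵢ)²/(xᵢ+yᵢ), with 0/0 terms
contributing zero. For probability vectors the distance is bounded by 1.

**Convergence.** The feature vector of an IHCT is the 12 NDC proportions
plus, optionally, the BM_ME ratio squashed to bm/(1+bm) so the unbounded
ratio cannot dominate 12 bounded proportions; when BM_ME is undefined on
either side of a step, the component is omitted from both vectors. A step
against an empty (zero-NDC-cell) histogram is recorded at the ceiling 1.0.
Convergence is declared once n_tiles ≥ 80 **and** the last 5 step distances
are all < τ = 1e-4 (patience guards against a single lucky small step).
If the grid is exhausted first, the report is emitted with
`converged: false` — never silently treated as converged.

**Cohen's kappa.** Delegated to scikit-learn, with one documented fix-up:
two identical constant label lists are perfect agreement (κ = 1), where
sklearn returns NaN.

## 3. Synthetic slide generator

Real aspirate WSIs cannot be redistributed, so the pipeline is exercised on
synthetic slides that reproduce the *statistical* structure the method
assumes, not marrow morphology:

* Cells are ellipses with class-specific mean radius, eccentricity and fill
  color (`taxonomy.DEFAULT_PALETTE`); axes preserve area (a·b = r²). Placement
  is rejection-sampled (≤ 100 retries) to cap pairwise box IoU at 0.1 on
  appropriate tiles. Background is (235, 228, 232) + Gaussian noise (σ 2.5);
  fill colors get per-cell jitter (σ 4).
* Appropriate tiles hold Poisson(10) objects drawn from the profile mixture.
  The original system expects ~800 cells from ~80 tiles, i.e. ~10 per tile;
  the preset mixtures (normal / MDS-like / AML-like) are package-defined
  placeholders capturing qualitative regimes (blast fraction, erythroid
  fraction), **not** clinically calibrated frequencies.
* Inappropriate tiles use three failure modes mirroring the ROI criteria:
  `overlap` (40× denser, unconstrained overlap), `overstain` (global color
  cast), `empty` (≤ 2 debris specks).
* Determinism: every tile's seed is `SeedSequence([slide_seed, row, col])`,
  so the lazy reader (`SyntheticSlideReader`, renders tiles on demand, ~1 MB
  resident) is bit-identical to the eager `render_slide` (236 MB for a full
  grid). Equal seeds ⇒ bit-identical rasters and annotations.
* `simulate_hct_stream` skips rendering and draws per-tile count vectors
  directly from the mixture, for convergence studies. `drift_to=` makes the
  stream nonstationary: linear interpolation of the mixture, or an abrupt
  regime switch at the midpoint (`drift_mode="switch"`).

**Limits.** The generator tests the pipeline's statistics, not vision: a
nearest-centroid classifier can approach a perfect score on it, and its ROI
failure modes are separable by design. Synthetic detection scores (mAP ≈ 0.95)
are therefore *not* comparable to the published clinical mAP of 0.75.

## 4. Reference backends

* **ROI backend** — product of three monotone factors: foreground fraction
  inside [0.004, 0.15] (linear falloff outside), background tint factor
  exp(−dev/25), and presence of ≥ 1 connected component in the single-cell
  area band [20, 8000] px.
* **Blob detector** — connected foreground components (color distance > 40
  from the reference background), classified by nearest palette centroid in
  (radius, mean RGB) space with radius weighted 3×; confidence
  exp(−d/60).
* **Trainable backend** (active learning) — same component features, but
  centroids are *learned* from reviewed annotations (components matched to
  annotations at IoU ≥ 0.3). It genuinely improves with data: unseen classes
  are never predicted, and centroids sharpen as examples accrue.

## 5. Active-learning loop

Per iteration: classes whose cumulative annotated count is at or below the
0.25 quantile are "rare"; unlabeled tiles are ranked by predicted rare-class
content and the top batch is sent to a simulated reviewer, who corrects
predictions against ground truth at 0.3 cost/object (vs 1.0 for from-scratch
annotation, matching the method's motivation) with an optional seeded error
rate. Corrected tiles join the training set, the backend is refit, and mAP is
measured on a frozen held-out synthetic benchmark. `selection="random"` gives
the uniform baseline for comparison.

## 6. Published-table parity

The original clinical tables are embedded as *input data*
(`reference_tables`). Feeding them through the package's own metric and
bookkeeping code reproduces the printed summary rows: Table 3 column averages
0.83/0.75/0.78/0.32 and mAP 0.75; Table 4 per-iteration totals 6128 → 24735
and final mean AP 0.75; Table 1 training total 204; ROI dataset
70,250 + 28,500 = 98,750. One caveat: recomputing F1 from the *printed*
(2 dp) precision/recall reproduces the printed F1 at 2 dp for 14 of 16 rows;
promyelocyte and platelet clump differ by one unit in the last digit (max
abs diff 0.0069), which is exactly the propagation of input rounding — the
original F1 was evidently computed before rounding. The acceptance test
asserts |F1(P,R) − printed| ≤ 0.01 per row and exact equality for ≥ 14 rows.

## 7. Test-suite design decisions

* **Problem sizes** are scaled to desk hardware: acceptance slides use a
  15×20 grid with the ROI fraction raised to 0.5 so ≥ 100 appropriate tiles
  are available for convergence; the active-learning tests use 192-px tiles,
  25-tile batches and a 230-tile pool. These are this package's choices, made
  a priori and committed before measuring pass/fail.
* **Parameter recovery** (seeds 11–15 per profile): converged NDC proportions
  must sit inside Bonferroni-corrected 99% multinomial bands
  (z = Φ⁻¹(1 − 0.01/24)) and the median relative BM_ME error over the 5 seeds
  must be < 10%. A converged count holds ~800 cells, so a single slide's
  BM_ME carries real multinomial noise (the detector itself was verified
  unbiased: pooled detected vs true proportions agree); the median over seeds
  is the stable statistic.
* **Convergence delay** uses the regime-switch stream (normal → AML-like at
  the midpoint of a 120-tile stream): a linear drift spread over hundreds of
  tiles moves the integrated proportions too slowly to delay the patience
  test reliably, whereas a mid-stream switch measurably postpones convergence
  (medians 80 vs 86.5 tiles over seeds 100–119).
* **Active-learning monotonicity** is asserted on the per-iteration *median*
  mAP over 10 seeds, read at 2 decimal places — the precision at which the
  original iteration table reports AP. At full float precision the plateau
  carries ±0.0005 benchmark re-evaluation noise between iterations that have
  effectively converged.
* **Metric oracles**: AP, matching, LAMR, ROC AUC and chi-square distance are
  each checked against independent brute-force re-implementations (written
  from the definitions, not the library code) on 1000 random instances at
  1e-9 tolerance.

## 8. Delegations to established libraries

scikit-image supplies ellipse rasterization, connected components and region
properties; scikit-learn supplies `roc_auc_score`, `cohen_kappa_score` and
the raw confusion-matrix tally (row normalization and all detection-specific
matching are this package's code); SciPy supplies distributions for the
statistical tests. The method-specific primitives — 11-point AP, LAMR,
chi-square convergence, greedy VOC matching, HCT/IHCT accumulation, the ROI
score and both detectors — are implemented here, since they are the point of
the package.
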