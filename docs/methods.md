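# Methods

This note records the scientific and numerical choices behind
`coastcore`: what is modeled, what the synthetic data do and do not
emulate, and where the design was genuinely open.

## The estimation problem

The package targets presence–background habitat modeling in its hardest
practical regime: ~25–30 unique presence sites, spatially clustered
along a narrow coastal ecotone, against a background restricted to the
accessible near-shore strip.  Three failure modes dominate in this
regime and the pipeline is organized around them:

1. **Overfitting** — controlled by modest feature classes (linear,
   quadratic; hinge available but rarely selected at this n), the
   published sample-size-dependent L1 penalty schedule scaled by a
   regularization multiplier (RM), and selection on a robustness score
   (mean CV AUC − 0.5 × SD) rather than raw AUC.
2. **Spatial leakage** — random CV shares spatial structure between
   folds; the primary validation is leave-one-cluster-out (LOCO),
   holding out whole DBSCAN presence clusters (ε = 250 m, with a
   150–300 m sensitivity grid).  Random k-fold survives only for the
   selection grid and sweeps, and its reports are labeled `random-CV`
   so the two are never conflated.
3. **False positives in regulation** — binarization is deliberately
   conservative: the headline threshold is the 0.98 quantile of
   training-background predictions (Spec0.980), followed by two
   ecological filters (the Q90 coastal belt and a 3-cell minimum
   mapping unit) and explicit leakage accounting.

## MaxEnt implementation

Features are min–max scaled with bounds frozen from the training rows
(presences ∪ background); prediction rows are clamped to [−0.1, 1.1].
The L1-penalized negative log-likelihood is minimized with FISTA
(proximal gradient with soft-thresholding, backtracking line search,
momentum restart on non-monotone steps), convergence at an objective
change below 1e−7, at most 10⁴ iterations; non-convergence raises.

Penalties follow the published default tables — linear/quadratic models
interpolate β over sample sizes {0, 10, 17, 30, 100} → {1.3, 0.8, 0.5,
0.25, 0.05}, linear-only {0, 10, 30, 100} → {1.0, 1.0, 0.2, 0.05},
hinge flat 0.5 — as β_j = RM · β_class(n) · sd_j/√n.  A minimum
deviation of 0.05 (on the [0, 1] feature scale) floors sd_j: hinge
bases active on a handful of cells otherwise receive a vanishing
penalty, and any feature that separates presences from background would
drive its coefficient to infinity (the optimizer diagnoses this as
non-convergence).  The same guard exists in the published
implementations.

`cloglog = 1 − exp(−e^H · raw)` with H the entropy of the fitted raw
distribution over the training background; with all coefficients at
zero this correctly reduces to 1 − e⁻¹ ≈ 0.632 everywhere.

AICc uses the presence log-likelihood of raw scores and counts nonzero
coefficients; it is flagged undefined when n ≤ k + 1.

Collinearity pruning runs Spearman |ρ| > 0.7 first (within an offending
pair, the unprotected member with the larger mean |ρ| to all others is
dropped), then iterative VIF to ≤ 5.  `DIST_COAST_M`, `ELEV_M`,
`SLOPE_DEG` and `TWI_APPROX` are ecologically protected: the first two
are the composite maritime-exposure proxies the analysis is about, the
latter two the microsite axes of the target syndrome.  A protected pair
exceeding the threshold is kept with a warning.

## Terrain predictors: declared conventions

Where a predictor has no canonical formula, the convention is declared
here and parameterized in `TerrainConfig`:

- TRI is the RMS elevation difference to available 8-neighbors (Riley
  variant); slope/aspect use Horn's stencil with NoData neighbors
  taking the focal value; aspect is radians clockwise from north,
  undefined (NaN) on flats, with EASTNESS/NORTHNESS set to 0 there.
- TPI excludes the focal cell from the circular window mean (radius
  90 m) and uses land cells only.
- The wetness proxy is −(scaled relief) − (scaled slope), each term
  min–max rescaled island-wide before summation so the two are
  commensurate; it is *not* the classic ln(a/tanβ) index.
- Heat load is the McCune–Keon exponential form with aspect folded
  about the SW axis; coefficients are stated in the source.
- WAVE_EXP = exp(−d/decay) × the fraction of 16 compass rays reaching
  sea within the decay length (default 200 m); EDGE_SLOPE is the mean
  slope of shoreline-adjacent cells within the decay radius;
  CLIFF_NEAR is the distance to the nearest cell ≥ 40°, with a large
  sentinel when no cliff exists.
- Distance to coast is the Euclidean distance transform to the nearest
  sea-cell center minus half a cell (the land/sea interface), clipped
  at zero; the grid border counts as sea.
- Aggregation to the fitting scale is the block mean over contributing
  land cells; the model is a fixed coefficient vector over scaled
  features, so it evaluates per-cell at either scale.  Background
  cells are sampled on the native grid and their fitting-scale rows
  read off the aggregated stack.

All areas are cell counts × cell², in the projected CRS.

## Decision layer

Thresholds use linear-interpolation (type-7) quantiles.  Binarization
is inclusive (score ≥ θ).  Because predictions tie wherever background
points share a fitting cell, the Spec0.980 rule resolves ties upward —
the threshold steps to the first unique score above the order statistic
covering 98% of the background — so the ≥ 98% training-specificity
guarantee holds exactly, not just approximately.  Youden-type argmax
ties resolve to the smallest maximizing score, then midpoint to the
next unique score below (perfectly separated samples get the midpoint
between the extremes).  The coverage-target rule returns the *largest*
unique score keeping ≥ 90% of belt presences, the conservative end of
the rule's feasible set.

CORE = MMU-filter(binary ∧ belt); post-belt leakage is asserted to be
exactly zero.  Coverage counts consolidated recent sites whose 5 m cell
falls in the CORE.  The mask × ratio sweep refits per combination,
recomputes Spec0.980 from that run's own training background, and
reports the min–max area envelope ("area band") with its percent
increase over the smallest extent.  Survey segments (100 m, rolling
median over 3 segments, nearest belt cell to the segment midpoint) are
ranked only in quantile bands; effort and safety priors are
user-supplied multipliers defaulting to 1.  On a habitat as fragmented
as the synthetic island's, the strict Spec0.980 rule typically yields
no candidate stretches at the segmentation scale, so the survey-
expansion driver ranks at the balanced-accuracy threshold instead —
the same division of labor (strict rule for regulation, balanced
layers for survey guidance) the pipeline applies elsewhere.

## The synthetic island

The generator's job is to produce data with the statistical structure
the pipeline assumes, at a size a single CPU handles comfortably: a
256 × 256 grid of 5 m cells (≈ 1.04 km² of land).  That is a ~1/6-scale
emulation of a real volcanic island in the horizontal; the vertical
scale (peak ~1000 m, coastal cliffs of hundreds of meters) is kept, so
slopes are steeper than reality.  Geometry: a radial cone, an
inverted-Gaussian caldera, and — critically — radially dissected flanks:
high cliff arcs notched by cove valleys (amplitude 400 m, 10
ridge-valley pairs, sharpened waveform), whose floors are gentle
alluvial ramps (0.08 m/m, varying ±50% around the island).  Smoothed
Gaussian roughness (sd 10 m, 35 m correlation length) is added; sea is
NoData; only the largest landmass is kept.

The truth surface is logistic in the link:
intercept 0.8, −0.028 per m of coastal distance, −0.020 per m of
elevation, a wetness-optimum quadratic (−5·(TWI+0.5)²), and a smoothed
unmeasured-noise field (sd 0.15, 60 m scale).  The negative distance
and elevation terms are the responses the fitted model must recover;
the elevation term also shuts off the cliff arcs, which is what makes
suitable habitat alongshore-patchy — as in the real system, where a
continuous core contrasts with fragmented satellites.  The noise field
keeps ~28 presences from being linearly separable in a feature space
of a hundred-plus columns.

Surveys place true sites by sequential suitability-weighted draws with
a 45 m minimum separation (sites are discrete clumps — exactly the
structure the 30 m consolidation is designed to recognize), then
simulate four periods with 90% detection, 50% duplicate records offset
15–25 m (the 20–30 m clump scale), N(0, 10 m) GPS jitter, a 20% site
loss in the last period and one colonization per later period.

Several structural choices were forced by measurement during
development and are worth recording.  On a radially symmetric cone,
distance-to-coast and elevation are a single collinear gradient and
near-shore background overlaps presences so heavily that no model —
including the truth itself — can exceed AUC ≈ 0.87; alongshore
patchiness through *measured* predictors (the dissection) is what
creates real discriminative structure.  Microsite truth terms must be
spatially coherent at ≥ 30–50 m or GPS jitter and consolidation
centroids destroy them (hence the wetness term, whose 90 m window makes
it coherent, and no slope term, since 5 m slope decorrelates within
15 m).  And the ramp-slope variation around the island is what decouples
elevation from distance inside the habitat zone, making both
coefficients separately identifiable at n ≈ 28 under L1 shrinkage.

Calibration targets, checked over multiple seeds before freezing the
defaults: ~25–30 unique recent sites, presence Q90 coastal distance
within 90 ± 30 m, 9–10 LOCO clusters at ε = 250 m, cluster-holdout AUC
of the lq model above 0.9, and negative end-to-end Δ-link responses for
both coastal proxies across RM 1.0–1.4.

What the generator does **not** emulate: tides, substrate and soil
chemistry, biotic interactions, observer heterogeneity beyond a
constant detection probability, and any demographic process — the
period-to-period losses are assigned, not simulated.  Passing tests
therefore show that the *pipeline* recovers planted structure under
realistic survey noise, not that the model would perform equally on any
particular real coastline.

## Scales and run sizes

The demo fits at a 15 m aggregated cell (the fitting-scale default in
`TerrainConfig` is 90 m, appropriate for a full-size island; at 1/6
horizontal scale a 90 m cell would span the entire cross-shore habitat
gradient, so the scenario scales the fitting cell accordingly).  The
background:presence target is 25:1 within 300 m of shore; sweeps use
masks of 300/450/600 m and ratios {10, 15, 20, 25, 30} (the ratio grid
is this package's sampling of the 10–30 range; any integer grid can be
configured).  A full blueprint run takes ~15 s on one CPU; the test
suite, including the end-to-end acceptance checks and a 20-replicate
permutation null, runs in under a minute.

## Known limitations

- The distance-to-coast convention (EDT minus half a cell) differs from
  vector shoreline distance by up to ~½ cell near complex coastlines.
- The coverage of the CORE under Spec0.980 is lower on the synthetic
  island (~0.2–0.3) than would be typical of a full-size system: with
  cloglog scores compressed near the top of the scale in the small
  coves, the 0.98 background quantile is very strict.  The invariants
  (specificity, zero leakage, monotonicities) are unaffected.
- Detection rates per period are descriptive; no occupancy–detection
  model is fitted, so detection probability and occupancy are
  confounded by design.
- Hinge features are exposed but, at these sample sizes, the selection
  grid prefers l/lq — the hinge path is exercised by tests more than by
  the default scenario.
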