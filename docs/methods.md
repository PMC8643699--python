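# Methods

This note documents the models implemented in `hempkite`, their
assumptions, the choices made where a formula or convention was genuinely
open, and what the synthetic-trial generator does and does not emulate.

## Kite geometry

The kite is a planar, bilaterally symmetric abstraction of the canopy
outline. Vertices sit at (0, TRKL) bottom, (±MCD/2, MCDH) lateral, and
(0, HT) top; the trunk below the first branch is excluded from the shape.
Validity requires TRKL < MCDH < HT; violations raise a validation error
naming the offending field. All lengths are carried in cm; area, perimeter
and volume are converted to m², m, m³ at the reporting boundary.

Derived quantities and the conventions behind them:

- **Circularity** KC = 4π·A/P² is the standard isoperimetric shape factor.
  Over all kites it is bounded by π/4, attained exactly when a = b = w (a
  square rotated 45°, branch angle 45°). For symmetric kites (a = b) the
  closed form is KC = (π/4)·sin(2θ) in the branch angle θ, so the maximum
  at 45° is analytic; `max_circularity_search` verifies it by grid search.
- **Branch angle** KBA = arctan(w/a) is measured from the vertical stem
  axis in the lower kite triangle. The complementary convention
  (arctan(a/w)) was rejected: only the stem-axis convention reproduces both
  the observed population mean near 41° and the circularity maximum at 45°.
- **Canopy volume** is the bicone of revolution of the kite about the stem
  axis, V = (π/3)·w²·(a+b). The source analyses used a volume formula whose
  exact form is not printed in the main text; the bicone is the natural
  solid of revolution of the kite and is the documented, configurable
  choice here. Canopy density is wet leaf mass divided by this volume.
- **Specific kite area** uses dry biomass in the denominator (m² kg⁻¹);
  wet biomass can be substituted by the caller.
- **Internode length** is 50/BPAIR from the branching-pair count along
  50 cm of primary stem. Note a population mean of 50/mean(BPAIR) differs
  from mean(50/BPAIR) by Jensen's inequality; the per-plant definition is
  the implemented one.

## Model-II regression

Allometric scaling relations treat both variables as measured with error,
so ordinary least squares (which attenuates slopes) is inappropriate. The
implemented estimators: OLS, major axis (MA, first principal axis of the
covariance), standardized major axis (SMA, sign(r)·sd(y)/sd(x)), and
ranged major axis (RMA): standardize x and y by their observed min–max
ranges, fit MA in standardized space, back-transform the slope by
range(y)/range(x). Intercepts always pass through the centroid. Ranges use
min–max (the conventional ranged-axis choice), log base 10 for allometry
(the exponent is base-invariant). Slope CIs: t-based for OLS; the
correlation-based interval slope·(√(B+1) ± √B) with
B = F₀.₀₅;₁,ₙ₋₂(1−r²)/(n−2) for the model-II estimators (exact for SMA, a
serviceable large-sample approximation for MA/RMA).

Under proportional symmetric errors (error sd the same fraction of signal
sd on both axes) RMA is consistent for the generating slope while OLS is
attenuated; this is property-tested at n=1000 over 200 replicates.

## Foliar traits

- Middle-leaflet area as a pointed oval: (2/3)·L·W, the parabolic-lens
  constant. The exact constant used in the source analyses is unstated;
  2/3 with whole-leaf length reproduces the reported population mean within
  1.5% and is configurable.
- Primary stem volume as a cone, (1/3)π(DIA/2)²·HT. A cylinder is excluded
  because only the cone reconciles the reported diameter, height and
  volume means (cone 814 cm³ vs reported 888 with positive
  diameter–height covariance; cylinder 2441 cm³).
- Specific leaf/petiole area = area/dry mass; leafing intensity =
  leaf count/stem volume.
- Green leaf index (2G−R−B)/(2G+R+B) is computed per pixel and then
  averaged over the mask — not on channel means — with zero-denominator
  pixels dropped and counted.

## Growth and phenology

Heights are smoothed with a cubic smoothing spline whose penalty is chosen
by bisection so that the trace of the hat matrix (effective degrees of
freedom) hits a target; the derivative is evaluated on a 50-point grid and
the maximum and its day reported. The default target is 7 edf for ~10–12
weekly points: R's `smooth.spline(spar=0.35)` — the smoothing the original
growth-rate analyses used — has 6.9 df on a weekly-sampled logistic and
recovers the analytic peak rate rK/4 within 3.5%; a smaller target (e.g. 4
edf) over-smooths and underestimates the peak by ~19%. The peak search is
restricted by default to the log-linear part of the curve, operationalised
as the span of observation triplets whose 3-point log-linear fit has
R² > 0.95 (a heuristic stand-in for an unstated definition; can be turned
off). Series with fewer than 4 points fall back to piecewise-linear slopes
with a warning.

Flowering classes partition pre-terminal flowering day as early (<50 DAP),
mid ([50, 70], closed on both ends — the printed "50–70" is ambiguous),
late (>70). Family segregation summaries report early/mid/late counts and
the closest simple ratio (all-early, all-late, 1:1, 2:1, 3:1 and
reciprocals) by chi-square distance on early vs later counts; this is
descriptive, not a test.

## Disease

AUDPC is the trapezoidal integral of percent severity over assessment days
(defaults 71, 86, 97 DAP), in %·days; it is linear in severities, additive
over contiguous sub-intervals, and bounded by 100·(t_last−t_first) (2600
for the default dates). The absolute form is primary; the relative form
divides by the bound.

## Variance components and heritability

One-way random-effects model per trait: method-of-moments from the ANOVA
expected mean squares with the unbalanced-design coefficient
n₀ = (N − Σnᵢ²/N)/(k−1); σ̂²_ε = MSW, σ̂²_F = max(0, (MSB−MSW)/n₀) with
clamping flagged. REML (statsmodels MixedLM) is a cross-check, not a
dependency. Half-sib heritability h² = 4σ²_F/(σ²_F+σ²_ε); the ×4
multiplier is applied to all families (including selfed ones, as the
original analysis did), with ×2 available for full-sib sensitivity.
Estimates above 1 — possible by sampling noise — are capped at 1 in
reports, with the uncapped value retained.

At 23 families the per-replicate h² ratio estimate carries a small Jensen
bias (≈−0.02 at h²=0.85) and substantial family-sampling noise
(sd ≈ 0.25). Monte-Carlo recovery summaries therefore pool: variance
components are averaged over replicates and h² formed from the pooled
components, which is unbiased and far less noisy.

## Biomass and cannabinoids

The packaged reference calibration maps wet biomass to whole-plant dry and
dry stripped floral biomass with fixed linear coefficients (slopes 0.31174
and 0.156749, residual sds 0.1446 and 0.1031, n=34); fresh calibrations
can be fitted by OLS. Predictions are clamped below at zero. Total
potential cannabinoid = neutral + f·acid with the molar-mass
decarboxylation factor f = 0.877 for the pentyl series and 0.867 for the
propyl (varin) series, both configurable. Cannabinoid yield per plant =
(Σ total %)/100 × DSBM × 1000 g.

## Predictor selection and relative importance

Stepwise OLS selection minimizes AIC = n·log(RSS/n) + 2(k+1) (the
constant-dropping convention; additive constants cannot change selections),
bidirectional from the full model, deterministic tie-breaks by column
order, aliased columns dropped with a warning. Note the standard AIC
penalty retains any given pure-noise column with probability ≈0.157, so
exact-support recovery is not to be expected of this criterion; the tests
assert the correct distributional behavior.

LMG decomposes the full-model R² into per-predictor shares: the average
over all p! predictor orderings of the increase in R² when the predictor
enters, computed exactly by subset enumeration with weights
|S|!(p−|S|−1)!/p! for p ≤ 12 and by Monte-Carlo ordering sampling beyond.
Shares are nonnegative and sum to R² exactly. Bootstrap CIs use case
resampling (default 1000 replicates) at the Bonferroni-adjusted
per-predictor level 1 − 0.05/p.

## Archetypal analysis

Canopy form is summarised by two dimensionless ratios, MCD/HT and MCDH/HT,
and plants are modelled as convex combinations of k archetypes that are
themselves convex combinations of the plants (Z = B·X), so archetypes are
extreme observable forms. Fitting alternates simplex-constrained least
squares: each simplex subproblem is solved by nonnegative least squares
with a sum-to-one augmentation row (weight 200); the Z-update solves the
unconstrained least-squares archetypes and projects them back onto the
data hull through B. Convergence: relative RSS change < 1e-8 or 500
iterations. Initialization is a seeded furthest-point heuristic per
restart (best of nrep=5 by default); k defaults to 4. The scree over
k=1..10 is made non-increasing by warm-starting k+1 from the best
k-solution plus the worst-reconstructed point; the advisory elbow is the
largest second difference of log-RSS (log scale, so a near-zero plateau
after a sharp drop dominates the large early decrements). Hard assignment
is argmax weight with ties to the lowest index; for k > d+1 the simplex
weights are not unique, so reconstructed points (not weights) are the
comparable quantity.

## Aerial trait extraction

The pipeline mirrors a standard UAS workflow: excess green (2G−R−B) on the
RGB orthoimage, Otsu binarization (256-bin histogram argmax of
between-class variance, via scikit-image and verified against an
exhaustive oracle), 8-connected component labeling with a 50-px minimum
blob, centroids mapped to ground coordinates through a GDAL-style
geotransform. Per plant: a fixed 1.83 m × 1.22 m bounding box crops the
point cloud; RANSAC (3-point samples, 0.05 m inlier distance, 500
iterations, seeded, least-squares refit on inliers) finds the ground
plane; canopy height is the 99th percentile of heights above the plane
(robust to stray points; the max is configurable), projected area counts
occupied 0.05 m grid cells, and volume sums cell-max height × cell area.
Vegetation indices (NDVI, GNDVI, GCI, EVI, OSAVI, MSAVI2, MNLI, standard
published forms) are averaged over a 0.28 m circle at each plant center;
NDVI/GNDVI/GCI are invariant to uniform band scaling while
EVI/OSAVI/MSAVI2/MNLI, which contain additive constants, are not.

Rasters are numpy arrays written as TIFF; point clouds are plain XYZ text.

## Synthetic-trial generator

The generator is a pure function of (config, seed); the master seed fans
out into independent per-module streams. Defaults encode the study
conditions: 23 families × 15 progeny with a common parent.

- **Flowering**: one major locus, recessive early allele, common parent
  heterozygous. The default cross mix (2 early-selfed, 6 EE×Ee, 7 Ee×Ee,
  8 ee×Ee families) yields all-early, all-late, ~3:1 and ~1:1 families by
  Mendelian sampling. Class phenotypes: early ~N(42, 3²) DAP, late
  ~N(75, 6²) — calibrated inventions consistent with the reported range
  (28–85 DAP) and family anecdotes, not measured facts. Leaflet number is
  tied to flowering class (means 3.9/5.3/6.3, rounded to odd values).
- **Size cascade**: basal stem diameter is the root latent (lognormal,
  mean 4.44 cm, CV 0.23); height scales as diameter^0.65 and wet biomass
  as diameter^1.7. Measurement error is placed on both log axes in equal
  proportion to the signal sds — the errors-in-both-variables structure
  under which RMA is consistent — at a level giving log-scale R² = 0.78
  for both pairs (the printed biomass fit quality; the height pair's is
  not printed and shares the single diameter error level). Family effects
  enter the diameter latent with σ²_F = h²σ²_P/4 at the configured
  h² (default 0.85), where σ²_P is the observed (error-inclusive) log
  variance. Half the height noise budget follows flowering day, making
  late-flowering plants taller without inflating total scatter.
- **Foliar cascade**: a leafing-intensity latent (negatively tied to
  plant size) drives leaf dry mass (slope −0.71, R² 0.66) and specific
  petiole area (slope 2.08, R² 0.55; this pair is noisier than the
  symmetric structure because the x-error is fixed by the leaf-mass pair,
  so its RMA slope recovery is slightly optimistic — documented, untested).
- **Disease**: a latent susceptibility correlated −0.6 with flowering day
  scales a lognormal severity multiplier on baseline severities
  (16/37/58% at 71/86/97 DAP), inducing an AUDPC–flowering correlation
  near −0.54 after clipping to [0, 100].
- **Biomass**: generated through the packaged calibrations with their
  stated residual sds. **Cannabinoids**: family-level chemotypes
  (87% CBD-dominant / 10% intermediate / 3% THC-dominant), a lognormal
  major-cannabinoid potency with its own family effects, THC:CBD ratio by
  chemotype, independent lognormal minors, and an acid/neutral split
  consistent with the 0.877 decarboxylation ground truth.
- **Growth series**: per-plant logistic curves with asymptote at the
  plant's final height, rate ~N(0.10, 0.012²) d⁻¹, and inflection
  0.55·flowering + 12 d, giving a positive day-of-max-growth–flowering
  correlation.
- **Scenes**: ground plane with 5 mm Gaussian roughness plus cone-shaped
  canopy point clusters (radius 0.22·height + 0.15 m) on the
  1.83 m × 1.22 m grid; rasters at 2 cm GSD with green vegetation on brown
  soil and NIR elevated on vegetation.

What the generator does **not** emulate: spatial field trends and
neighbour competition, lodging and stem breakage, measurement-date drift,
genotype×environment interaction, photoperiod dynamics (flowering classes
are drawn, not driven by daylength), radiometric artefacts, occlusion or
inflorescence structure in scenes, and any marker-level genetics. Passing
recovery tests therefore demonstrates the estimators are correct under the
assumed statistical structure — not that field data meet that structure.

## Problem sizes in tests and scripts

Monte-Carlo summaries use 345-plant trials: 50 seeds for allometric-slope
recovery, 100 replicates for heritability recovery (components pooled as
described above), 200 replicates for the pure one-way recovery property,
and a single full 23×15 scene at 2 cm GSD for the end-to-end aerial check
(≥95% of centers within 10 cm; extracted-vs-true height r > 0.95). These
sizes give Monte-Carlo noise comfortably inside the asserted tolerances.

## Known limitations

- The kite volume and pointed-oval constants are reasoned reconstructions
  of unprinted formulas (flagged above and configurable).
- MA/RMA confidence intervals are approximate (correlation-based).
- REML uses a general mixed-model optimizer; on unbalanced data with tiny
  family variance it may clamp differently than MoM.
- The RANSAC plane assumes the ground dominates each crop box; steep
  terrain or dense canopies violating this will misclassify.
- Archetype solutions are non-convex optima; restarts mitigate but do not
  guarantee globality, and weights are non-unique when k exceeds the data
  dimension + 1.
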