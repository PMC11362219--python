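# Methods

`hurdlemap` implements a two-step ("hurdle") workflow that joins species
distribution models (SDMs, occurrence probability) and species abundance
models (SAMs, individuals per km of survey effort), and converts their
agreement into a 4-level conservation-priority map. This note describes the
statistical procedure, the synthetic study system used to validate it, and
the numerical choices made where the design was genuinely open.

## The modeling procedure

### Occurrence preparation

Raw point records are cleaned by a fixed, documented rule order, so every
removal is attributed to exactly one rule: (1) non-finite coordinates,
(2) outside the species' range polygon, (3) observed before the minimum year
(default 1979), (4) coordinate uncertainty strictly above the threshold
(default 10 km), (5) duplicate (species, x, y, year), keeping the first. The
cleaning report satisfies `input = output + Σ removals` identically.

Cleaned records are collapsed to one per ~1-km² pixel (snapped to the pixel
centroid) and then spatially rarefied with a minimum-distance rule that
adapts to local environmental heterogeneity: records in the top heterogeneity
tercile are thinned at 1 km, the middle at 3 km, the bottom at 5 km. The
heterogeneity statistic is the per-cell mean, over all predictor layers, of
the absolute spatial gradient magnitude of the standardized layer — a
dimensionless multivariate roughness measure. Thinning is greedy in a
seed-shuffled order (ties broken by record order) and is idempotent.

### Calibration area and background

The background-sampling ("calibration") area concentrates pseudo-absences
near the occurrences ("background thickening"): occurrences are single-link
clustered at the hull distance (default 800 km), each cluster gets a convex
hull, hulls are buffered by the assumed annual movement range (default
40 km), and the union is merged with the published range polygon. Whether
the hull distance should be read as pairwise among peripheral points or
relative to a focal centroid is ambiguous; the clustering interpretation is
used and flagged here. With fewer than 3 records the degenerate path buffers
the points directly (logged).

Pseudo-absences (default 10,000) are drawn uniformly without replacement
from unmasked, unoccupied cells whose centroids fall in the calibration
area; a deficit of eligible cells is an error, never a silent shortfall.

### Predictor sets

Predictors come in seven categories (surface water, human impact,
topography, precipitation, temperature, dynamic habitat indices, soil
temperature). Thirteen candidate sets control model *structure*: S1–S7 are
the single categories, S8–S12 gradually combine them, and S13 starts from
every layer. The composition of S8–S12 is configuration-driven; the shipped
default is S8 = {water, human}, S9 = +topography, S10 = +precipitation
+temperature, S11 = +dhi, S12 = all seven.

Every set is decorrelated by the pairwise-|r|/VIF loop: while any pair of
member layers has |Pearson r| > 0.7 on a random cell sample (up to 10⁶
cells, capped at availability), the member of the worst pair with the larger
variance inflation factor is dropped (ties drop the lexicographically later
name — a deterministic convention). S13 is pruned in two stages: within each
category first, then jointly across the survivors.

### Suitability models

Presences and pseudo-absences are pooled, background points unweighted, and
modeled with a binomial logit. Four specifications per predictor set:

* **GLM** — `statsmodels` binomial GLM; the *selected* variant runs backward
  elimination on AIC, guaranteeing AIC(final) ≤ AIC(full).
* **GAM** — a penalized-IRLS additive model (see below); the *selected*
  variant adds a null-space shrinkage penalty so uninformative smooths can
  reach zero effective degrees of freedom.

Evaluation uses 5 independent random 80/20 calibration/evaluation splits
(Monte-Carlo CV; the classic disjoint-fold partition is available by flag —
the two readings of "iteratively 5-fold selecting 80%" are inconsistent, and
the Monte-Carlo reading is the default). Metrics: AUC as the Mann–Whitney
rank statistic (ties counted half) and the maximum TSS
(sensitivity + specificity − 1) over an exhaustive threshold scan. A model
is reliable when mean AUC > 0.7 and mean TSS > 0.4. Binarization uses the
TSS-maximizing threshold of the full-data refit (not pooled CV predictions —
an open choice, flagged), with presence declared at `suitability ≥
threshold` (inclusive, documented) and ties on TSS resolved to the smallest
maximizing threshold.

Predictor relevance for SDMs is permutation importance:
`1 − mean Pearson r` between original predictions and predictions with one
predictor permuted 100 times.

### The GAM engine

No installed Python package provides the needed double-penalty shrinkage
selection, so the additive model is fitted directly by penalized IRLS:

* Basis: degree-3 Bernstein polynomials (a B-spline with no interior knots),
  k = 4 functions per predictor — exactly the space of cubics. The
  sum-to-zero identifiability constraint is absorbed by projecting onto the
  null space of the training-sample column means, leaving k − 1 = 3
  full-rank columns per smooth.
* Penalty: squared second differences of the basis coefficients (unit
  normalized). With selection on, the penalty null space (the residual
  linear trend) is also penalized at a fixed 0.5 relative weight — a
  shrinkage-basis construction, so λ → ∞ removes the whole term.
* Smoothing parameters: per-smooth, chosen by coordinate-wise grid search
  (11 log-spaced points, 2 sweeps) on the deviance GCV score
  `n·D/(n − EDF)²`. For bootstrap refits and CV fold refits the
  full-data smoothing parameters are pinned, which keeps coefficient vectors
  commensurable across resamples and keeps runtime linear in resamples.
* Families: binomial, Poisson, Gamma (log link), negative binomial (θ by
  profile maximum likelihood). Link/variance/deviance algebra is delegated
  to `statsmodels` family objects.
* Predictions for covariate values outside the training range are clamped to
  the training support (polynomial bases extrapolate explosively; clamping
  is the conservative choice and interacts with the fence-based
  extrapolation control below).

A predictor with fewer than k + 1 distinct values is fitted as a linear term
(logged).

### Abundance models

Counts per pixel are modeled with a log link and `log(transect length within
the pixel)` as an offset, so coefficients describe individuals per km. (A
"logistic" link is sometimes quoted for count models in this literature; it
is not definable for unbounded counts, and the canonical log link — which is
also what makes the effort offset additive — is used.) Poisson, negative
binomial (θ by profile ML per resample, averaged θ reported), and Gamma
(strictly positive records only; exclusions logged) families, GLM or GAM.

Coefficients are estimated by bootstrapping the records (default 1000
resamples with replacement), refitting each resample, and averaging the
coefficient vectors; non-converging resamples are redrawn and counted. A
degenerate bootstrap (`n_boot=1, resample=False`) reduces exactly to the
ordinary fit. Fit quality is summarized as explained deviance,
`100·(1 − D(averaged β on original data)/D_null)` with the offset-absorbing
null model, and as observed-vs-predicted consistency: Pearson r (gate
r > 0.7) plus the observed-on-predicted least-squares line to expose scale
bias.

### Hurdle projection and extrapolation control

Abundance is projected only into cells binarized as "presence" by the best
SDM — the hurdle. Because projected rates are right-skewed, extrapolation is
controlled with bootstrap "inner fences": 100 bootstrap resamples of the
pooled projected values, per-replicate `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`
(linear-interpolation quantiles, fixed so the fence oracle is exact),
averaged. The printed 1.5·IQR formula is the default; the medcouple-adjusted
skew variant (`Q1 − 1.5e^{−4M}·IQR, Q3 + 1.5e^{3M}·IQR` for medcouple
M ≥ 0) is available by flag, since the two conventions conflict in the
literature. Fences are computed on the pooled projected-value distribution
per species, not per cell. Two policies: *no extrapolation* masks
out-of-fence cells; *extrapolation and clamping* replaces them with the
nearest fence.

### Abundance–suitability relationship and prioritization

Controlled abundance maps are min–max rescaled to [0, 1] and correlated with
suitability over a seed-deterministic random sample of ~10% of the jointly
unmasked (presence-region) cells: Pearson r, two-sided p, Fisher-z 95% CI.
Both pairing modes exist: same-predictor-set model pairs and best-SDM ×
best-SAM.

Per species, the presence mask and the median-binarized abundance map
(strictly above the median = "highly abundant"; ties at the median go to 0)
give two binary layers; summing the four layers of the two species yields
priority categories 1 (low, one species present) to 4 (very high, both
present and abundant). Hurdle containment (abundant ⇒ present) is validated
before summing because the category legend is meaningless without it.

Critical conservation areas are the very-high patches plus the high patches
intersecting the convex hull of the union of very-high patches (the minimal
convex set connecting them; a per-cluster hull mode exists behind a flag).
Areas are accounted in km² by exact cell-box ∩ polygon geometry on the
planar equal-area grid; protected/unprotected splits satisfy
`protected + unprotected = total` to rounding.

## The synthetic study system

The generator produces the complete study system with known truth:

* **Predictors** — Gaussian-filtered white noise (filter radius = the
  stated autocorrelation range, default 3 km), standardized, then mixed
  through the Cholesky factor of a target correlation matrix, so pairwise
  correlations are controlled exactly in expectation (empirically within
  ±0.1 on ≥100×100 grids). The default scenario has 14 layers — two variants
  per category correlated at 0.8, plus a 0.3 cross-category climate
  correlation — so decorrelation has real work to do.
* **Occurrences** — presence at each cell is Bernoulli with probability
  equal to the inverse-logit suitability; the requested number of records is
  subsampled from the successes. Dirty records (old years, uncertainty
  > 10 km, duplicates, out-of-range and non-finite coordinates) are injected
  in exact per-rule fractions so cleaning tests know the expected removals.
  The default dirty load is 20% of records.
* **Transects** — straight surveys from random start cells in cardinal
  directions, lengths uniform on 2–10 km, one count per intersected pixel
  drawn Poisson or negative-binomial with mean `exp(Xβ + log length)`.
* **Polygons** — a rectangular range, a handful of rectangular reserves
  (~25% coverage), and vertical-band "countries" for zonal accounting.

Default sizes — 200×200 km grid at 1-km resolution, 400 occurrence records
and 44 transects per species, two species — mirror a realistic presence-only
compilation for a widely distributed riparian vertebrate. The validation
suite and the acceptance script run this scenario end to end; smaller grids
and bootstrap counts are used in unit tests where only structure, not power,
is at stake.

What the generator does **not** emulate: imperfect detection (counts assume
every non-hatchling present is seen), river-network transect geometry,
spatially structured sampling bias in occurrences, temporal non-stationarity
of the environment, and real-world raster artifacts (projection distortion,
nodata seams). Passing tests therefore demonstrate the statistical machinery
recovers known structure under clean conditions, not that any field dataset
satisfies these assumptions.

## Determinism

Every stochastic stage (simulation, rarefaction order, pseudo-absence draw,
CV splits, bootstrap resampling, fence bootstrap, correlation sampling)
draws from a stream spawned from the single run seed; a rerun with the same
configuration reproduces every raster byte-identically. Seeds are recorded
in the run report alongside per-stage record counts.

## Known limitations

* The GAM's GCV grid search is coarse by design (speed); smoothing parameters
  are optimized to grid resolution, not to the exact GCV optimum, and REML
  selection is not offered.
* The Bernstein k = 4 basis spans cubics only; response shapes needing more
  wiggle require raising k, which the engine supports but the defaults do
  not exercise.
* Gamma-family abundance on data with zeros requires the documented
  positive-records policy; no zero-inflated or N-mixture alternatives are
  provided (out of scope).
* Spatial autocorrelation of residuals is ignored: no spatial random
  effects, no spatial-block CV.
* Geometry operations assume the synthetic planar equal-area CRS;
  geographic-coordinate inputs must be projected by the caller first.
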