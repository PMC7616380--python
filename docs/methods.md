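# Methods

This note documents the models implemented in `airstack`, the
assumptions behind them, the synthetic test-bed they are validated on,
and the numerical choices that were genuinely open.

## Problem and pipeline

The package reconstructs daily ground-level NO2, PM10 and PM2.5
concentrations (μg/m³) on a regular 1-km grid in a projected planar CRS
from sparse, spatially clustered monitor observations plus gridded
covariates (meteorology, chemical-transport-model output, satellite
proxies with cloud gaps, land use, roads). It runs in stages:

1. **QC** — hourly observations are screened against physical bounds,
   aggregated to daily means only where at least 18 of 24 hourly slots
   (75 %) are present, then filtered per monitor: months with fewer than
   9 daily records are dropped, then monitor-years with fewer than 270
   remaining days are dropped entirely. Co-located monitors from
   different networks whose co-occurring series agree within 1e-6 μg/m³
   are deduplicated, keeping the monitor with most observations (network
   priority, AURN first, breaks full ties).
2. **Stage 1** — PM2.5 is sparse relative to PM10, so monitor-days with
   co-located PM10 but no PM2.5 receive a reconstructed value from a
   yearly LGBM model `PM2.5 = f(PM10, type, yday, dow, month, weekend,
   x, y)`, tuned by random hyperparameter search and validated by
   10-fold monitor-blocked CV. Observations are never overwritten;
   provenance flags (`observed`/`reconstructed`) are kept so downstream
   weighting could be revisited.
3. **Stage 2** — cloud-masked satellite products (AOD-like, columnar-
   NO2-like) are gap-filled by a yearly random forest trained on
   unmasked cell-days from gap-free coarse proxies. The AOD target uses
   exactly the five coarse AOD wavelengths + yday + cell coordinates;
   the NO2 target uses BLH, MSLP, T2M, road density, elevation, urban
   and vegetation fractions + yday + coordinates. Validation is 10-fold
   cell-blocked CV (all days of a cell share a fold). For years with no
   satellite NO2 product at all, the coarse column proxy is substituted
   directly (`substitute_with_proxy`).
4. **Stage 3/4** — a stacked super learner: five base learners (RF,
   XGB, LGBM, ridge, lasso) produce out-of-fold (OOF) predictions under
   10-fold monitor-blocked CV; a non-negative least squares (NNLS)
   meta-learner fits `f̂(x) = Σ wᵢ fᵢ(x), wᵢ ≥ 0` on those OOF
   predictions — no intercept, no sum-to-one constraint, weights
   constant over space and time within a yearly model. Base models are
   then refitted on all data and the weighted combination predicts every
   cell-day of the grid; negative combined values are floored at zero
   and counted.

### Why OOF stacking and blocked folds

Fitting the meta-learner on in-sample base predictions would reward
overfitted learners. The monitor-blocked folds additionally emulate
prediction at unmonitored locations: all observations of a monitor share
one fold, so no model scoring a monitor ever saw any of its series.
For cross-validating the *super learner itself* we avoid a nested inner
CV: base OOF predictions are computed once; to score fold f the NNLS
weights are fitted on the OOF rows of the other nine folds and applied
to fold f's OOF rows. No base or meta model scoring fold f has seen
fold f.

NNLS guarantees, by feasibility of the unit-weight vectors, that the
in-sample residual sum of squares of the ensemble never exceeds that of
any single base learner; this is asserted on every fit and against a
brute-force oracle (support enumeration and a nonnegative coordinate
grid search) in the tests.

## Performance statistics

Skill is summarised by R², RMSE, intercept and slope of an OLS fit of
**observations on cross-validated predictions** (this direction makes
unbiased predictions give intercept ≈ 0, slope ≈ 1). RMSE is computed
from raw observation−prediction differences, never from the fitted
line; it is symmetric in its arguments while slope/intercept are not.
Performance is disaggregated into *overall* (all pairs), *spatial*
(per-monitor means vs per-monitor means) and *temporal* (deviations of
each pair from its monitor's means). The residual sums of squares obey
the exact identity total = between-monitor + within-monitor, checked
numerically to 1e-8. Monitors with a single observation contribute to
the spatial scope only; constant predictions yield an undefined
(NaN-flagged) OLS fit while RMSE is still reported.

## Base-learner settings

* RF is never tuned: 500 trees, ⌊p/3⌋ candidate variables per split,
  minimum node size 5 — conventional regression defaults.
* XGB, LGBM, ridge and lasso are tuned by random search (default budget
  100 draws; the desk-scale experiments use 10) minimising blocked-CV
  RMSE, ties broken to the first draw so the logged draw order fixes
  the result. The search spaces live in
  `ensemble.DEFAULT_SEARCH_SPACES` and are deliberately editable:
  tree counts 100–400, learning rates 0.03–0.2, depth/leaf-size grids,
  and log-spaced penalty strengths for the linear learners.
* Linear learners are standardized internally (their penalties are
  scale-sensitive); tree learners receive raw features.
* Boosted-tree libraries are row-order sensitive, so every fit first
  sorts training rows canonically on (block id, target, features);
  with fixed seeds the whole stage is then invariant to input row
  permutation.

## The synthetic world

`airstack.synth` generates the test-bed that stands in for the real
monitoring networks, reanalyses and satellite products. Per pollutant
the latent field is

    latent(x,y,t) = base + b_bg·B(x,y) + b_peak·P(x,y) + b_urb·U(x,y)
                    + b_tmp·s(t) + ε,

with B a low-rank sum of smooth radial-basis bumps (a cheap,
deterministic stand-in for a Gaussian-process draw with an ~8 km
correlation length), P a road-proximity kernel along generator-chosen
polylines, U an urban kernel, s(t) a winter-peaking seasonal cosine
plus an AR(1) meteorology driver, and ε iid noise. The NO2-like
pollutant has a large road-peak amplitude so it varies at a finer
spatial scale than the PM-like pollutants. PM2.5 is coupled to the
clean PM10 latent (ratio 0.55) so the Stage-1 reconstruction has signal
to learn. Positivity is enforced with a softplus transform rather than
truncation, avoiding a point mass at zero. Covariates are constructed
to be informative the way their real counterparts are: CTM-like fields
are spatially smoothed copies of the truth with bias and noise;
meteorology carries the temporal driver; CAMS-like proxies are gap-free
block averages at 5× coarser resolution; statics (elevation, urban and
vegetation fractions, road density) come from the same spatial
components. Satellite products are gain×truth plus optional noise,
masked under spatially correlated "cloud" blobs built by thresholding
a smoothed Gaussian field at the configured coverage quantile, so the
realized daily masked share equals the configured cloud fraction.

Hotspot monitors are placed preferentially near roads and the urban
core, background monitors uniformly — mirroring the urban clustering of
real networks. All randomness flows from one seed through named
`SeedSequence` substreams (one per field, fixed order), so regeneration
is bit-identical and partial regeneration is reproducible.

**Default conditions** (`WorldParams()`): 40×40 cells of 1 km, 365
days, 20 hotspot + 40 background monitors, observation noise sd
1 μg/m³, 5 % missing monitor-days, +2 μg/m³ hotspot bias, 40 % cloud
cover with a 6-km cloud correlation length. These defaults are the
study conditions for the end-to-end experiments; they are fixed, not
tuned per test.

What the generator does **not** emulate: real coastline/land-sea
geometry, true road-network topology, CAMS/ERA5 physics, instrument
drift, DST or timezone effects, and spatially varying observation-error
regimes. Passing the end-to-end checks therefore demonstrates the
correctness and leakage-safety of the machinery under the assumed
statistical structure, not predictive skill on real GB data.

## Numerical choices

* Relative humidity uses the August–Roche–Magnus formula (a = 17.625,
  b = 243.04 °C) applied to dewpoint and temperature, clipped to
  (0, 100]; wind direction follows the meteorological FROM convention
  (0° = north, clockwise).
* LOO-IDW surfaces: `value(p) = Σ d⁻ᵏAₘ / Σ d⁻ᵏ` over monitors of one
  type, powers 1 and 2; a monitor is excluded from its own surface by
  id (self only — co-located other monitors stay in). A query exactly
  on a remaining monitor takes that monitor's value (the IDW limit);
  excluding the only available monitor flags the value missing.
  Annual means are computed from QC-passed daily values of the same
  pollutant and year being modelled.
* Day-of-week runs 1 = Monday … 7 = Sunday; weekend = {6, 7}; days are
  naive calendar days in local standard time.
* Fold balancing is by block count, not observation count; assignment
  is an unstratified seeded permutation.
* Harmonisation aggregates finer-than-grid rasters by mean/sum/sd or
  per-class fractions and assigns coarser sources by nearest cell at
  the target centres; per-cell class fractions sum to 1, and road
  densities conserve total clipped polyline length.
* Co-location tolerance for deduplication is 10 m; value tolerance
  1e-6 μg/m³. Outlier bounds default to [0, 1000] μg/m³ and are
  configurable per pollutant; every rejection is logged with a reason.
* Boundary-layer height is carried unaveraged as two daily samples
  (`BLH`, `BLH12`); the gap-filling NO2 model uses the 00:00 sample.

## Desk-scale problem sizes

The repository's experiments run on a single CPU, so they use the
default synthetic world (60 monitors × 365 days ≈ 21k training rows),
a tuning budget of 10 random draws with 3-fold tuning CV inside the
10-fold evaluation CV, and a 40k-row training subsample for the
satellite gap-filling forest. The RF keeps its full 500-tree defaults
throughout. These sizes are the package's chosen test conditions; the
pipeline itself scales to arbitrary grids and budgets through its
configuration.

## Known limitations

* The NNLS meta-learner cannot assign spatially varying weights; a
  spatially adaptive meta-learner (e.g. GAM-based) is deliberately out
  of scope because spline extrapolation into sparsely monitored areas
  produces unstable predictions.
* Reconstructed PM2.5 values enter Stage 3 with the same weight as
  observed values (the provenance flag allows revisiting this).
* The land-class collapse mapping, per-year predictor lists and
  traffic-flow linkage of the full application are configuration
  inputs, not built-in data.
* Fold assignment is unstratified; area-based spatial blocking and
  sampling-intensity-weighted CV are not implemented.
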