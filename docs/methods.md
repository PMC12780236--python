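# Methods

`rsfscape` implements a range-wide, multiscale resource-selection-function
(RSF) workflow: telemetry preparation, scale-optimized covariate smoothing,
mixed-effects used/available modelling, suitability prediction,
presence-only validation, and a conservation overlay. Every stage is
driven by a synthetic-data generator with known ground truth, so the whole
chain is testable without restricted field data. This note documents the
models, the defaults and why they were chosen, the numerical decisions,
and the limits of what the synthetic tests demonstrate.

## The selection model

The design is a second-order used/available comparison. For individual
`i`, row `j` is either a GPS fix (`y = 1`) or a background point (`y = 0`)
drawn from the individual's availability domain, and

    y_ij ~ Bernoulli( logit^-1( x_ij' beta + u_i ) ),   u_i ~ N(0, sigma_id^2)

where `x_ij` are covariates smoothed at their retained scales and
standardized, and the per-individual random intercept `u_i` absorbs
behavioural heterogeneity. Because used/available designs identify
*relative* selection strength only, the predicted surface
`w = logit^-1(b0 + sum_c b_c z_c)` is a monotone transform of the
selection score; all downstream instruments (equal-frequency bins, Boyce
index, quartile masks) are rank-based and therefore invariant to that
choice of transform.

The marginal likelihood factorizes over individuals; each 1-D integral is
evaluated by adaptive Gauss–Hermite quadrature. Per likelihood evaluation,
the conditional mode of every `u_i` is found by a Newton iteration
vectorized across individuals (warm-started between evaluations, steps
clipped at 5), the integrand is re-centred at the mode and scaled by its
curvature, and a 7-node Hermite rule is applied. `L-BFGS-B` maximizes over
`(beta, log sigma)` with `log sigma` bounded in `[log 1e-3, log 50]`.
Standard errors are Wald, from the numerically differentiated observed
information of the marginal log-likelihood. On a direct simulation fixture
the estimates agree with `lme4::glmer(nAGQ = 7)` to ~1e-5 in coefficients
and log-likelihood (cross-checked by a test that runs `Rscript`).

Standardized coefficients with |beta| > 15 are treated as complete
separation and raise an error naming the covariate; constant columns are
rejected likewise.

## Pipeline stages and their parameters

**Spatial rarefaction.** At most one fix per 500 m pixel per individual;
the chronologically first fix in a pixel is kept (ties broken by input
order). "Overlap" everywhere in the package means sharing a 500 m pixel —
the analysis unit — not coordinate equality.

**Availability.** The availability radius is `7 * sqrt(home-range area)`
(km), the isometric approximation to median mammalian dispersal distance;
the domain is the union of discs of that radius around the individual's
retained fixes, clipped to the grid.

**Background sampling.** 10 background points per fix (configurable),
uniform over the domain by rejection sampling (capped at 1e6 attempts,
then an error naming the deficit), rejecting draws whose pixel already
holds any point of that individual. Each background point inherits the
calendar month of its fix; temporal matching is at month granularity.

**Train/validation split.** 80% of presences to training, stratified by
individual so every animal appears in both sets; background points follow
their matched fix. Scale optimization and model fitting use training rows
only; the Boyce validation uses the held-out presences.

**Kernel smoothing.** Scales ladder 0.5, 1, 2, 4, 8, 16, 32 km. The kernel
is an isotropic Gaussian with sigma equal to the scale distance, truncated
at 3 sigma (side `2*ceil(3*sigma/res)+1` pixels) and normalized to sum 1.
"Width" is not otherwise pinned down in the multiscale literature; sigma =
scale keeps the 0.5 km scale approximately the native pixel. Edges and
nodata use valid-mass renormalization (no mirroring or zero-padding, which
bias edge cells toward zero); output is nodata where less than 50% of the
kernel mass lies on valid cells. Smoothing is FFT convolution, verified
against a naive double-loop oracle to 1e-10. Kernels wider than 4x the
grid are clipped to the grid dimension with a warning. Scales whose
smoothed layers lack majority-valid coverage on the supplied grid are
excluded from a pipeline run and logged: a 32 km kernel on a 50 km map has
no cell with 50% valid mass, so such scales cannot be estimated on small
grids at all.

**Point extraction.** Containing-pixel value (no bilinear interpolation;
the pixel is the analysis unit). Time-labelled layers are matched to the
nearest label in decimal years; ties (to a 1e-9 tolerance, absorbing float
noise) go to the earlier label. Rows hitting nodata in any required layer
are dropped and counted in the log.

**Scale optimization.** Per covariate, a univariate model (intercept +
random intercept + the covariate at one scale) is fitted at every usable
scale and the scale with the lowest AICc is retained; ties go to the
smaller scale. AICc uses `n` = number of rows (used + available) and
`k` = fixed effects + intercept + variance. The scan standardizes each
column internally (AICc is invariant to linear rescaling) and uses the
Laplace approximation (one quadrature node, as `glmer`'s default); the
final model uses the full 7-node rule. Covariates whose fits all fail are
excluded and logged.

**Covariate selection.** Minimum-redundancy maximum-relevance over the
candidates at their retained scales, with Spearman |rho| against the
response as relevance and mean Spearman |rho| against already-selected
covariates as redundancy, combined by difference. Ties break
alphabetically, making the selection deterministic and invariant to
candidate order. 15 covariates are kept by default.

**Prediction and binning.** Fixed effects only (random intercept at zero),
training-set standardization record applied cellwise. The surface is cut
into 10 equal-frequency bins; tied values share the lower bin, so counts
are equal up to tie spill-over; a constant surface degenerates to a single
bin with a warning.

**Validation.** Boyce index: predicted-to-expected frequency ratio per bin
(expected = valid-cell share per bin; the grid is equal-area, so cell
counts are area weights), Spearman-correlated with bin rank using average
ranks for ties. ROC/AUC by trapezoid over all unique thresholds, the
operating point closest to (0,1), with sensitivity and specificity there.
Density regression: OLS of density records on mean suitability within a
circular buffer of radius sqrt(100/pi) ~ 5.642 km (area exactly 100 km^2).
Raster comparison: Pearson r over jointly valid cells.

**Conservation overlay.** Zone membership is by cell center (half-open
pixels), so partition sums are exact; areas are cell count x 0.25 km^2.
"Highly suitable" is the top quartile, thresholded at the 75th percentile
per stratum with ties flagged inclusively (flagged fraction >= 25%, equal
when values are distinct; a constant stratum flags everything with a
warning; strata under 4 valid cells are skipped). Range-based and
ecoregion-based scenarios differ only in the strata. Protected areas are
merged per country into touching blocks before filtering (block area
strictly > 100 km^2, unit-level maximum elevation strictly < 3000 m,
intersecting the 100 km-buffered current range). Zone proportions fall in
five categories (100–75%, 75–50%, 50–25%, 25–0%, 0%) with boundaries
assigned upward (exactly 50% -> "75–50%") and exact zero its own class.

**Orchestration.** Stages run in the order simulate, prep, scale, fit,
predict, validate, assess. One master seed; per-stage child seeds are
blake2b hashes of `"{seed}:{stage}"` reduced below 2^31, so stages are
individually reproducible. A manifest records the config hash, stage
seeds, row/cell counts and a content hash of every artifact; a rerun with
the same config and seed is byte-identical. Rasters persist as float32
multiband TIFF (nodata -9999) with a JSON sidecar carrying the grid
georeferencing and band names; vectors as GeoJSON; tables as CSV. All
spatial inputs must share one projected equal-area CRS token; nothing is
reprojected silently.

## The synthetic generator

Covariates are stationary Gaussian random fields: white noise convolved
with a Gaussian of sigma = autocorrelation range (default 1000 m) on a
periodic domain, standardized exactly. The grain is deliberately finer
than the smallest candidate scale so that the kernel ladder — not the
field itself — imposes the scale of effect; with a coarser grain the
sub-grain scales become nearly collinear and scale optimization is
uninformative for any estimator.

Telemetry follows the exponential selection law: within each individual's
availability disc, cells are drawn with probability proportional to
`exp(sum_c beta_c z_c)`, where `z_c` is the covariate smoothed at its true
scale and then standardized — so each beta is an effect size in SD units
of the scale-smoothed layer (smoothing shrinks variance; coefficients are
reported standardized). Covariates with beta = 0 do not constrain the
candidate cell set. Fixes are recorded at cell centers with day-precision
timestamps spread over a configurable month window. Zero-beta telemetry
is exactly uniform over the disc (property-tested).

Zones: the current range is the grid footprint; ecoregions are clipped
Voronoi cells of seeded points (an exact partition); countries are
vertical bands; protected areas are disjoint random squares with a country
tag and a maximum elevation.

Recovery-harness conditions (used by the acceptance tests): a 300 x 300
grid at 500 m (150 km side), 5 covariates, 30 individuals x 200 fixes
with 10:1 background, 25 km^2 home ranges — an availability radius of
35 km, well above the recoverable scales, emulating wide-ranging felids
whose availability domains dwarf the scales of effect — and true scales
drawn from {1, 2, 4, 8} km, which are resolvable on a desk-scale grid
(a 32 km kernel exceeds such maps). Under these conditions, coefficient
signs and generating scales (within one ladder step) are recovered in
>= 90% of cases, and the held-out Boyce index of the full pipeline
exceeds 0.7 in >= 90% of replicates. The end-to-end check runs a smaller
configuration (100 x 100 grid, 12 individuals x 100 fixes) appropriate to
a per-replicate smoke run.

What the generator does *not* emulate — and hence what passing tests do
not show about field data: serial autocorrelation of movement paths
(step-length/turning-angle structure), collar duty cycles and fix failure,
location error, covariate measurement error or non-Gaussian covariate
fields, interactions among covariates, and sex- or region-varying
selection. Real-data performance numbers are not reproduced here; the
published validation statistics depend on restricted telemetry and the
original covariate sources.

## Known limitations

* The GLMM treats the random intercept as independent of covariates; in
  used/available designs the implied per-individual intercept is a
  function of disc-level availability, which can correlate with
  broad-scale covariates. With availability domains much larger than the
  candidate scales (the regime both of the harness and of wide-ranging
  species) the induced scale-selection bias is small, but scale estimates
  approaching the availability radius should be treated with caution.
* Scale optimization is univariate per covariate, so strongly correlated
  covariates can each absorb the other's scale signal before mRMR prunes
  them.
* The Boyce index uses the fixed 10-bin variant (not the continuous
  moving-window variant).
* The suitability surface is fixed-effects only; no uncertainty raster is
  produced.
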