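# rsfscape

Multiscale resource-selection functions (RSFs) for range-wide habitat
modelling and conservation assessment, built for spatial ecologists who
have GPS-telemetry of a wide-ranging species, gridded environmental
covariates, and zone polygons (protected areas, priority units,
ecoregions, countries) — and who want the whole chain from raw fixes to a
per-country conservation tabulation to be scripted, seeded, and tested.

The workflow:

1. **Telemetry preparation** — spatial rarefaction to one fix per 500 m
   pixel per individual; an availability domain per animal (union of
   discs of radius `7·√(home-range area)` km, the isometric approximation
   to median mammalian dispersal distance); 10 temporally matched
   background points per fix, none sharing a pixel; an 80/20
   train/validation split of presences stratified by individual.
2. **Scale optimization** — each covariate is smoothed with Gaussian
   kernels at seven scales (0.5–32 km, σ = scale, truncated at 3σ); a
   univariate mixed model per scale retains the scale with the lowest
   AICc, `AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`.
3. **Model** — used/available logistic GLMM with a per-individual random
   intercept, `y ~ Bernoulli(logit⁻¹(x'β + u_i))`, `u_i ~ N(0, σ²_id)`,
   fitted by adaptive Gauss–Hermite quadrature (agrees with
   `lme4::glmer(nAGQ=7)` to ~1e-5); covariates chosen by
   minimum-redundancy maximum-relevance (Spearman relevance/redundancy),
   then a standardized multivariable fit reported as
   (covariate, scale, β, SE, z, p).
4. **Prediction & validation** — a relative-suitability surface
   (inverse-logit of the fixed effects) with 10 equal-frequency bins;
   Boyce index on held-out presences, ROC/AUC with the optimal threshold,
   density-vs-suitability regression in 100 km² buffers, and raster
   correlation.
5. **Conservation overlay** — summed-suitability shares by zone;
   top-quartile "highly suitable" masks computed range-wide or per
   ecoregion; protected areas merged into same-country blocks and
   filtered (>100 km², <3000 m, intersecting the 100 km-buffered range);
   per-zone reports with five proportion categories and a country table.

A first-class synthetic-data generator produces Gaussian-random-field
landscapes, zone polygons, and telemetry drawn from the exponential
selection law `P(use) ∝ exp(β'z)` with known coefficients and known
scales of effect, so estimator recovery is verified end to end. See
`docs/methods.md` for the models, defaults, and limitations.

## Worked example

Run the full pipeline on a synthetic landscape (100×100 cells at 500 m,
5 covariates, 12 individuals × 100 fixes), then read the validation
report:

```python
import json
from rsfscape import RunConfig, run_pipeline

cfg = RunConfig(output_dir="demo", seed=11, grid_rows=100, grid_cols=100,
                n_individuals=12, n_locs_per_individual=100)
manifest = run_pipeline(cfg)
report = json.load(open("demo/validation.json"))
print("held-out Boyce index: %.3f" % report["boyce_index"])
print("AUC: %.3f  sens: %.3f  spec: %.3f"
      % (report["auc"], report["sensitivity"], report["specificity"]))
print("Pearson r vs generating truth: %.3f" % report["pearson_r_vs_truth"])
```

prints (32 km is logged as unsupported on a 50 km map and excluded):

```
held-out Boyce index: 0.902
AUC: 0.899  sens: 0.839  spec: 0.819
Pearson r vs generating truth: 0.729
```

A Boyce index of 0.90 means the held-out fixes concentrate strongly in
the bins predicted most suitable (1 is perfect rank agreement, 0 is
random); the Pearson r compares the estimated surface against the one
implied by the generating coefficients. The fitted coefficient table
(`demo/final_model.csv`) recovers the generating effects — here truth was
β = ±1 on cov00/cov01 (true scale 1 km) with weaker recovery where the
chosen scale differs:

```
covariate,scale_km,beta,se,z,p
(Intercept),,-3.354,0.085,-39.46,0
cov00@1,1,0.923,0.054,17.18,3.6e-66
cov01@1,1,-0.943,0.054,-17.52,9.2e-69
...
```

The same stages are available from the shell:

```bash
rsfscape run-all --seed 11 --out demo          # or: simulate, prep, scale,
rsfscape assess --out demo                     # fit, predict, validate, assess
```

Every stage persists its artifacts (TIFF + JSON sidecar rasters, GeoJSON
zones, CSV tables) and a manifest with content hashes; a rerun with the
same config and seed is byte-identical.

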