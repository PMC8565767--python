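# firegam

Annual wildfire-probability modeling on gridded landscapes: penalized-spline
binomial GAMs, spatiotemporal blocked cross-validation, and counterfactual
covariate decomposition.

## The problem

Where and when wildfire occurs depends jointly on long-term climate (how much
fuel a place can grow, and how dry it gets), short-term climate anomalies,
human activity (ignition pressure near housing and infrastructure,
suppression and fragmentation near agriculture), and how long it has been
since the last burn left a place without fuel. `firegam` implements a
pixel-year modeling pipeline for this problem at a nominal 1-km resolution:
each valid pixel contributes one binary burned/unburned observation per
year, described by nine covariates:

| covariate | description | units |
|---|---|---|
| `aet_normal` | base-period mean annual actual evapotranspiration | mm |
| `cwd_normal` | base-period mean annual climatic water deficit | mm |
| `aet_dev3` | mean AET deviation from normal over the 3 preceding years | mm |
| `cwd_dev3` | mean CWD deviation from normal over the 3 preceding years | mm |
| `housing_density_25km` | mean housing density within a 25-km radius | units/ha |
| `cultivated_fraction` | proportion of the pixel under cultivation | – |
| `dist_roads` | distance to the nearest road | km |
| `dist_electrical` | distance to the nearest transmission line | km |
| `years_since_fire` | years since the most recent recorded burn, capped at 100 | yr |

## The model

The burn indicator $y_i \in \{0,1\}$ for pixel-year $i$ follows a binomial
additive model

$$\mathrm{logit}\, P(y_i = 1) = \beta_0 + \sum_{j=1}^{9} f_j(x_{ij}),$$

where each $f_j$ is a natural cubic regression spline with a small basis
(dimension 5, knots at covariate quantiles) and an integrated-squared-
curvature penalty $\lambda_j \int f_j''(x)^2\,dx$. Fitting is by penalized
iteratively reweighted least squares (P-IRLS) with step halving; smoothing
parameters come from generalized cross-validation on a shared log-spaced
grid (fixed values are also accepted); each term reports effective degrees
of freedom (EDF). Training pixels are thinned by Poisson-disk sampling
(default 5-km minimum spacing) to blunt spatial autocorrelation.

Skill is measured where it matters: years and pixels are each split into
ten random groups, and each CV iteration holds out one temporal and one
spatial group jointly, scoring ROC/AUC separately for novel locations,
novel years, and novel-both test cells. Regional models (per region, spatial
groups reassigned within the region) and leave-one-region-out models are
evaluated the same way and compared with paired t-tests.

Finally, predictions are decomposed by counterfactual parameter
elimination: inactive covariates are pinned to null values (training mean
for climate normals, zero for housing / cultivation / climate deviations,
training maximum for distances), and each sub-model's mean-annual-
probability map is correlated with the observed burn frequency and with the
full model's map.

Because the analysis's real data sources are large proprietary-scale GIS
archives, the package includes a first-class synthetic-landscape generator
with a known additive ground truth (spatially autocorrelated climate
surfaces, growing urban cores, rasterized infrastructure lines, and a fire
process with years-since-fire feedback), so every stage is testable against
the generating truth.

## Worked example

```python
import numpy as np
from firegam import (SyntheticConfig, generate_dataset, build_design_table,
                     poisson_disk_sample, SmoothTermSpec, fit_binomial_gam,
                     assign_cv_groups, run_spatiotemporal_cv, COVARIATES)

cfg = SyntheticConfig(n_rows=48, n_cols=48, year_start=1970, year_end=1999,
                      seed=42)
panel, history = generate_dataset(cfg)
print(f"burn fraction: {history.meta['burn_fraction']:.4f}")

table = build_design_table(panel, history, np.arange(1970, 2000))
pixels = table[["pixel_id", "row", "col"]].drop_duplicates("pixel_id")
sample = poisson_disk_sample(pixels.reset_index(drop=True),
                             min_distance_km=2.0, seed=0)
train = table[table["pixel_id"].isin(set(sample.pixel_id))]
print(f"training rows: {len(train)} ({len(sample)} pixels x 30 years)")

specs = [SmoothTermSpec(name) for name in COVARIATES]
model = fit_binomial_gam(train, specs)
print(f"intercept: {model.intercept:.3f}  total EDF: {model.edf_total:.2f}")

plan = assign_cv_groups(train["year"].unique(), train["pixel_id"].unique(),
                        n_groups=10, seed=1)
cv = run_spatiotemporal_cv(train, plan, specs)
print(cv.mean_auc().round(3))
```

Output:

```
burn fraction: 0.0289
training rows: 12930 (431 pixels x 30 years)
intercept: -4.422  total EDF: 36.02
novelty
novel_both         0.799
novel_locations    0.806
novel_years        0.804
Name: auc, dtype: float64
```

The simulated landscape burns at ~2.9% of pixel-years; after 2-km
Poisson-disk thinning, the fitted model separates burned from unburned
pixel-years with AUC ≈ 0.80 even in years *and* places it never saw — well
above the 0.5 no-skill line, and consistent with a covariate-driven fire
process the model's smooths have recovered.

There is also a CLI (`firegam simulate|features|sample|fit|cv|regional-cv|
loro-cv|decompose|run-all`) over YAML experiment configs; `firegam run-all
config.yaml` writes every artifact (NetCDF panel, CSV tables, JSON model)
with a checksummed manifest.

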