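# jsdmkit

Joint and single-species distribution modelling on presence-background data,
with synthetic landscapes for end-to-end validation.

## What problem this solves

Ecologists mapping the potential range of a species — an invasive bird, say —
usually fit a single-species distribution model (SDM) relating presence-only
records to environmental rasters. A recurring question is whether adding the
*local species community* improves those maps: joint species distribution
models (JSDMs) fit all species simultaneously and estimate a residual
correlation matrix capturing co-occurrence beyond the shared environment.
`jsdmkit` implements both sides of that comparison as one reproducible
pipeline:

* **occurrence preparation** — deduplication, date windows, greedy spatial
  thinning (species-specific foraging radius, then a fixed 3-km filter),
  home-range buffering, background/pseudo-absence sampling outside the focal
  range, predictor extraction and standardization;
* **SDM baseline** — an L1-penalized Bernoulli model over MaxEnt-style
  feature classes (L/Q/H/P/T), with multiplier × feature-class tuning,
  permutation-based percent contribution, backward elimination and
  replicate averaging;
* **JSDM core** — a multivariate probit fitted by Gibbs sampling
  (Albert–Chib latent augmentation, conjugate coefficient draws,
  parameter-expanded inverse-Wishart residual correlation), plus the
  decomposition of each species pair into environmental and residual
  correlation;
* **prediction** — probability-of-occurrence surfaces via
  `Mu = Phi(intercept + sum_p Beta_p P_p)`, averaged over posterior draws;
* **evaluation** — AUC on presences vs background, the maximum
  sensitivity-plus-specificity threshold, sensitivity at multiple evaluation
  cell sizes, seeded 60/40 cross-validation, and a side-by-side comparison
  table;
* **synthetic landscapes** — spatially autocorrelated climate-like and
  patchy urban-like rasters and multivariate-probit communities with known
  intercepts, coefficients and residual correlations, so every stage can be
  tested against ground truth.

## The model at the core

For site *i* and species *j*, with predictor vector `x_i`:

    y_ij = 1[z_ij > 0],    z_i ~ Normal(alpha + B x_i, R)

`R` is a species × species correlation matrix; its off-diagonals are the
*residual correlations*. The *environmental correlation* of a pair is the
Pearson correlation across sites of their linear predictors
`alpha_j + B_j · x_i`. Priors are `N(0, 10²)` on intercepts and coefficients
(standardized predictors) and inverse-Wishart(`J+1`, I) on the expanded
residual covariance. See `docs/methods.md` for the sampler, the prediction
formula and all numerical conventions.

## Worked example

```python
import numpy as np
from jsdmkit import landscape as lsc, jsdm, evaluate as ev

cfg = lsc.LandscapeConfig(
    extent=(34.0, 31.0, 34.4, 31.4), cell_size=0.004, seed=7,
    predictors=[lsc.PredictorSpecification("temp", corr_length=12),
                lsc.PredictorSpecification("urban", corr_length=6, urban=True)])
grid = lsc.generate_predictor_grid(cfg)

truth = lsc.CommunityTruth(
    species=["myna", "sparrow", "starling"], predictors=["temp", "urban"],
    alpha=[-0.5, 0.0, 0.3],
    beta=[[0.4, 1.5], [0.2, 0.9], [-0.8, -0.3]],
    residual_corr=[[1.0, 0.6, -0.1], [0.6, 1.0, 0.0], [-0.1, 0.0, 1.0]])

sites = lsc.simulate_community(grid, truth, n_sites=600, seed=1)
post = jsdm.fit_jsdm(sites, jsdm.desk_preset(chains=2, iterations=6000,
                                             burn_in=1000, seed=2))
print(post.posterior_mean_beta().round(2))
print(jsdm.cooccurrence_summary(post).round(3).to_string(index=False))
scores = post.site_probability(sites.X, "myna")
y = sites.Y["myna"].to_numpy()
print(f"myna AUC: {ev.auc(scores, y):.3f}   "
      f"max sens+spec threshold: {ev.max_sens_spec_threshold(scores, y):.3f}")
```

Output:

```
          temp  urban
myna      0.36   1.41
sparrow   0.11   1.30
starling -0.77  -0.31
            pair  env_mean  env_sd  res_mean  res_sd
    myna:sparrow     0.985   0.009     0.540   0.062
   myna:starling    -0.700   0.068    -0.060   0.085
sparrow:starling    -0.575   0.079     0.122   0.075
myna AUC: 0.783   max sens+spec threshold: 0.248
```

Reading it: the coefficient matrix recovers the simulated responses (the
"myna" loads positively on urbanization, the "starling" avoids warm cells);
the co-occurrence summary separates habitat similarity (`env_mean`, e.g.
0.985 for the two urban species) from residual association (`res_mean`
0.540, recovering the simulated 0.6, while pairs simulated near zero stay
near zero); and the AUC/threshold line is the discrimination summary the
model comparison is built on.

## Command line

The same pipeline is scriptable as a CLI chain:

```bash
jsdmkit simulate --out run --seed 5
jsdmkit prep     --grid run/grid --occurrences run/occurrences.csv \
                 --species-meta run/species_meta.csv --focal focal \
                 --background-n 2000 --date-start 2016-01-01 \
                 --date-end 2018-12-31 --seed 1 --out run/sites.csv
jsdmkit sdm-fit  --sites run/sites.csv --tune --replicates 100 --seed 2 --out run/sdm
jsdmkit jsdm-fit --sites run/sites.csv --preset desk --seed 3 --out run/jsdm
jsdmkit predict  --model run/jsdm --grid run/grid --species focal --out run/jsdm.asc
jsdmkit predict  --model run/sdm  --grid run/grid --out run/sdm.asc
jsdmkit evaluate --sites run/sites.csv --sdm-model run/sdm \
                 --jsdm-posterior run/jsdm --sdm-surface run/sdm.asc \
                 --jsdm-surface run/jsdm.asc --occurrences run/occurrences.csv \
                 --seed 4 --out run/eval
```

`run/eval/comparison.csv` holds the two-model table (AUC, threshold,
sensitivity per evaluation cell size); rasters are ESRI ASCII grids, tables
CSV, metadata JSON.

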