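# Methods

This note documents the models, algorithms and numerical choices behind
`jsdmkit`, and what the synthetic validation does and does not demonstrate.

## The scientific setting

The package compares two ways of mapping the potential distribution of a
focal species — in the motivating use case, an urbanization-associated avian
invader — from presence-only records and environmental rasters:

1. a **single-species presence-background SDM** in the MaxEnt model family,
   driven purely by environmental predictors; and
2. a **joint species distribution model (JSDM)**: a multivariate probit over
   the focal species plus a set of interactor species, which separates
   pairwise co-occurrence into an *environmental* component (similar habitat
   response) and a *residual* component (association left over once the
   modelled environment is accounted for).

Because suitable occurrence datasets are rarely redistributable, the package
ships a synthetic-data module that generates landscapes and communities with
known ground truth; every downstream stage is validated against that truth
or against independent brute-force oracles.

## Synthetic landscapes and communities

**Predictor rasters.** Each layer is smoothed white noise: a standard-normal
field convolved with a Gaussian kernel of standard deviation
`corr_length / 2` cells, then rescaled to the requested marginal mean and
sd. The implied correlogram is approximately
`rho(d) = exp(-(d / corr_length)^2)`, i.e. correlation ~0.37 at one
correlation length. This emulates smooth climate-like gradients; it is not
an exact variogram model and makes no claim about any particular geography.
"Urban" layers are additionally soft-thresholded at +1 sd before rescaling,
giving the patchy, right-skewed structure of impervious-surface data. The
zero-variance case (`sd = 0`) produces an exactly constant layer.

**Communities.** At site *i* with predictor vector `x_i`, species *j* is
present iff a latent normal exceeds zero:

    z_ij = alpha_j + B_j . x_i + e_ij,   e_i ~ N(0, R),   y_ij = 1[z_ij > 0]

with `R` a correlation matrix (symmetric, unit diagonal, positive definite —
validated before any sampling). True marginal probabilities
`Phi(alpha_j + B_j . x_i)` are retained for testing. Site locations are
uniform over valid cells by default; an effort-bias mode samples
proportionally to the urban layer, emulating observation effort concentrated
near anthropogenic centres (a test device for the thinning stage, not a
claim about real sampling). Presence-only records are a Bernoulli
(`detection_rate`) thinning of true presences; absences are never emitted.
Seed streams are consumed in documented order (sites, then latent residuals;
sub-stages spawn from a master `SeedSequence`), so every generator is
bit-reproducible.

**What the generator does not emulate:** temporal invasion dynamics,
abundance, spatially varying detection, georeferencing error, and real
covariate collinearity structure. Passing tests therefore demonstrate
correctness of the estimators under the assumed data-generating process, not
robustness to the full messiness of citizen-science data.

## Occurrence preparation

* **Distances** are great-circle (haversine, IUGG mean radius 6371.0088 km)
  on unprojected WGS84 coordinates — accurate at country scale without a
  projection choice.
* **Thinning** is greedy in input order: a record is kept iff it lies at
  least the radius from every previously kept record. This is deterministic,
  idempotent, and guarantees all pairwise distances ≥ the radius; a seeded
  random-order mode exists. Two radii are applied in sequence: the
  species-specific mean foraging flight distance, then a fixed 3-km
  minimum-distance filter against residual spatial autocorrelation. The
  order (foraging first) is a configuration choice; the two filters commute
  only approximately.
* **Ranges** are unions of great-circle buffers (the species' home-range
  radius) around retained records; range membership defines interactor
  presence/absence at analysis sites. Interactors enter the JSDM only as
  response columns, never as predictors.
* **Background**: 10,000 (default) distinct valid cell centers drawn
  uniformly *outside* the focal range, without replacement; masked cells are
  excluded. Background sites carry focal response 0.
* **Grid conventions**: row-major from the north-west corner, half-open
  intervals on cell edges, cell-center coordinates. Rasters are read and
  written as ESRI ASCII grids with `repr`-printed floats, so surfaces
  round-trip bit-exactly.
* **Standardization**: predictors are standardized to mean 0, sd 1 over the
  retained sites; the constants are stored so prediction grids can be put on
  the identical scale and raw values recovered exactly.

## The SDM baseline

The model is an L1-penalized Bernoulli regression over MaxEnt-style feature
expansions — linear, quadratic, hinge, product and threshold classes, with
10 knots per predictor at equally spaced interior quantiles (frozen at fit
time). This uses the established equivalence between MaxEnt and penalized
logistic regression on presence-background data; it is deliberately *not* a
reimplementation of the sequential-update MaxEnt program, trading exact
replication of that program's path for a reproducible, oracle-checkable
optimization in the same model family.

The regularization multiplier `m` scales a per-coefficient penalty of
`m / sqrt(n)` on the mean log-likelihood (mirroring MaxEnt's `1/sqrt(n)`
default scaling). The intercept is unpenalized; after the solver runs, the
intercept is polished by one-dimensional Newton on its score equation with
coefficients held fixed — a no-op at a converged optimum that also makes the
fully-shrunk limit exact (constant prediction at the training base rate).
Tuning minimizes cross-validated Bernoulli deviance over the standard grid
of seven multipliers (0.25–6) by six feature-class combinations (L … LQHPT);
the criterion is pluggable. Variable importance is permutation-based (drop
in training gain when a predictor's column is permuted, normalized to sum to
100%) rather than the MaxEnt program's path-dependent gain accounting, which
is algorithm-specific and not reproducible outside that program. Backward
elimination drops, iteratively, the lower-contribution member of any
predictor pair with Pearson |r| ≥ 0.75, then any predictor contributing
≤ 1%. Replicate fits (default 100) hold out a seeded random 20% each,
recording held-out AUC and threshold; the ensemble prediction is the
replicate mean, supporting mean ± sd reporting.

## The JSDM sampler

The multivariate probit is fitted by Gibbs sampling with the Albert–Chib
latent-variable augmentation:

1. **Latents.** Each `z_ij` is drawn from its univariate full conditional —
   normal with mean and variance from the partitioned current `R`, truncated
   to `(0, inf)` if `y_ij = 1`, `(-inf, 0]` otherwise. Draws use the inverse
   CDF with uniforms clipped to `[1e-15, 1 - 1e-15]` for tail safety.
2. **Coefficients.** `(alpha, B)` are drawn jointly from the conjugate
   multivariate normal under independent `N(0, 10^2)` priors (standardized
   predictors assumed; the scale is configurable).
3. **Residual correlation.** An expanded covariance is drawn from its
   inverse-Wishart full conditional, `IW(J + 1 + n, I + E'E)` with `E` the
   latent residuals (Bartlett decomposition), then rescaled to correlation
   form; latents and coefficients are rescaled by the same standard
   deviations (parameter expansion restoring the probit's unit-variance
   identification). Every retained `R` is checked symmetric, unit-diagonal
   and positive definite.

With one species the correlation matrix is identically 1, step 3 is a no-op
and the sampler reduces exactly to the univariate Albert–Chib probit — the
basis of the oracle-equivalence test. A switch can freeze `R = I`, under
which the model factorizes into independent probits (checked against
maximum-likelihood probit fits). Species with all-0 or all-1 responses are
rejected by name: complete separation leaves the probit unidentifiable.

Two run-length presets ship: the full-scale protocol (5 chains of 1,000,000
iterations, burn-in 15,000, thinning 1,000 — note the burn-in is small
relative to the run length; the accounting is implemented exactly as stated
rather than "corrected") and a desk preset (4 chains × 20,000, burn-in
5,000, thin 10) used by the tests and examples. Chain seeds spawn from the
master seed at fixed offsets; retention order is chain-by-chain, so
posteriors are bit-reproducible.

**Co-occurrence decomposition.** The residual correlation of a pair is
summarized as the posterior mean ± sd of `R_jk`. The environmental
correlation is, per draw, the Pearson correlation across sites of the two
species' environmental linear predictors `alpha_j + B_j . x_i`, summarized
across draws; it defaults to the fitted sites (a prediction grid can be
supplied instead — the choice matters only when the grid's covariate
distribution differs from the sites'). Convergence reporting uses
rank-normalized split-chain R-hat and effective sample size, flagging
parameters above a configurable 1.1.

## Prediction and evaluation

Per-cell probability follows the probit prediction formula
`Mu = Phi(intercept + sum_p Beta_p P_p)`. The default surface averages `Mu`
over retained draws ("average probabilities"); a plug-in mode evaluates at
posterior means. The two differ by a Jensen gap (`Phi` is convex below 0,
concave above), which is asserted numerically in tests. The analysis default
resolution is 0.0004° with 0.004° for map generation; both are configuration
keys, neither hard-coded, since source protocols use both.

AUC treats background pseudo-absences as the negative class (there are no
true absences) and is the rank-statistic/trapezoid value with ties counted
half. The operating threshold maximizes sensitivity + specificity over
observed score values, ties broken toward the lowest qualifying threshold;
prediction is positive at `score >= threshold` (ties count as presence).
Multi-resolution sensitivity aggregates the thresholded surface to each
evaluation cell size (default 0.004, 0.01, 0.02, 0.03, 0.05 degrees): a
coarse cell is predicted-present iff *any* constituent fine cell is — the
rule under which sensitivity is provably non-decreasing in cell size; a
mean-aggregation alternative sits behind a flag. Cross-validation uses
seeded random splits (default five at 60/40 train/validate), thresholds
derived from training scores only, and redraws (with logging, up to a cap)
any split that loses an entire response class. The comparison table aligns
AUC, threshold and per-resolution sensitivity side by side and deliberately
declares no winner.

## Problem sizes used in the shipped validation

The test suite and the reproduction script run at desk scale, chosen to
exercise every stage meaningfully on a single CPU: landscapes of roughly
40×40 to 250×250 cells, communities of 4–13 species, 800–4,000 simulated
sites, a 2,000-point background sample, 100 SDM replicates, and JSDM runs at
the desk preset (or shorter, clearly-marked reduced lengths for repeated
simulation studies such as interval-coverage checks). Parameter recovery at
these sizes is strong — coefficient posterior means correlate with truth
above r = 0.99, ±0.6 residual correlations are recovered with correct sign
and intervals excluding zero — but headline discrimination metrics on
synthetic strong-signal data (AUC ≈ 0.99) are higher than typically observed
on real occurrence data, and should be read as a correctness check, not a
field benchmark.

## Known limitations

* The sampler stores the full site table in the posterior object; very large
  designs should subsample before fitting.
* Parameter-expanded covariance draws induce a mild finite-sample bias
  toward larger |R| off-diagonals at small n with the `IW(J+1, I)` prior;
  the null-recovery test bounds this at ±0.15 for n = 800.
* Percent contribution is permutation-based and will split credit across
  strongly collinear predictors arbitrarily; backward elimination should be
  run first when predictors are highly correlated.
* The effort-bias sampling mode biases where sites fall but not detection
  given presence; preferential sampling corrections are out of scope.
* No spatial random effects, latent factors, or abundance responses.
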