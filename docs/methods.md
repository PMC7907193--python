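# Methods

## The model

Intensity of space use at camera site `s_i` (i = 1…S, planar metric
coordinates) during sampling occasion `t` (t = 1…T) is the detection rate
(independent events per active camera day), transformed to
`y = log(rate + 1)` and modelled as

```
y(s_i, t) = z(s_i, t) β + ξ(s_i, t) + ε(s_i, t)
```

- `z` is the vector of covariates, each mean-centred and scaled to unit
  sample sd over cells with an observed response (the scaling is stored and
  reapplied at prediction time);
- `ξ` is a zero-mean Gaussian field with **separable** space–time
  covariance: Matérn correlation with smoothness ν = 1 across sites and a
  first-order autoregressive process with coefficient `a` across occasions.
  The innovation marginal variance is `σ²_ω`, so the stationary marginal
  variance of the field is `σ²_ω / (1 − a²)`;
- `ε` is an iid Gaussian nugget with variance `σ²_ε` (measurement error).

The Matérn range uses the two-dimensional convention `ρ = √8/κ`, under
which correlation has decayed to ≈ 0.13 at distance ρ; with ν = 1 the
correlation function is `(κd) K₁(κd)`. Separability means the joint
covariance over all S·T cells is a Kronecker product
`Σ_T ⊗ R_S + σ²_ε I`, which the likelihood and sampler exploit: log
determinants and quadratic forms reduce to operations on an S×S and a T×T
matrix, and the full dense matrix is only formed (cheaply, S·T ≈ 500) when
subsetting to observed cells.

Missing responses (camera inactive for more than 7 days in an occasion)
drop out of the likelihood; the latent field is defined at every cell, so
missing cells get model-based predictions for free.

### Assumptions

- Gaussian errors on the log(x+1) scale — adequate at moderate rates;
  counts are not modelled as counts.
- Stationarity and isotropy of the spatial field; a single AR(1)
  coefficient shared by all sites.
- Separability: the spatial pattern does not change shape over time, only
  evolves with AR(1) persistence.
- Covariates are error-free except where explicitly imputed (below).

## Inference

A Metropolis-within-Gibbs sampler, deterministic given a seed:

1. **β | ·** — Gaussian full conditional under the `N(0, 1000)` prior on
   each coefficient (intercept included).
2. **ξ | ·** — one joint Gaussian draw of all S·T field values. The prior
   precision is `Σ_T⁻¹ ⊗ R_S⁻¹` (the AR(1) inverse is tridiagonal); adding
   the diagonal data precision gives a ~500×500 posterior precision whose
   Cholesky factorisation is the per-iteration cost bottleneck (~ms).
3. **σ²_ε | ·** — conjugate inverse-gamma (prior shape 1, rate 5·10⁻⁵ on
   the precision, a common weak default).
4. **(a, ρ, σ²_ω) | ξ** — joint random-walk Metropolis on the transformed
   vector (atanh a, log ρ, log σ²_ω). Priors: Fisher-z of `a` ~
   N(0, 1.5²); log ρ ~ N(log median inter-site distance, 1²); a gamma
   (1, 5·10⁻⁵) prior on the innovation precision expressed on log σ²_ω.
   Proposal scales adapt toward 30% acceptance during burn-in and are
   frozen afterwards, preserving detailed balance in the sampling phase.

Defaults are 20 000 iterations, 5 000 burn-in, thinning 5; the test-suite
and acceptance runs use 1 100–2 000 iterations with 400–600 burn-in, which
the recovery experiments show is sufficient at this data size (S·T = 504,
well-identified coefficients). Convergence is screened with split-R̂ on the
coefficients; values above 1.1 set a `converged = False` flag and log a
warning rather than failing silently.

Posterior summaries report mean, sd, 2.5/50/97.5% quantiles and a mode
taken from the peak of a Gaussian kernel density of the marginal draws.
A coefficient is flagged "significant" when its 95% credible interval
excludes zero.

### DIC

Model comparison uses the deviance information criterion with the deviance
**conditioned on the latent field**: `D(θ) = −2 log p(y | β, ξ, σ²_ε)`,
`p_D = D̄ − D(posterior means)`, `DIC = D̄ + p_D`. This latent-scale DIC is
flagged explicitly because marginalised alternatives exist and give
different absolute values. Calibration: feeding the exact conjugate
posterior of a known-variance linear model (no field) into the same code
returns `p_D` equal to the coefficient count to within 0.5.

Backward selection starts from the full covariate set, refits every
drop-one model, removes the covariate whose removal most lowers DIC, and
stops when no removal improves it; every evaluated model is logged. An
explicit candidate-model list is also accepted.

### Imputing an incomplete covariate

When an auxiliary series (human detection rates) is wanted as a covariate
but has missing cells, the same spatiotemporal model is first fitted to the
auxiliary response on its own predictors; the posterior mean of the **full
linear predictor** `η = zβ + ξ` at every site × occasion then serves as the
complete covariate. The full η (not ξ alone) is used because it carries the
covariate signal and is the quantity that correlates with the observed
auxiliary values; that Pearson correlation is returned as a fidelity
diagnostic, with a configurable warning floor (default 0.8).

## Diel activity

Event clock times map to angles (hour × 2π/24; clock time, no solar
correction). Densities are von Mises KDEs with the Taylor (2008) plug-in
concentration `ν = (3n κ̂² I₂(2κ̂) / (4√π I₀(κ̂)²))^{2/5}`, where κ̂ is the
ML von Mises concentration capped at 3 (near-unimodal rules
over-concentrate on multimodal diel data). The coefficient of overlapping
uses the grid estimator Δ1 (512-point rectangle rule, bandwidth multiplier
0.8) when the smaller sample has n < 75, else the point-evaluation
estimator Δ4 (multiplier 1.0) — the standard guidance for these
estimators. Confidence intervals come from a smoothed bootstrap (resample
angles, add kernel-scale von Mises noise; default 1 000 resamples,
percentile interval clamped to [0, 1]). Activity level is
`â = min(1, 1/(2π max f̂))` — 1 for uniform activity — with a bootstrap SE,
and two levels are compared by a Wald statistic against χ²₁.

## Food availability

For a species group, availability at one survey is
`F_m = Σ_k F_k · D_k · S_k`: mean 0–4 ripe-fruit score over the monitored
individuals (missing individuals skipped, not imputed) × adult stem density
(stems/ha over the total surveyed plot area) × mean adult DBH (cm). The
site-level variant recomputes both D_k and S_k from the plots inside the
site's 200 m buffer while keeping the global score — both quantities are
site-specific because the buffer's own composition is what the camera
samples. Units are a score·density·cm composite with no physical name;
this is harmless downstream because model covariates are z-scored. Adult
DBH thresholds are per-species configuration with a 10 cm default (the
survey's measurement floor).

## Prediction surfaces

Distance covariates are evaluated exactly at grid-cell centres from the
geometry. Availability covariates are extended from the 21 site values by
inverse-distance weighting (power 2), chosen because it interpolates
exactly at the sites and cannot overshoot the observed range. Both are then
standardized with the training scaling record.

For each retained posterior draw, the field at the grid is simulated from
its conditional Gaussian given that draw's site-level field (simple
kriging; separability makes the weights purely spatial), cell-wise — i.e.
marginal conditional simulation, sufficient because the map reports
per-cell posterior means, not joint functionals. The layer value is the
average over draws of `exp(zβ + ξ) − 1`, the inverse of the response
transform, floored at 0. Kriging is exact at observation nodes as the
nugget vanishes. Default cell size is 50 m — fine relative to the 200 m
buffers, coarse enough for dense kriging — with optional clipping to the
100% MCP home range. Output is ESRI ASCII grid (plain text, any GIS reads
it) plus PNG quicklooks; no cartographic styling.

## The synthetic generator

The generator emulates the survey design the package targets: 21 camera
sites with ≥ 500 m spacing in a ~5 km extent (matching a ~650 m mean
inter-trap distance), a forest block with agriculture, three villages, five
settlements and two roads; 24 contiguous 15-day occasions with mid-occasion
phenology surveys; 0–4 scores following raised-cosine seasonal pulses with
survey noise proportional to amplitude, configured so village-only fruits
peak (occasion ~8, Oct–Jan for a July start) when wild fruits trough (peak
occasion ~20) — the inverse seasonality that makes village food a risk
trade-off proxy; a latent field with a = 0.7, ρ = 1500 m and small
variances on the log-rate scale; and a detection stream built by inverting
the response transform (`count = round((exp(y) − 1) · active days)`,
floored at 0) and scattering counts as minute-resolution timestamps from
class-specific diel curves, spaced > 30 min within a day so event
assignment is exactly invertible. A second, human, stream declines with
distance from villages at roughly 1.3× the chimpanzee event total and has
its own diel curve. Camera outages longer than 7 days generate the missing
cells.

What it does **not** emulate — and therefore what passing tests cannot
show about real data: non-Gaussian overdispersion of real counts, detection
probability varying with vegetation or camera placement, behavioural
responses to the cameras, spatially clustered (rather than independent)
outages, anisotropy, and any feedback between the two species' streams.
Recovery results on generated data demonstrate correctness of the
machinery, not robustness to model misspecification.

The default effect sizes mirror the qualitative structure of the motivating
system (positive distance-to-village and palm-fruit effects, negative
distance-to-road effect, positive village-fruit effect) and are
illustrative, not a reproduction of any fitted values.

## Numerical choices

- Matérn evaluation guards d = 0 (limit 1); spatial correlation matrices
  get a 10⁻¹⁰ diagonal jitter before Cholesky.
- Likelihood construction subsets the dense Kronecker covariance to
  observed cells; verified against an independent dense multivariate-normal
  construction to 10⁻⁸ on hundreds of random instances (≤ 120 cells).
- Event chaining compares timestamps at minute resolution; the merge rule
  is *strictly less than* the gap, so a photo exactly 30 min after the
  previous one starts a new event (a testable boundary).
- Occasion boundaries default to the floor of the midpoint between
  consecutive phenology dates; explicit boundary lists override.
- z-scoring uses the sample sd (ddof = 1); constant columns raise an error
  naming the covariate.
- Degenerate inputs fail loudly: empty feature sets, all-zero availability
  series, collinear home-range points, |a| ≥ 1, non-positive variances.

## Problem sizes used by the test suite and acceptance script

Likelihood oracle: 500 (tests) / 200 (script) random instances ≤ 120
cells. Parameter recovery: 30 (tests) / 12 (script) seeded 21 × 24 studies
with 2 true + 2 null covariates at 1 100 MCMC iterations. Stepwise
selection consistency: 10 replicates at 12 sites × 10 occasions, 500
iterations. Overlap estimators: n = 500–2 000 events per sample. These
sizes give stable pass/fail behaviour at desk scale while exercising
exactly the code paths used at full scale.

## Known limitations

- Dense-covariance algebra limits practical problem size to a few thousand
  cells; a sparse SPDE-style backend would be the natural extension.
- Single-chain inference; split-R̂ on halves is a screen, not a guarantee.
- The latent-scale DIC is not comparable with marginalised DICs from other
  software.
- No solar-time correction in diel analysis; clock time only.
- Distances are planar Euclidean in one projected CRS; no geodesy, no
  reprojection.
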