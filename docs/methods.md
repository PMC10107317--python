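# Methods

This note documents the statistical model, the numerical choices behind
its implementation, the synthetic-data generator used for validation, and
the design decisions taken where the problem was genuinely open.

## The trend model

Per-sample aggregate counts (the summed abundance of one taxonomic group,
family or trophic guild in one kick sample) are modelled as overdispersed
Poisson:

    y_i ~ Poisson(λ_i)
    log λ_i = x_i'β + u0_s(i) + u1_s(i)·t_i + v_t(i) + ε_i

* `t = calendar year − 2002`, an integer 0–17 for the default 2002–2019
  window.
* Fixed effects `x_i'β`: intercept and year for the national model;
  reference-coded river-typology main effects and year × typology
  interactions for the typology model (reference class: alphabetically
  first, Calcareous/High).
* `(u0_s, u1_s)` — site random intercept and slope, bivariate normal with
  estimated correlation.  They absorb spatial pseudoreplication and
  between-site heterogeneity in trends.
* `v_t` — a year random intercept shared by all samples of year t,
  damping the influence of single good or bad years on the fixed trend.
* `ε_i` — an observation-level random effect (OLRE), one independent
  normal intercept per response row, giving a Poisson-lognormal marginal
  distribution that accommodates the non-zero-inflated overdispersion
  typical of kick-sample counts.

Reported per-model quantities: Wald z-tests for the fixed effects
(coefficient / SE against a standard normal), random-effect SDs, the
maximized marginal log-likelihood, AIC = −2ℓ + 2p and
BIC = −2ℓ + p·ln(n) with p = n_fixed + n_variance-parameters, and a
likelihood-ratio test (χ² reference) for nested comparisons such as
typology model vs national model.

### Estimation

The marginal likelihood integrates over all random effects; we maximize
its Laplace approximation, the standard approach for Poisson mixed models
of this size.  Two nested optimizations:

* **Inner:** for fixed variance parameters θ, the joint penalized Poisson
  log-likelihood is maximized over (β, u) by damped Newton iterations.
  The Newton system is never formed densely: the OLRE block is diagonal
  and eliminated first (leaving per-observation working weights
  w_i = μ_i/(1 + μ_i σ²_olre)), the site blocks are independent 2×2
  systems eliminated next, and only a dense core of dimension
  (n_years + n_fixed) — at most ~30 — remains.  Each iteration is O(n).
  Inner convergence: gradient ∞-norm below 1e-9·(1 + |objective|),
  typically 3–8 iterations with warm starts.
* **Outer:** L-BFGS-B with finite-difference gradients over the
  unconstrained parameters (log SDs, atanh-scaled site correlation),
  bounds log σ ∈ [−8, 3].  Start values: all log SDs at ln 0.5,
  correlation 0, β from an ordinary Poisson GLM (statsmodels).  The fit
  is deterministic given the data and options.

The Laplace log-determinant is taken over the random-effect block only
(β is profiled, not integrated), matching standard mixed-model practice.
The fixed-effect covariance is the inverse Schur complement of the β
block of the full joint Hessian at the optimum.

Convergence is flagged when the optimizer's relative-improvement
criterion is met or the projected-gradient norm falls below the `tol`
option (default 1e-4 — chosen because finite-difference gradients on
log-likelihoods of magnitude 1e4–1e5 carry noise of roughly that size).
Predictions from a non-converged fit warn rather than fail, so long
simulation loops degrade gracefully.

### Accuracy

On small instances with a single random-effect term the Laplace
log-likelihood is checked against adaptive numerical integration
(`tests/_oracles.py`, an independent implementation); observed gaps are
below 0.05 nats, against a 0.5-nat acceptance band.  Parameter-recovery
simulations (200 sites × 18 years × 2 seasons, variance components at the
magnitudes typical of national fits) recover a true slope of 0.02 within
±2 SE in ≥ 90 % of replicates with no detectable bias, and with a null
slope the Wald test rejects at the 5 % level in ≤ 10 % of replicates
(binomial tolerance).

### Derived quantities

Population-level predictions set all random effects to zero:
ŷ_t = exp(β₀ + β₁t) plus typology terms where applicable.  No
retransformation (lognormal mean) correction is applied by default — the
prediction is the conditional mode, matching the workflow the trend
categories were designed around; the exp(Σσ²/2) marginal correction is
available behind a flag.  Then

    Ѱ   = (ŷ_last − ŷ_first)/ŷ_first × 100        (total change, %)
    AGR = Ѱ / divisor                              (annual growth rate, %/yr)

Under population-level prediction Ѱ = 100·(exp(17 β₁) − 1) exactly.  The
divisor defaults to 18, the length of the yearly series, which is the
convention the published per-group AGR values follow; the alternative
reading (17 yearly steps) is supported and both are recorded in the
pipeline's fit metadata.

### Trend categories

Categories partition (AGR, significance) space.  Insignificant trends
(p > 0.05) are "no change".  Significant trends: AGR ≥ 2.81 → strong
increase, 1.16 ≤ AGR < 2.81 → moderate increase, −2.73 < AGR ≤ −1.14 →
moderate decrease, AGR ≤ −2.73 → strong decrease.  The 2.81/−2.73
endpoints are the closed forms 100·(2^(1/25) − 1) and 100·(0.5^(1/25) − 1)
— doubling/halving over 25 years; the provenance of the 1.16/−1.14
moderate bounds is purely conventional and they are kept as printed, with
`doubling_threshold(horizon)` available to build alternative schemes.  A
significant trend whose AGR falls inside (−1.14, 1.16) is labelled
"no change" with an explicit significant-but-small note rather than
silently absorbed.

## Filtering and aggregation

"At least 3 years in both seasons" is read as ≥ 3 calendar years that
each contain at least one spring and one autumn sample (the joint
reading); the independent reading (≥ 3 spring-years and ≥ 3 autumn-years
separately) is a configuration switch.  The coverage rule selects sites,
not samples: out-of-window-month samples at qualifying sites stay in the
modelling dataset by default, with a flag to restrict to spring+autumn.
Filtering is idempotent, and raising the minimum-year threshold can only
shrink the retained site set.

Aggregation conserves per-sample totals for resolvable taxa.  Absence is
encoded as *no row* in the raw aggregates, but trend models need explicit
zeros, so a materialization step fills the (sample × unit) grid with
zeros — on by default for group- and trophic-level aggregation, off for
families (where the unit universe is too sparse for a meaningful grid).
A taxon belonging to several trophic guilds (joint maximal diet scores)
contributes its full count to each guild, so trophic totals are not
additive across guilds by design.

## Trophic allocation

Genus profiles come straight from the trait table.  Family and
higher-group profiles are abundance-weighted means over member genera,
with weights equal to each genus's total summed abundance across the
whole filtered dataset (a single global weighting, not per site or per
subset): common genera should dominate the inherited diet of a family
record.  Weighted profiles are convex combinations (bounded by member
scores, invariant to weight rescaling); trait rows are used as published
without renormalizing row sums, with an optional renormalization mode for
sensitivity analysis since taxa whose fuzzy codes sum higher would
otherwise carry slightly more influence.  A profile whose unique maximum
is "microorganisms" maps to no guild and is flagged, never silently
dropped; all-zero profiles are errors.

## River typology

Dominance is the strict per-sediment maximum among chalk, limestone,
clay, hard rock and peat; ties (within 1e-9) or missing values exclude
the site.  An alternative pooled mode takes the maximum over the three
geology classes after summing constituent sediments — the two modes can
disagree (e.g. chalk 0.25 + limestone 0.25 vs clay 0.4), and the strict
per-sediment rule is the default because it reproduces the exclusion
behaviour of the reference classification.  The altitude boundary is
inclusive: exactly 200 m is High.

## The synthetic-data generator

The generator draws from exactly the hierarchy the model assumes, so it
provides known ground truth for every downstream stage.  Defaults are the
study conditions the pipeline targets: an 18-year series (2002–2019),
spring/autumn sampling with per-site-year-season inclusion probability
0.4 (reproducing the roughly 0.75 samples per site-year of the national
dataset), typology mix proportional to the national site census
(525, 3289, 72, 45, 525, 553 over the six classes), and variance
components at the magnitudes of the national fits (site intercept SD 1.0,
site slope SD 0.06, year SD 0.1, OLRE SD 0.9).  The default community is
three single-genus groups, one per trophic guild, with baselines and
trends at the national trophic-level estimates.

Choices worth knowing:

* Counts for different taxa within one sample share the year shock and
  site effects but draw independent OLRE deviates — the OLRE mirrors the
  model's per-response-row random effect.  Within-sample dependence
  between taxa beyond these shared effects is not simulated; nothing in
  the monitoring data constrains it, and the independence assumption is
  the conservative choice for validating a model that also assumes it.
* No seasonal effect by default (the trend model has no season term); an
  optional fixed autumn offset exists to test robustness.
* Zero counts are emitted as records by default so the complete design is
  visible; a drop-zeros mode emulates real survey encoding, and the
  aggregation's zero-materialization makes the two equivalent.
* One seed, per-site sub-streams spawned deterministically: identical
  configurations are byte-identical, and the sampling indicator is
  monotone in the inclusion probability under a fixed seed.
* Sediment shares give the intended dominant sediment a 0.55–0.90
  majority, so generated sites always classify to their intended type.

What passing synthetic tests do **not** show: robustness to spatial
autocorrelation between sites, taxonomic misidentification, non-linear
trends, or trait–abundance feedbacks — none of which the generator
emulates.

## Problem sizes in the validation suite

Simulation scales were fixed by a priori power analysis, before any
results were inspected:

* Slope recovery: 50 replicates of 200 sites × 18 years × 2 seasons
  (7200 rows each); expected SE(β̂₁) ≈ 0.006 at the default variance
  magnitudes, so ±2 SE coverage is a sharp test of both point estimate
  and standard error.
* Type-I error: 100 null replicates of 100 sites.  The pass bound of
  15/100 rejections is the 95th percentile of Binomial(100, 0.10).
* End-to-end guild recovery: 10 runs of 400 sites with small interannual
  and site-slope noise (SDs 0.003, OLRE 0.2, sampling probability 0.9).
  The generating guild trends imply AGRs of +1.06, +0.82 and −1.21 %/yr,
  which sit only 0.07–0.10 from the printed category boundaries; at the
  default noise magnitudes the estimated category would be a near
  coin-flip for any correct implementation (SE(AGR) ≈ 0.25), so this run
  uses a configuration with SE(AGR) ≈ 0.03, making the expected category
  identifiable while the default-noise condition is exercised by the
  slope-recovery test instead.

## Known limitations

* The Laplace approximation is least accurate for very small counts with
  large OLRE variance; the quadrature comparison covers sd ≤ 1.2 and the
  national-magnitude simulations sd ≈ 0.9.  Adaptive quadrature per
  random effect (beyond the validation oracle) is not implemented.
* Wald tests use the normal reference; with only 18 year levels the year
  variance is estimated with few degrees of freedom, which can make the
  type-I error mildly anti-conservative (observed ≤ 10 % against a 5 %
  nominal level in the validation suite).
* The sensitivity correlation (trends under 3-year vs 10-year coverage
  rules) implements the mechanism; its value on real data depends on the
  dataset and is not a fixed quantity of the package.
* Family-level trend fitting uses the same machinery but no zero
  materialization; extremely sparse families should be interpreted with
  care or excluded by the caller.
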