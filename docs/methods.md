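# Methods

This note documents the models, algorithms and design choices behind
`crowdasym`, in the order the pipeline runs them.

## Psychometric model of the simulated observer

Responses in the 9AFC letter-identification task are Bernoulli draws from the
Watson–Pelli Weibull psychometric function,

    Psi(x) = delta*gamma + (1 - delta) * [1 - (1 - gamma) * exp(-10^(beta*(x - t) + eps))]

with `x` and `t` the log10 letter size and log10 threshold, `gamma = 1/9` the
9AFC guess rate, `delta = 0.05` the lapse rate and `beta = 3.5` the slope.
Lapse trials still succeed at chance (the `delta*gamma` term), so the
asymptotes are `gamma` below and `1 - delta*(1 - gamma) = 0.9556` above. The
offset `eps` is fixed in closed form so that `Psi(t)` equals the threshold
criterion of 0.5 exactly:

    10^eps = -ln[ (1 - (c - delta*gamma)/(1 - delta)) / (1 - gamma) ]

giving `eps = -0.2096` at the defaults. The function depends on size and
threshold only through their log ratio, so it is invariant to joint
rescaling; letter identity confusion structure is not modelled — responses
are correct/incorrect only.

The configured guess rate is exactly 1/9 (one target among nine response
alternatives); a printed value of 0.11 is its two-decimal rounding.

## Synthetic population

The generator parameterises ground truth the way the analysis interrogates
it. Per (design, location) cell: an unflanked median threshold, an inward
crowding factor `cf >= 1` (inward-flanked = unflanked x cf) and an asymmetry
`ioa > 0` (outward-flanked = unflanked x cf x ioa). Observers deviate from the
population medians through centred normal offsets on the same varying-effect
basis the regression uses (intercept + location/flanker/design dummies), in
log10 units.

Default study conditions, chosen once: 38 observers; unflanked median 0.6 deg
at every location (a typical peripheral letter acuity at 7.5 deg
eccentricity); inward crowding factor 2.0 and IOA 2.5 in every cell (within
the 1.5–4.5 range such studies report, and strong enough that a cohort-level
analysis must find it); between-observer SD 0.1 log10 units on the intercept
and 0.05 on the other varying effects, giving cohort threshold spreads of
roughly +/- 25% around the medians. These are deliberately homogeneous across
cells: the generator defines a known truth for recovery experiments, not a
facsimile of any particular human dataset. What passing recovery tests show
is therefore that the chain staircase -> exclusion -> model -> ratios is
unbiased and calibrated *when the model family matches the generator*; they
do not certify behaviour under model misspecification (e.g. non-lognormal
observer noise, trial-to-trial threshold drift, or attention effects beyond a
shift in true thresholds, none of which the generator emulates).

## QUEST staircase

The staircase maintains an unnormalised log posterior over a grid of log10
thresholds. Defaults: Gaussian prior centred at log10(1.1 deg) with SD 3
log10 units; grid spanning the prior mean +/- 5 prior SDs in steps of 0.005
log10 units, so the prior is represented essentially untruncated (a fresh
state reports its full SD of 3.0) and the step is far below the 0.2-log10
exclusion cutoff. Each trial multiplies in the Weibull likelihood of the
observed response at the size actually shown. Placement is the posterior
mean of log10 threshold (the standard recommendation; the mode is a
documented one-line change), exponentiated and clamped to the displayable
[0.1, 3.0] deg range — the likelihood is always evaluated at the clamped,
displayed size.

Each cell is measured by two independent fresh-prior adaptive runs of 40
trials; the pooled 80 (size, correct) pairs are then re-evaluated through the
same Bayesian update starting again from the fresh prior. This pooled pass is
a pure re-analysis — likelihood products commute, so it is order-invariant —
and its posterior mean and SD are the cell's threshold estimate and
reliability. Because staircase state lives per cell, estimates are
independent of how trial slots interleave across blocks; the scheduler
(`design_core.build_schedule`) still produces a physically faithful
interleaving (blocked-design blocks hold one location; flankers exactly
balanced within every block) for anyone consuming trial tables, and session
structure is carried as metadata only.

Numerical notes: the Weibull exponent is clipped at 10^±300 before
exponentiation; likelihoods are clipped away from 0 and 1 before taking logs
(the lapse and guess floors keep them far from the clip in practice);
posterior moments are computed after max-subtraction normalisation.

## Reliability exclusion

Thresholds whose pooled posterior SD exceeds 0.2 log10 units ("log units"
read as log10, the staircase's native convention) are flagged — strictly
greater, boundary retained. Rows are flagged rather than deleted so cohort
counts stay auditable; the modelling stage drops flagged rows. Percentages
are reported to the nearest integer.

## Multilevel lognormal regression

Each retained threshold is modelled as

    y ~ LogNormal(eta, sigma),  eta = x(cell)' beta + z(cell)' b_p,
    b_p ~ Normal(0, diag(tau^2))

on the natural-log scale. The fixed-effect coding uses four location
intercepts (no global intercept), inward/outward flanker dummies,
pre-cued/random design dummies, and all two- and three-way interaction
dummies — 36 columns of full rank, so every cell mean is reachable.
Varying effects are the intercept plus the main-effect dummies (8 per
observer). Priors: N(1, 2) on the location intercepts, N(1, 0.5) on the two
flanker main effects (flanked thresholds expected larger; inward and outward
treated identically a priori), N(0, 1) on each design dummy and every
interaction individually, half-Cauchy(0, 10) on each varying-effect SD and
half-Cauchy(0, 1) on the residual SD.

Two deliberate choices:

- **Diagonal varying-effect covariance.** Only the SDs carry stated priors;
  this package models the varying effects as independent rather than
  estimating a correlation matrix. Correlations add many weakly-identified
  parameters at this design size and none of the reported quantities uses
  them.
- **Natural-log link.** With it, the N(1, 2) intercept prior implies a median
  unflanked threshold of e^1 ≈ 2.7 deg. Interval summaries sometimes quoted
  for such priors (e.g. a median near 1.6 deg) are not reproducible from the
  stated prior under either the natural-log or log10 convention; the
  prior-predictive check is exposed (`prior_predictive`) and reports what the
  implemented convention actually implies rather than forcing agreement. The
  half-Cauchy residual scale gives the unconditional prior predictive
  genuinely heavy tails, so the 75% HDI's upper bound is sensitive to the
  Monte-Carlo sample; varying effects are excluded from the prior predictive
  by default (their half-Cauchy(0, 10) scales would make it heavier-tailed
  still), switchable by flag.

### Sampler

No general-purpose MCMC engine for hierarchical models is among the package's
dependencies, and the model is exactly a Gaussian linear mixed model after
taking logs, so the fit uses a **partially collapsed Gibbs sampler** written
for this structure:

1. Each scale parameter (the 8 varying-effect SDs and the residual SD) is
   updated by univariate slice sampling (Neal 2003, stepping-out) on the log
   scale against the *marginal* likelihood with the varying effects
   integrated out. Woodbury identities reduce each observer's 36-row block to
   8x8 operations, batched across observers with stacked Cholesky/solve
   calls. Marginalisation is what avoids the funnel geometry that makes
   centred Gibbs updates of (b, tau) mix pathologically when tau is small.
2. The fixed-effect vector is drawn from its exact Gaussian conditional given
   the scales, again with varying effects marginalised — this removes the
   soft trade-off between the fixed location intercepts and the mean of the
   random intercepts, the other slow direction of a naive sampler.
3. The varying effects are redrawn from their conjugate Gaussian conditional.

Chains are independent with seed-derived generators, initialised at a
ridge-regularised least-squares solution. Convergence is summarised by split
R-hat and ESS (via arviz) over the fixed effects, SDs and residual SD; a max
R-hat above 1.01 (the modern convention, in place of "R-hat = 1" as printed
at lower precision) raises a warning rather than silently passing. Presets:
`smoke` = 2 chains x 500 warmup + 500 draws (seconds; used by tests),
`paper` = 4 chains x 1000 + 2000. On matched-generator data the smoke preset
reaches max R-hat ≈ 1.01 and ESS in the hundreds.

Degenerate inputs: a single-row dataset runs and returns a prior-dominated
posterior (tested); a *noise-free* threshold table (no staircase or residual
noise at all) drives sigma toward zero and mixes poorly — recovery tests
therefore always include measurement noise, as any real use of the pipeline
does.

**Bayesian R²** is computed per draw on the log scale as
Var(eta) / (Var(eta) + sigma²) with varying effects included in eta. Note the
synthetic cohort yields values near 0.99: staircase noise (~0.02 log10 MAE)
is small relative to the between-cell and between-observer spread the
generator builds in, whereas human data carry far more unexplained variance.

## Derived quantities

All ratios are per-draw transforms of the fixed effects (the "average
observer"): crowding factor = flanked/unflanked threshold; IOA =
outward/inward threshold, identically the ratio of the two crowding factors.
HDIs use the exact shortest-window definition on sorted samples (ties resolve
to the lowest window; the unusual 53% mass is kept as the analysis
ecosystem's convention alongside 97%). Exceedance probabilities use strict
inequality. Meridian and design contrasts are per-draw ratios of IOA values;
pools across locations use the geometric mean (ratios are multiplicative),
switchable to arithmetic.

The population simulation draws, for each of 1000 simulated participants, one
posterior sample (propagating posterior uncertainty) and a fresh
varying-effect vector from that sample's Normal(0, diag(tau²)), then reports
the proportion of the simulated sample whose IOA exceeds 1 and 1.5 per cell.
With the varying-effect SDs forced to zero this collapses, by construction,
to resampled average-observer IOAs.

## Recovery harness and problem sizes

`recovery_harness.run_scenario` chains every stage under one seed set and
reports per-cell truth coverage, exceedance probabilities and staircase
accuracy. The standard recovery scenario uses 12 observers and the smoke
MCMC preset, which keeps a three-seed scenario under a minute per seed while
leaving the per-cell posterior tight enough (97% HDI width ≈ 0.5 on an IOA
of 2.5) for coverage checks to be meaningful; the full 38-observer scale runs
in `scripts/acceptance.py`. Observed behaviour at these sizes: pooled
staircase estimates are unbiased within ±0.005 log10 with MAE ≈ 0.02 log10;
the 97% HPDI covers the true IOA in 12/12 cells on the tested seeds; a null
cohort (IOA = 1) yields median p(IOA > 1.5) = 0.

## Known limitations

- Correlations among varying effects are not estimated (diagonal covariance).
- The generator shares the model's lognormal factorial structure, so recovery
  tests cannot detect misspecification bias; they establish correctness of
  the machinery, not robustness.
- Letter confusions, eye movements, fixation enforcement and stimulus
  rendering are out of scope; attention and location uncertainty enter only
  as condition-dependent true thresholds.
- The staircase placement rule (posterior mean) is one of several defensible
  conventions; pooled estimates are insensitive to it at 80 trials per cell,
  but trial-by-trial sequences are not.
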