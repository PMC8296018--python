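# Methods

`excessnowcast` estimates delay-adjusted all-cause excess mortality from a
stack of provisional weekly death-count releases ("snapshots"). This note
records the models, the conventions the implementation had to fix where the
problem leaves them open, and what the synthetic world does and does not
establish.

## Data model

Deaths are tabulated by MMWR week (Sunday–Saturday; week 1 contains at
least four days of January; week-ending dates are Saturdays) and by
jurisdiction, using the 53-jurisdiction registry (50 states with New York
split into New York City and rest-of-state, plus the District of Columbia
and Puerto Rico). Snapshots are published on Wednesdays; counts in 1–9 are
masked for privacy, zeros are not. The publication week and the week before
it are excluded from every likelihood: their counts are systematically
missing in the release cycle. Cells whose count decreases between
snapshots (observed in real files, e.g. Vermont) are flagged by
`validate_monotone`, never rejected — the snapshot likelihood below never
differences consecutive snapshots, so no further handling is needed.

## Snapshot likelihood

Treating the latest snapshot `S` as complete, the partial count
`d(j, w, s)` of an earlier snapshot `s` is Poisson with mean
`d(j, w, S) · F_j(t)`, where `F_j` is the jurisdiction's reporting-delay
CDF and `t` the elapsed time from the death week to the publication date of
`s`. Elapsed time is measured from the mid-point of the death week
(week-ending Saturday minus 3.5 days) — the continuity correction for
evaluating a continuous CDF against weekly-binned, Wednesday-published
data. Masked partial counts enter as interval-censored observations
(the Poisson pmf summed over 1..9) in every fit; a masked *final* count is
replaced by the censoring-interval midpoint 5 and flagged.

## Delay models

All four estimation routes share that likelihood:

* **Independent parametric** — gamma, Weibull or lognormal, parameterised
  throughout by the mean and standard deviation of the delay (weeks);
  moment maps are closed-form (gamma, lognormal) or inverted numerically
  to 1e-13 (Weibull shape from the coefficient of variation).
* **Mixture** — the three families share one (mean, sd) pair and enter the
  jurisdiction-level likelihood as `Σ_i π_i L_i`, with uniform-simplex
  prior on π; sharing the parameters removes label switching by
  construction. Posterior component probabilities are the draw-wise
  normalised `π_i L_i`, averaged over draws.
* **Partial pool** (lognormal only) — per-jurisdiction delay means θ_j
  scatter around a shared mean μ with Student's-t(ν) deviations of scale
  σ_μ; the heavy tail keeps μ robust to outlying jurisdictions.
  θ_j is constrained positive; the Student-t density is *not* renormalised
  for the truncation (the truncated mass is ~1e-4 at the default scale).
  Per-jurisdiction sds are independent with half-normal priors.
* **Nonparametric** — reverse-time discrete hazards
  `g(d) = Pr(delay = d | delay ≤ d)` on bins d = 0..20, with `g(0) = 1`
  imposed and CDF `F(d) = Π_{d' > d} (1 − g(d'))`, so `F(D) = 1` exactly.

Priors (all fits): mean, sd ~ half-normal(0, 10 weeks); σ_μ ~
half-normal(0, 5); ν ~ gamma(2, 0.1); hazards uniform(0, 1). These are
deliberately weak; the snapshot likelihoods at realistic count scales
dominate them.

### Hazard-bin conventions

Bin 0 nominally spans the first 10 days after the (mid-week) death date;
`fraction_within_10_days` is `F` at that boundary for every delay type.
For the *mean* of a fitted hazard, the bins are centred on what they
actually measure: with Wednesday publications and the two-recent-week
exclusion, bin d is identified by observations 14.5 + 7d days after the
mid-week death date, so bin 0 is centred at 7.25 days and bin d ≥ 1 at
11 + 7d days. Centring on the nominal 10-day grid instead would understate
hazard-based means by ~0.65 weeks and break the expected overlay between
the nonparametric and parametric estimates.

### Outlier scan

For each posterior draw, the Student's-t tail percentile of θ_j under that
draw's (ν, μ, σ_μ) is computed; the per-jurisdiction P-value is the median
over draws of `min(F, 1 − F)`. The scan flags the most extreme
jurisdiction when its P-value falls below 0.025 (two-sided 5%), refits the
pool without it, and repeats until nothing is flagged.

## MCMC

No probabilistic-programming framework is available in the target
environment, so inference runs on a small adaptive random-walk Metropolis
engine (`excessnowcast.mcmc`): blocked Gaussian proposals on unconstrained
(log/logit) scales, Robbins–Monro scale adaptation towards 0.44/0.234
acceptance, 4 chains by default. The partial pool uses a structured
Metropolis-within-Gibbs sweep — per-jurisdiction (θ_j, sd_j) blocks whose
proposals adapt a 2×2 covariance during warm-up, plus cheap hyperparameter
sub-sweeps (ν is weakly identified and needs the extra moves). Split-R̂
(via arviz) is recorded on every fit with a 1.01 guideline; fits warn at
R̂ ≥ 1.05 rather than failing, since the default budgets (4 × 500 draws)
trade a little Monte-Carlo error for runtime. The seasonal baseline uses
an independence-style random-walk proposal pre-scaled by the GLM Laplace
covariance, which mixes in a few hundred iterations.

## Nowcast

Given a week's reported count `r` and delay CDF value `F` at the latest
publication date, the not-yet-reported count follows the failure-counting
negative binomial NB(size = r, p = F), so `E[final] = r / F`. Delay
uncertainty propagates by pairing one delay posterior draw with each
nowcast draw. Degenerate cases: `r = 0` nowcasts to 0 and is flagged
(the excluded recent weeks are where this would matter); a masked reported
count is nowcast from the midpoint 5 and flagged; `F = 0` with `r > 0`
raises. Retrospective validation refits delays using only snapshots up to
a cutoff and scores interval coverage and median relative error of the
nowcast against the final snapshot.

## Baseline and excess

Expected weekly deaths per jurisdiction follow a Bayesian Poisson
regression with log link: intercept, linear secular trend in continuous
weeks, and two annual harmonics with period 52.1775 weeks, trained on the
historical years (2014–2019 by default; 2020 never enters training). Two
per-week thresholds — the posterior median and the 95th percentile of the
expected count — convert the nowcast median into a weekly excess range,
with negative differences set to zero, summed over reporting periods
(March–December = MMWR weeks 10–53; September–December = weeks 36–53;
both configurable). **Percent change** divides the period excess by the
period sum of the posterior-median expected deaths — the denominator is a
package convention, stated here because the quantity is often reported
without one.

## Covariate regression

Mean reporting delay (weeks) is regressed on cumulative COVID-19 deaths
per 100 000 (September–December) under Student's-t errors; a zero-slope
null is compared by PSIS-LOO (arviz), reporting ΔLOOIC = LOOIC_null −
LOOIC_alt and pseudo-BMA+ (Bayesian-bootstrap) relative weights. The
covariate is stored cumulatively; the weekly-scale association divides by
the 18 weeks of the period, and the slope and its reciprocal are emitted
together.

## Synthetic world

The generator inverts the analysis' own assumptions so every stage has a
recovery target. Defaults, chosen once:

* 53 jurisdictions (tests scale to 20), intercepts log-spaced over weekly
  baselines of 150–3000 deaths, secular trend 3e-4/week, two annual
  harmonics (10% and 3%) with a winter peak;
* pandemic excess as additive Poisson waves (spring wave at week 15,
  relative magnitude 0.35; autumn wave at week 47, magnitude 0.25);
* delays lognormal with jurisdiction means ~ Student-t(ν = 4, μ = 2.8
  weeks, σ_μ = 0.7), truncated at 0.1 weeks, sd 1.5 weeks; planted
  outliers overwrite their means exactly. The sd of 1.5 weeks (rather
  than a CV-1 tail) keeps the final snapshot effectively complete for
  every covered week, which the generator's conservation contract
  (counts converge to the true finals) requires under the default
  21-Wednesday window (late September 2020 – mid-February 2021);
* covariates satisfy delay = 1.0 + slope · burden + t-noise with slope
  1/(4.5 · 18) weeks per cumulative death per 100k, i.e. ~4.5 weekly
  deaths per 100k per extra week of delay. Because the spec'd interface
  derives the covariate *from* the delay means, non-zero noise induces a
  mild errors-in-variables attenuation; recovery tests therefore use
  small noise.

What the generator does **not** emulate: time-varying delays, day-of-week
reporting effects, between-snapshot re-arrangements (Vermont-style),
age/race/cause structure, and jurisdiction-correlated excess waves. Green
recovery tests therefore establish internal consistency of the estimators
under the stated model, not robustness to those real-data features.

## Numerical notes and limitations

* Poisson log-pmfs with zero expectation return 0 for y = 0 and −inf
  otherwise; masked-cell sums use logsumexp.
* Weibull moment inversion brackets the shape in [1e-2, 1e3]; fits bound
  the CV to (1e-3, 1e3) and reject proposals outside.
* The nowcast treats the final snapshot as complete; when it is not
  (heavy delay tails, short follow-up), nowcasts are conservative —
  they underestimate the eventual totals, which the retrospective
  validation exposes as negative bias at early cutoffs.
* ν (both the pool dof and the regression dof) is weakly identified at
  these sample sizes; its posterior mostly reflects the prior when no
  outliers are present.
* The iterative outlier scan refits with a fresh seed each round;
  borderline jurisdictions (median P near the 0.025 threshold) can flag
  or not across reruns with different seeds.
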