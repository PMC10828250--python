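# Methods

## The framework

A physiological function declines with age. If every individual loses the
same *fraction* of their own baseline per year, the ranking and the
relative spread of the population are preserved: the cross-sectional SD
shrinks in proportion to the mean and the coefficient of variation
(COVAR = 100·SD/mean, %) stays constant. Any age trend in COVAR therefore
signals that individuals age at genuinely different rates. `agevar`
operationalises this as: estimate the age trend of the binned SD and COVAR
of a cross-sectional cohort, call each trend `decrease` / `none` /
`increase`, and map the pair onto one of four generative scenarios and a
coarse uniform-vs-individualistic verdict.

## Generative models

All scenarios are linear in age over `[t0, t_max]` (defaults 30–80 y).
With baseline `b` drawn from a normal distribution and τ the years since
`t0`:

- **S1** `v = b(1 − rτ)` — uniform relative loss, default r = 0.01/yr.
  The loss is a fixed fraction *of baseline*, not compounding: r = 0.01
  leaves exactly 50 % at age 80. A compounding rule would leave ~60.5 %
  and would not produce a constant COVAR with a linearly falling mean.
- **S2** `v = b − dτ` — uniform absolute loss, default d = 1 unit/yr.
- **S3** `v = b − dᵢτ` — each individual has their own constant loss rate
  `dᵢ ~ Normal(μ_d, σ_d)` truncated to `[0, slope_cap]`, independent of
  baseline. Defaults μ_d = 0.5, σ_d = 0.3 units/yr, cap = μ_d + 3σ_d: a
  population spanning rapid decline to barely any, as the three-individual
  exemplar (slopes 1.6 / 0.1 / 0.8) illustrates.
- **S4** `v = c + (b − c)(1 − kτ)` — loss proportional to the distance
  above a common floor `c`, so the best starters lose the most and
  trajectories converge. Defaults c = 20, k = 0.016/yr. With c = 0 this is
  S1 with r = k exactly.

Baseline defaults are μ_b = 80, σ_b = 20 function units (baseline CV 25 %,
consistent with the 100/80/60 exemplar trio used throughout). Measurement
noise is additive `Normal(0, noise_sd)` per observation, default 0.

### Validity truncation

A linear decline with normal baselines inevitably drives some tail
trajectories below zero, where the model is meaningless; such values are a
hard error, never silently clipped. The simulator therefore draws
baselines from the normal distribution truncated below at the scenario's
*validity floor* — 0 for S1 (r·span ≤ 1 is enforced), `d·span` for S2,
`slope_cap·span` for S3 and `c` for S4 — the minimal restriction that
keeps every trajectory non-negative over the whole age range. S3 slopes
are truncated to `[0, slope_cap]` for the same reason (and so that no
trajectory increases with age).

All closed-form moments (`analytic_moments`) use the truncated
distributions' means and variances (truncated-normal closed forms via
scipy), so large simulated cohorts converge on the analytic curves
exactly; the test suite verifies agreement for 10⁵ noise-free individuals
within 3 Monte-Carlo standard errors for every scenario. With the default
parameters the truncation is mild (e.g. the S2 floor sits 1.5σ below the
baseline mean), and the classic untruncated formulas are recovered to a
few parts in 10³ when the bound is far from the mean.

## Cohorts

Cross-sectional cohorts observe each subject once at an age drawn
uniformly on `[t0, t_max]` — no age design is assumed, and uniform
sampling gives every bin equal information. Longitudinal simulation (every
subject at every listed age) is provided as the ground-truth design the
framework substitutes for. One integer seed is split into independent
sub-streams for baselines, slopes, ages and noise, so changing the noise
level does not change which individuals are drawn. Cohorts interchange as
plain CSV (`subject_id,age,value`, 17 significant digits, exact
round-trip).

## Dispersion estimation

Subjects are grouped into age bins (default 10-year bins; half-open
`[lo, hi)` with the final bin closed so an exactly-`t_max`-aged subject is
kept; a short remainder is absorbed into the last bin). Per bin: n, mean,
sample SD (denominator n − 1, matching how published age-group tables
report SDs), and COVAR. At least 3 bins and, by default, at least 10
subjects per bin are required — the asymptotic standard errors below are
unreliable for tiny n. Binning (rather than kernel or spline smoothing)
keeps the estimator transparent and makes the stratified bootstrap
well-defined.

Two properties of binned cross-sections worth knowing:

- the within-bin decline of the mean adds `g²·w²/12` to the observed bin
  variance (g = mean slope, w = bin width);
- additive measurement noise adds `σ_ε²`.

The framework classifies *observed* dispersion, so both terms are part of
what it sees (see Limitations).

## Trend inference

The direction call for a statistic is the sign of a two-sided
confidence interval for the slope of the per-bin statistic against bin
midpoint: CI < 0 → decrease, CI > 0 → increase, otherwise (including a
degenerate zero-width CI at 0) → none. α = 0.05 by default. The SD and
COVAR calls are interpreted jointly as one decision; no multiplicity
correction is applied across the pair.

- **WLS** (`wls_trend`): weights 1/SE² from asymptotic standard errors
  `SE(SD) = sd/√(2(n−1))`, `SE(CV) = cv·√(1/(2(n−1)) + (cv/100)²/n)`
  (normal-theory approximation), `SE(mean) = sd/√n`; CI from the t
  distribution with (bins − 2) degrees of freedom. If a bin has sd = 0 the
  fit falls back to unweighted least squares with a logged warning.
- **Stratified bootstrap** (`bootstrap_trend`): resample subjects with
  replacement within each bin — whole-cohort resampling would add
  age-composition noise the framework does not model — recompute the
  binned statistic and its unweighted LS slope per replicate, percentile
  CI over replicates, point estimate from the original data. Replicates
  with an undefined statistic (a resampled bin mean ≤ 0) are redrawn;
  more than 10 % rejections is an error. Recommended for real data, since
  the CV standard error above is approximate.

Both methods are calibrated on the null (noise-free S1 cohorts, true COVAR
slope 0): the test suite checks a false-call rate within the Monte-Carlo
envelope of α over 200 replications, and that the two methods agree in
direction on ≥ 95 % of noise-free cohorts at n = 5000.

## Classification

| SD | COVAR | fine label | coarse verdict |
|---|---|---|---|
| decrease | none | S1 uniform relative | uniform |
| none | increase | S2 uniform absolute | individualistic |
| increase | increase | S3 random slopes | individualistic |
| decrease | decrease | S4 convergent | individualistic |
| none | none | indeterminate | uniform (may be underpowered) |
| increase | none | indeterminate | indeterminate |
| any other pair | indeterminate | individualistic |

Any changing COVAR means changing relative spread, hence an
individualistic verdict even when the pair matches no single scenario.
Rising SD with flat COVAR matches no decline scenario at all and is left
indeterminate at both levels. The (none, none) pair is labelled uniform at
the coarse level — no detected change in relative spread — but its
rationale text explicitly flags that it may simply reflect an underpowered
study or little decline over the sampled ages.

## What the simulations do and do not show

The generator emulates: heterogeneous baselines, the four decline
geometries, additive measurement error, and uniform cross-sectional age
sampling. It deliberately omits mortality and dropout (the framework as
formulated assumes none), covariates (sex, body size), realistic age
pyramids, and nonlinear decline. Passing tests show the statistical
machinery recovers the generating scenario under these idealised
conditions; they do not show robustness to selective survival or
confounding in real cohorts.

Problem sizes used in the shipped tests: cohorts of 5000 (100 seeds per
scenario) for end-to-end recovery with 1000 bootstrap replicates, 10⁵
individuals for moment agreement, 200 replications for type-I
calibration — sizes at which the Monte-Carlo bounds asserted are sharp.

## Known limitations

- **Measurement noise biases the framework away from 'uniform'.** Observed
  bin variance is population variance plus σ_ε². Under S1 the population
  SD shrinks with age while the noise floor does not, so the *observed*
  COVAR rises (with σ_ε at 5 % of the baseline mean: from ~25.6 % to
  ~27.1 % over 30–80 y at default parameters). This drift is real, grows
  in detectability with n (at n = 5000 roughly half of such cohorts are
  called individualistic), and cannot be removed by the direction-call
  machinery: it is a property of classifying observed dispersion. Users
  with a credible external estimate of measurement error should interpret
  a small positive COVAR trend accordingly; a noise-deconvolved estimator
  is out of scope here.
- The CI-sign rule operates on the linear scale; no guidance is taken on
  log-scale trends.
- The four scenarios are linear by construction; mixtures, breakpoints and
  nonlinear decline are non-goals.
- The per-bin SEs are asymptotic; with fewer than ~10 subjects per bin use
  the bootstrap and wider bins.
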