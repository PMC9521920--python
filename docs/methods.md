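# Methods

This note documents the models, conventions, numerical choices, and known
limitations of the package, in the order data flows through the pipeline.

## Seasonal covariates

Seasons follow the monitoring program's windows: winter 1 Nov–31 Mar,
spring 1 Apr–31 May, summer 1 Jun–31 Aug, fall 1 Sep–31 Oct. A winter is
labeled by its **ending** year, so the winter predictors paired with a
summer-`t` response cover Nov `t−1`–Mar `t`. Summer, fall, growing degree
days, SPEI, first fall freeze, and timber areas enter the predictor table
for response year `t` from calendar year `t−1` (maternal carryover and
habitat lags); each lagged value is used exactly once.

* **Freeze** is defined as daily tmin ≤ 0 °C (the monitoring protocol
  never defines it; 0 °C is the natural threshold). The first fall freeze
  is searched in 1 Aug–31 Dec of `t−1`, the last spring freeze in
  1 Jan–30 Jun of `t`; these windows bracket the mid-September–late-October
  and March–June ranges seen in subpolar maritime records with wide
  margin. Winter duration is the calendar-day separation of the two dates.
* **Mean monthly minimum winter temperature** is the mean over the five
  winter months of each month's minimum daily tmin. The alternative
  reading (mean of daily tmin) is available via
  `CovariateConfig.monthly_min_mode="daily"`.
* **Growing degree days** use the daily-average method,
  Σ max(0, (tmax+tmin)/2 − 5 °C), over 1 Jun–31 Aug, truncated at the base
  with no upper cutoff.
* **Missing data**: a seasonal statistic is reported missing when more
  than 10% of its window's days are absent (`max_missing_frac`); an
  entirely missing window is missing with a logged warning. Snow-depth
  means include zero-depth days across the whole winter window.

## SPEI

The climatic water balance D = P − PET is aggregated over trailing k-month
windows; for each calendar month separately a 3-parameter log-logistic
distribution is fit to the calibration years (default 1950–2021, ≥30 per
month required) by **unbiased probability-weighted moments**, and the
aggregate balance is mapped through the fitted CDF to standard-normal
deviates via `scipy.special.ndtri` (machine precision; no rational
approximation needed). CDF values are clipped to [1e-8, 1−1e-8] so the
index stays finite (|index| ≲ 5.6). The log-logistic cannot represent
negative skew; for a negatively skewed month the reflected sample is fit
and the index negated, which preserves both the N(0,1) calibration and
monotonicity in the water balance.

The forest index is the July value at a 6-month scale. A 6-month window
ending in July spans Feb–Jul; the program description of "January–July"
spans seven months, so the window length is exposed as
`CovariateConfig.spei6_months` (default 6, set 7 for Jan–Jul). The
grassland index is the September value at a 3-month scale (exactly
Jul+Aug+Sep). Thornthwaite PET uses the classical heat-index formulation
with astronomical mean day length per month (|latitude| ≤ 66°); the heat
index is computed per calendar year from that year's months above 0 °C.

## Downing reconstruction

Input is a year × age-class mortality table. Aged mortalities are binned
into m classes (default 5); un-aged mortalities in a year are allocated
proportionally to that year's aged class distribution (uniformly, or an
error, by option), so row totals equal all known mortalities — harvest
plus other known deaths, since the method assumes observed removals are
the dominant mortality.

The reconstruction is the deterministic cohort recursion
N_{i,t} = H_{i,t} + N_{i+1,t+1} for classes i ≤ m−2, working backward from
the terminal year (where N is the minimum-alive value, the year's own
harvest). The two oldest classes are closed by the equal-harvest-rate
assumption H_{m−1,t}/N_{m−1,t} = H_{m,t}/N_{m,t}; algebraically the pooled
old group N_{m−1,t} + N_{m,t} = N_{m,t+1} + H_{m−1,t} + H_{m,t}, split in
proportion to the two harvests. When both old-class harvests are zero the
pool is carried in the oldest class (minimum-alive fallback, logged). A
pure minimum-alive closure is available via `closure="minimum-alive"`.
The final m−1 data years are dropped (with m = 5, the four most recent
years). Fractional abundances are kept; totals are a **minimum** estimate
(≥ the year's summed harvest) and are treated downstream as an index, not
a census. Sexes are pooled.

Under harvest-only mortality with equal rates and a terminal complete
harvest, the recursion is exact — the synthetic generator's deterministic
mode creates precisely these conditions, giving a machine-precision
end-to-end oracle. On open-ended stochastic series the reconstruction
increasingly undercounts recent years (future harvests unobserved), which
is the documented reason the terminal years are discarded.

## Elk data screening

Record-level filters, each logged with a reason code: calves > cows
(recording error / partial group), zero calves (survey too late to
distinguish calves), cows missing (adults not sexed), blocklisted herds
(canopy cover precludes accurate counts). After record screening, any year
whose summed group count is ≤ 5 (configurable) is dropped whole. Age
ratios are pooled — 100·Σcalves/Σcows over the group's herds — never
averaged across herds. Count series are completed by linear interpolation
of interior gaps only (leading/trailing gaps are an error) with imputation
flags retained. Trends are OLS on calendar year with a two-sided t test
(n−2 df), α = 0.05. Predictors are z-scored over exactly the years
entering each model, with (mean, sd) stored for back-transformation.

## Predictor selection

Stage one: univariate OLS R² of the response on each candidate over
overlapping years (≥3 required). Stage two: one candidate per hypothesis,
maximizing first the number of hypotheses retained and then total R²,
subject to pairwise |Pearson r| ≤ 0.7 between chosen predictors. Because
the "replace with the next-best uncorrelated candidate" rule is ambiguous
when either member of a conflicting pair could move, the rule is made
deterministic by exhaustive search over per-hypothesis candidate choices
(feasible at the problem's ~20 candidates; capped at 20,000 combinations),
with lexicographic name order breaking exact ties. Correlations use
pairwise-complete cases.

## Recruitment model

y_t ~ Normal(β₀ + Σ β_k z_k,t, σ²) on complete-case rows. Priors:
β ~ Normal(0, 100²) — diffuse at the response scale of ~16–57 calves per
100 cows — and σ ~ Uniform(0, 100). Both full conditionals are standard,
so the sampler is pure Gibbs: multivariate normal for β, truncated
inverse-gamma for σ² (drawn by gamma rejection against the upper bound).
Defaults follow the analysis protocol: 3 chains, 50,000 iterations,
burn-in 10,000, thin 5. Convergence is the rank-normalized split-chain
R-hat (arviz) with threshold 1.1; a non-converged fit is returned flagged,
never silently. Influence = 95% credible interval excluding zero.
Posterior means agree with OLS (flat-prior equivalence) and are invariant
to row permutation; doubling the prior SD moves coefficient means by far
less than a posterior SD (tested).

**Posterior predictive p-value.** The default discrepancy is the sum of
squared standardized residuals. Because σ is itself estimated, this
statistic is nearly ancillary: its p-value anchors close to 0.5 for any
data — including data with a 30-SD outlier — so values near 0.5 certify
internal coherence of the error model rather than detect misfit. A
`max_abs` discrepancy (maximum absolute standardized residual), which does
respond to outliers, is available in
`posterior_predictive_pvalue(..., discrepancy="max_abs")`.

## Abundance model

Gompertz state-space model with explicit harvest: with x_t the log
abundance at the September count and H_t the known post-count removal,
q_t = log(exp(x_t) − H_t) and

    x_t = q_{t−1} + a + b·q_{t−1} + Σ_k c_k z_{k,t} + ε_t,  ε ~ N(0, σ_proc²)
    log(count_t) ~ N(x_t, σ_obs²).

Harvest is subtracted on the natural scale before the Gompertz step
(removal happens after the count); b < 0 is compensatory density
dependence on the log scale; covariates are standardized and matched to
the transition's target year. The initial state has a Normal(log count₁,
1) prior; priors and MCMC settings otherwise as in the recruitment model.
Any year with recorded harvest ≥ the observed count is an error before
fitting.

Sampling: coefficients (a, b, c) are a conjugate multivariate-normal block
given the states; both variances are truncated inverse-gamma; the latent
states are updated by adaptive single-site Metropolis in an odd/even
checkerboard (each site's conditional involves only its neighbors, so each
color updates vectorized; proposal scales adapt toward 44% acceptance
during burn-in only). A global residual-scaling move
x' = y + γ(x − y), γ lognormal, with Jacobian T·log γ, is interleaved each
iteration: it directly traverses the process/observation variance
partition that single-site moves mix slowly. The sampler was validated
against an independent JAGS implementation of the identical model on the
same simulated dataset (posterior means/SDs of all four parameters agree
to well within Monte Carlo error; the JAGS run needed ~300k iterations to
converge where this sampler needs ~15k). A `estimate_density_dependence=False`
switch fixes b = 0, which in the small-observation-error limit recovers
the random-walk-with-drift MLE.

The intercept and density-dependence parameters sit on a strong posterior
ridge (a ≈ −b·q̄): with only ~60 observations the data cannot sharply
separate drift from log-linear density dependence, and posterior means of
|b| tend to sit above the generating value when observation error is
present. This weak identifiability is exactly why the independent
density-dependence test exists.

## Density-dependence test

The Dennis–Taper parametric bootstrap likelihood-ratio test is applied to
the observed counts (optionally to counts − harvest via
`use_post_harvest`): H1 is the Ricker-form growth regression
log(N_{t+1}/N_t) = a + b·N_t + σZ, H0 forces b = 0 (random walk with
drift); Λ = 2(ℓ₁ − ℓ₀) = n·log(σ̂₀²/σ̂₁²) with MLE variances. The null
distribution is built by simulating `n_boot` (default 2,000) series from
the fitted H0 — same length, same N₁ — and refitting both models;
p = (1 + #{Λ* ≥ Λ})/(1 + n_boot), bit-reproducible given (n_boot, seed).
The Ricker form (b·N) in the test versus the Gompertz form (b·log N) in
the state-space model is intentional: the test keeps its original
formulation, the state-space model the program's. The test also emits the
(N_t, ln(N_{t+1}/N_t)) diagnostic point set; the growth rate is defined
forward (year t to t+1) against N_t.

## Synthetic data

The generators draw from the same families the models assume, sized to the
study system, so tests exercise realistic power:

* **Weather** — daily sinusoid (annual mean 5 °C, amplitude 7 °C, coldest
  day ~1 Feb) plus N(0, 2.5 °C) noise; tmin/tmax split by a 6 °C diurnal
  range with half-normal margins; wet-day gamma precipitation (~50% wet
  days, ~1.7 m/yr); precipitation falls as snow below 0 °C with a simple
  accumulation/degree-day-melt depth bucket. Spans 1950–2021 so a ~70-year
  SPEI calibration exists.
* **Bears** — 5 stage classes, per-capita recruitment 0.15, harvest rate
  0.12 (≈20 mortalities/yr at ~165 bears, ~3%/yr growth, abundance ~90
  rising toward ~390 over 1967–2017), aged fraction 0.92. Deterministic
  mode (fractional animals, exact rates, terminal full harvest) yields the
  exact reconstruction oracle; stochastic mode (binomial harvest/aging)
  feeds the pipeline.
* **Elk** — counts from the exact state-space process at a = 1.45,
  b = −0.27, σ_proc = 0.23, σ_obs = 0.20, 1958–2020 (63 years), harvest
  rule H_t = ⌊0.10·count_t⌋ (permits track observed counts; the rule
  raises if demanded harvest exhausts true abundance); age ratios from the
  linear model (intercept 33, residual SD 6.4 calves per 100 cows),
  1967–2013. Herd-level composition counts are Poisson around the target
  pooled ratio, with optional injection of the filterable failure modes.

What the generators do **not** emulate: sightability/misclassification
structure in composition counts, spatial herd structure, age-specific
bear vulnerability, real weather autocorrelation beyond the seasonal
cycle, and the permit-setting feedback between counts and harvest beyond
the proportional rule. Passing tests therefore demonstrate correctness of
the estimators under their assumed models at study-scale power — not
robustness to those field realities.

## Test and acceptance problem sizes

The statistical acceptance checks use: 3 replicate bear simulations
(exact recovery), 24 month×scale SPEI cells over a 72-year calibration,
100 recruitment replicates at n = 44 with chains of 1,500 iterations
(conjugate Gibbs mixes essentially immediately; coverage bands are
binomial at n = 100), 20 state-space replicates at 15,000 iterations
(burn-in 5,000) — the smallest run at which all replicates pass R-hat
< 1.1 — and 200 null series × 500 bootstrap replicates for the test's
type-I error, vectorized. The full-scale defaults (50,000 iterations) are
used for real runs.

## Known limitations

* The reconstruction is an index: it underestimates absolute abundance
  (literature suggests ~15% for comparable data) and degrades in its most
  recent years; no uncertainty is attached.
* Density dependence in recruitment is not modeled (herd-level abundances
  are unavailable by design of the monitoring data).
* Harvest and abundance are confounded through the permitting feedback, so
  the harvest effect on elk abundance is not separately estimable.
* The default posterior predictive p-value certifies coherence, not fit;
  see above.
* SPEI months with negative sample skew use the reflected-fit fallback
  rather than an alternative distribution family.
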