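# elkdemog

Climate covariates, predator reconstruction, and Bayesian demographic models
for long-term island elk monitoring data.

## The problem

Wildlife agencies monitoring an insular Roosevelt elk population hold three
long, heterogeneous records: ~60 years of aerial September counts and
July–August herd composition counts (calves per 100 adult females, the *age
ratio*), ~50 years of brown bear harvest-at-age records from cementum-aged
teeth, and daily weather-station data. The scientific question is which of
five non-exclusive mechanisms — winter severity, a spring nutritional
bottleneck, summer–autumn maternal carryover, bear predation, and timber
harvest — best explains variation in elk recruitment and abundance. This
package implements the full analysis chain as a tested, reusable library:

1. **Covariate engineering** (`elkdemog.covariates`) — seasonal
   temperature/precipitation/snow summaries, freeze dates and winter
   duration, growing degree days (base 5 °C), timber-stand areas by age
   class, and the standardized precipitation-evapotranspiration index
   (SPEI) with Thornthwaite potential evapotranspiration and a
   PWM-fitted 3-parameter log-logistic standardization.
2. **Downing cohort reconstruction** (`elkdemog.bear`) — a minimum
   abundance index for bears from harvest-at-age tables, closing the two
   oldest age classes with the equal-harvest-mortality-rate assumption and
   dropping the m−1 unreliable terminal years.
3. **Data screening** (`elkdemog.elk`) — composition-count filters
   (calves > cows, zero calves, unsexed adults, tiny survey years), pooled
   age ratios, linear interpolation of missing counts, standardization,
   OLS trend tests.
4. **Predictor selection** (`elkdemog.selection`) — per-hypothesis
   univariate-R² screening with |r| > 0.7 conflict resolution by exhaustive
   search (most hypotheses retained, then total R²).
5. **Bayesian models** (`elkdemog.recruitment`, `elkdemog.abundance`) —
   a Gibbs-sampled linear model for age ratios, and a Gompertz state-space
   model for counts with known post-count harvest,

   ```
   x_t = q_{t-1} + a + b·q_{t-1} + Σ_k c_k z_{k,t} + ε_t,  ε_t ~ N(0, σ_proc²)
   log(count_t) ~ N(x_t, σ_obs²),   q_t = log(exp(x_t) − H_t)
   ```

   plus the Dennis–Taper parametric bootstrap likelihood-ratio test of
   density dependence run directly on the counts.
6. **Synthetic data** (`elkdemog.synth`) — seeded generators for weather,
   bear, and elk data drawn from the exact model likelihoods, sized to the
   study (63 count years, ~47 mortality years, ~44 ratio years), so every
   stage is testable end to end with known truth.
7. **Pipeline + CLI** (`elkdemog.pipeline`, `elkdemog` console script) —
   one-command orchestration with exclusion logs, screening/summary tables,
   and a reproducible run manifest.

## Worked example

```python
from elkdemog import synth, bear
from elkdemog.abundance import dennis_taper_pblrt, fit_gompertz_ssm
from elkdemog.mcmc import MCMCConfig

records, table, truth = synth.simulate_bear_harvest(synth.BearConfig(), seed=1)
recon = bear.downing_reconstruct(table)
print(recon.total.index.min(), recon.total.index.max())   # 1967 2013
print(recon.total.iloc[0], recon.total.loc[2013])         # 90.0 350.6

sim = synth.simulate_elk_system(synth.ElkConfig(), seed=1)
fit = fit_gompertz_ssm(sim["counts"], sim["harvest"], None,
                       MCMCConfig(chains=3, iterations=15000, burn_in=5000,
                                  thin=5, seed=1))
print(fit.summary[["mean", "sd", "q2.5", "q97.5", "rhat"]].round(3))
dd = dennis_taper_pblrt(sim["counts"], n_boot=2000, seed=1)
print(f"Lambda={dd.statistic:.2f} p={dd.p_value:.3f}")
```

Output:

```
                     mean     sd   q2.5  q97.5   rhat
intercept           1.496  0.569  0.551  2.741  1.022
density_dependence -0.279  0.115 -0.530 -0.087  1.022
sigma_proc          0.255  0.072  0.141  0.403  1.033
sigma_obs           0.200  0.078  0.009  0.312  1.051
Lambda=15.38 p=0.004
```

The generating values were a = 1.45, b = −0.27, σ_proc = 0.23,
σ_obs = 0.20: every 95% credible interval covers its generating value.
The reconstruction recovers the simulated bear population exactly on all
non-truncated years (it is a deterministic cohort sum under harvest-only
mortality), and the bootstrap test detects the simulated density
dependence (b < 0) at p = 0.004. A full pipeline run
(`elkdemog run --seed 4 --out out/`) writes the predictor table, the
reconstruction, exclusion logs, Table-style screening and posterior
summaries, the growth diagnostic, and `manifest.json`.

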