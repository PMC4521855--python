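# bushmarket

Statistical pipeline for long-running bushmeat-market censuses: how do
carcass volumes in an urban wildlife market respond to political shocks,
environmental legislation and rising incomes?

The package implements the full analysis chain for a 13-year daily
census of the Malabo bushmeat market (Bioko Island, Equatorial Guinea,
October 1997 – September 2010): monthly carcass-rate construction, a
seasonal-ARIMA intervention model of legislative/political events, loess
trend–seasonal decomposition, per-period normalized trend slopes,
heteroscedastic two-factor GLS ANOVA, bootstrap correlations, and
income-proxy regressions. Because the original field census is not
publicly deposited, the package ships a synthetic census generator that
reproduces the statistical structure the analysis assumes, so every
stage is testable end to end and the estimation machinery can be
validated by parameter recovery.

## The model

The central response is the **carcass rate** `Y_t` — carcasses recorded
per market day, aggregated monthly. Two complementary models are fitted:

**Intervention (transfer-function) model.** On the square-root scale,

    z_t = mu + sum_j m_t^(j) + N_t,        N_t ~ ARIMA(2,0,0) x (1,0,0)_12

where each external event *j* contributes a transfer response built from
a step `w_S S_t` (permanent mean shift), a pulse `w_P P_t` (momentary
deviation), and optionally a geometric time lag `1/(1 - delta B)` applied
to the pulse, giving `w_P delta^(t-T)` — the gradual return of the
perturbed mean to its new baseline. Estimation is exact Gaussian maximum
likelihood via the state-space prediction-error decomposition
(statsmodels SARIMAX), with the nonlinear lag parameter profiled.

**Additive decomposition and trends.**

    Y_t = T_t + S_t + E_t

with `T` a first-order loess over 24 monthly points, `S` a second-order
loess of the detrended series over 6 points, and `E` the remainder.
Deseasonalized rates (`T+E`) feed per-period quadratic-versus-linear
trend regressions on serially numbered months; the reported "slope" is
the average change in carcass rate per month (at the period midpoint
when curvature is retained), with 95% CIs from linear-model theory, and
is normalized by the taxon/total SD ratio for cross-taxon comparison.
Method-by-period effects are tested with a two-factor GLS ANOVA on log
rates allowing a separate residual variance per factor-level cell.

## Worked example

Run the whole pipeline on the packaged demo scenario (a synthetic
156-month market with four sqrt-scale shocks on the primate group):

```bash
bushmarket run-all --seed 7 --out demo_out
```

The intervention stage writes `intervention_parameters.csv`, a per-event
"estimate (standard error)" table. With seed 7 the generator's true
weights (2/1998 pulse −1.357; 3/2002 step 0.457, pulse −0.625; 11/2003
step −1.001, pulse 3.037; 11/2007 step 3.037, pulse −5.202, lag 0.945)
are recovered as:

```
          02/1998         03/2002         11/2003         11/2007
step          ---   0.458 (0.108)  -0.687 (0.122)   4.204 (0.328)
pulse  -1.495 (0.136) -0.595 (0.093)  2.906 (0.099) -6.139 (0.651)
time_lag      ---             ---             ---    0.957 (0.012)
```

i.e. every configured component is detected with the right sign and
magnitude — the 11/2007 ban event shows the characteristic deep negative
pulse (market crash), a large positive step (post-ban rebound above the
old mean) and a lag near 1 (slow recovery). The diagnostics line reports
`rmse 0.129, Ljung-Box Q = 13.57 (df 9, p = 0.138)` — no residual
autocorrelation — and all four events survive significance pruning. The
associate stage prints the method-by-period interaction
`F(2,306) = 557.8, p < 0.001`: the trap-to-shotgun transition differs
sharply across market periods, as built into the scenario.

As a library:

```python
from bushmarket import census_io, intervention_ts

summary = census_io.reference_summary(census_io.load_species_reference())
census_io.summary_value(summary, "primate", "n")            # 35235.0
census_io.summary_value(summary, "rodent", "count_share_pct")  # 41.09
```

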