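# lbpseudo

Pseudo-observation Cox regression for **length-biased, right-censored (LBRC)
survival data**.

## The problem

Prevalent-cohort studies — dementia registries, retirement-community rosters,
cross-sectional disease surveys — recruit subjects who have already
experienced disease onset and are still alive at recruitment.  A subject is
captured with probability proportional to its survival time, so the observed
lifetimes follow the *length-biased* density `t f(t) / mu` rather than the
population density `f(t)`.  Follow-up after recruitment may end in censoring,
and because the censoring time shares the pre-recruitment duration `A` with
the event time, the censoring is informative on the total-time scale.
Ordinary Kaplan–Meier curves and Cox fits are badly biased in this setting.

`lbpseudo` estimates the Cox proportional-hazards coefficients
`lambda(t|x) = lambda0(t) exp(x'beta)` of the *unbiased* population from an
LBRC cohort `(a_i, y_i, delta_i, x_i)` by:

1. estimating the unbiased survival function `S` nonparametrically — the
   **Wang product-limit estimator**
   `S_W(t) = prod_{u<=t} (1 - dH_n(u)/R_n(u))` built on the LBRC risk process
   `R_i(t) = 1{a_i<=t<=y_i} + delta_i 1{y_i-a_i<=t<=y_i}`, the **Vardi
   NPMLE** (EM on the length-biased distribution, then the `1/x` inversion
   `S_V(y) = ∫_y^∞ x^{-1} S_LB(dx) / ∫_0^∞ x^{-1} S_LB(dx)`), or a
   **left-truncated Kaplan–Meier** comparator;
2. converting the estimator into **jackknife pseudo-observations** on a time
   grid `tau_1 < … < tau_m`:
   `S_i(tau_j) = n S(tau_j) - (n-1) S^{(-i)}(tau_j)`;
3. regressing the pseudo-values on time-specific intercepts plus covariates
   with the complementary log-log link,
   `log(-log S(tau_j|x)) = log Lambda0(tau_j) + x'beta`, solved as a GEE
   with independence working covariance and a **sandwich covariance**
   `Sigma = I^{-1} [sum_i U_i U_i'] I^{-1}` for Wald inference.

A cohort simulator (stationary uniform onset over a long window, rejection
to `A <= T`, censoring-scale calibration to a target rate) and a
replication harness (Bias / SE / RMSE / CP with invalid-fit accounting)
reproduce the accompanying Monte-Carlo study design.

## Worked example

Simulate a 250-subject LBRC cohort with constant baseline hazard 2,
`beta = (log 2, log 0.8)` and ~10% censoring, then fit Wang
pseudo-observations on the ten grid points 0.4, 0.5, …, 1.3:

```bash
lbpseudo simulate --scenario I --n 250 --censoring 0.10 --seed 7 --out cohort.csv
lbpseudo fit cohort.csv --method wang --grid 0.4:1.3:0.1
```

```
    coefficient  estimate       se         z      p_value  ci_low_0.95  ci_high_0.95
logLambda0(0.4) -0.222554 0.089920 -2.475029 1.332254e-02    -0.398793     -0.046314
...
  logLambda0(1)  0.711788 0.056677 12.558606 3.565578e-36     0.600703      0.822874
             x1  0.953715 0.259597  3.673831 2.389411e-04     0.444915      1.462516
             x2 -0.079710 0.096632 -0.824879 4.094400e-01    -0.269106      0.109686
```

The intercepts estimate `log Lambda0(tau)` (truth at `tau = 0.4` is
`log 0.8 = -0.223`; at `tau = 1.0`, `log 2 = 0.693` — both hit within one
standard error), and the covariate rows estimate the log hazard ratios
(truth `log 2 = 0.693` and `log 0.8 = -0.223`); this single draw puts
`x1` at `0.95 ± 0.26`.

The packaged Channing House retirement cohort (450 residents entering at age
65+, 62% censored) asks whether gender affects survival past 65:

```bash
lbpseudo channing
```

```
method  coef_female  exp_coef       se  p_value    ci_low  ci_high  converged
  ltrc    -0.295210  0.744375 0.233460 0.206052 -0.752784 0.162364       True
 vardi    -0.090040  0.913895 0.199316 0.651454 -0.480691 0.300612       True
  wang    -0.184721  0.831336 0.204084 0.365399 -0.584718 0.215275       True
```

Women show hazard ratios of 0.74–0.91 relative to men, none statistically
significant at the 5% level.

A replicated simulation cell (this is the Monte-Carlo engine behind the
acceptance script):

```bash
lbpseudo study --scenario I --n 250 --censoring 0.10 --method wang --reps 500 --seed 1
```

## Package layout

| module | contents |
| --- | --- |
| `lbpseudo.cohort` | `LBRCSample` container and validation |
| `lbpseudo.simulate` | Cox–Weibull LBRC cohort simulator, censoring calibration |
| `lbpseudo.survfit` | Wang, Vardi-NPMLE and left-truncated KM survival estimators; influence function |
| `lbpseudo.pseudo` | jackknife pseudo-observation matrices, time grids |
| `lbpseudo.gee` | cloglog GEE solver, sandwich covariance, Wald intervals, validity rules |
| `lbpseudo.study` | replication engine and Bias/SE/RMSE/CP summaries |
| `lbpseudo.io` / `lbpseudo.cli` | CSV round-trips, Channing House preprocessing, `lbpseudo` command |

See `docs/methods.md` for the statistical background, numerical choices and
known limitations.
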