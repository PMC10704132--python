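# survineq

Quantify how a therapy changes **health inequality in survival outcomes**,
starting from nothing more than published Kaplan-Meier curves.

Randomized trials report survival curves, not patient-level data, and a
therapy that improves *median* survival can still widen the gap between the
patients who do best and the patients who do worst. `survineq` implements a
complete aggregate-data workflow for oncology/HTA analysts who want to
measure that gap:

1. **Pseudo-IPD reconstruction** — invert the product-limit recursion on
   digitized KM coordinates plus the numbers-at-risk table to recover one
   (time, event) record per subject.
2. **Equal-contribution pooling** — pool several trials per arm with weights
   (N/K)/n_j so every study contributes equally.
3. **Parametric survival modeling** — weighted MLE for the six standard
   families (exponential, gamma, Gompertz, log-logistic, log-normal,
   Weibull) and any two-component mixture, on an unconstrained transformed
   scale with observed-information covariances.
4. **Model selection** — a registry-based gate (modeled S(120 mo) must not
   exceed the cancer type's 10-year relative survival rate × 1.10) followed
   by combined-AIC ranking, with the same family forced on both arms.
5. **Inequality metrics** — stratify the fitted curve into G equal patient
   groups; group k's median survival is the event-time quantile at
   p = (2k−1)/(2G). Report the **absolute inequality**
   `Δ = m_G − m_1` (for G = 2 and G = 5) and the **inequality gradient**
   `IG = Σ_k (k−3)·m_k / 10` (OLS slope of the five group medians on the
   group index, months per group).
6. **Impact with uncertainty** — intervention-vs-comparator differences
   (absolute months and % of comparator), propagated through a
   multivariate-normal probabilistic analysis on the transformed parameter
   scale (mean and empirical 95% interval per metric).

A synthetic-data module generates trial-like right-censored arms with known
truth (uniform accrual, administrative + exponential dropout censoring) and
"digitizes" them into the exact input format, so the whole pipeline is
testable offline.

## Worked example

Run one of the bundled archetype scenarios end to end (simulate three
two-arm trials, digitize, reconstruct, pool, fit, select, analyze):

```bash
survineq simulate --archetype mcrc_like --out-dir inputs --seed 1
survineq run --config inputs/run_config.json --out-dir results_mcrc
```

which prints the selected family and a summary table:

```
selected family: loglogistic
metric                intervention            comparator            difference                    relative
----------------------------------------------------------------------------------------------------------
2-group           10.5 (9.7; 11.4)        7.6 (7.0; 8.2)        2.9 (1.8; 4.1)        38.2% (22.8%; 56.3%)
5-group          25.0 (22.8; 27.5)     18.1 (16.4; 19.9)       6.9 (4.1; 10.1)        38.4% (21.2%; 59.5%)
IG                  5.8 (5.3; 6.4)        4.2 (3.8; 4.6)        1.6 (1.0; 2.3)        38.4% (21.5%; 59.0%)
```

Reading: pooled over three simulated trials, the intervention raises the
gap between the best- and worst-surviving quintiles from 18.1 to 25.0
months — a **+6.9 month (95% CI 4.1–10.1) increase in 5-group survival
inequality** — and steepens the inequality gradient by 1.6 months per
quintile step. Intervals that exclude zero indicate a significant change.
The `mnsclc_like` archetype shows the opposite regime: crossing survival
curves where the 2-group inequality increases while the 5-group inequality
*decreases* with a wide interval spanning zero.

The same stages are available as library functions
(`reconstruct_ipd`, `pool_arms`, `fit_parametric` / `fit_mixture`,
`select_family`, `health_distribution`, `probabilistic_inequality`) and as
individual CLI subcommands (`reconstruct`, `pool`, `fit`, `select`,
`inequality`, `psa`).

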