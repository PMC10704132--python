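# Methods

## The health distribution and its inequality metrics

For one treatment arm with survival function S(t), patients are stratified
into G groups of equal size by their (latent) survival time: group 1 holds
the first 1/G of patients to die, group G the last. For a continuous
distribution the median survival of group k — the patients between the
(k−1)/G and k/G event-time quantiles — is exactly the event-time quantile
at probability

    p_k = (2k − 1) / (2G),

so the *health distribution* is the ordered vector of quantiles
m_k = S⁻¹(1 − p_k). Two stratifications are computed by default (G = 2 and
G = 5; quintiles are the convention for population health distributions,
and the 2-group split shows how conclusions depend on G). Three summaries:

- **absolute inequality** (months): m_G − m_1;
- **inequality gradient, IG** (months per group, G = 5 only): the OLS slope
  of m_k on the group index k = 1…5, which reduces to Σ_k (k−3)·m_k / 10.
  The regressor is the integer index, not the quintile midpoint; any affine
  recoding of the groups only rescales IG by a constant, and index coding
  gives it the natural unit "months per group step";
- **impact**: intervention minus comparator per metric, in months and as a
  percentage of the comparator.

Group medians are taken from the *fitted parametric model*, not from the
within-follow-up KM curve: the top group's median usually lies beyond
observed follow-up, which is exactly why parametric extrapolation is needed.
Non-evaluable quantiles (an improper model whose survival plateaus above
1 − p_k) are reported as missing, never capped at a horizon — capping would
bias inequality downward.

A deliberate non-goal is relative treatment-effect modeling (e.g. a hazard
ratio on the comparator's scale parameter): applying a uniform proportional
effect mechanically produces larger absolute gains for groups with higher
baseline survival and therefore widens inequality *by construction*. The
two arms are always fitted independently; a property test verifies the
mechanical widening under a uniform HR = 0.7.

## Pseudo-IPD reconstruction

Inputs are digitized KM coordinates (time, survival), the numbers-at-risk
table, and optionally the published total event count. Within each
risk-table interval the algorithm proposes a censoring count, spreads the
censoring times uniformly over the interval, recovers event counts at each
digitized step from the product-limit recursion
(d_k = round(n_k·(1 − S_k/Ŝ)), with Ŝ the running reconstructed estimate),
and iterates the censoring count until the reconstructed at-risk count
equals the published count at the next risk-table time. A table that cannot
be matched without negative censoring raises an error naming the interval.

In the final interval (no closing risk count) the censoring count is chosen
to minimize the deviation from the digitized steps, seeded by the average
censoring rate of the earlier intervals; subjects still at risk after the
last coordinate are administratively censored there. When the published
total event count is known, a final adjustment reconciles the reconstructed
count with it by swapping an event and a censoring *at the same time* — the
swap leaves every at-risk count unchanged and perturbs the curve by about
S/n, so the swap is made at the coordinate where that cost is smallest.

Conventions: ties resolve events-before-censorings (the product-limit
convention, required for exact round trips); coordinates are treated as
exact step values (digitization pixel noise is out of scope); a risk table
with only the initial sample size triggers a degraded no-dropout mode with
a warning. Weighted KM estimation (weights enter both the risk set and the
event count) and Greenwood variances support validation; each
reconstruction is validated by re-estimating its KM and reporting the
maximum absolute deviation from the input coordinates, the reconstructed
median, and the event-count comparison.

## Pooling

K studies inform each arm. Records of study j (size n_j) get weight
(N/K)/n_j, where N = Σ n_j: each study's weights sum to N/K (equal
contribution) and the total weight equals N. Keeping the total on the
subject scale — rather than normalizing mean weight to 1 per study —
preserves the information content of the weighted log-likelihood, so AIC
differences and covariance magnitudes remain on the natural sample-size
scale.

## Survival models

Six families, parameterized as in the mainstream parametric-survival
ecosystem:

| family | parameters | transform |
|---|---|---|
| exponential | rate λ>0 | log |
| gamma | shape a>0, rate r>0 | log, log |
| Gompertz | shape γ∈ℝ, rate λ>0 | identity, log |
| log-logistic | shape a>0, scale b>0 | log, log |
| log-normal | meanlog μ, sdlog σ>0 | identity, log |
| Weibull | shape a>0, scale b>0 | log, log |

plus two-component mixtures S = π·S₁ + (1−π)·S₂ (logit transform for π,
names canonicalized to alphabetical component order). The weighted
censored-data log-likelihood Σ w_i[δ_i log f + (1−δ_i) log S] is maximized
on the transformed scale (L-BFGS-B with a Nelder-Mead polish; moment-based
starting values). Mixtures use direct multi-start maximization (default 10
seeded starts: one split-at-the-median start plus jittered restarts) rather
than EM — for arbitrary censored component families direct maximization is
simpler and equally accurate at trial-size data. The mixing weight is
clamped to (1e−6, 1−1e−6); same-family mixtures order components by
ascending median to resolve label switching. The negative-shape Gompertz is
improper (plateau exp(λ/γ)); its out-of-range quantiles are NaN by design.

Covariances are inverse numerically-differentiated Hessians of the negative
weighted log-likelihood at the MLE, on the transformed scale; non-PD
results have eigenvalues floored at 1e−10 with a logged warning. The
closed-form check var(log λ̂) = 1/n for the uncensored exponential anchors
the implementation.

## Model selection

Extrapolated models must be plausible at 10 years, not just well-fitting in
follow-up. A candidate family is admissible iff, for *both* arms, modeled
survival at the horizon (default 120 months) does not exceed
`seer_rate · (1 + uplift)` — the registry 10-year relative survival rate
for the cancer type with a 10% relative allowance for post-registry-era
therapies. The original procedure's visual plausibility inspection is
operationalized as machine-checkable gates: every group median required
downstream must be evaluable for both arms, the extrapolated survival must
be a proper non-increasing curve on a grid, and a config-level veto list
allows an explicit analyst override. Admissible families are ranked by
combined AIC (intervention + comparator; the same family on both arms keeps
structural assumptions symmetric); ties break toward fewer parameters, then
lexicographic name. An empty admissible set raises an error listing every
exclusion reason; the result always carries a per-family audit trail.

## Probabilistic analysis

Parameters are drawn from MVN(θ̂, Σ̂) on the transformed scale (so every
draw back-transforms into the valid domain) independently per arm — the
arms were fitted separately and share no covariance. Per draw, all group
medians, inequality metrics and impacts are recomputed (vectorized over
draws; mixture quantiles by bracketed bisection); reported are the mean and
the empirical 2.5th/97.5th percentiles over evaluable draws, with 1,000
draws by default. Point estimates are therefore probabilistic means, and
the relative change is the per-draw relative change averaged over draws
(mean of ratios), matching the summary convention of probabilistic
analyses. An interval excluding zero is read as a significant change.

Draws whose required group medians are non-evaluable are counted and
excluded. Two mechanisms produce them: an improper draw (plateau above a
required level), and a draw beyond the plausibility bound of 1,200 months
(100 years) — under a nearly flat likelihood direction (e.g. a degenerate
mixture component) an MVN draw can predict medians of astronomically many
months, which would make the mean meaningless. The excluded count is always
reported, and more than 50% non-evaluable draws aborts the analysis as an
unstable extrapolation.

## Synthetic data and the bundled archetypes

`simulate_trial` draws event times from a truth model by quantile
inversion, censors at min(administrative, dropout) where administrative
censoring follows uniform accrual over an enrolment window and dropout is
exponential, and `digitize` emits exact KM step coordinates, a
numbers-at-risk table at regular intervals, and the total event count —
the published-figure representation the pipeline consumes. The generator
does *not* emulate digitization pixel noise or covariate-dependent
censoring, so passing round-trip tests show algorithmic fidelity on clean
extractions, not robustness to extraction error.

Three archetype scenarios (three studies per arm each) are bundled:

- **mbc_like** — log-logistic arms, shape 1.6, scales 22 vs 17 months;
  SEER-style 10-year rate 0.148; study sizes 300/400/520, 48-month
  follow-up. True 5-group inequality 81.3 vs 62.8 months (widening).
- **mcrc_like** — log-logistic arms, shape 1.8, scales 8 vs 6 months; rate
  0.10; sizes 280/350/500, 30-month follow-up. True 5-group inequality
  24.8 vs 18.6 months.
- **mnsclc_like** — gamma+weibull mixtures with *crossing* curves: the
  intervention (0.88·gamma(2.5, 0.18) ⊕ 0.12·weibull(1.6, 30)) improves
  the median while the comparator (0.84·gamma(2.2, 0.28) ⊕
  0.16·weibull(1.3, 75)) carries a heavier long-survivor tail. True
  5-group inequality *decreases* (≈24.6 vs ≈39.6 months) while the
  2-group inequality increases. Follow-up (36 months) ends while ~11% of
  comparator patients are alive, so the top-group median is
  extrapolation-driven and its interval is wide; study sizes 120/160/220
  keep the decrease non-significant (interval spanning zero), the regime
  in which the two stratifications genuinely disagree.

Scenario parameters were fixed from truth-model quantile calculations
(the tables above) before any pipeline run; censoring combines the accrual
mechanism with small exponential dropout rates (0.002–0.004/month).

## Numerical choices and problem sizes

- Optimization tolerances: convergence assessed by the finite-difference
  gradient norm at the optimum (flagged, not fatal); mixture fits keep the
  best of the multi-start incumbents.
- Quantile inversion: closed forms for all single families; mixtures by
  plateau-checked doubling bracket + 200-step bisection (|S(t)−(1−p)| well
  below 1e−8).
- All randomness flows from one root seed, split per stage/arm/family with
  CRC-derived `SeedSequence` keys; identical configuration and seed give
  byte-identical JSON output (sorted keys, no timestamps).
- Default problem sizes: 1,000 probabilistic draws; simulation-based checks
  use 10,000–50,000 subjects for parameter recovery and closed-form
  checks, 2,000/arm × 50 replicates for selection consistency, and
  500/arm × 200 replicates for interval coverage.

## Known limitations

- Reconstruction accuracy degrades when risk-table intervals are sparse or
  the digitized curve is noisy; the validation report (max KM deviation,
  event-count match) should be inspected per arm.
- The equal-contribution pooling weights studies, not patients; it answers
  "what does the average trial show", not "what does the average patient
  experience".
- Mixture likelihoods can be nearly flat when a component is weakly
  identified (few tail events); the covariance floor and the plausibility
  bound keep the probabilistic analysis finite, but wide, skewed intervals
  are the honest output in that regime.
- Interval-censored or left-truncated data, covariate regression, cure
  models, >2 mixture components and inequality indices beyond the
  max-min difference and the gradient (e.g. Gini-type measures) are out of
  scope.
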