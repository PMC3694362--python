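# Methods

## Burden model

Tick counts per host are modelled as NB2 negative binomial with log link:
`y_i ~ NB(mu_i, theta)` with `log mu_i = x_i' beta` and
`Var(y_i) = mu_i + mu_i^2 / theta`. The dispersion parameter is the **size**
`theta` (aggregation increases as `theta` decreases). Many libraries
parameterise by `alpha = 1/theta`; everything here is on the size scale.

Fitting alternates (1) IRLS updates of `beta` at fixed `theta` (delegated to
statsmodels' GLM with a fixed-size NB family) with (2) univariate
maximum-likelihood updates of `theta` at fixed fitted means (bounded search
on `log theta` in `[1e-4, 1e7]`), until the joint log-likelihood changes by
less than `1e-8` or 100 outer iterations are exhausted. Non-convergence sets
an explicit status and warns; it is never silent. All-zero responses return
a degenerate fit with status `degenerate_all_zero`.

Accounting conventions:

* deviance `2 Σ [y log(y/mu) − (y+theta) log((y+theta)/(mu+theta))]`, with
  `y log(y/mu) ≡ 0` at `y = 0`;
* `AIC = −2 loglik + 2(|beta| + 1)`, counting `theta` as one parameter, so
  models with different predictor sets are comparable on a common footing
  (some implementations condition on `theta`; this one does not);
* the null deviance entering the explained-deviance proportion
  `1 − D_res/D_null` uses the **same** `theta` as the fitted model, because
  deviance differences are only meaningful at a common dispersion. The null
  mean at any fixed `theta` is the sample mean, so no extra fit is needed.
* Wald standard errors come from the final IRLS step at the converged
  `theta` (test values are Wald z; the significance marks are
  `#` 0.1, `*` 0.05, `**` 0.01, `***` 0.001).

Stepwise selection starts from the intercept-only model (plus any forced
terms, e.g. the sex factor in the combined model), evaluates every
single-term addition and deletion, and applies the move with the lowest AIC
when it is strictly lower than the current AIC; ties break toward fewer
terms, then lexicographic names. `theta` is re-estimated for every candidate
model. Failed candidate fits are skipped and logged, never fatal.

Multicollinearity is diagnosed with `VIF_j = 1/(1 − R²_j)` from an OLS
regression of predictor `j` on the others (ordinal age class and numeric
year enter as-is); perfect collinearity reports `inf`, and the Poisson
Pearson `chi²/df` statistic quantifies the overdispersion that motivates the
NB family (for NB data it approaches `1 + mu/theta`).

## Deviance partitioning

The final model's explained deviance is split over the three factor groups —
Ind (total length, age class, kidney fat index, sex), Pop (deer and wild
boar censuses and their one- and two-year lags), Env (30-day mean
temperature, accumulated precipitation, Turc AET, year) — by
inclusion–exclusion over seven fitted models:

```
I   = D(full) − D(Pop+Env)        IP  = D(full) − D(Env) − I − P
P   = D(full) − D(Ind+Env)        IE  = D(full) − D(Pop) − I − E
E   = D(full) − D(Ind+Pop)        PE  = D(full) − D(Ind) − P − E
IPE = D(full) − I − P − E − IP − IE − PE
```

These rules are the unique solution of the linear system in which each
model's explained deviance is the sum of the components its factor set
touches; a generic n-group solver of that system ships alongside and serves
as an independent cross-check in the tests. The components sum to `D(full)`
exactly. Shared components may legitimately be negative (suppression) and
are reported unclamped. All partial models are fitted with `theta` fixed at
the full model's estimate (per-model re-estimation is available behind
`refit_theta=True`), again because deviance fractions are only comparable at
a common dispersion. Standardized components are expressed as % of
`D(full)`.

The pipeline partitions over the full candidate predictor pool rather than
each stepwise-selected subset: the three partitions then weigh identical
factor pools, and a final model that collapses onto a single group (which
happens for hinds in some replicates) still partitions cleanly.

## Calibration validation

"Evenly sized intervals" are implemented as equal-count (quantile) bins:
records are stably sorted by predicted burden and cut into contiguous groups
whose sizes differ by at most one. Equal-width binning on NB-skewed
predictions would leave most bins nearly empty and is available only behind
a flag. When a validation set has fewer than 10 records per requested bin,
the bin count is halved (to a minimum of 5) and the reduction logged;
`auto_reduce=False` disables this. Precision is operationalised as the
Spearman rank correlation of bin mean observed burden against bin order, and
accuracy as the observed/predicted ratio, overall and per bin; the source
study uses these terms qualitatively, so the metrics are this package's
operationalisation and are labelled as such in outputs. Cross-sex
application uses the source model's coefficients unchanged — no
recalibration. The 70/30 split is stratified by sex (each stratum cut at
`round(0.7 n)`), disjoint and exhaustive, and reproducible under seed.

## Covariates

* **Meteorology windows**: half-open 30-day windows strictly before the
  sampling date (the sampling day is excluded — "30 days before sampling"
  read literally). Missing days are an error listing the dates; nothing is
  imputed.
* **Turc AET**: `L = 300 + 25t + 0.05t³`, `AET = P/sqrt(0.9 + P²/L²)`. The
  formula is sometimes typeset with a spurious `×` in the heat term; the
  additive form is the standard one (the multiplicative form would make `L`
  vanish at 0 °C, which is physically and historically wrong). AET is not
  capped at `P` by default (`cap_at_precipitation=True` restores the classic
  convention). Note that at monthly scales `P²/L² ≪ 0.9`, so AET is nearly
  proportional to `P` (≈ `P/sqrt(0.9)`): AET and accumulated precipitation
  are almost collinear as predictors. Group-level analyses (partitioning)
  are unaffected; within the Env group the two share explained deviance, and
  stepwise usually retains whichever fits marginally better.
* **Censuses** enter at lags 0, 1 and 2 years; two pre-study census years
  guarantee the lags exist in year one.
* Sex is coded with males as reference (`sex_female`), age class as ordinal
  numeric 1–5, and year as a single numeric slope.

## Prevalence descriptives

The Wald interval `p ± 1.96 sqrt(p(1−p)/n)` (clamped to [0, 100]%, rounded
half-up to one decimal in reports) is the default because it reproduces the
published descriptive intervals exactly; the Wilson interval is available
behind a flag for real use, where it behaves better at extreme `p` or small
`n`.

## Synthetic cohort generator

The generator emulates the study conditions: 306 deer across 2004–2010 with
the published per-year totals (12, 36, 56, 64, 40, 60, 38) split by the
overall sex ratio; age classes drawn from the published sex × age-class
counts; morphometrics from the published moments (standard errors converted
to SDs via the class sample sizes; kidney fat index drawn from a
moment-matched gamma to keep it positive and right-skewed); sampling dates
drawn by the observed seasonal mix (heavily autumn/winter) and uniformly
within season; daily meteorology from a temperature sinusoid (15 ± 9.5 °C,
peak late July, 2 °C daily noise) and a seasonal wet-day/gamma rain model
tuned to ~500 mm/yr (the study area's 300–700 mm band); censuses as
independent annual draws around base levels matching the published series'
mean and spread.

Burdens are NB draws with `log mu = beta_sex' x` over (intercept, TL, age
class, KFI, AvT_M, AP_M, AET_M, deer census, boar census lag-2). The default
coefficient vectors encode the study's headline contrast and were calibrated
once, at design time:

* signs follow the published models (positive size/age/temperature/censuses,
  negative condition and precipitation);
* for males, individual + population terms carry most of the
  linear-predictor variance; for hinds, environmental terms dominate, with
  hind allometric coefficients at 0.7× the male magnitudes;
* the two intercepts were set so the simulated sex means match the published
  20.4 (males) and 2.4 (hinds) ticks/deer, averaged over replicate cohorts.

Conditional dispersion defaults to `k = 1` (NB size given covariates).
Marginal aggregation is much stronger — variance/mean ≈ 60–70, effective
marginal size ≈ 0.2 — because covariate heterogeneity spreads the means,
matching the strong aggregation typical of tick burdens. Collected ticks
mimic the field protocol: complete collection up to 30 ticks, binomial
subsampling (p = 0.3) above. The true linear predictor and mean are retained
per record for recovery tests.

What the generator does **not** emulate: host movement and home ranges,
spatial structure in questing-tick density, tick life-stage dynamics,
between-individual immune heterogeneity beyond the KFI covariate, and any
real dependence between censuses and weather. Passing tests therefore show
that the *analysis chain* behaves correctly under the assumed generating
process, not that the process captures every feature of the field data. One
concrete consequence: with NB counts at the published sex means, the
high-burden male dataset is intrinsically easier to rank than the hind
dataset (per-record relative noise ≈ `1/mu + 1/k`), so cross-applied models
score high bin-level rank correlations on males even when the hind model
carries little male-relevant structure. The field study's observation that
the hind model performed *worst* on males presumably reflects real-data
features outside this generator's scope; under the generator the asymmetry
is weak and often reversed (see the decisions recorded alongside the test
suite: the corresponding end-to-end check is expected to fail and is kept
honest rather than weakened).

## Problem sizes and numerical choices

Simulation-based tests use deliberately scaled problem sizes chosen for
stable statistics: coefficient-recovery at ~5,000 hosts per sex with
effects of ~0.4–0.6 SD each on the log scale (so a ±10% recovery band spans
several standard errors and tests estimator correctness, not sampling
noise); Wald coverage over 200 replicate cohorts of ~420 hosts; stepwise
operating characteristics over 100 replicates at n = 2,000 (a single noise
candidate for the false-inclusion rate, matching the per-term χ²₁ theory;
one true + five noise candidates for power); end-to-end sex-bias properties
over 50 default-sized cohorts. Tie-breaks, tolerances and iteration caps are
stated inline above; degenerate inputs (all-zero responses, constant
predictors, constant predictions, empty factor groups) are reported with
explicit statuses or errors rather than silently handled.
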