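# tickburden

Sex-biased drivers of tick parasitism on red deer (*Cervus elaphus*): an
analysis pipeline for overdispersed tick-burden counts, built around a
synthetic cohort generator with known ground truth.

## The problem

Adult exophilic ticks aggregate strongly on a few hosts, and red deer are
sharply dimorphic: males carry roughly an order of magnitude more ticks than
hinds. The question this pipeline addresses is *why* — do host **individual**
traits (body size, age, condition), host **population** traits (ungulate
densities in the current and preceding years) and the **environment**
(recent temperature, precipitation, evapotranspiration) drive burdens on
males and hinds with the same weights? The analysis answers it three ways:

1. **Negative-binomial burden models.** Tick counts per necropsied deer are
   modelled as NB2 with log link, `Var(y) = mu + mu^2/theta`, with predictors
   selected by a forward–backward stepwise search on AIC. Separate models for
   males, hinds, and both sexes combined with a sex factor.
2. **Deviance partitioning.** Each final model's explained deviance
   `1 − D_res/D_null` is split by inclusion–exclusion over seven partial
   models into pure `I`, `P`, `E` components and their overlaps
   (`IP`, `IE`, `PE`, `IPE`), e.g. `I = D(full) − D(Pop+Env)`.
3. **Cross-sex calibration.** A model fitted on one sex is applied unchanged
   to the other; predictions are binned into equal-count intervals of
   increasing predicted burden and scored for *precision* (rank correlation of
   bin mean observed burden vs bin order) and *accuracy* (observed/predicted
   ratio).

Covariates include the Turc actual evapotranspiration over the 30 days before
each sampling date, a hydric-stress index for questing ticks:

```
AET = P / sqrt(0.9 + P²/L²),   L = 300 + 25t + 0.05t³
```

with `P` the accumulated precipitation (mm) and `t` the mean temperature (°C)
of the window.

Individual-level deer records are not public, so the chain runs on synthetic
cohorts (`tickburden.synthetic`) that reproduce the study's structure — 306
deer over 7 years (182 males / 124 hinds), published morphometric moments and
age-class mix, Mediterranean meteorology, census series with lags — with
sex-specific generating coefficients retained per record for recovery tests.

## Worked example

Running the numbered analysis scripts in order:

```
python analysis/01_simulate_cohort.py
python analysis/02_descriptive_tables.py
python analysis/03_fit_models.py
python analysis/04_partition_deviance.py
python analysis/05_cross_validate.py
python analysis/06_full_pipeline.py
```

Step 02 recomputes the published descriptive margins:

```
prevalence total : 59.5% (95% CI 54.0-65.0)
mean counted ticks/deer : 13.1
deer census mean (2002-2010): 379.4
```

Step 03 prints the coefficient table (coefficient/Wald z, stars at
0.1/0.05/0.01/0.001). On the seed-1 cohort:

```
males:    theta=0.979  AIC=1211.5  explained deviance=47.25%  n=182
females:  theta=0.850  AIC=385.0   explained deviance=43.05%  n=124
combined: theta=0.823  AIC=1624.6  explained deviance=54.27%  n=306
sex_female (combined): -1.3475/-6.60 ***
```

— the combined model retains sex with a strongly negative hind coefficient
(hinds carry `exp(−1.35) ≈ 0.26` times the male burden at equal covariates).
Step 04 partitions each model's explained deviance:

```
(I+P) share: males 94.0% vs hinds 14.5%
E share:     males 15.0% vs hinds 82.1%
```

— individual + population factors dominate the male partition, environment
dominates the hind partition. Step 05 cross-applies the models:

```
male_model_on_females:  precision +0.98   accuracy 0.22
female_model_on_males:  precision +0.66   accuracy 7.11
combined_holdout:       precision +1.00   accuracy 1.03
```

— the male model ranks hind burdens almost perfectly (precise) while
overestimating them ~4.6-fold (not accurate); the combined model is
calibrated on its own held-out 30%.

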