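# nucleobayes

Bayesian multilevel pharmacokinetic modeling of urinary nucleoside
concentrations normalized by creatinine, for case/control metabolomics
studies whose groups are imbalanced and unmatched in age and sex.

## The problem

Urinary metabolite concentrations are routinely divided by creatinine to
remove urine-dilution (diuresis) effects. But creatinine excretion itself
depends on age and sex — renal function declines with age roughly as
age^-0.203 and is lower by a factor 0.742 in women (the MDRD relation) — so
in a study where cancer patients are older and more often male than the
healthy controls, a naive group comparison of nucleoside/creatinine ratios
confounds disease with demographics. `nucleobayes` addresses this with a
hierarchical regression on the log ratios that adjusts for age and sex with
physiologically informed priors and regularizes the disease effects.

## The model

For individual *i* and nucleoside *h* (typically the 13-nucleoside panel,
including methylthioadenosine, MTA), the standardized log ratio is

```
y_i ~ MVN(beta_0 + beta_age ln(age_i/50) + beta_sex sex_i + beta_cancer z_i,  Lambda)
```

with sex coded female = 1, status z coded cancer = 1, and a full p x p
between-subject covariance Lambda (parameterised internally by its
precision). Priors per nucleoside:

* `beta_cancer,h ~ N(0, sigma_cancer^2)` — a regularizing prior shrinking
  disease effects toward zero;
* `beta_age,h ~ N(0.203, sigma_age^2)` and `beta_sex,h ~ N(0.293,
  sigma_sex^2)` — informative means elicited from the MDRD creatinine
  relation (exp(0.203) = 1.22 per age doubling scale, 1/0.742 = 1.35 for
  women);
* `beta_0,h ~ N(0, 100^2)`; `sigma_* ~ Uniform(0.001, 1000)`;
* `Lambda^-1 ~ Wishart(rho Lambda_0, rho)` with `rho = p`,
  `Lambda_0 = 0.05 I` (prior expected precision 20 per coordinate).

The posterior is sampled by a blocked Gibbs sampler with exact conjugate
conditionals (default protocol: 3 chains x 6000 iterations, burn-in 3000,
thin 3, i.e. 3000 retained draws; convergence requires Gelman–Rubin < 1.2
for every parameter). Individuals whose status is unknown get a posterior
cancer probability by exact marginalization, `P(z=1|y,theta) =
L1/(L1+L0)` under a flat Beta(1,1) prior, averaged over posterior draws;
discrimination is summarized by the posterior distributions of AUROC,
sensitivity and specificity. Model criticism: percentile-band posterior
predictive checks, residual-vs-age diagnostics, DIC comparison of models
with and without the status covariate, and the posterior between-nucleoside
correlation matrix.

Because raw cohorts of this kind are generally not public, the package
includes a first-class synthetic-data module that generates cohorts with
the study's structure (248 individuals, 13 nucleosides, patients
64.04 ± 11.89 y / 73.4% male vs. controls 37.2 ± 15.36 y / 34.8% male),
either directly from the regression model or from the underlying
steady-state excretion mechanism (diuresis, lognormal excretion rates,
measurement error), in which creatinine normalization provably cancels
diuresis.

## Worked example

```python
import numpy as np
import nucleobayes as nb

cfg = nb.SimulationConfig(n=248, p=4, seed=1,
                          metabolite_names=["MTA", "I", "G", "A"],
                          true_beta_cancer=np.log([1.42, 1.25, 1.0, 1.0]))
cohort = nb.generate_cohort(cfg)
train, val = nb.split_cohort(cohort, 0.7, seed=1)
train_s, val_s = nb.standardize(train, val)

draws = nb.run_mcmc(train_s, settings=nb.McmcSettings(
    n_chains=3, n_iter=2000, burn_in=1000, thin=1, seed=1))
print("max R-hat:", round(float(nb.gelman_rubin(draws).max()), 3))

summary = nb.summarize_posterior(draws)
row = summary.loc["beta_cancer[MTA]"]
print("MTA cancer factor: %.2f (%.2f-%.2f)"
      % (row["factor_q50"], row["factor_q5"], row["factor_q95"]))

result = nb.classification_with_uncertainty(
    draws, val_s.with_hidden_status(), truth=val_s.status)
print(result.metric_summary().round(2))
```

prints

```
max R-hat: 1.007
MTA cancer factor: 1.50 (1.08-2.11)
             mean    q5   q50   q95
metric                             
auc          0.76  0.62  0.76  0.85
sensitivity  0.70  0.57  0.72  0.80
specificity  0.67  0.55  0.69  0.79
```

The chains mixed (R-hat well below 1.2). The cancer effect on MTA is
reported on the factor scale of the *standardized* log ratio — a
multiplicative effect whose 90% interval excludes 1, recovering the
injected signal — and the validation-set classification metrics carry
their full posterior uncertainty (here the injected effects make the
cohort more separable than a weak-signal panel would be; with no true
effect the AUC distribution centers on 0.5).

A `nucleobayes` command-line tool exposes the same stages
(`simulate`, `fit`, `ppc`, `dic`, `correlate`, `classify`, `pipeline`,
`report`); `nucleobayes pipeline --config cfg.yaml --seed 6 --out outdir`
runs the whole workflow and exits non-zero if any R-hat reaches 1.2
(disable with `--no-strict`).

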