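# Methods

## Observation model

Let m_ih be the measured urine concentration of nucleoside h in individual
i, and c_i the creatinine concentration. At steady state both are excretion
rate over diuresis, so on the log scale

    ln m_ih = ln(k_m,ih / V0_i) + eps_m,ih
    ln c_i  = ln(k_c,i  / V0_i) + eps_c,i

and the log ratio ln(m_ih/c_i) is free of the individual diuresis rate V0_i.
With lognormal inter-individual variability on the excretion rates, the log
ratio decomposes into a population mean plus a zero-mean residual kappa_ih
whose p x p covariance Lambda mixes between-subject rate variability and
measurement error of both the nucleoside and creatinine channels. The
regression layer puts the physiology into the mean:

    y_ih = beta_0,h + beta_age,h ln(age_i/50) + beta_sex,h sex_i
           + beta_cancer,h z_i + kappa_ih,
    kappa_i ~ MVN(0, Lambda),

on the standardized (train-scale) log ratios. beta_0,h is the level for a
50-year-old healthy man; sex is coded female = 1 and status cancer = 1, so
the positive sex prior mean matches the direction of the 1/0.742 creatinine
inflation in women. The coding is a modeling convention the data cannot
identify on their own; it is fixed here once and used consistently by the
generator, the likelihood and the classifier.

## Priors

* beta_cancer,h ~ N(0, sigma_cancer^2): regularizing; shrinks the p disease
  effects toward zero with a shared learned scale.
* beta_age,h ~ N(0.203, sigma_age^2), beta_sex,h ~ N(0.293, sigma_sex^2):
  informative means from the MDRD creatinine-excretion relation
  k_c ≈ 186 · age^-0.203 · [0.742 if female]. Only relative rates matter,
  so the 186 constant cancels everywhere. Note exp(0.293) = 1.340 is close
  to, but not exactly, 1/0.742 = 1.348; the conventional printed value
  0.293 is used verbatim.
* beta_0,h ~ N(0, sd 100) (precision 1e-4), independent per metabolite.
* sigma_cancer, sigma_age, sigma_sex ~ Uniform(0.001, 1000) on the
  standard-deviation scale. Out-of-support values evaluate to a -inf log
  prior rather than raising, so samplers reject naturally.
* Lambda^-1 ~ Wishart(rho Lambda_0, rho), rho = p, Lambda_0 = 0.05 I_p,
  in the convention where the first argument is the rate-like scale:
  E[Lambda^-1] = rho (rho Lambda_0)^-1 = Lambda_0^-1 = 20 I_p. In
  scipy terms this is `wishart(df=rho, scale=(rho*Lambda_0)^-1)`. DIC and
  density cross-checks depend on this convention, so it is fixed here.

## Sampling

The posterior is sampled by blocked Gibbs; every block is an exact draw
from its full conditional, which is what makes the short default burn-in
safe:

1. **Coefficients.** Stacking the 4 x p coefficient matrix column-wise, the
   conditional is Gaussian with precision `Omega ⊗ X'X + D` (Omega the
   current residual precision, X the n x 4 design with intercept, D the
   diagonal of per-coefficient prior precisions) and mean solving that
   system against `vec(X'Y Omega) + D m0`. Sampled via Cholesky.
2. **Residual precision.** Wishart with degrees of freedom rho + n and
   rate rho Lambda_0 + E'E (E the current residual matrix).
3. **Hyper-scales.** With a uniform prior on sigma, the precision
   u = sigma^-2 has density proportional to u^((p-3)/2) exp(-S u/2) with
   S the summed squared deviations of the p coefficients from their prior
   mean — a Gamma((p-1)/2, rate S/2) truncated to (10^-6, 10^6), sampled by
   inverse CDF. For p = 1 the shape is zero and a log-grid inverse CDF over
   the truncated support is used instead.

Initialization draws the coefficients and scales from their priors and
starts the precision at its prior mean Lambda_0^-1 = 20 I; because step 1
conditions only on Omega and the sigmas, the first coefficient draw is
already data-informed and wild initial points are forgotten in one sweep.
Numerical failure (a non-positive-definite conditional) triggers bounded
re-initialization (5 attempts) before failing with diagnostics.

Default protocol: 3 chains x 6000 iterations, first 3000 discarded, every
third retained — 1000 draws per chain, 3000 total. The retained count is
floor((n_iter - burn_in)/thin) per chain, with retained iteration indices
burn_in + thin, burn_in + 2 thin, ....

**Convergence.** The Gelman–Rubin potential scale reduction factor is
computed on the retained draws for every scalar parameter (all 4p
coefficients, the three hyper-scales and the p(p+1)/2 distinct precision
entries), using Vhat = (n-1)/n W + (1 + 1/m) B/n. Chains that are exactly
constant and identical are defined to give 1 (the degenerate 0/0 case).
Chains pass at max R-hat < 1.2.

## Classification of missing status

For a validation individual with observed y, age and sex but unknown
status, the flat Beta(1,1) prior over the per-individual cancer probability
marginalizes (for a single Bernoulli draw) to prior P(z=1) = 1/2, and the
per-draw posterior probability is the two-term Bayes rule
L1·pi / (L1·pi + L0·(1-pi)). Probabilities are computed per posterior draw
and per individual; the reported probability is the average over draws, and
AUROC/sensitivity/specificity are computed per draw and summarized by
their 5th/50th/95th percentiles, so the intervals propagate parameter
uncertainty. The marginalization is exact — a brute-force enumeration over
all 2^n status configurations (n ≤ 10) agrees to 1e-10 and is kept as a
test oracle. The classification threshold defaults to 0.5 and is exposed;
whether metrics are better computed per draw or on posterior-mean
probabilities is a genuine design choice — per draw was chosen to produce
interval-style metric reports, and the plug-in alternative is recoverable
from the returned probability matrix. The prior deliberately does not
encode disease prevalence; a prevalence-informed prior would be a
one-line change (the `prior_prob` argument) but is out of scope.

## Diagnostics

* **Posterior predictive check.** Each replicate draws theta from the
  posterior, simulates a full cohort from the MVN observation model at the
  observed covariates, and records the 5th/50th/95th percentile per
  metabolite. Bands are the central 90% interval of each percentile across
  replicates (default 500); an observed percentile outside its band flags
  misspecification.
* **Residuals.** Observed minus fitted at the posterior-mean parameters,
  reported against age and status, with the residual-age correlation as a
  scalar no-pattern check.
* **DIC.** Dbar is the posterior mean deviance (-2 log likelihood);
  pD = Dbar - D(theta_bar) with theta_bar the element-wise posterior mean
  of the coefficients and of the precision matrix (the classic plug-in;
  reported deltas depend on this choice). Negative pD warns rather than
  fails. The "model without status" is fitted by zeroing the status column,
  which removes the covariate from the likelihood while leaving the
  parameter block structure identical.
* **Correlation matrix.** Each precision draw is inverted and converted to
  a correlation matrix; the posterior mean of correlations is reported
  (not the correlation of posterior means — both are recoverable).
  Numerically singular draws are skipped and counted.

## Synthetic data

The generator is the package's stand-in for the kind of cohort this model
targets, which is typically not publicly deposited. Defaults are the
reference study conditions: n = 248, p = 13 nucleosides, prevalence
153/248, cases 64.04 ± 11.89 years / 73.4% male, controls 37.2 ± 15.36
years / 34.8% male; effects beta_age = 0.203 and beta_sex = 0.293 on all
metabolites, beta_cancer = ln(1.42) on MTA and ln(1.25) on inosine, zero
elsewhere; between-subject covariance with standard deviation 0.5 and
compound-symmetry correlation 0.4, with MTA decorrelated (0.1) from the
rest to mimic its distinct polyamine-pathway origin. Ages are group-normal
truncated at 18 (which shifts the control mean up by ~3.1 years relative
to the nominal 37.2; tests compare against the analytic truncated mean).
One master seed fans out to named substreams (status, ages, sexes,
residuals, mechanism, split) so adding draws to one stage never perturbs
another.

The mechanistic generator additionally simulates diuresis, lognormal rate
variability and measurement error at the raw-concentration level, scales
creatinine excretion by the MDRD age/sex relation, and verifies that
ratioing removes diuresis to machine precision.

What the generator does **not** emulate: below-detection-limit censoring,
batch/analytical drift, non-lognormal tails, covariate measurement error,
and any real biological correlation structure beyond the single
compound-symmetry + decorrelated-MTA pattern. Passing tests therefore show
the pipeline is correct and calibrated *under the model's own assumptions*,
not that the model fits any particular real cohort.

## Data handling choices

* The train/validation split is stratified by status with round-half-up
  stratum sizes; a published 178/70 split of 248 is not exactly 70%, so the
  procedure (not the exact counts) is what is reproduced.
* Standardization (per-metabolite center and scale) is computed on the
  training set only, after splitting, and applied to both sets; this
  avoids leakage into validation-set classification. Coefficients are
  therefore on the train-standardized scale, and simulation-truth
  comparisons divide the injected effects by the training scale.
* CSV is the interchange format (no metabolomics container standard covers
  a ratio table); sex is M/F, status cancer/healthy/NA, schema versioned in
  a header comment. A raw-concentration dialect computes
  ln(metabolite/creatinine) on read.

## Problem sizes used in the test suite

Unit and property tests run at small sizes (n = 120–400, p = 1–4, chains of
a few hundred iterations), chosen so exact conditionals keep R-hat well
below 1.2 at those lengths. The full-scale check (n = 248, p = 13, 3 x 6000
iterations) runs once in the acceptance suite and once in
`scripts/acceptance.py`. Replicated studies (coverage: 50 replicates;
PPC coverage and DIC direction: 10 each) use shortened chains; their
assertions carry binomial slack consistent with those replicate counts.

## Known limitations

* The Gibbs kernel relies on the conjugate structure; swapping in a
  non-conjugate prior (e.g. LKJ on the correlation) would require a
  different sampler. Wishart-only is intentional.
* DIC is the only model-comparison criterion (no WAIC/LOO).
* The classifier treats age and sex of validation individuals as observed;
  missing covariates other than status are not handled.
* pD can be negative for multimodal or poorly identified posteriors; it is
  reported with a warning.
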