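"""The hierarchical regression model as pure density evaluations.

Each individual's vector of standardized log nucleoside/creatinine ratios is
multivariate normal,

    y_i ~ MVN(beta0 + beta_age ln(age_i/50) + beta_sex sex_i
              + beta_cancer z_i,  Lambda),

parameterised here by the precision matrix ``lambda_prec`` = Lambda^-1.
Priors: a zero-mean regularizing normal on each cancer effect; informative
normals on the age (mean 0.203) and sex (mean 0.293) effects elicited from
the renal-function dependence of creatinine excretion (MDRD); a diffuse
normal (precision 1e-4, i.e. sd 100) on the intercepts; Uniform(0.001, 1000)
on the three hyper standard deviations; and Wishart(rho*Lambda0, rho) on the
precision, with rho = p and Lambda0 = 0.05 I so the prior expected precision
is 20 per coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import CohortData

MDRD_COEF = 186.0
MDRD_AGE_EXP = -0.203
MDRD_FEMALE_FACTOR = 0.742

COEF_NAMES = ("beta0", "beta_age", "beta_sex", "beta_cancer")


@dataclass
class PriorSpec:
    """Prior hyper-constants (all overridable; defaults are the canonical
    values of the model)."""

    cancer_prior_mean: float = 0.0
    age_prior_mean: float = 0.203
    sex_prior_mean: float = 0.293
    intercept_mean: float = 0.0
    intercept_precision: float = 0.0001
    sigma_bounds: tuple[float, float] = (0.001, 1000.0)
    wishart_df: float | None = None          # rho; defaults to p at use time
    wishart_scale_diag: float = 0.05         # Lambda0 = wishart_scale_diag * I_p

    def __post_init__(self) -> None:
        lo, hi = self.sigma_bounds
        if not 0 < lo < hi:
            raise ValueError("sigma_bounds must satisfy 0 < lo < hi")
        if self.intercept_precision <= 0:
            raise ValueError("intercept_precision must be positive")
        if self.wishart_scale_diag <= 0:
            raise ValueError("wishart_scale_diag must be positive")

    def rho(self, p: int) -> float:
        rho = self.wishart_df if self.wishart_df is not None else float(p)
        if rho < p:
            raise ValueError("Wishart degrees of freedom must be >= p")
        return rho

    def lambda0(self, p: int) -> np.ndarray:
        return self.wishart_scale_diag * np.eye(p)

    def coef_prior_means(self, p: int) -> np.ndarray:
        """(4, p) prior mean for each coefficient row."""
        return np.tile(
            np.array([
                self.intercept_mean, self.age_prior_mean,
                self.sex_prior_mean, self.cancer_prior_mean,
            ])[:, None],
            (1, p),
        )


@dataclass
class RegressionParams:
    """One point in parameter space: per-metabolite coefficients, the three
    hyper-scales and the residual precision matrix."""

    beta0: np.ndarray
    beta_age: np.ndarray
    beta_sex: np.ndarray
    beta_cancer: np.ndarray
    sigma_cancer: float
    sigma_age: float
    sigma_sex: float
    lambda_prec: np.ndarray

    def __post_init__(self) -> None:
        for f in COEF_NAMES:
            setattr(self, f, np.asarray(getattr(self, f), dtype=float))
        self.lambda_prec = np.asarray(self.lambda_prec, dtype=float)
        p = self.beta0.shape[0]
        for f in COEF_NAMES:
            if getattr(self, f).shape != (p,):
                raise ValueError(f"{f} must be a length-{p} vector")
        if self.lambda_prec.shape != (p, p):
            raise ValueError("lambda_prec must be p x p")
        if not np.allclose(self.lambda_prec, self.lambda_prec.T):
            raise ValueError("lambda_prec must be symmetric")

    @property
    def p(self) -> int:
        return self.beta0.shape[0]

    @property
    def coef_matrix(self) -> np.ndarray:
        """(4, p) stack of intercept, age, sex, cancer coefficients."""
        return np.vstack([self.beta0, self.beta_age, self.beta_sex, self.beta_cancer])


def mdrd_rate(age, sex):
    """Relative creatinine excretion rate from age and sex.

    k_c = 186 * age^-0.203, multiplied by 0.742 for women (sex code 1).
    Only ratios of this quantity are ever used, so the leading constant
    cancels in all model quantities.
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    rate = MDRD_COEF * age ** MDRD_AGE_EXP * MDRD_FEMALE_FACTOR ** sex
    return rate if rate.ndim else float(rate)


def build_design(cohort: CohortData) -> np.ndarray:
    """n x 3 covariate design: ln(age/50), sex (female=1), status (cancer=1).

    Rows with missing status are rejected — they belong to classification,
    where status is inferred rather than conditioned on.
    """
    if np.any(cohort.age <= 0):
        raise ValueError("ages must be positive")
    if np.any(cohort.status_missing):
        raise ValueError(
            "cohort contains individuals with missing status; the design "
            "matrix is defined only for fully observed cohorts"
        )
    return np.column_stack([np.log(cohort.age / 50.0), cohort.sex, cohort.status])


def _chol_precision(lambda_prec: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(lambda_prec)
    except np.linalg.LinAlgError:
        raise ValueError("lambda_prec is not positive definite") from None


def mvn_logpdf_prec(resid: np.ndarray, lambda_prec: np.ndarray) -> np.ndarray:
    """Row-wise MVN log-density at residuals ``resid`` (n, p) for a zero-mean
    normal with *precision* lambda_prec. Returns (n,) log-densities."""
    L = _chol_precision(lambda_prec)
    p = lambda_prec.shape[0]
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    quad = np.einsum("ij,ij->i", resid @ L, resid @ L)
    return 0.5 * (logdet - p * np.log(2.0 * np.pi) - quad)


def model_mean(params: RegressionParams, design: np.ndarray) -> np.ndarray:
    """(n, p) model mean for a given design matrix."""
    X = np.column_stack([np.ones(design.shape[0]), design])
    return X @ params.coef_matrix


def log_likelihood(params: RegressionParams, cohort: CohortData) -> float:
    """Sum over individuals of the p-variate normal log-density of y_i."""
    design = build_design(cohort)
    resid = cohort.y - model_mean(params, design)
    return float(np.sum(mvn_logpdf_prec(resid, params.lambda_prec)))


def _log_uniform(x: float, lo: float, hi: float) -> float:
    return -np.log(hi - lo) if lo < x < hi else -np.inf


def log_prior(params: RegressionParams, spec: PriorSpec) -> float:
    """Joint log prior density. Out-of-support hyper-scales yield -inf
    (natural rejection for samplers) rather than an exception."""
    p = params.p
    lo, hi = spec.sigma_bounds
    total = 0.0
    for sig in (params.sigma_cancer, params.sigma_age, params.sigma_sex):
        lp = _log_uniform(sig, lo, hi)
        if not np.isfinite(lp):
            return -np.inf
        total += lp
    total += float(np.sum(stats.norm.logpdf(
        params.beta_cancer, spec.cancer_prior_mean, params.sigma_cancer)))
    total += float(np.sum(stats.norm.logpdf(
        params.beta_age, spec.age_prior_mean, params.sigma_age)))
    total += float(np.sum(stats.norm.logpdf(
        params.beta_sex, spec.sex_prior_mean, params.sigma_sex)))
    total += float(np.sum(stats.norm.logpdf(
        params.beta0, spec.intercept_mean, 1.0 / np.sqrt(spec.intercept_precision))))
    rho = spec.rho(p)
    # Lambda^-1 ~ Wishart with rate-like first argument rho*Lambda0, i.e.
    # scale (rho*Lambda0)^-1 in the scipy convention: E[Lambda^-1] = Lambda0^-1.
    scale = np.linalg.inv(rho * spec.lambda0(p))
    total += float(stats.wishart.logpdf(params.lambda_prec, df=rho, scale=scale))
    return total


def log_posterior(params: RegressionParams, cohort: CohortData, spec: PriorSpec) -> float:
    """Unnormalised log posterior: log likelihood plus log prior."""
    lp = log_prior(params, spec)
    if not np.isfinite(lp):
        return -np.inf
    return log_likelihood(params, cohort) + lp
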