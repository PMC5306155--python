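"""Posterior sampling by blocked Gibbs, convergence diagnostics and summaries.

The model is conditionally conjugate, so every block has an exact full
conditional:

* the 4p regression coefficients are jointly matrix-normal given the
  residual precision and the hyper-scales (precision Omega (x) X'X plus the
  diagonal prior precision);
* the residual precision is Wishart given the coefficients;
* each hyper standard deviation sigma with a Uniform(0.001, 1000) prior has
  a truncated Gamma full conditional on the precision scale u = sigma^-2
  (shape (p-1)/2, rate S/2 with S the summed squared deviations of the
  coefficients from their prior mean).

The default protocol is three chains of 6000 iterations, the first 3000
discarded and every third retained, giving 3000 draws; convergence is judged
by the Gelman-Rubin potential scale reduction factor (< 1.2 for all scalar
parameters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from .data import CohortData
from .model import COEF_NAMES, PriorSpec, RegressionParams, build_design

logger = logging.getLogger("nucleobayes.inference")

MAX_INIT_RETRIES = 5


@dataclass
class McmcSettings:
    """Chain protocol: counts of chains, iterations, burn-in and thinning."""

    n_chains: int = 3
    n_iter: int = 6000
    burn_in: int = 3000
    thin: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")

    @property
    def retained_per_chain(self) -> int:
        # floor division: the canonical protocol (6000, 3000, 3) divides evenly
        return (self.n_iter - self.burn_in) // self.thin

    def retained_iterations(self) -> np.ndarray:
        """1-based iteration indices retained per chain:
        burn_in + thin, burn_in + 2 thin, ..."""
        return self.burn_in + self.thin * np.arange(1, self.retained_per_chain + 1)


@dataclass
class PosteriorDraws:
    """Retained posterior draws with chain labels.

    ``beta`` has shape (n_draws, 4, p) stacking intercept, age, sex and
    cancer coefficient rows; ``sigma`` is (n_draws, 3) in the order cancer,
    age, sex; ``lambda_prec`` is (n_draws, p, p).
    """

    beta: np.ndarray
    sigma: np.ndarray
    lambda_prec: np.ndarray
    chain_id: np.ndarray
    iteration: np.ndarray
    metabolite_names: list[str]
    settings: McmcSettings

    SIGMA_NAMES = ("sigma_cancer", "sigma_age", "sigma_sex")

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def p(self) -> int:
        return self.beta.shape[2]

    def params_at(self, idx: int) -> RegressionParams:
        return RegressionParams(
            beta0=self.beta[idx, 0], beta_age=self.beta[idx, 1],
            beta_sex=self.beta[idx, 2], beta_cancer=self.beta[idx, 3],
            sigma_cancer=float(self.sigma[idx, 0]),
            sigma_age=float(self.sigma[idx, 1]),
            sigma_sex=float(self.sigma[idx, 2]),
            lambda_prec=self.lambda_prec[idx],
        )

    def posterior_mean_params(self) -> RegressionParams:
        """Point estimate used for DIC and residuals: element-wise posterior
        means of the coefficients and of the precision matrix."""
        b = self.beta.mean(axis=0)
        s = self.sigma.mean(axis=0)
        return RegressionParams(
            beta0=b[0], beta_age=b[1], beta_sex=b[2], beta_cancer=b[3],
            sigma_cancer=float(s[0]), sigma_age=float(s[1]), sigma_sex=float(s[2]),
            lambda_prec=self.lambda_prec.mean(axis=0),
        )

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """Every scalar parameter as a (n_draws,) array, keyed by name."""
        out: dict[str, np.ndarray] = {}
        for k, row in enumerate(COEF_NAMES):
            for h, met in enumerate(self.metabolite_names):
                out[f"{row}[{met}]"] = self.beta[:, k, h]
        for k, name in enumerate(self.SIGMA_NAMES):
            out[name] = self.sigma[:, k]
        p = self.p
        for i in range(p):
            for j in range(i, p):
                out[f"lambda_prec[{i},{j}]"] = self.lambda_prec[:, i, j]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Columnar text-friendly layout: chain and iteration columns plus
        one column per scalar parameter."""
        cols = {"chain": self.chain_id, "iteration": self.iteration}
        cols.update(self.scalar_draws())
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, settings: McmcSettings | None = None
                   ) -> "PosteriorDraws":
        beta_cols = [c for c in frame.columns if c.startswith("beta0[")]
        mets = [c[len("beta0["):-1] for c in beta_cols]
        p = len(mets)
        n = len(frame)
        beta = np.empty((n, 4, p))
        for k, row in enumerate(COEF_NAMES):
            for h, met in enumerate(mets):
                beta[:, k, h] = frame[f"{row}[{met}]"].to_numpy()
        sigma = np.column_stack([frame[s].to_numpy() for s in cls.SIGMA_NAMES])
        lam = np.empty((n, p, p))
        for i in range(p):
            for j in range(i, p):
                v = frame[f"lambda_prec[{i},{j}]"].to_numpy()
                lam[:, i, j] = v
                lam[:, j, i] = v
        if settings is None:
            n_chains = int(frame["chain"].nunique())
            settings = McmcSettings(
                n_chains=max(n_chains, 2), n_iter=max(n // max(n_chains, 1), 2),
                burn_in=0, thin=1, seed=0,
            )
        return cls(
            beta=beta, sigma=sigma, lambda_prec=lam,
            chain_id=frame["chain"].to_numpy(),
            iteration=frame["iteration"].to_numpy(),
            metabolite_names=mets, settings=settings,
        )


def _sample_sigma(rng: np.random.Generator, ssq: float, p: int,
                  bounds: tuple[float, float]) -> float:
    """Draw sigma from its full conditional under a Uniform(lo, hi) prior.

    On the precision scale u = sigma^-2 the conditional is
    Gamma((p-1)/2, rate ssq/2) truncated to (hi^-2, lo^-2); sampled by
    inverse CDF. The p=1 case (shape 0) falls back to a log-grid inverse CDF
    of the improper-but-truncated density u^-1 exp(-ssq u / 2).
    """
    lo, hi = bounds
    u_lo, u_hi = hi ** -2, lo ** -2
    shape = (p - 1) / 2.0
    if shape > 0 and ssq > 0:
        g = stats.gamma(a=shape, scale=2.0 / ssq)
        c_lo, c_hi = g.cdf(u_lo), g.cdf(u_hi)
        if c_hi - c_lo > 1e-12:
            u = g.ppf(c_lo + rng.random() * (c_hi - c_lo))
            return float(np.clip(u, u_lo, u_hi)) ** -0.5
    # degenerate/flat cases: numeric inverse CDF on a log grid
    log_u = np.linspace(np.log(u_lo), np.log(u_hi), 4096)
    u = np.exp(log_u)
    log_dens = shape * log_u - 0.5 * ssq * u  # density of u times u (log-grid)
    w = np.exp(log_dens - log_dens.max())
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return float(np.interp(rng.random(), cdf, u)) ** -0.5


def _init_state(rng: np.random.Generator, p: int, spec: PriorSpec):
    """Prior draws for the coefficients and hyper-scales; precision starts at
    Lambda0^-1 (its prior expectation)."""
    lo, hi = spec.sigma_bounds
    sigma = rng.uniform(lo, hi, size=3)  # cancer, age, sex
    m0 = spec.coef_prior_means(p)
    sds = np.array([1.0 / np.sqrt(spec.intercept_precision), sigma[1], sigma[2], sigma[0]])
    beta = m0 + sds[:, None] * rng.standard_normal((4, p))
    prec = np.linalg.inv(spec.lambda0(p))
    return beta, sigma, prec


def _run_chain(cohort: CohortData, spec: PriorSpec, settings: McmcSettings,
               rng: np.random.Generator):
    y = cohort.y
    n, p = y.shape
    X = np.column_stack([np.ones(n), build_design(cohort)])
    XtX = X.T @ X
    rho = spec.rho(p)
    prior_rate = rho * spec.lambda0(p)          # rate-like Wishart first argument
    m0 = spec.coef_prior_means(p)               # (4, p)
    n_keep = settings.retained_per_chain

    beta_out = np.empty((n_keep, 4, p))
    sigma_out = np.empty((n_keep, 3))
    lam_out = np.empty((n_keep, p, p))

    for attempt in range(MAX_INIT_RETRIES):
        try:
            beta, sigma, prec = _init_state(rng, p, spec)
            kept = 0
            for t in range(1, settings.n_iter + 1):
                # --- coefficients | precision, sigmas (matrix-normal) ---
                row_prec = np.array([
                    spec.intercept_precision,
                    sigma[1] ** -2, sigma[2] ** -2, sigma[0] ** -2,
                ])
                d = np.tile(row_prec, p)                      # vec_F order: h outer
                P = np.kron(prec, XtX)
                P[np.diag_indices_from(P)] += d
                rhs = (X.T @ y @ prec).flatten(order="F") + d * m0.flatten(order="F")
                c, low = sla.cho_factor(P, lower=True)
                mean = sla.cho_solve((c, low), rhs)
                z = rng.standard_normal(4 * p)
                bvec = mean + sla.solve_triangular(c, z, lower=True, trans="T")
                beta = bvec.reshape((p, 4)).T                 # undo vec_F

                # --- residual precision | coefficients (Wishart) ---
                resid = y - X @ beta
                post_scale = np.linalg.inv(prior_rate + resid.T @ resid)
                post_scale = 0.5 * (post_scale + post_scale.T)
                prec = stats.wishart.rvs(df=rho + n, scale=post_scale, random_state=rng)

                # --- hyper-scales | coefficients (truncated gamma) ---
                for k, row in ((0, 3), (1, 1), (2, 2)):       # cancer, age, sex
                    ssq = float(np.sum((beta[row] - m0[row]) ** 2))
                    sigma[k] = _sample_sigma(rng, ssq, p, spec.sigma_bounds)

                if t > settings.burn_in and (t - settings.burn_in) % settings.thin == 0:
                    beta_out[kept] = beta
                    sigma_out[kept] = sigma
                    lam_out[kept] = prec
                    kept += 1
            return beta_out, sigma_out, lam_out
        except (np.linalg.LinAlgError, sla.LinAlgError) as exc:
            logger.warning("chain initialization attempt %d failed: %s", attempt + 1, exc)
    raise RuntimeError(
        f"MCMC failed to initialize after {MAX_INIT_RETRIES} attempts; "
        "check the cohort for degenerate columns"
    )


def run_mcmc(cohort: CohortData, spec: PriorSpec | None = None,
             settings: McmcSettings | None = None) -> PosteriorDraws:
    """Sample the posterior of the hierarchical model on a training cohort.

    The cohort must be standardized and have fully observed status. Draws
    are reproducible for a given ``settings.seed``; each chain uses an
    independent child stream.
    """
    spec = spec or PriorSpec()
    settings = settings or McmcSettings()
    if not cohort.standardized:
        raise ValueError("cohort must be standardized before fitting")
    if np.any(cohort.status_missing):
        raise ValueError("training cohort must have fully observed status")

    p = cohort.p
    n_keep = settings.retained_per_chain
    streams = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    beta = np.empty((settings.n_chains * n_keep, 4, p))
    sigma = np.empty((settings.n_chains * n_keep, 3))
    lam = np.empty((settings.n_chains * n_keep, p, p))
    chain_id = np.repeat(np.arange(settings.n_chains), n_keep)
    iteration = np.tile(settings.retained_iterations(), settings.n_chains)

    for c, ss in enumerate(streams):
        logger.info("running chain %d/%d (%d iterations)", c + 1,
                    settings.n_chains, settings.n_iter)
        b, s, l = _run_chain(cohort, spec, settings, np.random.default_rng(ss))
        sl = slice(c * n_keep, (c + 1) * n_keep)
        beta[sl], sigma[sl], lam[sl] = b, s, l

    return PosteriorDraws(
        beta=beta, sigma=sigma, lambda_prec=lam, chain_id=chain_id,
        iteration=iteration, metabolite_names=list(cohort.metabolite_names),
        settings=settings,
    )


def psrf(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` is (m, n): m chains of n draws. Constant identical chains
    (zero within- and between-chain variance) are defined to give 1.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    if m < 2 or n < 2:
        raise ValueError("psrf needs at least 2 chains of at least 2 draws")
    means = chains.mean(axis=1)
    w = float(np.mean(chains.var(axis=1, ddof=1)))
    b_over_n = float(np.var(means, ddof=1))
    if w == 0.0:
        return 1.0 if b_over_n == 0.0 else np.inf
    v_hat = (n - 1) / n * w + (1.0 + 1.0 / m) * b_over_n
    return float(np.sqrt(v_hat / w))


def gelman_rubin(draws: PosteriorDraws) -> pd.Series:
    """Gelman-Rubin statistic for every scalar parameter, computed on the
    retained (post burn-in, thinned) draws."""
    chains = np.unique(draws.chain_id)
    if chains.size < 2:
        raise ValueError("Gelman-Rubin diagnostics require at least 2 chains")
    out = {}
    for name, values in draws.scalar_draws().items():
        stacked = np.stack([values[draws.chain_id == c] for c in chains])
        out[name] = psrf(stacked)
    return pd.Series(out, name="gelman_rubin")


_EFFECT_ROWS = ("beta_age", "beta_sex", "beta_cancer")


def summarize_posterior(draws: PosteriorDraws,
                        percentiles: tuple[float, ...] = (5, 25, 50, 75, 95)
                        ) -> pd.DataFrame:
    """Per-parameter posterior summary (mean and requested percentiles).

    Covariate effects are additionally summarized on the factor scale
    (exponentiated), so a cancer effect reads directly as a multiplicative
    change in the nucleoside/creatinine excretion-rate ratio, e.g.
    "1.42 (1.09-2.03)". Because exp is monotone, factor percentiles are the
    exponentials of the log-scale percentiles.
    """
    if draws.n_draws == 0:
        raise ValueError("no draws to summarize")
    pcts = tuple(float(q) for q in percentiles)
    if any(not 0 < q < 100 for q in pcts):
        raise ValueError("percentiles must lie strictly between 0 and 100")
    rows = []
    for name, values in draws.scalar_draws().items():
        row = {"parameter": name, "mean": float(np.mean(values))}
        for q in pcts:
            row[f"q{q:g}"] = float(np.percentile(values, q))
        is_effect = any(name.startswith(e + "[") for e in _EFFECT_ROWS)
        if is_effect:
            with np.errstate(over="ignore"):  # prior-only effects can be huge
                row["factor_mean"] = float(np.mean(np.exp(values)))
                for q in pcts:
                    row[f"factor_q{q:g}"] = float(np.exp(np.percentile(values, q)))
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
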