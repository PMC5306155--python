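"""Model criticism: posterior predictive checks, residuals, DIC and the
between-metabolite posterior correlation structure.

The posterior predictive check follows the percentile-band convention: for
each replicate, a parameter draw is taken from the posterior, a full data
set is simulated from the multivariate-normal observation model, and the
5th/50th/95th percentiles of each metabolite are recorded. If an observed
percentile falls outside the 90% interval of the replicated percentiles,
there is evidence of model misspecification.

DIC uses the classic effective-parameter definition pD = Dbar - D(theta_bar)
with theta_bar the element-wise posterior mean of the coefficients and of
the precision matrix; DIC = Dbar + pD. Reported deltas therefore depend on
this pD convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CohortData
from .inference import PosteriorDraws
from .model import build_design, log_likelihood, model_mean

logger = logging.getLogger("nucleobayes.diagnostics")

PPC_PERCENTILES = (5.0, 50.0, 95.0)
PPC_BAND_LEVEL = 90.0  # central interval across replicates


@dataclass
class PpcSummary:
    """Observed percentiles against replicated percentile bands, per
    metabolite."""

    table: pd.DataFrame  # metabolite, percentile, observed, band_lo, band_hi, inside
    n_rep: int

    @property
    def n_outside(self) -> int:
        return int((~self.table["inside"]).sum())

    @property
    def all_inside(self) -> bool:
        return self.n_outside == 0


@dataclass
class DicResult:
    dbar: float
    pd_eff: float

    @property
    def dic(self) -> float:
        return self.dbar + self.pd_eff


def posterior_predictive_check(draws: PosteriorDraws, cohort: CohortData,
                               n_rep: int = 500,
                               seed: int = 0) -> PpcSummary:
    """Percentile-band posterior predictive check on a fitted cohort.

    Each replicate re-simulates the full cohort (same covariates) from one
    posterior draw; bands are the central 90% interval of each percentile
    across replicates.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be at least 2")
    rng = np.random.default_rng(seed)
    design = build_design(cohort)
    n, p = cohort.y.shape
    pick = rng.integers(0, draws.n_draws, size=n_rep)
    rep_pct = np.empty((n_rep, len(PPC_PERCENTILES), p))
    for r, d in enumerate(pick):
        params = draws.params_at(int(d))
        cov = np.linalg.inv(params.lambda_prec)
        L = np.linalg.cholesky(0.5 * (cov + cov.T))
        y_rep = model_mean(params, design) + rng.standard_normal((n, p)) @ L.T
        rep_pct[r] = np.percentile(y_rep, PPC_PERCENTILES, axis=0)
    obs_pct = np.percentile(cohort.y, PPC_PERCENTILES, axis=0)
    tail = (100.0 - PPC_BAND_LEVEL) / 2.0
    lo = np.percentile(rep_pct, tail, axis=0)
    hi = np.percentile(rep_pct, 100.0 - tail, axis=0)
    rows = []
    for h, met in enumerate(cohort.metabolite_names):
        for k, q in enumerate(PPC_PERCENTILES):
            rows.append({
                "metabolite": met, "percentile": q,
                "observed": obs_pct[k, h],
                "band_lo": lo[k, h], "band_hi": hi[k, h],
                "inside": bool(lo[k, h] <= obs_pct[k, h] <= hi[k, h]),
            })
    return PpcSummary(table=pd.DataFrame(rows), n_rep=n_rep)


def residuals(draws: PosteriorDraws, cohort: CohortData) -> pd.DataFrame:
    """Observed minus posterior-mean fitted values, with age and status for
    plotting; also reports the residual-vs-ln(age/50) correlation per
    metabolite as a no-pattern check."""
    params = draws.posterior_mean_params()
    design = build_design(cohort)
    resid = cohort.y - model_mean(params, design)
    frames = []
    lage = design[:, 0]
    for h, met in enumerate(cohort.metabolite_names):
        r = resid[:, h]
        corr = float(np.corrcoef(r, lage)[0, 1]) if np.std(r) > 0 else 0.0
        frames.append(pd.DataFrame({
            "id": cohort.ids, "metabolite": met, "age": cohort.age,
            "status": cohort.status, "residual": r,
            "age_correlation": corr,
        }))
    return pd.concat(frames, ignore_index=True)


def dic(draws: PosteriorDraws, cohort: CohortData) -> DicResult:
    """Deviance information criterion on a fitted cohort.

    Dbar is the posterior mean of the deviance -2 log L; pD subtracts the
    deviance at the posterior-mean parameters. Negative pD is reported with
    a warning rather than an error (it can occur for poorly behaved
    posteriors).
    """
    devs = np.empty(draws.n_draws)
    for d in range(draws.n_draws):
        devs[d] = -2.0 * log_likelihood(draws.params_at(d), cohort)
    dbar = float(np.mean(devs))
    d_at_mean = -2.0 * log_likelihood(draws.posterior_mean_params(), cohort)
    pd_eff = dbar - d_at_mean
    if pd_eff < 0:
        logger.warning("negative effective parameter count pD = %.3f", pd_eff)
    return DicResult(dbar=dbar, pd_eff=pd_eff)


def compare_dic(model_with: DicResult, model_without: DicResult) -> float:
    """Delta DIC = DIC(without the covariate) - DIC(with); positive favours
    the model that includes it."""
    return model_without.dic - model_with.dic


def nucleoside_correlation(draws: PosteriorDraws, order: bool = False
                           ) -> pd.DataFrame:
    """Posterior-mean between-metabolite correlation matrix.

    Each precision draw is inverted to the covariance Lambda and converted
    to a correlation matrix; the average over draws is reported. Numerically
    singular draws are skipped with a logged count. With ``order=True`` the
    rows/columns are sorted by average correlation with the others.
    """
    p = draws.p
    acc = np.zeros((p, p))
    used = 0
    skipped = 0
    for d in range(draws.n_draws):
        try:
            cov = np.linalg.inv(draws.lambda_prec[d])
            sd = np.sqrt(np.diag(cov))
            if np.any(~np.isfinite(sd)) or np.any(sd <= 0):
                raise np.linalg.LinAlgError("non-positive variance")
            acc += cov / np.outer(sd, sd)
            used += 1
        except np.linalg.LinAlgError:
            skipped += 1
    if skipped:
        logger.warning("skipped %d numerically singular precision draws", skipped)
    if used == 0:
        raise ValueError("no invertible precision draws")
    corr = acc / used
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 1.0)
    names = list(draws.metabolite_names)
    if order:
        offdiag = corr - np.eye(p)
        idx = np.argsort(-np.abs(offdiag).sum(axis=1))
        corr = corr[np.ix_(idx, idx)]
        names = [names[i] for i in idx]
    return pd.DataFrame(corr, index=names, columns=names)
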