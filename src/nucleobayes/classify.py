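"""Posterior disease-probability classification for individuals whose status
is missing, plus ROC-based discrimination summaries with posterior
uncertainty.

Given a posterior draw of the regression parameters, an individual's cancer
probability follows from Bayes' rule over the two status values: with a flat
Beta(1,1) prior on the per-individual probability (which marginalizes to a
prior P(z=1) = 1/2 for a single Bernoulli draw),

    P(z_i = 1 | y_i, theta) = L1 / (L1 + L0),

where L_z is the multivariate-normal likelihood of y_i at status z. This
exact marginalization over both the latent status and its Beta parameter is
used instead of discrete Gibbs sampling — the posterior is identical and
there are no discrete-chain mixing concerns. Conditional on theta the
individuals are independent, so the joint posterior factorizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .data import CohortData
from .inference import PosteriorDraws
from .model import RegressionParams, _chol_precision

PRIOR_CANCER_PROB = 0.5  # E[p_i] under Beta(1,1)


@dataclass
class ClassificationResult:
    """Per-individual posterior cancer probabilities and the posterior
    distributions of the discrimination metrics."""

    per_individual: pd.DataFrame       # id, posterior_prob_mean, q5, q95
    prob_draws: np.ndarray             # (n_draws, n_individuals)
    auc_dist: np.ndarray
    sens_dist: np.ndarray
    spec_dist: np.ndarray
    threshold: float

    def metric_summary(self, percentiles=(5, 50, 95)) -> pd.DataFrame:
        rows = []
        for name, dist in (("auc", self.auc_dist),
                           ("sensitivity", self.sens_dist),
                           ("specificity", self.spec_dist)):
            row = {"metric": name, "mean": float(np.mean(dist))}
            for q in percentiles:
                row[f"q{q:g}"] = float(np.percentile(dist, q))
            rows.append(row)
        return pd.DataFrame(rows).set_index("metric")


def _loglik_by_status(params: RegressionParams, val: CohortData) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual MVN log-likelihoods at status 0 and 1 (age and sex
    observed, status counterfactual)."""
    L = _chol_precision(params.lambda_prec)
    base = (
        params.beta0[None, :]
        + np.outer(np.log(val.age / 50.0), params.beta_age)
        + np.outer(val.sex, params.beta_sex)
    )
    r0 = (val.y - base) @ L
    r1 = (val.y - base - params.beta_cancer[None, :]) @ L
    # constants (log det, 2*pi) cancel in the likelihood ratio but are kept
    # so the values are genuine log-densities
    p = val.p
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    const = 0.5 * (logdet - p * np.log(2.0 * np.pi))
    q0 = np.einsum("ij,ij->i", r0, r0)
    q1 = np.einsum("ij,ij->i", r1, r1)
    return const - 0.5 * q0, const - 0.5 * q1


def _check_scale_match(draws_or_train, val: CohortData) -> None:
    if not val.standardized:
        raise ValueError("validation cohort must be standardized with the training scale")


def cancer_posterior(draws: PosteriorDraws, val: CohortData,
                     prior_prob: float = PRIOR_CANCER_PROB
                     ) -> tuple[pd.DataFrame, np.ndarray]:
    """Posterior cancer probabilities for each validation individual.

    For every retained parameter draw, applies the two-term Bayes rule with
    prior probability ``prior_prob`` (0.5 under the flat Beta(1,1) prior);
    the per-individual posterior probability is the average over draws. The
    full (n_draws, n_individuals) probability matrix is returned alongside
    the summary for uncertainty propagation.
    """
    _check_scale_match(draws, val)
    if not 0.0 < prior_prob < 1.0:
        raise ValueError("prior_prob must lie strictly inside (0, 1)")
    probs = np.empty((draws.n_draws, val.n))
    log_odds_prior = np.log(prior_prob) - np.log1p(-prior_prob)
    for d in range(draws.n_draws):
        l0, l1 = _loglik_by_status(draws.params_at(d), val)
        probs[d] = special.expit(l1 - l0 + log_odds_prior)
    summary = pd.DataFrame({
        "id": val.ids,
        "posterior_prob_mean": probs.mean(axis=0),
        "q5": np.percentile(probs, 5, axis=0),
        "q95": np.percentile(probs, 95, axis=0),
    })
    return summary, probs


def brute_force_posterior(fixed_params: RegressionParams, val: CohortData,
                          prior_prob: float = PRIOR_CANCER_PROB) -> np.ndarray:
    """Enumeration oracle: P(z_i = 1 | y, theta) by summing the joint
    likelihood-times-prior mass over all 2^n status configurations.

    Limited to n <= 10 individuals (combinatorial guard). Must agree with
    :func:`cancer_posterior` at the same fixed parameters.
    """
    _check_scale_match(fixed_params, val)
    n = val.n
    if n > 10:
        raise ValueError("brute-force enumeration is limited to n <= 10 individuals")
    l0, l1 = _loglik_by_status(fixed_params, val)
    post = np.zeros(n)
    total = 0.0
    for mask in range(2 ** n):
        z = np.array([(mask >> i) & 1 for i in range(n)], dtype=float)
        loglik = float(np.sum(np.where(z == 1.0, l1, l0)))
        logprior = float(np.sum(np.where(z == 1.0, np.log(prior_prob),
                                         np.log1p(-prior_prob))))
        w = np.exp(loglik + logprior - (l0.sum()))  # stabilised by a constant
        total += w
        post += w * z
    return post / total


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the ROC curve as the Mann-Whitney concordance probability.

    Equals the probability that a randomly drawn diseased individual scores
    higher than a randomly drawn healthy one; tied scores count 1/2. Both
    classes must be present. Invariant to monotone transforms of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=float)
    n_pos = int(np.sum(truth == 1))
    n_neg = int(np.sum(truth == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute the AUC")
    ranks = stats.rankdata(scores)  # midranks handle ties as 1/2
    rank_sum_pos = float(np.sum(ranks[truth == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def sensitivity_specificity(scores: np.ndarray, truth: np.ndarray,
                            threshold: float = 0.5) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) when classifying
    positive iff score > threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if np.sum(truth == 1) == 0 or np.sum(truth == 0) == 0:
        raise ValueError("both classes must be present")
    pred = scores > threshold
    tp = int(np.sum(pred & (truth == 1)))
    fn = int(np.sum(~pred & (truth == 1)))
    tn = int(np.sum(~pred & (truth == 0)))
    fp = int(np.sum(pred & (truth == 0)))
    return tp / (tp + fn), tn / (tn + fp)


def classification_with_uncertainty(draws: PosteriorDraws, val: CohortData,
                                    truth: np.ndarray,
                                    threshold: float = 0.5,
                                    prior_prob: float = PRIOR_CANCER_PROB
                                    ) -> ClassificationResult:
    """Discrimination metrics with posterior uncertainty.

    AUC, sensitivity and specificity are computed for every posterior draw
    from that draw's per-individual probabilities, so their spread reflects
    parameter uncertainty; summaries report the 5th/50th/95th percentiles.
    ``truth`` is used only for evaluation, never during inference.
    """
    truth = np.asarray(truth, dtype=float)
    summary, probs = cancer_posterior(draws, val, prior_prob=prior_prob)
    n_draws = probs.shape[0]
    auc = np.empty(n_draws)
    sens = np.empty(n_draws)
    spec = np.empty(n_draws)
    for d in range(n_draws):
        auc[d] = roc_auc(probs[d], truth)
        sens[d], spec[d] = sensitivity_specificity(probs[d], truth, threshold)
    return ClassificationResult(
        per_individual=summary, prob_draws=probs,
        auc_dist=auc, sens_dist=sens, spec_dist=spec, threshold=threshold,
    )
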