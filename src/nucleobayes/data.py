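"""Synthetic cohort generation for urinary nucleoside/creatinine studies.

Real cohorts of this kind (case/control urine metabolomics with age- and
sex-imbalanced groups) are rarely deposited, so this module generates
cohorts with the statistical structure the hierarchical model assumes:
log nucleoside/creatinine ratios that are linear in ln(age/50), sex and
cancer status with correlated between-subject residuals, and demographics
matching a typical urogenital-cancer case/control study (patients
64.04 +/- 11.89 y, 73.4% male; healthy 37.2 +/- 15.36 y, 34.8% male).

Two generators are provided:

``generate_cohort``
    draws directly from the reduced regression model (the model the
    sampler fits), so parameter-recovery experiments have a known truth;
``generate_mechanistic``
    draws from the underlying steady-state excretion model — individual
    diuresis, lognormal excretion rates with inter-individual variability,
    and measurement error on raw concentrations — and forms the ratios,
    demonstrating that diuresis cancels exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# Canonical panel of 13 urinary nucleosides (abbreviations as used in the
# urogenital-cancer biomarker literature).
NUCLEOSIDES_13 = [
    "Pseu", "1mA", "3mC", "X", "A", "N4ac", "N2N2",
    "MTA", "7mG", "I", "G", "5mU", "6mA",
]

MIN_ADULT_AGE = 18.0

# Fixed substream order: adding a draw to one stage must not perturb the
# others, so each stage gets its own child of the master SeedSequence.
_SUBSTREAMS = ("status", "age", "sex", "kappa", "mechanistic", "split")


def _rng_for(seed: int, stream: str) -> np.random.Generator:
    """Named, mutually independent substream of a single master seed."""
    idx = _SUBSTREAMS.index(stream)
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return np.random.default_rng(children[idx])


def _default_beta_cancer(p: int, names: list[str]) -> np.ndarray:
    """Cancer effects of the reference scenario: a factor 1.42 on MTA and
    1.25 on inosine, no effect elsewhere."""
    beta = np.zeros(p)
    if "MTA" in names:
        beta[names.index("MTA")] = np.log(1.42)
    if "I" in names:
        beta[names.index("I")] = np.log(1.25)
    return beta


def default_lambda(p: int, names: list[str] | None = None) -> np.ndarray:
    """Between-subject covariance of the reference scenario.

    Compound-symmetry correlation 0.4 (sd 0.5) across the panel, with MTA
    decorrelated from the rest (cross-correlation 0.1) — mimicking its
    distinct polyamine-pathway origin.
    """
    sd = 0.5
    corr = np.full((p, p), 0.4)
    np.fill_diagonal(corr, 1.0)
    if names and "MTA" in names:
        j = names.index("MTA")
        corr[j, :] = 0.1
        corr[:, j] = 0.1
        corr[j, j] = 1.0
    return sd * sd * corr


@dataclass
class MechanisticParams:
    """Latent quantities of the steady-state excretion model.

    Concentrations arise as excretion rate over diuresis: ln m_ih =
    ln(k_m,ih / V0_i) + eps_m,ih and ln c_i = ln(k_c,i / V0_i) + eps_c,i,
    with lognormal inter-individual variability on the rates.

    Parameters
    ----------
    v0 : (n,) positive diuresis rates (volume/time, arbitrary units).
    beta_km : (p,) population typical metabolite excretion rates.
    beta_kc : scalar population creatinine excretion rate.
    omega_km : (p, p) between-subject covariance of log metabolite rates.
    omega_kc_sq : between-subject variance of the log creatinine rate.
    sigma_m : (p, p) measurement-error covariance for log metabolite
        concentrations.
    sigma_c_sq : measurement-error variance for log creatinine.
    """

    v0: np.ndarray
    beta_km: np.ndarray
    beta_kc: float
    omega_km: np.ndarray
    omega_kc_sq: float
    sigma_m: np.ndarray
    sigma_c_sq: float

    def __post_init__(self) -> None:
        self.v0 = np.asarray(self.v0, dtype=float)
        self.beta_km = np.asarray(self.beta_km, dtype=float)
        self.omega_km = np.asarray(self.omega_km, dtype=float)
        self.sigma_m = np.asarray(self.sigma_m, dtype=float)
        if np.any(self.v0 <= 0):
            raise ValueError("v0 (diuresis rates) must be strictly positive")
        if self.omega_kc_sq < 0 or self.sigma_c_sq < 0:
            raise ValueError("omega_kc_sq and sigma_c_sq must be non-negative")
        for name in ("omega_km", "sigma_m"):
            m = getattr(self, name)
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(m)) < -1e-10:
                raise ValueError(f"{name} must be positive semi-definite")

    @property
    def p(self) -> int:
        return self.beta_km.shape[0]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Demographic defaults follow the reference case/control study: cancer
    prevalence 153/248, patients 64.04 +/- 11.89 years and 73.4% male,
    healthy controls 37.2 +/- 15.36 years and 34.8% male. Effect defaults
    are the reference scenario: age effect 0.203 and sex (female) effect
    0.293 on every metabolite, cancer effect ln(1.42) on MTA and ln(1.25)
    on inosine.
    """

    n: int = 248
    p: int = 13
    prevalence: float = 153 / 248
    age_mean_case: float = 64.04
    age_sd_case: float = 11.89
    age_mean_control: float = 37.2
    age_sd_control: float = 15.36
    male_frac_case: float = 0.734
    male_frac_control: float = 0.348
    true_beta0: np.ndarray | None = None
    true_beta_age: np.ndarray | None = None
    true_beta_sex: np.ndarray | None = None
    true_beta_cancer: np.ndarray | None = None
    true_lambda: np.ndarray | None = None
    metabolite_names: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        for f in ("age_mean_case", "age_sd_case", "age_mean_control", "age_sd_control"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if not self.metabolite_names:
            if self.p == 13:
                self.metabolite_names = list(NUCLEOSIDES_13)
            else:
                self.metabolite_names = [f"met{h+1}" for h in range(self.p)]
        if len(self.metabolite_names) != self.p:
            raise ValueError("metabolite_names length must equal p")
        if self.true_beta0 is None:
            self.true_beta0 = np.zeros(self.p)
        if self.true_beta_age is None:
            self.true_beta_age = np.full(self.p, 0.203)
        if self.true_beta_sex is None:
            self.true_beta_sex = np.full(self.p, 0.293)
        if self.true_beta_cancer is None:
            self.true_beta_cancer = _default_beta_cancer(self.p, self.metabolite_names)
        if self.true_lambda is None:
            self.true_lambda = default_lambda(self.p, self.metabolite_names)
        for f in ("true_beta0", "true_beta_age", "true_beta_sex", "true_beta_cancer"):
            v = np.asarray(getattr(self, f), dtype=float)
            if v.shape != (self.p,):
                raise ValueError(f"{f} must be a length-{self.p} vector")
            setattr(self, f, v)
        lam = np.asarray(self.true_lambda, dtype=float)
        if lam.shape != (self.p, self.p) or not np.allclose(lam, lam.T):
            raise ValueError("true_lambda must be a symmetric p x p matrix")
        self.true_lambda = lam

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class CohortData:
    """A cohort: covariates plus the n x p matrix of log metabolite/creatinine
    ratios.

    Sex is coded female=1 / male=0; status cancer=1 / healthy=0 with NaN for
    missing (individuals to be classified). ``scale_params`` records the
    per-metabolite (center, scale) applied when ``standardized`` is True.
    """

    ids: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    status: np.ndarray
    y: np.ndarray
    metabolite_names: list[str]
    standardized: bool = False
    scale_params: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        self.status = np.asarray(self.status, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.ids.shape[0]
        if not (self.age.shape == self.sex.shape == self.status.shape == (n,)):
            raise ValueError("covariate arrays must all have length n")
        if self.y.shape != (n, len(self.metabolite_names)):
            raise ValueError("y must be n x p with p = len(metabolite_names)")
        if np.any(~np.isfinite(self.age)) or np.any(~np.isfinite(self.sex)):
            raise ValueError("ages and sexes must not be missing")
        if np.any(~np.isfinite(self.y)):
            raise ValueError("y must contain no non-finite entries")
        if self.standardized:
            if self.scale_params is None:
                raise ValueError("standardized cohort requires scale_params")
            center, scale = self.scale_params
            if np.any(np.asarray(scale) <= 0):
                raise ValueError("scale entries must be strictly positive")

    @property
    def n(self) -> int:
        return self.ids.shape[0]

    @property
    def p(self) -> int:
        return len(self.metabolite_names)

    @property
    def status_missing(self) -> np.ndarray:
        return np.isnan(self.status)

    def subset(self, mask: np.ndarray) -> "CohortData":
        return CohortData(
            ids=self.ids[mask], age=self.age[mask], sex=self.sex[mask],
            status=self.status[mask], y=self.y[mask],
            metabolite_names=list(self.metabolite_names),
            standardized=self.standardized, scale_params=self.scale_params,
        )

    def with_hidden_status(self) -> "CohortData":
        """Copy with status masked, as for validation-set inference."""
        c = self.subset(np.ones(self.n, dtype=bool))
        c.status = np.full(self.n, np.nan)
        return c


def _draw_demographics(config: SimulationConfig):
    """Status, age and sex draws under the group-specific distributions."""
    n = config.n
    rng_status = _rng_for(config.seed, "status")
    rng_age = _rng_for(config.seed, "age")
    rng_sex = _rng_for(config.seed, "sex")
    status = (rng_status.random(n) < config.prevalence).astype(float)

    age = np.empty(n)
    for z, mu, sd in (
        (1.0, config.age_mean_case, config.age_sd_case),
        (0.0, config.age_mean_control, config.age_sd_control),
    ):
        mask = status == z
        a = (MIN_ADULT_AGE - mu) / sd
        age[mask] = stats.truncnorm.rvs(
            a, np.inf, loc=mu, scale=sd, size=int(mask.sum()), random_state=rng_age
        )

    # female = 1, so P(sex=1) is one minus the male fraction of the group
    p_female = np.where(status == 1.0, 1 - config.male_frac_case, 1 - config.male_frac_control)
    sex = (rng_sex.random(n) < p_female).astype(float)
    return status, age, sex


def _kappa_factor(true_lambda: np.ndarray, allow_singular: bool) -> np.ndarray:
    """Cholesky-like factor of the between-subject covariance."""
    try:
        return np.linalg.cholesky(true_lambda)
    except np.linalg.LinAlgError:
        if not allow_singular:
            raise ValueError(
                "true_lambda is not positive definite; pass allow_singular=True "
                "only for degenerate test scenarios"
            ) from None
        w, v = np.linalg.eigh(true_lambda)
        if np.min(w) < -1e-10:
            raise ValueError("true_lambda is not positive semi-definite") from None
        return v * np.sqrt(np.clip(w, 0.0, None))


def generate_cohort(config: SimulationConfig, allow_singular: bool = False) -> CohortData:
    """Simulate a cohort from the reduced regression model.

    y_ih = beta0_h + beta_age_h ln(age_i/50) + beta_sex_h sex_i
           + beta_cancer_h z_i + kappa_ih,   kappa_i ~ MVN(0, true_lambda),

    ages drawn from the group-specific normal truncated at 18 years. The same
    seed always yields the identical cohort.
    """
    status, age, sex = _draw_demographics(config)
    L = _kappa_factor(config.true_lambda, allow_singular)
    rng_kappa = _rng_for(config.seed, "kappa")
    kappa = rng_kappa.standard_normal((config.n, config.p)) @ L.T
    mean = (
        config.true_beta0[None, :]
        + np.outer(np.log(age / 50.0), config.true_beta_age)
        + np.outer(sex, config.true_beta_sex)
        + np.outer(status, config.true_beta_cancer)
    )
    ids = np.array([f"S{i+1:04d}" for i in range(config.n)])
    return CohortData(
        ids=ids, age=age, sex=sex, status=status, y=mean + kappa,
        metabolite_names=list(config.metabolite_names),
    )


def generate_mechanistic(
    config: SimulationConfig, mech: MechanisticParams
) -> tuple[pd.DataFrame, CohortData]:
    """Simulate raw log concentrations from the steady-state excretion model
    and form the creatinine-normalised ratios.

    Each individual's metabolite concentration is their excretion rate over
    their diuresis rate, with lognormal inter-individual variability (eta) on
    the rates and additive log-scale measurement error (eps). The creatinine
    excretion rate carries the renal age/sex dependence (age^-0.203, times
    0.742 for women); the cancer effect enters the metabolite rates. Ratioing
    by creatinine removes diuresis exactly, which the function verifies.

    Returns the raw concentration table (columns ln_<met>, ln_creatinine) and
    the ratio cohort.
    """
    from .model import mdrd_rate  # local import to avoid a cycle

    if mech.p != config.p:
        raise ValueError(
            f"mechanistic parameters are for p={mech.p} metabolites "
            f"but config requests p={config.p}"
        )
    if mech.v0.shape[0] != config.n:
        raise ValueError("v0 must have one diuresis rate per individual")

    status, age, sex = _draw_demographics(config)
    rng = _rng_for(config.seed, "mechanistic")
    n, p = config.n, config.p

    eta_m = rng.multivariate_normal(np.zeros(p), mech.omega_km, size=n, method="eigh")
    eta_c = rng.normal(0.0, np.sqrt(mech.omega_kc_sq), size=n)
    eps_m = rng.multivariate_normal(np.zeros(p), mech.sigma_m, size=n, method="eigh")
    eps_c = rng.normal(0.0, np.sqrt(mech.sigma_c_sq), size=n)

    # log excretion rates; creatinine scaled by the renal age/sex relation
    ln_km = (
        np.log(mech.beta_km)[None, :]
        + np.outer(status, config.true_beta_cancer)
        + eta_m
    )
    kc_scale = mdrd_rate(age, sex) / mdrd_rate(50.0, 0.0)
    ln_kc = np.log(mech.beta_kc * kc_scale) + eta_c

    ln_v0 = np.log(mech.v0)
    ln_m = ln_km - ln_v0[:, None] + eps_m
    ln_c = ln_kc - ln_v0 + eps_c

    y = ln_m - ln_c[:, None]
    # diuresis must cancel identically in the ratio
    direct = (ln_km + eps_m) - (ln_kc + eps_c)[:, None]
    if not np.allclose(y, direct, rtol=0, atol=1e-9):
        raise AssertionError("diuresis failed to cancel in the concentration ratio")

    ids = np.array([f"S{i+1:04d}" for i in range(n)])
    raw = pd.DataFrame(ln_m, columns=[f"ln_{m}" for m in config.metabolite_names])
    raw.insert(0, "id", ids)
    raw["ln_creatinine"] = ln_c
    cohort = CohortData(
        ids=ids, age=age, sex=sex, status=status, y=y,
        metabolite_names=list(config.metabolite_names),
    )
    return raw, cohort


def split_cohort(
    cohort: CohortData, train_fraction: float, seed: int
) -> tuple[CohortData, CohortData]:
    """Status-stratified random split into training and validation cohorts.

    Stratum training sizes use round-half-up of n_stratum * train_fraction.
    The two parts are disjoint, their union is the input, and the partition
    is deterministic for a given seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = _rng_for(seed, "split")
    train_mask = np.zeros(cohort.n, dtype=bool)
    for z in np.unique(cohort.status[~cohort.status_missing]):
        idx = np.flatnonzero(cohort.status == z)
        if idx.size < 2:
            raise ValueError(
                f"stratum status={z:g} has fewer than 2 members; cannot split"
            )
        n_train = int(np.floor(idx.size * train_fraction + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)
        chosen = rng.choice(idx, size=n_train, replace=False)
        train_mask[chosen] = True
    return cohort.subset(train_mask), cohort.subset(~train_mask)


def standardize(train: CohortData, val: CohortData) -> tuple[CohortData, CohortData]:
    """Mean-center and scale each metabolite column to unit variance.

    Center and scale are computed on the training cohort only and applied to
    both cohorts, so validation-set inference uses no validation statistics.
    """
    if train.standardized or val.standardized:
        raise ValueError("cohorts are already standardized")
    if train.metabolite_names != val.metabolite_names:
        raise ValueError("train and validation cohorts measure different metabolites")
    center = train.y.mean(axis=0)
    scale = train.y.std(axis=0, ddof=1)
    if np.any(scale <= 0):
        bad = train.metabolite_names[int(np.argmin(scale))]
        raise ValueError(f"zero training variance for metabolite {bad!r}")

    def _apply(c: CohortData) -> CohortData:
        out = c.subset(np.ones(c.n, dtype=bool))
        out.y = (c.y - center) / scale
        out.standardized = True
        out.scale_params = (center.copy(), scale.copy())
        return out

    return _apply(train), _apply(val)


def unstandardize(cohort: CohortData) -> CohortData:
    """Invert ``standardize`` using the recorded per-metabolite center/scale."""
    if not cohort.standardized:
        raise ValueError("cohort is not standardized")
    center, scale = cohort.scale_params
    out = cohort.subset(np.ones(cohort.n, dtype=bool))
    out.y = cohort.y * scale + center
    out.standardized = False
    out.scale_params = None
    return out
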