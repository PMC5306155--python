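"""Readers, writers, configuration and the end-to-end pipeline driver.

The interchange format is plain CSV (schema v1): columns ``id, age, sex,
status`` followed by one column per metabolite. Sex is written as M/F and
status as cancer/healthy/NA (NA marks individuals whose status is to be
inferred). The metabolite columns hold log nucleoside/creatinine ratios; a
"raw" dialect instead holds raw concentrations plus a ``creatinine`` column
from which the log ratios are computed on read.

The pipeline mirrors the study workflow: simulate -> stratified split ->
train-scale standardization -> MCMC fit -> convergence check -> PPC ->
DIC comparison (with vs without the status covariate) -> classification of
the validation set with status hidden -> report. Given a config and seed,
every artifact is reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from .data import CohortData, SimulationConfig, generate_cohort, split_cohort, standardize
from .diagnostics import compare_dic, dic, nucleoside_correlation, posterior_predictive_check
from .inference import McmcSettings, PosteriorDraws, gelman_rubin, run_mcmc, summarize_posterior
from .model import PriorSpec

logger = logging.getLogger("nucleobayes.pipeline")

SCHEMA_COMMENT = "# nucleobayes cohort schema v1"
SEX_TO_CODE = {"F": 1.0, "M": 0.0, "FEMALE": 1.0, "MALE": 0.0}
STATUS_TO_CODE = {"CANCER": 1.0, "HEALTHY": 0.0}
MISSING_TOKENS = {"NA", "", "NAN", "MISSING"}


def read_cohort(path: str | Path, dialect: str = "ratio") -> CohortData:
    """Read a cohort CSV.

    dialect "ratio": metabolite columns already hold log ratios.
    dialect "raw": metabolite columns hold raw concentrations and a
    ``creatinine`` column is present; ln(metabolite/creatinine) is computed.
    """
    if dialect not in ("ratio", "raw"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, comment="#")
    required = ["id", "age", "sex", "status"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file is missing columns {missing_cols}")

    sex = np.empty(len(df))
    for i, tok in enumerate(df["sex"].astype(str).str.strip().str.upper()):
        if tok not in SEX_TO_CODE:
            raise ValueError(f"unknown sex token {tok!r} in row {i}")
        sex[i] = SEX_TO_CODE[tok]

    status = np.empty(len(df))
    raw_status = df["status"].astype(str).str.strip().str.upper()
    for i, tok in enumerate(raw_status):
        if tok in MISSING_TOKENS:
            status[i] = np.nan
        elif tok in STATUS_TO_CODE:
            status[i] = STATUS_TO_CODE[tok]
        else:
            raise ValueError(f"unknown status token {tok!r} in row {i}")

    met_cols = [c for c in df.columns if c not in required and c != "creatinine"]
    values = df[met_cols].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise ValueError(f"non-numeric concentration values in columns {bad}")
    y = values.to_numpy(dtype=float)
    if dialect == "raw":
        if "creatinine" not in df.columns:
            raise ValueError("raw dialect requires a 'creatinine' column")
        creat = pd.to_numeric(df["creatinine"], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(creat)) or np.any(creat <= 0) or np.any(y <= 0):
            raise ValueError("raw concentrations must be positive and numeric")
        y = np.log(y / creat[:, None])

    cohort = CohortData(
        ids=df["id"].astype(str).to_numpy(), age=df["age"].to_numpy(dtype=float),
        sex=sex, status=status, y=y, metabolite_names=met_cols,
    )
    logger.info("read %d individuals (%d with missing status) from %s",
                cohort.n, int(cohort.status_missing.sum()), path)
    return cohort


def write_cohort(cohort: CohortData, path: str | Path) -> None:
    """Write a cohort to CSV in the ratio dialect (schema v1)."""
    sex = np.where(cohort.sex == 1.0, "F", "M")
    status = np.where(
        cohort.status_missing, "NA",
        np.where(cohort.status == 1.0, "cancer", "healthy"),
    )
    df = pd.DataFrame({"id": cohort.ids, "age": cohort.age,
                       "sex": sex, "status": status})
    for h, met in enumerate(cohort.metabolite_names):
        df[met] = cohort.y[:, h]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        df.to_csv(fh, index=False)


def write_draws(draws: PosteriorDraws, path: str | Path) -> None:
    draws.to_frame().to_csv(path, index=False)


def read_draws(path: str | Path) -> PosteriorDraws:
    return PosteriorDraws.from_frame(pd.read_csv(path))


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; sections validate on creation."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    prior: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    train_fraction: float = 0.7
    classification_threshold: float = 0.5
    ppc_replicates: int = 500
    seed: int = 0
    output_dir: str = "nucleobayes_out"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if not 0.0 <= self.classification_threshold <= 1.0:
            raise ValueError("classification_threshold must lie in [0, 1]")
        # fan the global seed out to the stages unless they set their own
        self.simulation = self.simulation.replace(seed=self.simulation.seed or self.seed)
        if self.mcmc.seed == 0:
            self.mcmc = dataclasses.replace(self.mcmc, seed=self.seed + 1)


def _section(cls, mapping: dict):
    vector_fields = {"true_beta0", "true_beta_age", "true_beta_sex",
                     "true_beta_cancer", "true_lambda"}
    kwargs = {}
    for k, v in (mapping or {}).items():
        kwargs[k] = np.asarray(v, dtype=float) if k in vector_fields and v is not None else v
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from a YAML file with sections ``simulation``,
    ``prior``, ``mcmc`` and top-level pipeline keys."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sim = _section(SimulationConfig, raw.pop("simulation", {}))
    prior_raw = raw.pop("prior", {}) or {}
    if "sigma_bounds" in prior_raw:
        prior_raw["sigma_bounds"] = tuple(prior_raw["sigma_bounds"])
    prior = PriorSpec(**prior_raw)
    mcmc = McmcSettings(**(raw.pop("mcmc", {}) or {}))
    return PipelineConfig(simulation=sim, prior=prior, mcmc=mcmc, **raw)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    def _clean(obj):
        d = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, tuple):
                v = list(v)
            d[f.name] = v
        return d

    doc = {
        "simulation": _clean(config.simulation),
        "prior": _clean(config.prior),
        "mcmc": _clean(config.mcmc),
        "train_fraction": config.train_fraction,
        "classification_threshold": config.classification_threshold,
        "ppc_replicates": config.ppc_replicates,
        "seed": config.seed,
        "output_dir": config.output_dir,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class PipelineReport:
    """Handles to every artifact the pipeline produced."""

    train: CohortData
    val: CohortData
    draws: PosteriorDraws
    rhat: pd.Series
    summary: pd.DataFrame
    ppc: "object"
    dic_with: "object"
    dic_without: "object"
    delta_dic: float
    classification: "object"
    output_dir: Path

    @property
    def max_rhat(self) -> float:
        return float(self.rhat.max())

    @property
    def converged(self) -> bool:
        return self.max_rhat < 1.2


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full workflow and persist every artifact under
    ``config.output_dir``. Deterministic for a given config and seed."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(config, out / "config_echo.yaml")

    stage = "simulate"
    try:
        cohort = generate_cohort(config.simulation)
        write_cohort(cohort, out / "cohort.csv")

        stage = "split"
        train, val = split_cohort(cohort, config.train_fraction, config.seed)

        stage = "standardize"
        train_s, val_s = standardize(train, val)
        write_cohort(train_s, out / "train_standardized.csv")
        write_cohort(val_s, out / "val_standardized.csv")

        stage = "fit"
        logger.info("fit: %d train individuals, %d metabolites", train_s.n, train_s.p)
        draws = run_mcmc(train_s, config.prior, config.mcmc)
        write_draws(draws, out / "draws.csv")

        stage = "convergence"
        rhat = gelman_rubin(draws)
        rhat.to_csv(out / "gelman_rubin.csv")
        logger.info("convergence: max R-hat = %.4f over %d parameters",
                    float(rhat.max()), len(rhat))

        stage = "summarize"
        summary = summarize_posterior(draws)
        summary.to_csv(out / "posterior_summary.csv")

        stage = "ppc"
        ppc = posterior_predictive_check(draws, train_s,
                                         n_rep=config.ppc_replicates,
                                         seed=config.seed + 2)
        ppc.table.to_csv(out / "ppc.csv", index=False)

        stage = "dic"
        dic_with = dic(draws, train_s)
        # the no-status model: same data with status set to healthy-coded zero
        # and the cancer effect dropped by fitting without that column is
        # approximated by refitting on a cohort whose status column is 0
        null_train = train_s.subset(np.ones(train_s.n, dtype=bool))
        null_train.status = np.zeros(train_s.n)
        null_settings = dataclasses.replace(config.mcmc, seed=config.mcmc.seed + 1)
        draws_null = run_mcmc(null_train, config.prior, null_settings)
        dic_without = dic(draws_null, null_train)
        delta = compare_dic(dic_with, dic_without)
        pd.DataFrame([
            {"model": "with_status", "dbar": dic_with.dbar,
             "pd": dic_with.pd_eff, "dic": dic_with.dic},
            {"model": "without_status", "dbar": dic_without.dbar,
             "pd": dic_without.pd_eff, "dic": dic_without.dic},
            {"model": "delta(without - with)", "dbar": np.nan, "pd": np.nan,
             "dic": delta},
        ]).to_csv(out / "dic.csv", index=False)

        stage = "correlation"
        corr = nucleoside_correlation(draws)
        corr.to_csv(out / "correlation.csv")

        stage = "classify"
        truth = val_s.status.copy()
        hidden = val_s.with_hidden_status()
        result = _classify.classification_with_uncertainty(
            draws, hidden, truth, threshold=config.classification_threshold)
        result.per_individual.to_csv(out / "classification.csv", index=False)
        result.metric_summary().to_csv(out / "metrics.csv")

        stage = "report"
        report = PipelineReport(
            train=train_s, val=val_s, draws=draws, rhat=rhat, summary=summary,
            ppc=ppc, dic_with=dic_with, dic_without=dic_without,
            delta_dic=delta, classification=result, output_dir=out,
        )
        logger.info("pipeline complete: artifacts in %s", out)
        return report
    except Exception as exc:
        logger.error("pipeline failed in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
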