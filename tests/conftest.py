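import numpy as np
import pytest

import nucleobayes as nb


@pytest.fixture(scope="session")
def small_config() -> nb.SimulationConfig:
    """A small but fully structured cohort scenario: 3 metabolites, the
    default demographics, a cancer effect on the first metabolite."""
    return nb.SimulationConfig(
        n=150, p=3, seed=42,
        true_beta_cancer=np.array([np.log(1.42), 0.0, 0.0]),
    )


@pytest.fixture(scope="session")
def small_fit(small_config):
    """A standardized cohort and a short-chain posterior fit, shared across
    tests that only need *some* valid fitted draws."""
    cohort = nb.generate_cohort(small_config)
    train, _ = nb.standardize(cohort, cohort.with_hidden_status())
    settings = nb.McmcSettings(n_chains=2, n_iter=500, burn_in=200, thin=2, seed=5)
    draws = nb.run_mcmc(train, settings=settings)
    return train, draws


def make_standardized_cohort(y, age=None, sex=None, status=None, names=None):
    """Hand-build a cohort already flagged as standardized (unit scale)."""
    y = np.asarray(y, dtype=float)
    n, p = y.shape
    return nb.CohortData(
        ids=np.array([f"T{i}" for i in range(n)]),
        age=np.full(n, 50.0) if age is None else np.asarray(age, float),
        sex=np.zeros(n) if sex is None else np.asarray(sex, float),
        status=np.zeros(n) if status is None else np.asarray(status, float),
        y=y,
        metabolite_names=[f"m{h}" for h in range(p)] if names is None else list(names),
        standardized=True,
        scale_params=(np.zeros(p), np.ones(p)),
    )
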