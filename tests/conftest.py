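import numpy as np
import pandas as pd
import pytest

import survcompare as sc

# Final-model coefficients of the cardiac length-of-stay study (log-hours scale)
FINAL_MODEL = {
    "intercept": 1.5928,
    "protocol[fast-track]": -0.2557,
    "patient[coronary]": 0.5552,
}
FINAL_SIGMA = 0.2230


@pytest.fixture(scope="session")
def cardiac_schema():
    return sc.CovariateSchema(
        {
            "protocol": ("conventional", "fast-track"),
            "patient": ("congenital", "coronary"),
        }
    )


@pytest.fixture(scope="session")
def final_model_fit(cardiac_schema):
    """The published two-covariate Weibull fit, assembled from its coefficients."""
    return sc.WeibullAFTFit.from_parameters(FINAL_MODEL, FINAL_SIGMA, cardiac_schema)


def make_cohort(times, events, covariates=None, schema=None):
    """Build a cohort from plain arrays; default schema is a single binary group."""
    times = np.asarray(times, dtype=float)
    if covariates is None:
        covariates = pd.DataFrame({"group": ["a"] * len(times)})
        schema = sc.CovariateSchema({"group": ("a", "b")})
    return sc.CohortDataset(
        times=times, events=np.asarray(events), covariates=covariates, schema=schema
    )


def random_censored_cohort(rng, n, n_groups=2, tie_prob=0.0):
    """Small random cohort for oracle comparisons (optionally with tied times)."""
    if tie_prob > 0:
        times = rng.integers(1, max(3, n // 2), size=n).astype(float)
    else:
        times = rng.exponential(5.0, size=n) + 0.01
    events = rng.integers(0, 2, size=n)
    levels = tuple("g%d" % i for i in range(n_groups))
    labels = [levels[i] for i in rng.integers(0, n_groups, size=n)]
    schema = sc.CovariateSchema({"group": levels})
    return sc.CohortDataset(
        times=times,
        events=events,
        covariates=pd.DataFrame({"group": labels}),
        schema=schema,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230313)
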