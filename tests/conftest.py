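import numpy as np
import pandas as pd
import pytest

from fedcohort.synthetic_cohort import (
    CohortTable,
    VariableSpec,
    build_default_specs,
    calibrate_intercept,
    generate_logistic_cohorts,
)

MIXED_SCHEMA = (
    VariableSpec("age", "continuous", units="year"),
    VariableSpec("biomarker", "continuous"),
    VariableSpec("smoking", "categorical", categories=("No", "Former", "Yes")),
    VariableSpec("copd", "categorical", categories=("No", "Yes")),
)


def make_mixed_cohort(center_id="A", n=60, seed=0, missing_rate=0.0, prevalence=0.3):
    """Small mixed continuous/categorical cohort for unit tests."""
    rng = np.random.default_rng(seed)
    age = rng.normal(80, 6, n)
    biomarker = rng.normal(100, 40, n)
    smoking = rng.choice(["No", "Former", "Yes"], size=n, p=[0.5, 0.3, 0.2]).astype(object)
    copd = rng.choice(["No", "Yes"], size=n, p=[0.7, 0.3]).astype(object)
    logit = 0.1 * (age - 80) - 1.0 + (copd == "Yes") * 0.8
    y = (rng.random(n) < 1 / (1 + np.exp(-(logit + np.log(prevalence / (1 - prevalence)))))).astype(int)
    df = pd.DataFrame(
        {"age": age, "biomarker": biomarker, "smoking": smoking, "copd": copd, "outcome": y}
    )
    if missing_rate:
        for col in ("age", "biomarker", "smoking", "copd"):
            mask = rng.random(n) < missing_rate
            df.loc[mask, col] = np.nan
    df.index = pd.Index([f"{center_id}-{i:04d}" for i in range(n)], name="patient_id")
    return CohortTable(data=df, schema=MIXED_SCHEMA, center_id=center_id)


@pytest.fixture(scope="session")
def default_specs():
    return build_default_specs()


@pytest.fixture
def mixed_cohort():
    return make_mixed_cohort(seed=7)


@pytest.fixture(scope="session")
def logit_pair():
    """Two-center continuous-feature cohorts from a known logistic model."""
    coefs = {"x1": 1.0, "x2": -0.7, "x3": 0.5}
    b0 = calibrate_intercept(coefs, 0.0, 0.3)
    return generate_logistic_cohorts(coefs, (b0, b0), (160, 120), (0.0, 0.2), seed=11)


@pytest.fixture(scope="session")
def numeric_training_data():
    """Plain (X, y, probe) arrays for learner-contract tests."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(150, 6))
    beta = np.array([1.0, -0.8, 0.5, 0.0, 0.3, -0.2])
    y = (rng.random(150) < 1 / (1 + np.exp(-(X @ beta - 0.5)))).astype(int)
    probe = rng.normal(size=(40, 6))
    return X, y, probe
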