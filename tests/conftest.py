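import numpy as np
import pandas as pd
import pytest

from permfit import (
    EstimatorFactory,
    SyntheticConfig,
    encode_design_matrix,
    generate_cohort,
    pecarn_schema,
)
from permfit.synthetic_data import simulation_config


@pytest.fixture(scope="session")
def schema24():
    return pecarn_schema()


@pytest.fixture(scope="session")
def cohort24():
    """Small cohort on the full 24-feature schema."""
    return generate_cohort(SyntheticConfig(n=600, seed=42))


@pytest.fixture(scope="session")
def sim_cohort():
    """Compact-schema cohort with one planted binary signal (logit effect 2)."""
    return generate_cohort(simulation_config(n=1500, seed=7, effect=2.0))


@pytest.fixture(scope="session")
def sim_design(sim_cohort):
    return encode_design_matrix(sim_cohort.table)


@pytest.fixture()
def logistic_factory():
    return EstimatorFactory("logistic", seed=0)


@pytest.fixture()
def tiny_dnn_factory():
    """Scaled-down stable-DNN factory for fast tests."""
    return EstimatorFactory(
        "stable_dnn",
        hyperparameters={"hidden_widths": (8,), "epochs": 25, "n_members": 4},
        seed=0,
    )


def write_cohort_csv(path, cohort, outcome_column="tbi"):
    df = cohort.table.values.copy()
    df[outcome_column] = cohort.outcome.as_int()
    df.to_csv(path, index=False)
    return path


@pytest.fixture()
def cohort_csv(tmp_path, cohort24):
    return write_cohort_csv(tmp_path / "cohort.csv", cohort24)
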