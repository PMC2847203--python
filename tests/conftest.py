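import numpy as np
import pandas as pd
import pytest

from bayesce.inference import TransitionData, sample_posterior
from bayesce.model_spec import (build_model_config, build_parameter_index,
                                two_state_config)
from bayesce.synthetic_data import CohortConfig, default_theta_star, simulate_cohort


@pytest.fixture(scope="session")
def m1_config():
    return build_model_config("M1")


@pytest.fixture(scope="session")
def m1_index(m1_config):
    return build_parameter_index(m1_config)


@pytest.fixture(scope="session")
def m1_theta_star(m1_index):
    return default_theta_star(m1_index)


@pytest.fixture(scope="session")
def m1_cohort(m1_config, m1_theta_star):
    """Small M1-truth cohort reused across inference/assessment tests."""
    cfg = CohortConfig(n_patients=120, theta_star=m1_theta_star,
                       max_followup_years=3.0, seed=42)
    return simulate_cohort(cfg, m1_config)


@pytest.fixture(scope="session")
def m1_sample(m1_cohort, m1_config):
    return sample_posterior(m1_cohort, m1_config, n_iter=1500, n_burnin=500,
                            seed=11)


@pytest.fixture(scope="session")
def two_state():
    return two_state_config()


@pytest.fixture(scope="session")
def two_state_data(two_state):
    """Hand-built alive/dead rows: known counts, one free intercept."""
    rows = pd.DataFrame({
        "patient": np.arange(1, 9), "year": 0, "from_state": 1, "age": 63.0,
    })
    counts = np.zeros((8, 2))
    counts[:, 0] = [364, 365, 180, 365, 364, 365, 365, 200]
    counts[:, 1] = [1, 0, 1, 0, 1, 0, 0, 1]
    return TransitionData(rows, counts)


def make_single_row(config, r, counts_by_state, age=63.0, **raw):
    """One multinomial row with given covariates."""
    defaults = {c: 0.0 for c in config.raw_covariate_names}
    defaults.update(raw)
    rows = pd.DataFrame([{"patient": 1, "year": 0, "from_state": r,
                          "age": age, **defaults}])
    counts = np.zeros((1, config.state_space.n_states))
    for s, c in counts_by_state.items():
        counts[0, s - 1] = c
    return TransitionData(rows, counts)
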