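import numpy as np
import pandas as pd
import pytest

from mortalq import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    """Default mortal-cohort scenario at reduced size for unit tests."""
    return SimConfig(n_individuals=600, seed=20240101)


@pytest.fixture(scope="session")
def mortal_panel(default_config):
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """No death, everyone interviewed: full panel with known truth."""
    return SimConfig(
        n_individuals=600,
        seed=20240102,
        death_model=(-50.0, 0.0, 0.0),
        obs_model=(50.0, 0.0, 0.0),
    )


@pytest.fixture(scope="session")
def clean_panel(clean_config):
    return simulate_cohort(clean_config)


@pytest.fixture()
def iid_median_panel():
    """One-wave panel of iid standard-normal outcomes (median regression)."""

    def make(n=500, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "id": np.arange(n),
                "wave": 1,
                "fi": rng.standard_normal(n),
                "observed": True,
                "alive": True,
                "age": 65.0,
                "sex": 0,
                "educ_years": 0.0,
                "base_age": 65.0,
                "born_1946plus": 0,
            }
        )

    return make
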