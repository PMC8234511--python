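import numpy as np
import pandas as pd
import pytest

import postaki as pk


@pytest.fixture(scope="session")
def grampian_cohort():
    """Moderate synthetic all-survivors cohort shared across tests."""
    config = pk.grampian_scenario(n=8000, seed=42)
    return config, pk.simulate_cohort(config)


@pytest.fixture(scope="session")
def alberta_cohort():
    config = pk.alberta_scenario(n=9382, seed=42)
    return config, pk.simulate_cohort(config)


@pytest.fixture
def reference_subject():
    """Subject sitting at the reference level of every Aberdeen model term."""
    return {
        "age": 0.0,
        "residential_care": 0,
        "rural": 0,
        "prior_admissions": 0,
        "emergency": 0,
        "aki_stage": "0",
        "baseline_egfr": 0.0,
        "cancer": 0,
        "cardiac_failure": 0,
        "diabetes": 0,
        "pulmonary": 0,
    }


def toy_cohort(risks, outcomes, **extra_cols) -> pd.DataFrame:
    df = pd.DataFrame({"risk": np.asarray(risks, float), "outcome": np.asarray(outcomes, int)})
    for k, v in extra_cols.items():
        df[k] = v
    return df
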