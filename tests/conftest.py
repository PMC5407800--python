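import numpy as np
import pandas as pd
import pytest

from findcut.data_model import CohortTable, OutcomeSpec
from findcut.synthetic import (
    BinarySimConfig,
    SurvivalSimConfig,
    ZDist,
    simulate_binary_cohort,
    simulate_survival_cohort,
)


@pytest.fixture(scope="session")
def survival_cohort() -> CohortTable:
    """Mid-sized survival cohort with a real two-cut effect (BMI-like)."""
    cfg = SurvivalSimConfig(
        n=400,
        z_dist=ZDist("lognormal", (3.1884, 0.18), decimals=1),
        true_cuts=(20.0, 29.0),
        group_hazards=(0.3, 0.1, 0.3),
        censor_rate=0.05,
        admin_censor_time=10.0,
        seed=11,
    )
    return simulate_survival_cohort(cfg)


@pytest.fixture(scope="session")
def binary_cohort() -> CohortTable:
    """Mid-sized binary cohort with a real two-cut effect."""
    cfg = BinarySimConfig(
        n=400,
        z_dist=ZDist("lognormal", (3.1884, 0.18), decimals=1),
        true_cuts=(20.0, 29.0),
        group_event_prob=(0.6, 0.2, 0.7),
        seed=13,
    )
    return simulate_binary_cohort(cfg)


@pytest.fixture
def tiny_survival_df() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": ["a", "b", "c"],
            "bmi": [21.0, 27.5, 31.2],
            "os_years": [3.2, 5.0, 1.1],
            "death": [1, 0, 1],
        }
    )


def make_cohort(z, *, time=None, event=None, y=None) -> CohortTable:
    """Small helper to build a CohortTable from raw arrays."""
    if y is not None:
        df = pd.DataFrame({"z": z, "y": y})
        spec = OutcomeSpec(mode="binary", z="z", y="y")
    else:
        df = pd.DataFrame({"z": z, "time": time, "event": event})
        spec = OutcomeSpec(mode="survival", z="z", time="time", event="event")
    return CohortTable(df, spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
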