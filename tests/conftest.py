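import numpy as np
import pandas as pd
import pytest

from aircount.simulate import SimulationConfig, simulate_observations, simulate_transect_counts


@pytest.fixture
def four_row_table() -> pd.DataFrame:
    """Minimal valid table with one row per observation fate."""
    return pd.DataFrame(
        {
            "object_id": ["a", "b", "c", "d"],
            "survey_id": ["north_2018-02-10"] * 4,
            "site": ["north"] * 4,
            "date": ["2018-02-10"] * 4,
            "klass": ["unique_detection", "duplicate", "false_positive", "missed"],
            "temperature": [12.0, 12.0, 12.0, 12.0],
            "wind_speed": [5.0, 5.0, 5.0, 5.0],
            "dist_edge": [40.0, 40.0, 10.0, 80.0],
            "dist_nearest": [30.0, 8.0, 55.0, np.nan],
            "time_since_prev": [120.0, 15.0, 300.0, np.nan],
            "perp_distance": [10.0, 12.0, 50.0, 70.0],
        }
    )


@pytest.fixture(scope="session")
def campaign():
    """Default synthetic campaign: (observation table, truth)."""
    return simulate_observations(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def transect_data():
    """Default synthetic 9-transect x 5-visit count array: (data, truth)."""
    return simulate_transect_counts(SimulationConfig(seed=42))
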