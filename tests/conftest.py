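import dataclasses

import numpy as np
import pandas as pd
import pytest

from ozonemap import exposure, synthetic
from ozonemap.exposure import SeasonWindow, StationSeries


@pytest.fixture
def window() -> SeasonWindow:
    return SeasonWindow()


def make_series(values, valid=None, start="2007-04-01", station_id="ST01"):
    """Hourly StationSeries starting at midnight of ``start``."""
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(len(values), dtype=bool)
    index = pd.date_range(start, periods=len(values), freq="h")
    return StationSeries(station_id=station_id, index=index,
                         values=values, valid=np.asarray(valid, dtype=bool))


@pytest.fixture
def make_hourly():
    return make_series


@pytest.fixture(scope="session")
def default_config() -> synthetic.FieldConfig:
    return synthetic.FieldConfig(seed=7)


@pytest.fixture(scope="session")
def simulation(default_config):
    """One full seeded simulation shared across tests."""
    return synthetic.simulate(default_config)


@pytest.fixture(scope="session")
def station_metrics(simulation, default_config) -> pd.DataFrame:
    return exposure.compute_station_metrics(
        simulation.series, simulation.truth.stations,
        default_config.season_window())


@pytest.fixture
def linear_metrics() -> pd.DataFrame:
    """A noise-free metric table exactly linear in altitude."""
    rng = np.random.default_rng(11)
    n = 12
    alt = np.linspace(100.0, 1200.0, n)
    xy = rng.uniform(0.0, 200.0, (n, 2))
    z = 30.0 + 0.01 * alt
    return pd.DataFrame({
        "station_id": [f"ST{i:02d}" for i in range(n)],
        "x_km": xy[:, 0], "y_km": xy[:, 1], "altitude_m": alt,
        "seasonal_mean_ppb": z,
        "afternoon_mean_ppb": z + 5.0,
        "increment_ppb": np.full(n, 5.0),
    })
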