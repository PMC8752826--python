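import warnings

import numpy as np
import pandas as pd
import pytest

import lagoonhab as lh
from lagoonhab import environment as env

warnings.filterwarnings("ignore", message=".*convergence.*", category=UserWarning)
try:
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    warnings.filterwarnings("ignore", category=ConvergenceWarning)
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def lagoon():
    """Default three-region lagoon and its 100-m bathymetry."""
    return lh.generate_lagoon(seed=1)


@pytest.fixture(scope="session")
def covariates(lagoon):
    geometry, bathy = lagoon
    grid = env.build_grid(geometry)
    cov = env.derive_covariates(grid, bathy, geometry)
    return grid, cov


@pytest.fixture(scope="session")
def tide():
    return lh.generate_tide_series("2013-10-01", "2013-10-31", seed=1)


@pytest.fixture(scope="session")
def simulated(lagoon, tide):
    geometry, bathy = lagoon
    cfg = lh.SimulationConfig(
        n_individuals=4, track_durations_days=(6, 8, 7, 9), seed=4
    )
    return lh.simulate_tracks(geometry, bathy, tide, cfg)


def hourly_track(xy: np.ndarray, start="2013-01-01") -> pd.DataFrame:
    """Helper: wrap an (n, 2) position array as an hourly track frame."""
    n = len(xy)
    return pd.DataFrame(
        {
            "timestamp": pd.Timestamp(start) + pd.to_timedelta(np.arange(n), "h"),
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
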