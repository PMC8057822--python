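import numpy as np
import pandas as pd
import pytest

from airburden.grid_io import ConcentrationField, Grid, Pollutant, PopulationGrid
from airburden.pipeline import run_end_to_end
from airburden.synthetic_data import SyntheticConfig


@pytest.fixture
def tiny_grid():
    return Grid(np.array([30.0, 31.0, 32.0, 33.0]), np.array([110.0, 111.0, 112.0, 113.0]))


@pytest.fixture
def hourly_year_index():
    return pd.date_range("2015-01-01", "2015-12-31 23:00", freq="h")


def make_o3_year(values, grid, time):
    """Hourly ozone field over one year from (T, nlat, nlon) values."""
    return ConcentrationField(
        grid=grid, pollutant=Pollutant.O3, values=values, time=time
    )


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=7, n_lat=6, n_lon=9, n_stations=8)


@pytest.fixture(scope="session")
def small_result(small_config):
    """One shared end-to-end run on a reduced domain."""
    return run_end_to_end(small_config)


@pytest.fixture
def uniform_population(tiny_grid):
    return PopulationGrid(tiny_grid, np.full(tiny_grid.shape, 1000.0))
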