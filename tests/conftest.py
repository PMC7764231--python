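import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from lunarpm.io_formats import GridField
from lunarpm.synthetic import SimulationConfig, generate_station_series


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact one-cycle world: 6 stations, Jan-Mar 2013, fixed seed."""
    return SimulationConfig(
        n_stations=6,
        grid_extent=(100.0, 102.0, 30.0, 32.0),
        start_date=dt.date(2013, 1, 18),
        end_date=dt.date(2013, 3, 31),
        new_year_dates=(dt.date(2013, 2, 10),),
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_station_series(small_config)


def make_grid(data, variable="AOD", units="1", date=dt.date(2013, 2, 10),
              lat0=30.05, lon0=100.05, res=0.1) -> GridField:
    data = np.asarray(data, dtype=float)
    nlat, nlon = data.shape
    return GridField(
        variable=variable,
        units=units,
        date=date,
        data=data,
        lats=lat0 + res * np.arange(nlat),
        lons=lon0 + res * np.arange(nlon),
    )
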