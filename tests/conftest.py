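import numpy as np
import pytest

from phenoscan import (
    DEFAULT_BOX,
    SiteYear,
    WeatherSeries,
    build_database,
    generate_sobol_sets,
    make_siteyears,
)


@pytest.fixture(scope="session")
def siteyears():
    """The default synthetic panel's eleven site-years."""
    return make_siteyears(seed=11)


@pytest.fixture(scope="session")
def small_db(siteyears):
    """A 2048-set simulation database over the full panel."""
    sets = generate_sobol_sets(DEFAULT_BOX, 2048)
    return build_database(sets, siteyears)


def constant_weather_siteyear(
    tmax=30.0, tmin=20.0, year=2006, sowing_doy=100, latitude=0.0
):
    """Site-year with flat weather: exact accounting by hand is possible."""
    dates = np.arange(
        np.datetime64(f"{year}-01-01"), np.datetime64(f"{year + 2}-01-01")
    )
    w = WeatherSeries(
        dates, np.full(len(dates), float(tmax)), np.full(len(dates), float(tmin))
    )
    return SiteYear("CONST", latitude, 0.0, year, sowing_doy, w)


@pytest.fixture()
def const_siteyear():
    return constant_weather_siteyear()
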