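"""Weather and site data model, thermal time, and photoperiod.

The environmental driver of the phenology model is a daily weather series
(Tmax/Tmin, °C) attached to a site-year: one location x growing season,
identified by latitude, calendar year and sowing day-of-year.  Two
derived quantities feed development: the daily thermal-time increment
(growing degree-days above a base temperature, capped at an optimum) and
the photoperiod, computed astronomically and including civil twilight
(sun less than 6 degrees below the horizon).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureResponse",
    "WeatherSeries",
    "SiteYear",
    "WeatherError",
    "daily_thermal_time",
    "photoperiod",
    "read_weather",
    "write_weather",
    "read_sites",
    "CIVIL_TWILIGHT_DEG",
]

#: Solar depression angle (degrees below horizon) defining civil twilight.
CIVIL_TWILIGHT_DEG = 6.0


class WeatherError(ValueError):
    """Raised for malformed weather records (gaps, Tmax < Tmin, bad columns)."""


@dataclass(frozen=True)
class TemperatureResponse:
    """Cardinal temperatures of the thermal-time response.

    Parameters
    ----------
    tbase : float
        Base temperature (°C) below which no thermal time accrues.
    topt : float
        Optimum temperature (°C) at which the daily increment saturates.
    """

    tbase: float = 8.0
    topt: float = 34.0

    def __post_init__(self) -> None:
        if not self.topt > self.tbase:
            raise ValueError(
                f"topt ({self.topt}) must exceed tbase ({self.tbase})"
            )


def daily_thermal_time(
    tmax: float, tmin: float, resp: TemperatureResponse
) -> float:
    """Growing degree-days for one day from its temperature extremes.

    The daily mean temperature ``(tmax + tmin) / 2`` is capped at
    ``resp.topt`` and referenced to ``resp.tbase``; the increment is never
    negative.  Piecewise linear in the mean: zero at or below the base,
    linear between base and optimum, constant ``topt - tbase`` above.

    Raises
    ------
    WeatherError
        If ``tmax < tmin``.
    """
    if tmax < tmin:
        raise WeatherError(f"tmax ({tmax}) < tmin ({tmin})")
    mean = 0.5 * (tmax + tmin)
    return max(0.0, min(mean, resp.topt) - resp.tbase)


def _solar_declination(doy) -> float:
    """Solar declination (radians) from day of year, annual sinusoid."""
    return np.deg2rad(-23.45) * np.cos(2.0 * np.pi * (doy + 10.0) / 365.0)


def photoperiod(
    latitude: float, doy, depression: float = CIVIL_TWILIGHT_DEG
):
    """Day length in hours at a latitude and day of year.

    ``depression`` is the solar depression angle in degrees below the
    horizon that still counts as day; 6° gives day length including civil
    twilight, 0° the geometric sunrise-to-sunset interval.  The hour
    angle at which the sun crosses ``-depression`` solves

        cos w = (sin(-depression) - sin(lat) sin(decl)) / (cos(lat) cos(decl))

    with the cosine argument clamped to [-1, 1] so that polar day (24 h)
    and polar night (0 h) are returned rather than an error.  Vectorised
    over ``doy``.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    if depression < 0:
        raise ValueError("depression must be >= 0")
    phi = math.radians(latitude)
    decl = _solar_declination(np.asarray(doy, dtype=float))
    h0 = math.radians(-depression)
    cos_phi_cos_decl = math.cos(phi) * np.cos(decl)
    with np.errstate(divide="ignore", invalid="ignore"):
        cosw = np.where(
            cos_phi_cos_decl != 0.0,
            (math.sin(h0) - math.sin(phi) * np.sin(decl)) / cos_phi_cos_decl,
            np.inf,
        )
    cosw = np.clip(cosw, -1.0, 1.0)
    hours = 2.0 * np.degrees(np.arccos(cosw)) / 15.0
    return hours if hours.ndim else float(hours)


@dataclass
class WeatherSeries:
    """Ordered daily weather records: calendar date, Tmax and Tmin (°C).

    Dates must increase by exactly one day with no gaps, and
    ``tmax >= tmin`` on every record.
    """

    dates: np.ndarray  # datetime64[D]
    tmax: np.ndarray
    tmin: np.ndarray

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.tmax = np.asarray(self.tmax, dtype=float)
        self.tmin = np.asarray(self.tmin, dtype=float)
        if not (len(self.dates) == len(self.tmax) == len(self.tmin)):
            raise WeatherError("dates, tmax, tmin must have equal length")
        deltas = np.diff(self.dates).astype(int)
        if np.any(deltas != 1):
            i = int(np.argmax(deltas != 1))
            raise WeatherError(
                f"gap or disorder in weather dates after {self.dates[i]}"
            )
        bad = self.tmax < self.tmin
        if np.any(bad):
            i = int(np.argmax(bad))
            raise WeatherError(
                f"tmax < tmin on {self.dates[i]} "
                f"({self.tmax[i]} < {self.tmin[i]})"
            )

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "tmax": self.tmax, "tmin": self.tmin}
        )

    def doy(self) -> np.ndarray:
        """Day of year (1-366) for every record."""
        years = self.dates.astype("datetime64[Y]")
        return (self.dates - years).astype(int) + 1


@dataclass
class SiteYear:
    """One location x growing season: the unit of the field panel.

    ``weather`` must cover at least the window from sowing through
    ``sowing + 250`` days; late sowings therefore wrap into the following
    calendar year, which the absolute-date weather storage permits.
    """

    site_id: str
    latitude: float
    longitude: float
    year: int
    sowing_doy: int
    weather: WeatherSeries
    #: minimum post-sowing coverage (days) demanded of the weather series
    min_horizon: int = 250
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not 1 <= self.sowing_doy <= 366:
            raise ValueError(f"sowing_doy {self.sowing_doy} outside [1, 366]")
        sow = self.sowing_date
        start = np.datetime64(sow, "D")
        end = start + self.min_horizon
        if self.weather.dates[0] > start or self.weather.dates[-1] < end:
            raise WeatherError(
                f"{self.site_id}: weather [{self.weather.dates[0]}, "
                f"{self.weather.dates[-1]}] does not cover sowing "
                f"{sow} + {self.min_horizon} days"
            )

    @property
    def sowing_date(self) -> date:
        return date(self.year, 1, 1) + timedelta(days=self.sowing_doy - 1)

    def season(self, horizon: int) -> pd.DataFrame:
        """Daily records for days 1..horizon after sowing.

        Day 1 is the day after the sowing date.  Columns: ``dap`` (day
        after sowing), ``doy``, ``tmax``, ``tmin``, ``daylength`` (h,
        civil twilight).
        """
        start = np.datetime64(self.sowing_date, "D") + 1
        i0 = int(np.searchsorted(self.weather.dates, start))
        if i0 >= len(self.weather.dates) or self.weather.dates[i0] != start:
            raise WeatherError(f"{self.site_id}: weather missing {start}")
        i1 = min(i0 + horizon, len(self.weather.dates))
        dates = self.weather.dates[i0:i1]
        doy = (dates - dates.astype("datetime64[Y]")).astype(int) + 1
        return pd.DataFrame(
            {
                "dap": np.arange(1, len(dates) + 1),
                "doy": doy,
                "tmax": self.weather.tmax[i0:i1],
                "tmin": self.weather.tmin[i0:i1],
                "daylength": photoperiod(self.latitude, doy),
            }
        )


def read_weather(path: str | Path) -> WeatherSeries:
    """Read a daily weather CSV with header ``date,tmax,tmin``.

    Dates are ISO-8601; temperatures °C.  Gaps and ``tmax < tmin``
    records raise :class:`WeatherError` naming the offending date.
    """
    df = pd.read_csv(path)
    missing = {"date", "tmax", "tmin"} - set(df.columns)
    if missing:
        raise WeatherError(f"{path}: missing column(s) {sorted(missing)}")
    return WeatherSeries(
        dates=df["date"].to_numpy(dtype="datetime64[D]"),
        tmax=df["tmax"].to_numpy(),
        tmin=df["tmin"].to_numpy(),
    )


def write_weather(series: WeatherSeries, path: str | Path) -> None:
    """Write a weather series to the ``date,tmax,tmin`` CSV dialect."""
    series.to_frame().to_csv(path, index=False)


def read_sites(path: str | Path, weather_dir: str | Path | None = None) -> list[SiteYear]:
    """Read site metadata CSV and the weather files it references.

    Expected header:
    ``site_id,latitude,longitude,year,sowing_doy,weather_file``; weather
    paths are resolved relative to ``weather_dir`` (default: the metadata
    file's directory).
    """
    path = Path(path)
    base = Path(weather_dir) if weather_dir is not None else path.parent
    df = pd.read_csv(path)
    required = {"site_id", "latitude", "longitude", "year", "sowing_doy", "weather_file"}
    missing = required - set(df.columns)
    if missing:
        raise WeatherError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SiteYear(
                site_id=str(row.site_id),
                latitude=float(row.latitude),
                longitude=float(row.longitude),
                year=int(row.year),
                sowing_doy=int(row.sowing_doy),
                weather=read_weather(base / row.weather_file),
            )
        )
    return out
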