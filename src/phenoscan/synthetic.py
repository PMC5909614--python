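"""Synthetic panel generator: site-years, weather, line populations, observations.

Everything downstream of the field data can be exercised without any
download: this module fabricates a panel with the same structure as the
multi-environment maize trials the analysis is designed for — eleven
site-years spanning latitudes 18.00-42.73 °N with sowing days of year
from 120 to 314, a population of lines whose anthesis dates are
produced by the phenology model itself from known ("true") parameters
drawn in the scanned box, integer-day observation noise, and per
line x site-year missingness.  Weather is a seasonal sinusoid plus
Gaussian noise: adequate for driving thermal time and photoperiod,
not a climate emulator.

Because observations are generated by the same model family that the
inversion assumes, closed-loop runs (zero noise, truths snapped to the
database grid) must recover every line exactly; the test suites build
on that property.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .env import SiteYear, WeatherSeries, write_weather
from .inversion import LineObservations
from .phenology import PhenologyConfig, simulate_anthesis_batch
from .sobol_db import DEFAULT_BOX, ParameterBox

__all__ = [
    "SiteTemplate",
    "SyntheticConfig",
    "TruePopulation",
    "default_site_templates",
    "make_weather",
    "make_siteyears",
    "make_population",
    "make_observations",
    "write_panel",
]


@dataclass(frozen=True)
class SiteTemplate:
    """Climate and calendar template for one synthetic site-year."""

    site_id: str
    latitude: float
    longitude: float
    year: int
    sowing_doy: int
    tmax_mean: float  # annual-mean daily maximum, °C
    tmax_amplitude: float  # seasonal half-range of the maximum, °C
    peak_doy: int = 200  # warmest day of year
    diurnal_range: float = 10.0  # tmax - tmin before noise, °C
    temp_noise_sd: float = 2.0  # day-to-day Gaussian jitter, °C


# Site-year calendar of the emulated study: latitudes span 18.00-42.73 °N
# and sowing runs from DOY 120 (spring, North Carolina) to DOY 314
# (November, Puerto Rico).
_SITE_CALENDAR = [
    ("NY6", 42.73, -76.66, 2006, 128),
    ("NY7", 42.73, -76.66, 2007, 135),
    ("NC6", 35.67, -78.49, 2006, 122),
    ("NC7", 35.67, -78.49, 2007, 120),
    ("MO6", 38.89, -92.23, 2006, 137),
    ("MO7", 38.89, -92.23, 2007, 138),
    ("IL6", 40.08, -88.20, 2006, 128),
    ("IL7", 40.08, -88.20, 2007, 137),
    ("FL6", 25.51, -80.49, 2006, 265),
    ("FL7", 25.51, -80.49, 2007, 280),
    ("PR6", 18.00, -66.51, 2006, 314),
]


def default_site_templates() -> list[SiteTemplate]:
    """Templates for the eleven emulated site-years.

    Climate scales with latitude: warmer annual means and flatter
    seasonal cycles toward the tropics.
    """
    out = []
    for site_id, lat, lon, year, doy in _SITE_CALENDAR:
        out.append(
            SiteTemplate(
                site_id=site_id,
                latitude=lat,
                longitude=lon,
                year=year,
                sowing_doy=doy,
                tmax_mean=32.0 - 0.35 * (lat - 18.0),
                tmax_amplitude=2.0 + 0.45 * (lat - 18.0),
            )
        )
    return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the full synthetic panel.

    Defaults define the package's standard study conditions: eleven
    site-years, 600 lines, integer-day observation noise with sd 1.5
    days, 15% missingness.
    """

    templates: tuple[SiteTemplate, ...] = field(
        default_factory=lambda: tuple(default_site_templates())
    )
    n_lines: int = 600
    box: ParameterBox = DEFAULT_BOX
    noise_sd: float = 1.5
    missing_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class TruePopulation:
    """Per-line true parameters the observations were generated from."""

    table: pd.DataFrame  # columns: line_id + one per GSP (+ grid_row if snapped)

    @property
    def line_ids(self) -> list[str]:
        return list(self.table["line_id"])


def make_weather(template: SiteTemplate, seed: int) -> WeatherSeries:
    """Two calendar years of daily weather for one template.

    ``tmax = mean + amplitude * cos(2 pi (doy - peak_doy) / 365) + noise``
    and ``tmin = tmax - diurnal_range + noise``, clipped so that
    ``tmax >= tmin`` every day.  Covering ``year`` and ``year + 1``
    lets late sowings wrap across the year end.
    """
    rng = np.random.default_rng(seed)
    start = np.datetime64(f"{template.year}-01-01", "D")
    end = np.datetime64(f"{template.year + 2}-01-01", "D")
    dates = np.arange(start, end)
    doy = (dates - dates.astype("datetime64[Y]")).astype(int) + 1
    seasonal = template.tmax_mean + template.tmax_amplitude * np.cos(
        2.0 * np.pi * (doy - template.peak_doy) / 365.0
    )
    tmax = seasonal + rng.normal(0.0, template.temp_noise_sd, len(dates))
    tmin = tmax - template.diurnal_range + rng.normal(
        0.0, template.temp_noise_sd, len(dates)
    )
    tmin = np.minimum(tmin, tmax)
    return WeatherSeries(dates=dates, tmax=tmax, tmin=tmin)


def make_siteyears(
    cfg: SyntheticConfig | None = None, seed: int | None = None
) -> list[SiteYear]:
    """Instantiate the configured site-years with generated weather.

    Per-site weather streams are spawned deterministically from the
    master seed, so the full panel is reproducible from ``(cfg, seed)``.
    """
    cfg = cfg or SyntheticConfig()
    master = cfg.seed if seed is None else seed
    children = np.random.SeedSequence(master).spawn(len(cfg.templates))
    out = []
    for template, child in zip(cfg.templates, children):
        weather = make_weather(template, seed=child.generate_state(1)[0])
        out.append(
            SiteYear(
                site_id=template.site_id,
                latitude=template.latitude,
                longitude=template.longitude,
                year=template.year,
                sowing_doy=template.sowing_doy,
                weather=weather,
            )
        )
    return out


def make_population(
    n_lines: int,
    box: ParameterBox = DEFAULT_BOX,
    seed: int = 0,
    grid: pd.DataFrame | None = None,
) -> TruePopulation:
    """Draw true parameters for ``n_lines`` lines.

    By default each axis is drawn independently and uniformly inside the
    box.  With ``grid`` (e.g. the parameter sets of a simulation
    database) truths are instead sampled from its rows — "snapped to the
    grid" — which makes exact closed-loop recovery possible; the source
    row index is recorded in a ``grid_row`` column.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"L{i:05d}" for i in range(n_lines)]
    if grid is not None:
        rows = rng.integers(0, len(grid), size=n_lines)
        table = grid.iloc[rows].reset_index(drop=True)
        table.insert(0, "line_id", ids)
        table["grid_row"] = rows
    else:
        data = {"line_id": ids}
        for axis in box.axes:
            data[axis.name] = rng.uniform(axis.lo, axis.hi, size=n_lines)
        table = pd.DataFrame(data)
    return TruePopulation(table=table)


def make_observations(
    pop: TruePopulation,
    siteyears: Sequence[SiteYear],
    cfg: PhenologyConfig | None = None,
    noise_sd: float = 1.5,
    missing_rate: float = 0.15,
    seed: int = 0,
) -> tuple[list[LineObservations], pd.DataFrame]:
    """Simulate every line in every site-year and corrupt the panel.

    Observed = simulated + rounded Gaussian(0, noise_sd), in whole days
    (anthesis is scored in days), floored at one day.  Entries are then
    deleted independently with probability ``missing_rate``; site-years
    where a line's simulation did not flower are missing by
    construction.  Returns the per-line observation objects and the
    long-form table (``line_id, site_year, anthesis_dap``).
    """
    cfg = cfg or PhenologyConfig()
    rng = np.random.default_rng(seed)
    t = pop.table
    n = len(t)
    tbase = t["tbase"].to_numpy() if "tbase" in t else None
    topt = t["topt"].to_numpy() if "topt" in t else None
    records = []
    for sy in siteyears:
        sim = simulate_anthesis_batch(
            sy,
            t["p1"].to_numpy(),
            t["p2"].to_numpy(),
            t["p2o"].to_numpy(),
            t["phint"].to_numpy(),
            cfg,
            tbase=tbase,
            topt=topt,
        )
        noise = (
            np.rint(rng.normal(0.0, noise_sd, n)).astype(int)
            if noise_sd > 0
            else np.zeros(n, dtype=int)
        )
        observed = np.maximum(sim + noise, 1)
        drop = rng.random(n) < missing_rate
        keep = (sim > 0) & ~drop
        for i in np.flatnonzero(keep):
            records.append(
                {
                    "line_id": t["line_id"].iloc[i],
                    "site_year": sy.site_id,
                    "anthesis_dap": int(observed[i]),
                }
            )
    table = pd.DataFrame(records, columns=["line_id", "site_year", "anthesis_dap"])
    obs = [
        LineObservations(
            line_id=line_id,
            dates=dict(zip(group["site_year"], group["anthesis_dap"])),
        )
        for line_id, group in table.groupby("line_id", sort=True)
    ]
    return obs, table


def write_panel(
    out_dir: str | Path,
    siteyears: Sequence[SiteYear],
    pop: TruePopulation,
    obs_table: pd.DataFrame,
) -> None:
    """Write the panel in the CSV formats the pipeline reads.

    ``sites.csv`` + one weather CSV per site-year, ``observations.csv``
    and ``truths.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sy in siteyears:
        wfile = f"weather_{sy.site_id}.csv"
        write_weather(sy.weather, out / wfile)
        rows.append(
            {
                "site_id": sy.site_id,
                "latitude": sy.latitude,
                "longitude": sy.longitude,
                "year": sy.year,
                "sowing_doy": sy.sowing_doy,
                "weather_file": wfile,
            }
        )
    pd.DataFrame(rows).to_csv(out / "sites.csv", index=False)
    obs_table.to_csv(out / "observations.csv", index=False)
    pop.table.to_csv(out / "truths.csv", index=False)
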