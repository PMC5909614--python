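"""Anthesis-date submodel: juvenile, photoperiod-sensitive and leaf-expansion stages.

Development from sowing to anthesis is driven by thermal time and day
length through three stages:

* **Stage 1 (juvenile)** — begins at emergence (a fixed thermal-time lag
  after sowing) and ends when accumulated growing degree-days since
  emergence reach the cultivar parameter ``P1``.
* **Stage 2 (photoperiod-sensitive)** — ends at tassel initiation.  At
  day lengths at or below the critical short day length ``P2O`` it lasts
  exactly four days; beyond ``P2O`` each hour of day length adds ``P2``
  days.  Implemented as a daily rate accumulation: each day contributes
  ``1 / (4 + P2 * max(0, daylength - P2O))`` and the stage ends when the
  contributions sum to one.
* **Stage 3 (leaf expansion)** — the total leaf number at tassel
  initiation is ``TOLN = SUMDTT / (0.5 * PHINT) + 5`` where ``SUMDTT``
  is thermal time accumulated from emergence through tassel initiation
  (five embryonic leaves; two leaves initiated per phyllochron).
  Anthesis falls on the first day on which thermal time accumulated
  since tassel initiation reaches ``(TOLN + 0.5) * PHINT - SUMDTT``.

All stage boundaries are whole days after sowing; a simulation that
exhausts its weather horizon before flowering returns the failure
sentinel ``ANTHESIS_FAILED`` rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .env import SiteYear, TemperatureResponse

__all__ = [
    "CultivarParams",
    "PhenologyConfig",
    "PhenologyResult",
    "ANTHESIS_FAILED",
    "stage2_daily_increment",
    "total_leaf_number",
    "simulate_anthesis",
    "simulate_anthesis_batch",
]

#: Sentinel anthesis value for simulations that did not flower in horizon.
ANTHESIS_FAILED = -1

# Stage-2 completion threshold; the slack absorbs float accumulation of
# daily rate increments (e.g. six additions of 1/6) without ever letting
# a genuinely incomplete stage pass.
_STAGE2_TOL = 1e-9


@dataclass(frozen=True)
class CultivarParams:
    """Genotype-specific parameters of the anthesis-date model.

    Parameters
    ----------
    p1 : float
        Thermal time from emergence to end of juvenile phase (GDD °C).
    p2 : float
        Photoperiod sensitivity: extra Stage-2 days per hour of day
        length beyond ``p2o`` (days/hour).
    p2o : float
        Critical short day length (h) below which Stage 2 takes its
        minimum four-day duration.
    phint : float
        Phyllochron interval: thermal time between successive leaf-tip
        appearances (GDD °C).
    resp : TemperatureResponse, optional
        Cardinal temperatures of the thermal-time response; when None
        the configured defaults apply.
    """

    p1: float
    p2: float
    p2o: float
    phint: float
    resp: Optional[TemperatureResponse] = None

    def __post_init__(self) -> None:
        if not self.p1 > 0:
            raise ValueError(f"p1 must be > 0, got {self.p1}")
        if self.p2 < 0:
            raise ValueError(f"p2 must be >= 0, got {self.p2}")
        if not 0 < self.p2o <= 24:
            raise ValueError(f"p2o must be in (0, 24], got {self.p2o}")
        if not self.phint > 0:
            raise ValueError(f"phint must be > 0, got {self.phint}")


@dataclass(frozen=True)
class PhenologyConfig:
    """Configuration of the phenology run shared by all cultivars.

    ``emergence_gdd`` is the fixed thermal-time lag from sowing to
    emergence (the emergence parameters proper are not genotype-specific
    here).  ``stage2_mode`` selects between daily rate accumulation
    (``"rate"``, the default) and a single duration computed from the
    day length at end of the juvenile phase (``"fixed"``, for
    sensitivity checks).  ``sumdtt_origin`` selects whether SUMDTT
    accumulates from ``"emergence"`` (default) or is reset at the
    ``"juvenile_end"``.
    """

    resp: TemperatureResponse = field(default_factory=TemperatureResponse)
    emergence_gdd: float = 45.0
    stage2_mode: str = "rate"
    sumdtt_origin: str = "emergence"
    max_horizon_days: int = 250

    def __post_init__(self) -> None:
        if self.stage2_mode not in ("rate", "fixed"):
            raise ValueError(f"unknown stage2_mode {self.stage2_mode!r}")
        if self.sumdtt_origin not in ("emergence", "juvenile_end"):
            raise ValueError(f"unknown sumdtt_origin {self.sumdtt_origin!r}")
        if self.emergence_gdd <= 0:
            raise ValueError("emergence_gdd must be > 0")

    def to_dict(self) -> dict:
        return {
            "tbase": self.resp.tbase,
            "topt": self.resp.topt,
            "emergence_gdd": self.emergence_gdd,
            "stage2_mode": self.stage2_mode,
            "sumdtt_origin": self.sumdtt_origin,
            "max_horizon_days": self.max_horizon_days,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhenologyConfig":
        d = dict(d)
        resp = TemperatureResponse(
            tbase=float(d.pop("tbase", 8.0)), topt=float(d.pop("topt", 34.0))
        )
        return cls(resp=resp, **{k: v for k, v in d.items()})


@dataclass(frozen=True)
class PhenologyResult:
    """Stage boundaries of one simulation, in integer days after sowing.

    ``anthesis_dap == ANTHESIS_FAILED`` flags a crop that did not flower
    within the weather horizon ("did not flower"); the other fields are
    then whatever stages were reached, -1 beyond.
    """

    emergence_dap: int
    end_juvenile_dap: int
    tassel_initiation_dap: int
    anthesis_dap: int
    sumdtt_at_ti: float
    toln: float

    @property
    def failed(self) -> bool:
        return self.anthesis_dap == ANTHESIS_FAILED


def stage2_daily_increment(daylength: float, p2: float, p2o: float) -> float:
    """Fraction of Stage 2 completed in one day of the given day length.

    ``1 / (4 + p2 * max(0, daylength - p2o))``: exactly 0.25 at or below
    the critical short day length (the four-day minimum), decreasing in
    day length beyond it when ``p2 > 0``.
    """
    return 1.0 / (4.0 + p2 * max(0.0, daylength - p2o))


def total_leaf_number(sumdtt: float, phint: float) -> float:
    """Total leaf number at tassel initiation.

    Five embryonic leaves plus two initiated per phyllochron interval of
    accumulated thermal time: ``sumdtt / (phint * 0.5) + 5``.
    """
    if phint <= 0:
        raise ValueError(f"phint must be > 0, got {phint}")
    if sumdtt < 0:
        raise ValueError(f"sumdtt must be >= 0, got {sumdtt}")
    return sumdtt / (phint * 0.5) + 5.0


def _prepared(siteyear: SiteYear, cfg: PhenologyConfig):
    """Season arrays (tmean, daylength, cumulative GDD) cached per site-year."""
    key = (
        cfg.resp.tbase,
        cfg.resp.topt,
        cfg.max_horizon_days,
    )
    cached = siteyear._cache.get(key)
    if cached is not None:
        return cached
    season = siteyear.season(cfg.max_horizon_days)
    tmean = 0.5 * (season["tmax"].to_numpy() + season["tmin"].to_numpy())
    gdd = np.clip(
        np.minimum(tmean, cfg.resp.topt) - cfg.resp.tbase, 0.0, None
    )
    out = (tmean, season["daylength"].to_numpy(), np.cumsum(gdd))
    siteyear._cache[key] = out
    return out


def _cumgdd(tmean: np.ndarray, resp: TemperatureResponse) -> np.ndarray:
    return np.cumsum(
        np.clip(np.minimum(tmean, resp.topt) - resp.tbase, 0.0, None)
    )


_FAILED_RESULT_TAIL = dict(sumdtt_at_ti=float("nan"), toln=float("nan"))


def simulate_anthesis(
    siteyear: SiteYear,
    params: CultivarParams,
    cfg: PhenologyConfig | None = None,
) -> PhenologyResult:
    """Run the three-stage model for one cultivar in one site-year.

    Day 1 is the first day after sowing.  Stage boundaries are the first
    day on which the relevant accumulation reaches its threshold.
    Returns a failed result (sentinel anthesis) when the weather horizon
    ends before a boundary is reached.
    """
    cfg = cfg or PhenologyConfig()
    if params.resp is not None and params.resp != cfg.resp:
        cfg = replace(cfg, resp=params.resp)
    tmean, daylength, cumg = _prepared(siteyear, cfg)
    horizon = len(cumg)

    def first_at(target: float) -> int:
        """Index of first day with cumulative GDD >= target, or -1."""
        i = int(np.searchsorted(cumg, target))
        return i if i < horizon else -1

    emerg = first_at(cfg.emergence_gdd)
    if emerg < 0:
        return PhenologyResult(-1, -1, -1, ANTHESIS_FAILED, **_FAILED_RESULT_TAIL)

    juv_end = first_at(cumg[emerg] + params.p1)
    if juv_end < 0:
        return PhenologyResult(
            emerg + 1, -1, -1, ANTHESIS_FAILED, **_FAILED_RESULT_TAIL
        )

    if cfg.stage2_mode == "rate":
        rates = 1.0 / (
            4.0
            + params.p2
            * np.clip(daylength[juv_end + 1 :] - params.p2o, 0.0, None)
        )
        csum = np.cumsum(rates)
        k = int(np.searchsorted(csum, 1.0 - _STAGE2_TOL))
        ti = juv_end + 1 + k if k < len(csum) else -1
    else:  # fixed: one duration from the day length at end of juvenile phase
        dur = 4.0 + params.p2 * max(0.0, daylength[juv_end] - params.p2o)
        ti = juv_end + int(np.ceil(dur - _STAGE2_TOL))
        if ti >= horizon:
            ti = -1
    if ti < 0:
        return PhenologyResult(
            emerg + 1, juv_end + 1, -1, ANTHESIS_FAILED, **_FAILED_RESULT_TAIL
        )

    origin = emerg if cfg.sumdtt_origin == "emergence" else juv_end
    sumdtt = float(cumg[ti] - cumg[origin])
    toln = total_leaf_number(sumdtt, params.phint)
    anth = first_at(cumg[ti] + (toln + 0.5) * params.phint - sumdtt)
    return PhenologyResult(
        emergence_dap=emerg + 1,
        end_juvenile_dap=juv_end + 1,
        tassel_initiation_dap=ti + 1,
        anthesis_dap=anth + 1 if anth >= 0 else ANTHESIS_FAILED,
        sumdtt_at_ti=sumdtt,
        toln=toln,
    )


def simulate_anthesis_batch(
    siteyear: SiteYear,
    p1: np.ndarray,
    p2: np.ndarray,
    p2o: np.ndarray,
    phint: np.ndarray,
    cfg: PhenologyConfig | None = None,
    tbase: np.ndarray | None = None,
    topt: np.ndarray | None = None,
    chunk: int = 16384,
) -> np.ndarray:
    """Vectorised anthesis day for many parameter sets in one site-year.

    Equivalent to mapping :func:`simulate_anthesis` over rows, returning
    an int32 array of anthesis days after sowing with ``ANTHESIS_FAILED``
    where the horizon ran out.  When ``tbase``/``topt`` arrays are given
    the thermal-time response varies per set (six-parameter scans);
    otherwise the configured response is shared.  Work is chunked to
    bound memory.
    """
    cfg = cfg or PhenologyConfig()
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p2o = np.asarray(p2o, dtype=float)
    phint = np.asarray(phint, dtype=float)
    n = len(p1)
    out = np.empty(n, dtype=np.int32)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        out[lo:hi] = _batch_chunk(
            siteyear,
            p1[lo:hi],
            p2[lo:hi],
            p2o[lo:hi],
            phint[lo:hi],
            cfg,
            None if tbase is None else np.asarray(tbase, float)[lo:hi],
            None if topt is None else np.asarray(topt, float)[lo:hi],
        )
    return out


def _batch_chunk(siteyear, p1, p2, p2o, phint, cfg, tbase, topt):
    tmean, daylength, cumg_shared = _prepared(siteyear, cfg)
    horizon = len(tmean)
    n = len(p1)
    failed = np.zeros(n, dtype=bool)

    if tbase is None:
        # shared temperature response: one cumulative-GDD vector
        cumg = np.broadcast_to(cumg_shared, (n, horizon))
        emerg = np.full(
            n, int(np.searchsorted(cumg_shared, cfg.emergence_gdd))
        )
        failed |= emerg >= horizon
        emerg = np.minimum(emerg, horizon - 1)
        juv_target = cumg_shared[emerg] + p1
        juv_end = np.searchsorted(cumg_shared, juv_target)
    else:
        gdd = np.clip(
            np.minimum(tmean[None, :], topt[:, None]) - tbase[:, None],
            0.0,
            None,
        )
        cumg = np.cumsum(gdd, axis=1)
        emerg = (cumg < cfg.emergence_gdd).sum(axis=1)
        failed |= emerg >= horizon
        emerg = np.minimum(emerg, horizon - 1)
        juv_target = np.take_along_axis(
            cumg, emerg[:, None], axis=1
        ).ravel() + p1
        juv_end = (cumg < juv_target[:, None]).sum(axis=1)
    failed |= juv_end >= horizon
    juv_end = np.minimum(juv_end, horizon - 1)

    if cfg.stage2_mode == "rate":
        rates = 1.0 / (
            4.0
            + p2[:, None] * np.clip(daylength[None, :] - p2o[:, None], 0.0, None)
        )
        crates = np.cumsum(rates, axis=1)
        base = np.take_along_axis(crates, juv_end[:, None], axis=1).ravel()
        ti = (crates < (base + 1.0 - _STAGE2_TOL)[:, None]).sum(axis=1)
    else:
        dl_at_juv = daylength[juv_end]
        dur = 4.0 + p2 * np.clip(dl_at_juv - p2o, 0.0, None)
        ti = juv_end + np.ceil(dur - _STAGE2_TOL).astype(int)
    failed |= ti >= horizon
    ti = np.minimum(ti, horizon - 1)

    origin = emerg if cfg.sumdtt_origin == "emergence" else juv_end
    cum_ti = np.take_along_axis(cumg, ti[:, None], axis=1).ravel()
    cum_origin = np.take_along_axis(cumg, origin[:, None], axis=1).ravel()
    sumdtt = cum_ti - cum_origin
    toln = sumdtt / (phint * 0.5) + 5.0
    target = cum_ti + (toln + 0.5) * phint - sumdtt
    if tbase is None:
        anth = np.searchsorted(cumg_shared, target)
    else:
        anth = (cumg < target[:, None]).sum(axis=1)
    failed |= anth >= horizon

    result = (anth + 1).astype(np.int32)
    result[failed] = ANTHESIS_FAILED
    return result
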