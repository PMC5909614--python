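"""Per-line parameter estimation: database scan and continuous refinement.

The fit criterion for line *l* over a set of site-years is the root mean
square error between simulated and observed anthesis dates,

    RMSE_l = sqrt( (1/n) * sum_i (Yp_i - Yo_i)^2 ),

with one term per scored site-year.  Because both dates are whole days,
the sum of squares is an exact integer, and tie detection — the count
of parameter sets attaining the same minimal RMSE, the measure of
equifinality — is done on that integer, never on floats.

The database scan reports the *first-best-found* estimate: rows are
visited in generation order and the incumbent is replaced only on a
strictly smaller error, so the reported set is the earliest one
attaining the minimum and every later row with an equal error counts as
one tie.

`de_search` fits the same objective by differential evolution over a
continuous box, used to check whether the discrete scan's reachable
phenotypes are an artifact of gridding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import differential_evolution

from .env import SiteYear
from .phenology import (
    ANTHESIS_FAILED,
    CultivarParams,
    PhenologyConfig,
    simulate_anthesis,
)
from .sobol_db import ParameterBox, SimDatabase

__all__ = [
    "LineObservations",
    "EstimateRecord",
    "DEConfig",
    "InversionError",
    "score_line",
    "first_best_found",
    "de_search",
]


class InversionError(ValueError):
    """Raised when a line cannot be scored (no usable observations/rows)."""


@dataclass(frozen=True)
class LineObservations:
    """Observed anthesis dates (integer days after sowing) for one line."""

    line_id: str
    dates: Mapping[str, int]  # site_year -> anthesis day after sowing

    def __post_init__(self) -> None:
        if not self.dates:
            raise ValueError(f"line {self.line_id}: no observations")
        bad = {s: d for s, d in self.dates.items() if d <= 0}
        if bad:
            raise ValueError(f"line {self.line_id}: non-positive dates {bad}")

    def subset(self, site_ids: Sequence[str]) -> list[str]:
        """Site-years in ``site_ids`` for which this line has a date."""
        return [s for s in site_ids if s in self.dates]


@dataclass(frozen=True)
class EstimateRecord:
    """Outcome of one line x site-year-subset search.

    ``n_ties`` is the number of database rows beyond the first that
    attain the same minimal integer SSE — the extent of equifinality.
    """

    line_id: str
    site_ids: tuple[str, ...]
    best_index: int
    best_params: dict
    sse: int
    n_obs: int
    n_ties: int
    tied_indices: np.ndarray | None = field(default=None, compare=False)

    @property
    def rmse(self) -> float:
        return float(np.sqrt(self.sse / self.n_obs))


def score_line(
    sim: Mapping[str, int] | Sequence[int],
    obs: LineObservations,
    subset: Sequence[str],
) -> tuple[int, int, float]:
    """Exact-integer SSE, observation count and RMSE over a subset.

    ``sim`` maps site-years to simulated days (or lists them in subset
    order).  Site-years in ``subset`` without an observation for this
    line are dropped; an empty intersection is an error.
    """
    scored = obs.subset(subset)
    if not scored:
        raise InversionError(
            f"line {obs.line_id}: no observations in subset {list(subset)}"
        )
    if isinstance(sim, Mapping):
        sim_vals = [sim[s] for s in scored]
    else:
        if len(sim) != len(subset):
            raise ValueError("positional sim must match subset length")
        lookup = dict(zip(subset, sim))
        sim_vals = [lookup[s] for s in scored]
    sse = 0
    for s, yp in zip(scored, sim_vals):
        d = int(yp) - int(obs.dates[s])
        sse += d * d
    n = len(scored)
    return sse, n, float(np.sqrt(sse / n))


def first_best_found(
    db: SimDatabase,
    obs: LineObservations,
    subset: Sequence[str] | None = None,
    keep_ties: bool = False,
) -> EstimateRecord:
    """Scan the database in generation order for the minimal-RMSE row.

    Rows whose simulation failed ("did not flower") on any scored
    site-year are ineligible.  The returned record carries the earliest
    minimal row, its exact integer SSE, and the tie count; with
    ``keep_ties`` the full tied index list (including the winner) is
    attached.
    """
    subset = list(subset) if subset is not None else list(db.site_ids)
    scored = obs.subset(subset)
    if not scored:
        raise InversionError(
            f"line {obs.line_id}: no observations in subset {subset}"
        )
    cols = db.site_index(scored)
    sim = db.anthesis[:, cols]
    eligible = np.all(sim != ANTHESIS_FAILED, axis=1)
    if not np.any(eligible):
        raise InversionError(
            f"line {obs.line_id}: all {db.n_sets} rows failed to flower "
            f"on subset {scored}"
        )
    target = np.array([obs.dates[s] for s in scored], dtype=np.int64)
    diff = sim.astype(np.int64) - target
    sse = np.einsum("ij,ij->i", diff, diff)
    sse[~eligible] = np.iinfo(np.int64).max
    best_sse = int(sse.min())
    tied = np.flatnonzero(sse == best_sse)
    best = int(tied[0])
    return EstimateRecord(
        line_id=obs.line_id,
        site_ids=tuple(scored),
        best_index=best,
        best_params=dict(db.params.iloc[best]),
        sse=best_sse,
        n_obs=len(scored),
        n_ties=len(tied) - 1,
        tied_indices=tied if keep_ties else None,
    )


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution hyperparameters (rand/1/bin)."""

    popsize: int = 15  # members per dimension, scipy convention
    mutation: float = 0.7
    recombination: float = 0.9
    maxiter: int = 500
    tol: float = 1e-8
    polish: bool = False


def de_search(
    obs: LineObservations,
    siteyears: Sequence[SiteYear],
    bounds: ParameterBox,
    cfg: PhenologyConfig | None = None,
    de: DEConfig | None = None,
    seed: int = 0,
) -> tuple[dict, float]:
    """Continuous minimal-RMSE fit of one line by differential evolution.

    The objective composes the phenology simulation with the line's
    RMSE over the given site-years; candidates that fail to flower in
    any scored site-year receive an effectively infinite (but finite)
    penalty so the search moves away from them.  Returns the best
    parameter dict (keyed like ``bounds`` axes) and its RMSE in days.
    Seed-reproducible.
    """
    cfg = cfg or PhenologyConfig()
    de = de or DEConfig()
    scored = [sy for sy in siteyears if sy.site_id in obs.dates]
    if not scored:
        raise InversionError(
            f"line {obs.line_id}: no observations for given site-years"
        )
    names = bounds.names
    extra = set(names) - {"p1", "p2", "p2o", "phint", "tbase", "topt"}
    if extra:
        raise ValueError(f"unknown parameter axes {sorted(extra)}")
    penalty = 1e6

    def objective(x: np.ndarray) -> float:
        kw = dict(zip(names, x))
        resp = None
        if "tbase" in kw or "topt" in kw:
            tb = kw.pop("tbase", cfg.resp.tbase)
            to = kw.pop("topt", cfg.resp.topt)
            if to <= tb:
                return penalty
            from .env import TemperatureResponse

            resp = TemperatureResponse(tb, to)
        params = CultivarParams(resp=resp, **kw)
        sse = 0
        for sy in scored:
            r = simulate_anthesis(sy, params, cfg)
            if r.failed:
                return penalty
            d = r.anthesis_dap - obs.dates[sy.site_id]
            sse += d * d
        return float(np.sqrt(sse / len(scored)))

    result = differential_evolution(
        objective,
        bounds=[(a.lo, a.hi) for a in bounds.axes],
        strategy="rand1bin",
        popsize=de.popsize,
        mutation=de.mutation,
        recombination=de.recombination,
        maxiter=de.maxiter,
        tol=de.tol,
        seed=seed,
        polish=de.polish,
        init="sobol",
    )
    best = dict(zip(names, result.x))
    return best, float(result.fun)
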