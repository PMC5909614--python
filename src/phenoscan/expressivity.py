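"""Phenotype-space analysis: achievable anthesis-date tuples and the frontier.

For a chosen subset of site-years, every database row maps to a tuple
of simulated anthesis dates — a point in an integer "phenotype space".
The set of distinct tuples is everything the model can express within
the scanned parameter box.  An observed line either falls on one of
those points (*expressible*) or not (*inexpressible*), in which case it
is assigned the parameters of the nearest achievable tuple — the
nearest point on the expressivity frontier.  Because many inexpressible
lines project to the same frontier point, they inherit identical
parameter estimates irrespective of their genetics; this module makes
that phenomenon directly measurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .inversion import LineObservations
from .phenology import ANTHESIS_FAILED
from .sobol_db import SimDatabase

__all__ = [
    "AchievableSet",
    "ExpressivityRow",
    "achievable_tuples",
    "classify_line",
    "classify_lines",
    "expressivity_summary",
    "frontier_tableau",
]


@dataclass
class AchievableSet:
    """Distinct simulated anthesis-date tuples over a site-year subset.

    ``tuples`` is an ``(m, k)`` int array sorted lexicographically;
    ``witness`` holds, per tuple, the index of the first database row
    (in generation order) that produces it.
    """

    site_ids: tuple[str, ...]
    tuples: np.ndarray
    witness: np.ndarray
    params: pd.DataFrame  # witness rows' parameters, aligned with tuples

    def __len__(self) -> int:
        return len(self.tuples)

    def contains(self, obs_tuple: Sequence[int]) -> bool:
        return self._find_exact(np.asarray(obs_tuple, dtype=np.int64)) >= 0

    def _find_exact(self, t: np.ndarray) -> int:
        """Index of an exactly matching tuple, or -1 (lexicographic search)."""
        lo, hi = 0, len(self.tuples)
        for j in range(self.tuples.shape[1]):
            col = self.tuples[lo:hi, j]
            lo, hi = lo + np.searchsorted(col, t[j], side="left"), lo + np.searchsorted(
                col, t[j], side="right"
            )
            if lo >= hi:
                return -1
        return lo


def achievable_tuples(
    db: SimDatabase, subset: Sequence[str] | None = None
) -> AchievableSet:
    """Deduplicated simulated tuples with first-witness rows.

    Rows whose simulation failed on any subset member are excluded.
    """
    subset = list(subset) if subset is not None else list(db.site_ids)
    if not subset:
        raise ValueError("empty site-year subset")
    cols = db.site_index(subset)
    sim = db.anthesis[:, cols]
    ok = np.all(sim != ANTHESIS_FAILED, axis=1)
    sim_ok = sim[ok].astype(np.int64)
    rows_ok = np.flatnonzero(ok)
    uniq, first = np.unique(sim_ok, axis=0, return_index=True)
    # np.unique returns, per distinct row, the index of its first
    # occurrence in the filtered array; map back to database rows
    witness = rows_ok[first]
    return AchievableSet(
        site_ids=tuple(subset),
        tuples=uniq,
        witness=witness,
        params=db.params.iloc[witness].reset_index(drop=True),
    )


@dataclass(frozen=True)
class ExpressivityRow:
    """Classification of one observed tuple against the achievable set."""

    line_id: str
    observed: tuple[int, ...]
    expressible: bool
    nearest: tuple[int, ...]
    distance_days: float  # RMSE metric: euclidean / sqrt(k)
    params: dict


def classify_line(
    obs: LineObservations | Sequence[int],
    ach: AchievableSet,
    line_id: str = "",
) -> ExpressivityRow:
    """Expressibility and nearest achievable tuple for one observed tuple.

    Exact membership decides expressibility; otherwise the nearest tuple
    under Euclidean distance (equivalently, minimal RMSE — the same
    objective the database scan minimises) is chosen, ties broken by
    first-witness generation order.  The distance is reported on the
    RMSE scale (days).
    """
    if isinstance(obs, LineObservations):
        missing = [s for s in ach.site_ids if s not in obs.dates]
        if missing:
            raise ValueError(
                f"line {obs.line_id}: missing observations for {missing}"
            )
        t = np.array([obs.dates[s] for s in ach.site_ids], dtype=np.int64)
        line_id = obs.line_id
    else:
        t = np.asarray(obs, dtype=np.int64)
        if t.shape != (len(ach.site_ids),):
            raise ValueError(
                f"observed tuple has shape {t.shape}, expected "
                f"({len(ach.site_ids)},)"
            )
    k = len(t)
    i = ach._find_exact(t)
    if i >= 0:
        return ExpressivityRow(
            line_id=line_id,
            observed=tuple(int(v) for v in t),
            expressible=True,
            nearest=tuple(int(v) for v in ach.tuples[i]),
            distance_days=0.0,
            params=dict(ach.params.iloc[i]),
        )
    d2 = np.einsum("ij,ij->i", ach.tuples - t, ach.tuples - t)
    best_d2 = d2.min()
    cand = np.flatnonzero(d2 == best_d2)
    i = int(cand[np.argmin(ach.witness[cand])])
    return ExpressivityRow(
        line_id=line_id,
        observed=tuple(int(v) for v in t),
        expressible=False,
        nearest=tuple(int(v) for v in ach.tuples[i]),
        distance_days=float(np.sqrt(best_d2 / k)),
        params=dict(ach.params.iloc[i]),
    )


def classify_lines(
    observations: Sequence[LineObservations], ach: AchievableSet
) -> list[ExpressivityRow]:
    """Classify every line that observes all site-years of the subset."""
    out = []
    for obs in observations:
        if all(s in obs.dates for s in ach.site_ids):
            out.append(classify_line(obs, ach))
    return out


def expressivity_summary(reports: Sequence[ExpressivityRow]) -> dict:
    """Counts of expressible/inexpressible lines and frontier sharing.

    ``shared_param_groups`` tabulates, among inexpressible lines, how
    many distinct nearest-frontier points they collapse onto and the
    size of each group — lines in one group receive identical parameter
    estimates regardless of genotype.
    """
    if not reports:
        raise ValueError("no reports given")
    n_exp = sum(r.expressible for r in reports)
    groups: dict[tuple, int] = {}
    for r in reports:
        if not r.expressible:
            groups[r.nearest] = groups.get(r.nearest, 0) + 1
    return {
        "n_lines": len(reports),
        "n_expressible": n_exp,
        "n_inexpressible": len(reports) - n_exp,
        "shared_param_groups": dict(
            sorted(groups.items(), key=lambda kv: -kv[1])
        ),
    }


def frontier_tableau(
    ach: AchievableSet,
    reports: Sequence[ExpressivityRow],
    param: str = "p1",
) -> pd.DataFrame:
    """Numeric phenotype-space tableau for a two-site-year subset.

    Rows and columns are anthesis dates in the two site-years.  Cells
    inside the achievable set show the witness value of ``param`` (the
    estimate any line observed there would receive); cells holding
    inexpressible observations show ``-count``, the (negated) number of
    lines stranded there.  Empty cells are NaN.
    """
    if len(ach.site_ids) != 2:
        raise ValueError("tableau is defined for two-site-year subsets only")
    obs_counts: dict[tuple, int] = {}
    for r in reports:
        if not r.expressible:
            obs_counts[r.observed] = obs_counts.get(r.observed, 0) + 1
    xs = sorted(
        set(int(t[0]) for t in ach.tuples) | {t[0] for t in obs_counts}
    )
    ys = sorted(
        set(int(t[1]) for t in ach.tuples) | {t[1] for t in obs_counts}
    )
    grid = pd.DataFrame(np.nan, index=xs, columns=ys)
    vals = ach.params[param].to_numpy()
    for (a, b), v in zip(ach.tuples, vals):
        grid.loc[int(a), int(b)] = v
    for (a, b), c in obs_counts.items():
        grid.loc[a, b] = -c
    grid.index.name = ach.site_ids[0]
    grid.columns.name = ach.site_ids[1]
    return grid
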