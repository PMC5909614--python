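"""Cross-environment stability of parameter estimates.

If a genotype-specific parameter really is genotype-specific, the value
estimated for a line should not depend on which environments were used
to estimate it.  The test: enumerate k-of-n subsets of the available
site-years, re-estimate every line on every subset (discarding tied,
i.e. equifinal, searches and thinly covered subsets), and fit the
crossed random-effects model

    rho_{l,e} = mu + a_l + b_e + eps_{l,e},
    a_l ~ N(0, s2_line),  b_e ~ N(0, s2_subset),  eps ~ N(0, s2_resid)

by maximum likelihood, once with and once without the subset effect.
Stability means s2_subset = 0; the likelihood-ratio statistic is
referred to a boundary null (central chi-square with half a degree of
freedom by default, or the conventional 50:50 mixture of chi2_0 and
chi2_1).  Reported alongside: AIC/BIC of both fits, the Index of
Variability (subset-effect standard deviation as a percentage of the
grand mean) and the subset share of total variance.

The fitter exploits the model's low-rank covariance structure
(Woodbury identity on the line/subset indicator blocks), making a fit
cost one small Cholesky per likelihood evaluation; this is what allows
hundreds of replicate fits in the calibration suites.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .inversion import InversionError, LineObservations, first_best_found
from .sobol_db import SimDatabase

__all__ = [
    "StabilityDataset",
    "VarianceModelFit",
    "StabilityResult",
    "enumerate_subsets",
    "build_stability_dataset",
    "fit_variance_model",
    "stability_statistics",
    "stability_analysis",
    "simulate_crossed_panel",
    "chernoff_log10_sf",
]


def enumerate_subsets(n_siteyears: int, k: int) -> list[tuple[int, ...]]:
    """All k-subsets of ``range(n_siteyears)`` in lexicographic order."""
    if not 1 <= k <= n_siteyears:
        raise ValueError(f"k={k} outside [1, {n_siteyears}]")
    return list(itertools.combinations(range(n_siteyears), k))


@dataclass
class StabilityDataset:
    """Long table of per-(line, subset) estimates surviving the filters.

    ``table`` columns: ``line_id``, ``subset`` (index into ``subsets``),
    one column per GSP.  ``provenance`` records how many searches were
    attempted, dropped for ties, and how many subsets were dropped for
    covering fewer than ``min_lines`` lines.
    """

    table: pd.DataFrame
    subsets: list[tuple[str, ...]]
    provenance: dict = field(default_factory=dict)

    @property
    def gsp_names(self) -> list[str]:
        return [
            c for c in self.table.columns if c not in ("line_id", "subset")
        ]


def build_stability_dataset(
    db: SimDatabase,
    observations: Sequence[LineObservations],
    subsets: Sequence[Sequence[str]] | None = None,
    k: int = 7,
    min_lines: int = 100,
) -> StabilityDataset:
    """Run every line x subset search and apply the tie/coverage filters.

    Only lines observed in every site-year of the database enter (the
    complete panel).  Estimates from searches with one or more ties are
    discarded; subsets retaining fewer than ``min_lines`` lines are
    dropped entirely.
    """
    if subsets is None:
        idx_subsets = enumerate_subsets(len(db.site_ids), k)
        subsets = [tuple(db.site_ids[i] for i in s) for s in idx_subsets]
    else:
        subsets = [tuple(s) for s in subsets]
    complete = [
        obs for obs in observations if all(s in obs.dates for s in db.site_ids)
    ]
    n_attempted = len(complete) * len(subsets)
    rows = []
    n_tied = 0
    n_failed = 0
    for e, sub in enumerate(subsets):
        for obs in complete:
            try:
                rec = first_best_found(db, obs, sub)
            except InversionError:
                n_failed += 1
                continue
            if rec.n_ties > 0:
                n_tied += 1
                continue
            rows.append({"line_id": obs.line_id, "subset": e, **rec.best_params})
    table = pd.DataFrame(rows)
    if len(table):
        keep = table.groupby("subset")["line_id"].transform("count") >= min_lines
        dropped_subsets = int(table.loc[~keep, "subset"].nunique())
        table = table.loc[keep].reset_index(drop=True)
    else:
        dropped_subsets = len(subsets)
    if not len(table):
        raise ValueError(
            "no (line, subset) estimate survived the tie/coverage filters"
        )
    coverage = table.groupby("line_id")["subset"].nunique().to_dict()
    return StabilityDataset(
        table=table,
        subsets=list(subsets),
        provenance={
            "n_lines_complete": len(complete),
            "n_subsets": len(subsets),
            "n_searches_attempted": n_attempted,
            "n_dropped_ties": n_tied,
            "n_dropped_inexpressible": n_failed,
            "n_subsets_dropped_coverage": dropped_subsets,
            "min_lines": min_lines,
            "per_line_subset_coverage": coverage,
        },
    )


@dataclass(frozen=True)
class VarianceModelFit:
    """Maximum-likelihood fit of the crossed (or line-only) variance model."""

    mu: float
    var_line: float
    var_subset: float | None  # None in the reduced (line-only) model
    var_resid: float
    loglik: float
    n_obs: int
    n_params: int
    converged: bool

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * math.log(self.n_obs)


class _CrossedML:
    """Profile log-likelihood of the two-way crossed random-intercept model.

    With Z the (line, subset) indicator matrix and G the diagonal of
    component variances, V = s2r I + Z G Z'; the Woodbury identity and
    the matched determinant lemma reduce every likelihood evaluation to
    a Cholesky factorisation of the q x q matrix
    A = I + (1/s2r) G^{1/2} Z'Z G^{1/2}, q = n_lines + n_subsets.  The
    grand mean is profiled out by GLS.
    """

    def __init__(self, y, line_codes, subset_codes, n_lines, n_subsets):
        y = np.asarray(y, dtype=float)
        self.n = len(y)
        self.nl = n_lines
        self.ne = n_subsets
        # Z'Z blocks: per-level counts and the line x subset incidence
        self.cnt_l = np.bincount(line_codes, minlength=n_lines).astype(float)
        self.cnt_e = np.bincount(subset_codes, minlength=n_subsets).astype(float)
        self.inc = np.zeros((n_lines, n_subsets))
        np.add.at(self.inc, (line_codes, subset_codes), 1.0)
        self.zty_l = np.bincount(line_codes, weights=y, minlength=n_lines)
        self.zty_e = np.bincount(subset_codes, weights=y, minlength=n_subsets)
        self.yy = float(y @ y)
        self.y1 = float(y.sum())

    def loglik(self, var_line: float, var_subset: float, var_resid: float):
        """Profile log-likelihood and the GLS grand mean at these variances.

        The line block of A is diagonal, so its Schur complement reduces
        the factorisation to the (n_subsets x n_subsets) block.
        """
        vl = max(var_line, 0.0)
        ve = max(var_subset, 0.0)
        vr = var_resid
        # A = I + Z'Z scaled by component variances over vr, in blocks:
        a11 = 1.0 + vl * self.cnt_l / vr  # diagonal
        a12 = (math.sqrt(vl * ve) / vr) * self.inc
        schur = np.diag(1.0 + ve * self.cnt_e / vr) - a12.T @ (
            a12 / a11[:, None]
        )
        try:
            chol = np.linalg.cholesky(schur)
        except np.linalg.LinAlgError:
            return -np.inf, 0.0
        logdet = (
            self.n * math.log(vr)
            + np.log(a11).sum()
            + 2.0 * np.log(np.diag(chol)).sum()
        )
        # W = G^{1/2} Z' [y, 1]; solve A X = W blockwise
        sl, se = math.sqrt(vl), math.sqrt(ve)
        w1 = np.column_stack([sl * self.zty_l, sl * self.cnt_l])
        w2 = np.column_stack([se * self.zty_e, se * self.cnt_e])
        rhs = w2 - a12.T @ (w1 / a11[:, None])
        x2 = np.linalg.solve(chol.T, np.linalg.solve(chol, rhs))
        x1 = (w1 - a12 @ x2) / a11[:, None]
        waw = w1.T @ x1 + w2.T @ x2  # W' A^{-1} W, 2x2
        # bilinear forms a' V^{-1} b for a, b in {y, 1}
        gram_plain = np.array([[self.yy, self.y1], [self.y1, float(self.n)]])
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            gram = (gram_plain - waw / vr) / vr
            s_yy, s_y1, s_11 = gram[0, 0], gram[0, 1], gram[1, 1]
            mu = s_y1 / s_11
            quad = s_yy - s_y1 * s_y1 / s_11
            ll = -0.5 * (self.n * math.log(2.0 * math.pi) + logdet + quad)
        if not math.isfinite(ll):  # pathological variances during search
            return -np.inf, 0.0
        return ll, mu


def fit_variance_model(
    dataset: StabilityDataset | pd.DataFrame,
    gsp: str,
    include_subset_effect: bool = True,
) -> VarianceModelFit:
    """ML fit of the crossed (full) or line-only (reduced) variance model.

    Deterministic: multiple fixed starting points (including the
    boundary ``var_subset = 0``) are polished with L-BFGS-B on the
    profile likelihood and the best is returned.  Variances are bounded
    below by zero (boundary estimates allowed); the residual variance
    by a small positive floor.
    """
    table = dataset.table if isinstance(dataset, StabilityDataset) else dataset
    y = table[gsp].to_numpy(dtype=float)
    lines, line_codes = np.unique(table["line_id"].to_numpy(), return_inverse=True)
    subs, subset_codes = np.unique(table["subset"].to_numpy(), return_inverse=True)
    if len(lines) < 2:
        raise ValueError("need >= 2 lines")
    if include_subset_effect and len(subs) < 2:
        raise ValueError("need >= 2 subsets for the full model")
    ml = _CrossedML(y, line_codes, subset_codes, len(lines), len(subs))
    scale = max(float(np.var(y)), 1e-12)
    floor = 1e-10

    if include_subset_effect:
        def neg(theta):
            ll, _ = ml.loglik(theta[0] * scale, theta[1] * scale, theta[2] * scale)
            return -ll / ml.n

        starts = [(0.4, 0.3, 0.3), (0.45, 0.0, 0.55), (0.1, 0.8, 0.1), (0.8, 0.1, 0.1)]
        bounds = [(0.0, None), (0.0, None), (floor, None)]
    else:
        def neg(theta):
            ll, _ = ml.loglik(theta[0] * scale, 0.0, theta[1] * scale)
            return -ll / ml.n

        starts = [(0.5, 0.5), (0.1, 0.9), (0.9, 0.1)]
        bounds = [(0.0, None), (floor, None)]

    best = None
    converged = False
    for x0 in starts:
        res = minimize(
            neg, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    theta = best.x * scale
    if include_subset_effect:
        vl, ve, vr = theta
        ll, mu = ml.loglik(vl, ve, vr)
        return VarianceModelFit(
            mu=mu, var_line=vl, var_subset=ve, var_resid=vr,
            loglik=ll, n_obs=ml.n, n_params=4, converged=converged,
        )
    vl, vr = theta
    ll, mu = ml.loglik(vl, 0.0, vr)
    return VarianceModelFit(
        mu=mu, var_line=vl, var_subset=None, var_resid=vr,
        loglik=ll, n_obs=ml.n, n_params=3, converged=converged,
    )


def chernoff_log10_sf(x: float, df: float) -> float:
    """Chernoff upper bound on log10 P(chi2_df > x), valid for x > df.

    P(X >= x) <= (x/df)^(df/2) * exp((df - x)/2); used to report the
    order of magnitude of p-values too small for floating point.
    """
    if x <= df:
        return 0.0
    ln_p = 0.5 * df * math.log(x / df) + 0.5 * (df - x)
    return ln_p / math.log(10.0)


@dataclass(frozen=True)
class StabilityResult:
    """Stability verdict for one GSP."""

    gsp: str
    full: VarianceModelFit
    reduced: VarianceModelFit
    lrt_stat: float
    p_value: float
    log10_p: float
    p_method: str  # "half_df" | "mixture", suffixed ":chernoff" when bounded
    iov_pct: float
    var_pct_subset: float


def stability_statistics(
    full: VarianceModelFit,
    reduced: VarianceModelFit,
    gsp: str = "",
    null: str = "half_df",
    tol: float = 1e-6,
) -> StabilityResult:
    """Boundary LRT and summary descriptors from the two fits.

    ``null`` selects the reference distribution for the test of
    ``var_subset = 0``: ``"half_df"`` refers 2*(ll_full - ll_reduced)
    to a central chi-square with 0.5 degrees of freedom; ``"mixture"``
    to the 50:50 mixture of a point mass at zero and chi-square with
    one df.  P-values beyond floating-point range are reported via the
    Chernoff tail bound in ``log10_p`` and tagged in ``p_method``.
    """
    if null not in ("half_df", "mixture"):
        raise ValueError(f"unknown null {null!r}")
    lrt = 2.0 * (full.loglik - reduced.loglik)
    if lrt < -tol * max(1.0, abs(full.loglik)):
        raise RuntimeError(
            f"reduced log-likelihood ({reduced.loglik:.6f}) exceeds full "
            f"({full.loglik:.6f}); fits inconsistent"
        )
    lrt = max(lrt, 0.0)
    if null == "half_df":
        p = float(chi2.sf(lrt, 0.5))
        df = 0.5
    else:
        # point mass at zero never exceeds the observed statistic, so the
        # mixture tail is half the chi2_1 tail (0.5 exactly at lrt = 0)
        p = float(0.5 * chi2.sf(lrt, 1.0))
        df = 1.0
    method = null
    if p > 0.0:
        log10_p = math.log10(p)
    else:
        bound = chernoff_log10_sf(lrt, df)
        log10_p = bound - math.log10(2.0) if null == "mixture" else bound
        method = f"{null}:chernoff"
    mu = full.mu
    ve = full.var_subset or 0.0
    total = ve + full.var_line + full.var_resid
    return StabilityResult(
        gsp=gsp,
        full=full,
        reduced=reduced,
        lrt_stat=lrt,
        p_value=p,
        log10_p=log10_p,
        p_method=method,
        iov_pct=100.0 * math.sqrt(ve) / mu if mu != 0 else float("inf"),
        var_pct_subset=100.0 * ve / total if total > 0 else 0.0,
    )


def stability_analysis(
    dataset: StabilityDataset, null: str = "half_df"
) -> list[StabilityResult]:
    """Fit both models and compute the stability test for every GSP."""
    out = []
    for gsp in dataset.gsp_names:
        full = fit_variance_model(dataset, gsp, include_subset_effect=True)
        reduced = fit_variance_model(dataset, gsp, include_subset_effect=False)
        out.append(stability_statistics(full, reduced, gsp=gsp, null=null))
    return out


def simulate_crossed_panel(
    mu: float,
    sd_line: float,
    sd_subset: float,
    sd_resid: float,
    n_lines: int,
    n_subsets: int,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Draw one panel from the crossed random-effects model.

    Used by the calibration suites: null panels (``sd_subset = 0``) to
    check test size, alternative panels to check power.
    """
    a = rng.normal(0.0, sd_line, n_lines)
    b = rng.normal(0.0, sd_subset, n_subsets)
    eps = rng.normal(0.0, sd_resid, (n_lines, n_subsets))
    values = mu + a[:, None] + b[None, :] + eps
    li, ei = np.meshgrid(np.arange(n_lines), np.arange(n_subsets), indexing="ij")
    table = pd.DataFrame(
        {
            "line_id": [f"L{i:04d}" for i in li.ravel()],
            "subset": ei.ravel(),
            "value": values.ravel(),
        }
    )
    if missing_rate > 0.0:
        table = table[rng.random(len(table)) >= missing_rate].reset_index(
            drop=True
        )
    return table
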