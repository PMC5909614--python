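"""End-to-end pipeline: simulate -> build database -> invert -> expressivity -> stability.

Stages communicate only through documented on-disk artifacts (CSV,
parquet database, JSON), so any stage can be resumed from what a
previous run left behind.  A run manifest records the configuration
snapshot, seeds, input hashes and the database content hash; two runs
with equal manifests (timestamps aside) produce bit-identical outputs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .env import SiteYear, read_sites
from .expressivity import achievable_tuples, classify_lines, expressivity_summary
from .inversion import InversionError, LineObservations, first_best_found
from .phenology import PhenologyConfig
from .sobol_db import (
    DEFAULT_BOX,
    ParameterBox,
    SimDatabase,
    build_database,
    generate_sobol_sets,
    load_database,
    save_database,
)
from .stability import build_stability_dataset, stability_analysis
from .synthetic import SyntheticConfig, make_observations, make_population, make_siteyears, write_panel

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "read_observations",
    "estimate_all_lines",
    "ConfigError",
]

log = logging.getLogger("phenoscan")


class ConfigError(ValueError):
    """Raised before any stage runs when the configuration is invalid."""


_KNOWN_KEYS = {
    "synthetic": {"n_lines", "noise_sd", "missing_rate", "seed"},
    "phenology": {
        "tbase", "topt", "emergence_gdd", "stage2_mode",
        "sumdtt_origin", "max_horizon_days",
    },
    "database": {"n_sets", "skip", "box"},
    "inversion": {"subset"},
    "expressivity": {"subset"},
    "stability": {"k", "min_lines", "null"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (plain dict per section)."""

    synthetic: dict
    phenology: dict
    database: dict
    inversion: dict
    expressivity: dict
    stability: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        errors = []
        sections = {}
        for name, allowed in _KNOWN_KEYS.items():
            section = raw.get(name, {}) or {}
            if not isinstance(section, dict):
                errors.append(f"{name}: must be a mapping")
                continue
            for key in section:
                if key not in allowed:
                    errors.append(f"{name}.{key}: unknown key")
            sections[name] = dict(section)
        for key in raw:
            if key not in _KNOWN_KEYS:
                errors.append(f"{key}: unknown section")
        if errors:
            raise ConfigError(
                "invalid configuration:\n  " + "\n  ".join(sorted(errors))
            )
        return cls(**sections)

    def phenology_config(self) -> PhenologyConfig:
        return PhenologyConfig.from_dict(self.phenology)

    def box(self) -> ParameterBox:
        if "box" in self.database:
            return ParameterBox.from_dict(self.database["box"])
        return DEFAULT_BOX

    def to_dict(self) -> dict:
        return {
            "synthetic": self.synthetic,
            "phenology": self.phenology,
            "database": self.database,
            "inversion": self.inversion,
            "expressivity": self.expressivity,
            "stability": self.stability,
        }


def read_observations(path: str | Path) -> list[LineObservations]:
    """Read the long-form ``line_id,site_year,anthesis_dap`` CSV."""
    df = pd.read_csv(path)
    required = {"line_id", "site_year", "anthesis_dap"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        LineObservations(
            line_id=str(line_id),
            dates=dict(zip(g["site_year"], g["anthesis_dap"].astype(int))),
        )
        for line_id, g in df.groupby("line_id", sort=True)
    ]


def estimate_all_lines(
    db: SimDatabase,
    observations: Sequence[LineObservations],
    subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """First-best-found estimates for every scorable line, as a table."""
    rows = []
    n_inexpressible_horizon = 0
    for obs in observations:
        try:
            rec = first_best_found(db, obs, subset)
        except InversionError:
            n_inexpressible_horizon += 1
            log.info("line %s: no eligible database row", obs.line_id)
            continue
        rows.append(
            {
                "line_id": rec.line_id,
                **rec.best_params,
                "rmse": rec.rmse,
                "sse": rec.sse,
                "n_obs": rec.n_obs,
                "n_ties": rec.n_ties,
            }
        )
    if n_inexpressible_horizon:
        log.warning(
            "%d line(s) had no eligible database row", n_inexpressible_horizon
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: dict | PipelineConfig,
    out_dir: str | Path,
    seed: int = 0,
    data_dir: str | Path | None = None,
    resume: bool = True,
) -> dict:
    """Run the full estimation study into ``out_dir``.

    With no ``data_dir`` a synthetic panel is generated first.  Stages:
    panel -> simulation database -> per-line estimates ->
    expressivity report -> stability table; each stage's artifact is
    reused when ``resume`` and it already exists.  Returns a summary
    dict with per-stage counts; writes ``manifest.json``.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pcfg = cfg.phenology_config()
    summary: dict = {}

    # --- stage: field panel (synthetic unless provided) -----------------
    if data_dir is None:
        data_dir = out / "data"
        if not (resume and (Path(data_dir) / "sites.csv").exists()):
            syn = SyntheticConfig(
                n_lines=int(cfg.synthetic.get("n_lines", 600)),
                box=cfg.box(),
                noise_sd=float(cfg.synthetic.get("noise_sd", 1.5)),
                missing_rate=float(cfg.synthetic.get("missing_rate", 0.15)),
                seed=int(cfg.synthetic.get("seed", seed)),
            )
            siteyears = make_siteyears(syn)
            pop = make_population(syn.n_lines, syn.box, seed=syn.seed + 1)
            _, obs_table = make_observations(
                pop, siteyears, pcfg, syn.noise_sd, syn.missing_rate,
                seed=syn.seed + 2,
            )
            write_panel(data_dir, siteyears, pop, obs_table)
            log.info("panel: %d site-years, %d lines", len(siteyears), syn.n_lines)
    data_dir = Path(data_dir)
    siteyears: list[SiteYear] = read_sites(data_dir / "sites.csv")
    observations = read_observations(data_dir / "observations.csv")
    summary["n_siteyears"] = len(siteyears)
    summary["n_lines"] = len(observations)

    # --- stage: simulation database --------------------------------------
    db_dir = out / "db"
    if resume and (db_dir / "meta.json").exists():
        db = load_database(db_dir)
        log.info("database: resumed %d sets (hash %s)", db.n_sets,
                 db.meta["content_hash"][:12])
    else:
        n_sets = int(cfg.database.get("n_sets", 65536))
        skip = int(cfg.database.get("skip", 0))
        sets = generate_sobol_sets(cfg.box(), n_sets, skip=skip)
        db = build_database(
            sets, siteyears, pcfg,
            meta={"n_sets": n_sets, "skip": skip, "box": cfg.box().to_dict(),
                  "code_version": __version__},
        )
        save_database(db, db_dir)
        log.info("database: built %d sets x %d site-years", db.n_sets,
                 len(db.site_ids))
    summary["n_sets"] = db.n_sets
    summary["db_hash"] = db.meta["content_hash"]

    # --- stage: per-line estimates ---------------------------------------
    est_path = out / "estimates.csv"
    subset = cfg.inversion.get("subset")
    if not (resume and est_path.exists()):
        est = estimate_all_lines(db, observations, subset)
        est.to_csv(est_path, index=False)
    est = pd.read_csv(est_path)
    summary["n_estimated"] = len(est)
    summary["n_equifinal"] = int((est["n_ties"] > 0).sum())

    # --- stage: expressivity ---------------------------------------------
    exp_subset = cfg.expressivity.get("subset") or list(db.site_ids)[:2]
    ach = achievable_tuples(db, exp_subset)
    reports = classify_lines(observations, ach)
    exp_path = out / "expressivity.csv"
    if not (resume and exp_path.exists()):
        pd.DataFrame(
            [
                {
                    "line_id": r.line_id,
                    "expressible": r.expressible,
                    "nearest_dates": "|".join(map(str, r.nearest)),
                    "distance_days": r.distance_days,
                    **r.params,
                }
                for r in reports
            ]
        ).to_csv(exp_path, index=False)
    if reports:
        summary["expressivity"] = {
            k: v
            for k, v in expressivity_summary(reports).items()
            if k != "shared_param_groups"
        }
        summary["expressivity"]["subset"] = list(exp_subset)

    # --- stage: stability -------------------------------------------------
    stab_path = out / "stability.csv"
    if not (resume and stab_path.exists()):
        k = int(cfg.stability.get("k", 7))
        min_lines = int(cfg.stability.get("min_lines", 100))
        null = str(cfg.stability.get("null", "half_df"))
        try:
            dataset = build_stability_dataset(
                db, observations, k=k, min_lines=min_lines
            )
        except ValueError as e:
            log.warning("stability stage skipped: %s", e)
            dataset = None
        if dataset is not None:
            results = stability_analysis(dataset, null=null)
            pd.DataFrame(
                [
                    {
                        "gsp": r.gsp,
                        "mu": r.full.mu,
                        "var_line": r.full.var_line,
                        "var_subset": r.full.var_subset,
                        "var_resid": r.full.var_resid,
                        "loglik_full": r.full.loglik,
                        "loglik_reduced": r.reduced.loglik,
                        "aic_full": r.full.aic,
                        "aic_reduced": r.reduced.aic,
                        "bic_full": r.full.bic,
                        "bic_reduced": r.reduced.bic,
                        "lrt_stat": r.lrt_stat,
                        "p_value": r.p_value,
                        "log10_p": r.log10_p,
                        "p_method": r.p_method,
                        "iov_pct": r.iov_pct,
                        "var_pct_subset": r.var_pct_subset,
                    }
                    for r in results
                ]
            ).to_csv(stab_path, index=False)
            summary["stability"] = dataset.provenance.copy()
            summary["stability"].pop("per_line_subset_coverage", None)

    # --- manifest ----------------------------------------------------------
    manifest = {
        "code_version": __version__,
        "config": cfg.to_dict(),
        "seed": seed,
        "phenology": pcfg.to_dict(),
        "inputs": {
            p.name: _sha256(p)
            for p in sorted(data_dir.glob("*.csv"))
        },
        "database_hash": db.meta["content_hash"],
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return summary
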