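"""Quasi-random scan of the parameter box and the simulated-anthesis database.

The inversion strategy trades optimisation for enumeration: a Sobol
low-discrepancy sequence fills the genotype-parameter box as uniformly
as possible, the phenology model is run for every sampled set in every
site-year, and the resulting table of simulated anthesis dates becomes a
reusable lookup structure.  Any per-line objective can then be evaluated
against the whole table without further model runs, which is what makes
equifinality (ties) and expressivity (the achievable phenotype set)
directly observable.

Generation order matters: it defines the "first-best-found" convention
used downstream, so it is deterministic and recorded in the database
metadata together with everything needed to rebuild the table
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .env import SiteYear
from .phenology import ANTHESIS_FAILED, PhenologyConfig, simulate_anthesis_batch

__all__ = [
    "AxisSpec",
    "ParameterBox",
    "SimDatabase",
    "DatabaseIntegrityError",
    "generate_sobol_sets",
    "build_database",
    "save_database",
    "load_database",
    "DEFAULT_BOX",
    "EXTENDED_BOX",
]

SCHEMA_VERSION = 1

#: refuse to generate more than this many sets in one call (shard instead)
MAX_SETS_PER_CALL = 2**25


class DatabaseIntegrityError(RuntimeError):
    """Raised when a persisted database fails schema or hash validation."""


@dataclass(frozen=True)
class AxisSpec:
    """One axis of the parameter box: name, range and rounding resolution.

    ``resolution`` is the grid step to which sampled coordinates are
    rounded (anchored at ``lo``); the number of distinct values an axis
    can take is therefore ``(hi - lo) / resolution + 1``.
    """

    name: str
    lo: float
    hi: float
    resolution: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: lo must be < hi")
        if not self.resolution > 0:
            raise ValueError(f"{self.name}: resolution must be > 0")

    @property
    def n_unique(self) -> int:
        return int(round((self.hi - self.lo) / self.resolution)) + 1


@dataclass(frozen=True)
class ParameterBox:
    """The box scanned by the Sobol sequence: one :class:`AxisSpec` per GSP."""

    axes: tuple[AxisSpec, ...]

    def __post_init__(self) -> None:
        names = [a.name for a in self.axes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate axis names in {names}")

    @property
    def dim(self) -> int:
        return len(self.axes)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.axes]

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        lo = np.array([a.lo for a in self.axes])
        hi = np.array([a.hi for a in self.axes])
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    def to_dict(self) -> dict:
        return {
            "axes": [
                {"name": a.name, "lo": a.lo, "hi": a.hi, "resolution": a.resolution}
                for a in self.axes
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterBox":
        return cls(
            tuple(
                AxisSpec(a["name"], a["lo"], a["hi"], a["resolution"])
                for a in d["axes"]
            )
        )


#: Four-parameter box scanned in the main study: ranges and resolutions
#: give 30001 / 401 / 20001 / 45001 distinct values per axis.
DEFAULT_BOX = ParameterBox(
    (
        AxisSpec("p1", 150.0, 450.0, 0.01),
        AxisSpec("p2o", 10.0, 14.0, 0.01),
        AxisSpec("p2", 0.0, 2.0, 0.0001),
        AxisSpec("phint", 25.0, 70.0, 0.001),
    )
)

#: Deliberately over-wide bounds used for the continuous (DE) cross-check,
#: far beyond biologically expected values.
EXTENDED_BOX = ParameterBox(
    (
        AxisSpec("p1", 75.0, 600.0, 0.01),
        AxisSpec("p2o", 6.0, 21.0, 0.01),
        AxisSpec("p2", 0.0, 6.0, 0.0001),
        AxisSpec("phint", 20.0, 100.0, 0.001),
    )
)


def generate_sobol_sets(
    box: ParameterBox, n: int, skip: int = 0
) -> pd.DataFrame:
    """First ``n`` points of the Sobol sequence scaled into the box.

    The sequence is unscrambled, so generation is fully deterministic:
    point ``i`` is the same in every run and the row order is the scan
    order used by first-best-found estimation.  Each coordinate is
    rounded to its axis resolution (grid anchored at the axis minimum).

    Parameters
    ----------
    box : ParameterBox
    n : int
        Number of parameter sets (need not be a power of two).
    skip : int
        Number of initial sequence points to discard (burn-in).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > MAX_SETS_PER_CALL:
        raise MemoryError(
            f"n={n} exceeds the per-call budget ({MAX_SETS_PER_CALL}); "
            "shard the scan into multiple databases"
        )
    sampler = qmc.Sobol(d=box.dim, scramble=False)
    if skip:
        sampler.fast_forward(skip)
    with warnings.catch_warnings():
        # unscrambled + non-power-of-two draws are intentional here
        warnings.simplefilter("ignore", UserWarning)
        u = sampler.random(n)
    lo = np.array([a.lo for a in box.axes])
    hi = np.array([a.hi for a in box.axes])
    res = np.array([a.resolution for a in box.axes])
    x = lo + u * (hi - lo)
    x = lo + np.round((x - lo) / res) * res
    x = np.clip(x, lo, hi)
    return pd.DataFrame(x, columns=box.names)


@dataclass
class SimDatabase:
    """Simulated anthesis dates for every parameter set x site-year.

    ``params`` holds the scanned sets in generation order; ``anthesis``
    is an ``(n_sets, n_siteyears)`` int32 table of days after sowing
    with ``ANTHESIS_FAILED`` marking simulations that did not flower.
    ``meta`` records the box, generation rule, phenology configuration,
    site metadata and a content hash, which together allow the table to
    be rebuilt bit-identically.
    """

    params: pd.DataFrame
    anthesis: np.ndarray
    site_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.anthesis = np.asarray(self.anthesis, dtype=np.int32)
        if self.anthesis.shape != (len(self.params), len(self.site_ids)):
            raise ValueError(
                f"anthesis shape {self.anthesis.shape} != "
                f"({len(self.params)}, {len(self.site_ids)})"
            )
        ok = (self.anthesis > 0) | (self.anthesis == ANTHESIS_FAILED)
        if not np.all(ok):
            raise ValueError("anthesis entries must be > 0 or the failure sentinel")

    @property
    def n_sets(self) -> int:
        return len(self.params)

    def site_index(self, site_ids: Sequence[str]) -> np.ndarray:
        """Column indices of the given site-year labels."""
        pos = {s: i for i, s in enumerate(self.site_ids)}
        try:
            return np.array([pos[s] for s in site_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"site-year {e.args[0]!r} not in database") from None

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.params.to_numpy(float)).tobytes())
        h.update(np.ascontiguousarray(self.anthesis).tobytes())
        h.update(",".join(self.site_ids).encode())
        return h.hexdigest()


def build_database(
    sets: pd.DataFrame,
    siteyears: Sequence[SiteYear],
    cfg: PhenologyConfig | None = None,
    meta: dict | None = None,
) -> SimDatabase:
    """Simulate every parameter set in every site-year.

    Equivalent to calling ``simulate_anthesis`` cell by cell, evaluated
    with the vectorised batch kernel; the result is independent of any
    internal chunking.  Optional ``tbase``/``topt`` columns in ``sets``
    make the scan six-dimensional.
    """
    cfg = cfg or PhenologyConfig()
    if len(sets) == 0:
        raise ValueError("no parameter sets given")
    ids = [sy.site_id for sy in siteyears]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate site-year ids in {ids}")
    tbase = sets["tbase"].to_numpy() if "tbase" in sets else None
    topt = sets["topt"].to_numpy() if "topt" in sets else None
    anth = np.empty((len(sets), len(siteyears)), dtype=np.int32)
    for j, sy in enumerate(siteyears):
        anth[:, j] = simulate_anthesis_batch(
            sy,
            sets["p1"].to_numpy(),
            sets["p2"].to_numpy(),
            sets["p2o"].to_numpy(),
            sets["phint"].to_numpy(),
            cfg,
            tbase=tbase,
            topt=topt,
        )
    db = SimDatabase(
        params=sets.reset_index(drop=True),
        anthesis=anth,
        site_ids=ids,
        meta={
            "schema_version": SCHEMA_VERSION,
            "phenology": cfg.to_dict(),
            "sites": [
                {
                    "site_id": sy.site_id,
                    "latitude": sy.latitude,
                    "longitude": sy.longitude,
                    "year": sy.year,
                    "sowing_doy": sy.sowing_doy,
                }
                for sy in siteyears
            ],
            **(meta or {}),
        },
    )
    db.meta["content_hash"] = db.content_hash()
    return db


def save_database(db: SimDatabase, path: str | Path) -> None:
    """Persist a database to a directory of parquet tables plus metadata.

    Layout: ``params.parquet`` (one column per GSP, generation order),
    ``anthesis.parquet`` (one int32 column per site-year), ``meta.json``
    (schema version, provenance, content hash).  Writing is
    deterministic: saving the same database twice yields byte-identical
    files.
    """
    import pyarrow as pa
    import pyarrow.parquet as pq

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pq.write_table(
        pa.Table.from_pandas(db.params, preserve_index=False),
        path / "params.parquet",
    )
    pq.write_table(
        pa.table(
            {s: db.anthesis[:, j] for j, s in enumerate(db.site_ids)}
        ),
        path / "anthesis.parquet",
    )
    meta = dict(db.meta)
    meta.setdefault("schema_version", SCHEMA_VERSION)
    meta["content_hash"] = db.content_hash()
    (path / "meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def load_database(path: str | Path) -> SimDatabase:
    """Load a persisted database, verifying schema version and content hash."""
    import pyarrow.parquet as pq

    path = Path(path)
    try:
        meta = json.loads((path / "meta.json").read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise DatabaseIntegrityError(f"cannot read {path}/meta.json: {e}") from e
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise DatabaseIntegrityError(
            f"schema version {version!r} != supported {SCHEMA_VERSION}"
        )
    try:
        params = pq.read_table(path / "params.parquet").to_pandas()
        anth_tbl = pq.read_table(path / "anthesis.parquet")
    except Exception as e:  # pyarrow raises various types on corruption
        raise DatabaseIntegrityError(f"corrupt database at {path}: {e}") from e
    site_ids = list(anth_tbl.column_names)
    anthesis = np.column_stack(
        [anth_tbl.column(s).to_numpy() for s in site_ids]
    ).astype(np.int32)
    db = SimDatabase(params=params, anthesis=anthesis, site_ids=site_ids, meta=meta)
    expected = meta.get("content_hash")
    actual = db.content_hash()
    if expected is not None and expected != actual:
        raise DatabaseIntegrityError(
            f"content hash mismatch: meta {expected[:12]}.. != data {actual[:12]}.."
        )
    return db
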