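"""Readers, writers and run configuration shared by all pipeline stages.

All file formats are plain CSV (one header row; column names match the field
names of the corresponding domain types) and YAML for configuration.  Output
floats are written with 17 significant digits so that every writer/reader
pair round-trips losslessly.  See ``docs/schemas.md`` for the full schemas.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .framework import VALID_RANKS
from .refpoints import NUTRIENTS, NutrientProfile
from .sizespectrum import GearSelectivity, ResourceParams, SpeciesParams

__all__ = [
    "RunConfig",
    "FLOAT_FORMAT",
    "read_species_csv",
    "write_species_csv",
    "read_selectivity_csv",
    "write_selectivity_csv",
    "read_nutrients_csv",
    "write_nutrients_csv",
    "read_interaction_csv",
    "write_interaction_csv",
    "read_catch_csv",
    "write_catch_csv",
    "load_config",
]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.17g"

SPECIES_COLUMNS = [
    "name", "w_min", "w_inf", "w_mat", "L_inf", "h", "n", "gamma", "q",
    "beta", "sigma", "alpha", "ks", "p", "mu_b0", "erepro", "R_max",
]
SELECTIVITY_COLUMNS = ["gear", "species", "w50", "slope", "Q"]
CATCH_COLUMNS = ["region", "taxon", "rank", "catch_tonnes", "vulnerability"]


@dataclass
class RunConfig:
    """Run-wide settings: grid, numerics, effort grid, optimiser, thresholds."""

    n_bins: int = 100
    resource_decades: float = 3.0
    dt: float = 0.1
    tol: float = 1e-5
    t_max: float = 600.0
    effort_max: float = 4.0
    effort_step: float = 0.05
    f_bounds: tuple[float, float] = (0.01, 2.0)
    n_starts: int = 5
    collapse_threshold: float = 0.10
    neutrality_tolerance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.collapse_threshold < 1:
            raise ValueError("collapse threshold must be in (0, 1)")
        lo, hi = self.f_bounds
        if not 0 <= lo < hi:
            raise ValueError("fishing-mortality bounds must be ordered")
        if self.dt <= 0 or self.tol <= 0:
            raise ValueError("dt and tol must be positive")

    @property
    def equil_kwargs(self) -> dict:
        return {"tol": self.tol, "t_max": self.t_max, "dt": self.dt}


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; sections grid/numerics/sweep/optimiser/seed are
    merged over the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    flat: dict = {}
    for section in ("grid", "numerics", "sweep", "optimiser"):
        flat.update(raw.get(section, {}) or {})
    if "seed" in raw:
        flat["seed"] = raw["seed"]
    if "f_bounds" in flat:
        flat["f_bounds"] = tuple(flat["f_bounds"])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(flat) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**flat)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns: {missing}")


def _row_errors(rows: list[str]) -> None:
    if rows:
        raise ValueError("; ".join(rows))


# ---------------------------------------------------------------------------
# species parameters
# ---------------------------------------------------------------------------

def read_species_csv(path: str | Path) -> list[SpeciesParams]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SPECIES_COLUMNS, "species table")
    out, errors = [], []
    for i, row in df.iterrows():
        try:
            kwargs = {c: row[c] for c in SPECIES_COLUMNS if c != "name"}
            out.append(SpeciesParams(name=str(row["name"]), **kwargs))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    _row_errors(errors)
    return out


def write_species_csv(species: Sequence[SpeciesParams], path: str | Path) -> None:
    df = pd.DataFrame(
        [{c: getattr(sp, c) for c in SPECIES_COLUMNS} for sp in species]
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# gear selectivities
# ---------------------------------------------------------------------------

def read_selectivity_csv(path: str | Path) -> list[GearSelectivity]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SELECTIVITY_COLUMNS, "selectivity table")
    out, errors = [], []
    for i, row in df.iterrows():
        try:
            out.append(
                GearSelectivity(
                    gear=str(row["gear"]), species=str(row["species"]),
                    w50=float(row["w50"]), slope=float(row["slope"]),
                    Q=float(row["Q"]),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i + 2}: {exc}")
    _row_errors(errors)
    return out


def write_selectivity_csv(
    gears: Sequence[GearSelectivity], path: str | Path
) -> None:
    df = pd.DataFrame(
        [{c: getattr(g, c) for c in SELECTIVITY_COLUMNS} for g in gears]
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# nutrient profiles
# ---------------------------------------------------------------------------

def read_nutrients_csv(path: str | Path) -> list[NutrientProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["species", *NUTRIENTS], "nutrient table")
    out, errors = [], []
    for i, row in df.iterrows():
        try:
            out.append(
                NutrientProfile(
                    species=str(row["species"]),
                    concentrations={n: float(row[n]) for n in NUTRIENTS},
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i + 2}: {exc}")
    _row_errors(errors)
    return out


def write_nutrients_csv(
    profiles: Sequence[NutrientProfile], path: str | Path
) -> None:
    df = pd.DataFrame(
        [{"species": p.species, **p.concentrations} for p in profiles]
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# interaction matrix
# ---------------------------------------------------------------------------

def read_interaction_csv(path: str | Path) -> pd.DataFrame:
    """Square interaction matrix with species labels as row/column headers."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"interaction matrix must be square, got {df.shape}"
        )
    if list(df.index) != list(df.columns):
        raise ValueError("interaction matrix row and column labels differ")
    vals = df.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("interaction coefficients must be in [0, 1]")
    return df


def write_interaction_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# catch tables
# ---------------------------------------------------------------------------

def read_catch_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, CATCH_COLUMNS, "catch table")
    errors = []
    for i, row in df.iterrows():
        if row["rank"] not in VALID_RANKS:
            errors.append(f"row {i + 2}: unknown rank {row['rank']!r}")
        if row["catch_tonnes"] < 0:
            errors.append(f"row {i + 2}: negative catch")
        v = row["vulnerability"]
        if np.isfinite(v) and not (1 <= v <= 100):
            errors.append(f"row {i + 2}: vulnerability outside [1, 100]")
    _row_errors(errors)
    return df[CATCH_COLUMNS].copy()


def write_catch_csv(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, CATCH_COLUMNS, "catch table")
    df[CATCH_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)
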