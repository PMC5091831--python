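"""Validated readers and writers for the pipeline's file formats.

Tables are CSV with a header row (UTF-8, empty fields for missing values);
trees are Newick, one per line; configuration and fitted models are JSON.
Readers check schemas and closed category vocabularies up front so that
errors name the file, column and offending values instead of surfacing as
numerical failures later.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .fixtures import DIET_LEVELS, FORAGE_LEVELS
from .phylo import read_newick

__all__ = [
    "read_records",
    "read_traits",
    "read_stations",
    "read_trees",
    "SchemaError",
]


class SchemaError(ValueError):
    """An input table violates its schema."""


_RECORD_COLS = ["individual", "species", "station", "year", "age", "sex", "d2hf"]
_TRAIT_COLS = ["species", "forage_substrate", "diet", "nest_substrate"]
_STATION_COLS = [
    "station", "latitude", "longitude",
    "habitat_100m", "habitat_station", "wetland_area",
]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _check_levels(df: pd.DataFrame, col: str, allowed, path) -> None:
    bad = sorted(set(df[col].dropna().unique()) - set(allowed))
    if bad:
        raise SchemaError(
            f"{path}: column {col!r} has unknown levels {bad}; "
            f"allowed levels are {sorted(allowed)}"
        )


def read_records(path) -> pd.DataFrame:
    """Individual-level records; duplicate individual IDs are rejected."""
    df = pd.read_csv(path)
    _require_columns(df, _RECORD_COLS, path)
    dup = df["individual"][df["individual"].duplicated()]
    if len(dup):
        raise SchemaError(
            f"{path}: duplicate individual IDs {sorted(dup.unique())[:10]}"
        )
    if "sex" in df.columns:
        _check_levels(df, "sex", {"M", "F", "U"}, path)
    if not pd.api.types.is_numeric_dtype(df["d2hf"]):
        raise SchemaError(f"{path}: column 'd2hf' must be numeric (‰)")
    return df


def read_traits(path) -> pd.DataFrame:
    """Species trait table with closed forage/diet vocabularies."""
    df = pd.read_csv(path)
    _require_columns(df, _TRAIT_COLS, path)
    dup = df["species"][df["species"].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate species codes {sorted(dup.unique())}")
    _check_levels(df, "forage_substrate", FORAGE_LEVELS, path)
    _check_levels(df, "diet", DIET_LEVELS, path)
    return df


def read_stations(path) -> pd.DataFrame:
    """Station covariate table; wetland area must be non-negative."""
    df = pd.read_csv(path)
    _require_columns(df, _STATION_COLS, path)
    dup = df["station"][df["station"].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate station IDs {sorted(dup.unique())}")
    if (df["wetland_area"] < 0).any():
        rows = df.index[df["wetland_area"] < 0].tolist()
        raise SchemaError(f"{path}: negative wetland_area at rows {rows}")
    return df


def read_trees(path):
    """Newick tree sample, one tree per line."""
    trees = read_newick(Path(path))
    if not trees:
        raise SchemaError(f"{path}: no trees found")
    return trees
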