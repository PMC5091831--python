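"""Design matrices for the 16 candidate fixed-effect structures.

Structure ids follow the candidate table: 0 intercept-only; 1 species;
2 forage substrate (collapsed to ground vs non-ground); 3 diet; 4 nest
substrate; 5 land cover at the station point; 6 dominant land cover within
100 m; 7 wetland area (continuous, m²); 8 latitude (continuous, decimal
degrees); 9 body mass; 10 body mass + mass²; 11 sex; 12 ForSub × Diet;
13 ForSub × Land100m; 14 NestSub × Diet; 15 ForSub × Diet × NestSub — all
interaction structures include their main effects.

Factors are treatment-coded against the alphabetically first level observed
in the data. Interaction structures can produce empty or aliased cells
(e.g. no omnivorous aerial foragers); linearly dependent columns are dropped
by a rank-revealing QR so the resulting matrix always has full column rank.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_design", "FIXED_EFFECT_NAMES", "MissingCovariateError"]

FIXED_EFFECT_NAMES = {
    0: "Null Model",
    1: "Species",
    2: "ForSub",
    3: "Diet",
    4: "NestSub",
    5: "LandStation",
    6: "Land100m",
    7: "WetArea",
    8: "Latitude",
    9: "IndMass",
    10: "IndMass^2",
    11: "Sex",
    12: "ForSub x Diet",
    13: "ForSub x Habitat",
    14: "NestSub x Diet",
    15: "ForSub x Diet x NestSub",
}

#: Scale at which each structure acts (species / station / individual traits).
FIXED_EFFECT_SCALE = {
    0: "-", 1: "Species", 2: "Species", 3: "Species", 4: "Species",
    5: "Station", 6: "Station", 7: "Station", 8: "Station",
    9: "Individual", 10: "Individual", 11: "Individual",
    12: "Species", 13: "Species", 14: "Species", 15: "Species",
}

# which merged-table columns each structure needs
_REQUIRED = {
    0: [],
    1: ["species"],
    2: ["forage_class"],
    3: ["diet"],
    4: ["nest_substrate"],
    5: ["habitat_station"],
    6: ["habitat_100m"],
    7: ["wetland_area"],
    8: ["latitude"],
    9: ["mass"],
    10: ["mass"],
    11: ["sex"],
    12: ["forage_class", "diet"],
    13: ["forage_class", "habitat_100m"],
    14: ["nest_substrate", "diet"],
    15: ["forage_class", "diet", "nest_substrate"],
}


class MissingCovariateError(ValueError):
    """A covariate required by the fixed-effect structure is missing."""


def merge_covariates(
    records: pd.DataFrame,
    traits: pd.DataFrame | None,
    stations: pd.DataFrame | None,
) -> pd.DataFrame:
    """Join species traits and station covariates onto the record table."""
    df = records.copy()
    if traits is not None:
        trait_cols = ["species", "forage_substrate", "diet", "nest_substrate"]
        df = df.merge(traits[trait_cols], on="species", how="left", validate="m:1")
    if stations is not None:
        station_cols = [
            "station", "latitude", "longitude",
            "habitat_station", "habitat_100m", "wetland_area",
        ]
        df = df.merge(stations[station_cols], on="station", how="left", validate="m:1")
    if "forage_substrate" in df.columns:
        # candidate-table convention: ground vs non-ground foragers
        df["forage_class"] = np.where(
            df["forage_substrate"].astype("string") == "G", "ground", "nonground"
        )
        df.loc[df["forage_substrate"].isna(), "forage_class"] = np.nan
    return df


def _check_missing(df: pd.DataFrame, cols: list[str], fixed_effect_id: int) -> None:
    for col in cols:
        if col not in df.columns:
            raise MissingCovariateError(
                f"structure {fixed_effect_id} needs column {col!r}, "
                "which is absent after merging traits/stations"
            )
        bad = df.index[df[col].isna()]
        if len(bad):
            ids = df.loc[bad, "individual"] if "individual" in df.columns else bad
            raise MissingCovariateError(
                f"structure {fixed_effect_id}: column {col!r} missing for "
                f"records {list(ids[:10])}" + (" ..." if len(bad) > 10 else "")
            )


def _dummies(values: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded indicator columns against the first sorted level."""
    levels = sorted(values.dropna().unique())
    cols, labels = [], []
    for level in levels[1:]:
        cols.append((values == level).to_numpy(dtype=float))
        labels.append(f"{name}[{level}]")
    if not cols:
        return np.empty((len(values), 0)), []
    return np.column_stack(cols), labels


def _interact(
    blocks: list[tuple[np.ndarray, list[str]]]
) -> tuple[np.ndarray, list[str]]:
    """All products of one column from each block (k-way interaction)."""
    mat, labels = blocks[0]
    for other, other_labels in blocks[1:]:
        cols, new_labels = [], []
        for i, li in enumerate(labels):
            for j, lj in enumerate(other_labels):
                cols.append(mat[:, i] * other[:, j])
                new_labels.append(f"{li}:{lj}")
        mat = np.column_stack(cols) if cols else np.empty((mat.shape[0], 0))
        labels = new_labels
    return mat, labels


def _drop_dependent(X: np.ndarray, labels: list[str]) -> tuple[np.ndarray, list[str]]:
    """Keep a maximal linearly independent, non-constant-zero column subset."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    return X[:, keep], [labels[i] for i in keep]


def build_design(
    records: pd.DataFrame,
    traits: pd.DataFrame | None,
    stations: pd.DataFrame | None,
    fixed_effect_id: int,
) -> tuple[np.ndarray, list[str]]:
    """Build the design matrix (with intercept) for one candidate structure.

    Returns ``(X, labels)`` where X has full column rank. Raises
    :class:`MissingCovariateError` when a required covariate is absent,
    naming the offending records.
    """
    if fixed_effect_id not in _REQUIRED:
        raise ValueError(f"unknown fixed-effect structure: {fixed_effect_id}")
    df = merge_covariates(records, traits, stations)
    _check_missing(df, _REQUIRED[fixed_effect_id], fixed_effect_id)

    n = len(df)
    X_blocks: list[np.ndarray] = [np.ones((n, 1))]
    labels: list[str] = ["Intercept"]

    def add(mat: np.ndarray, labs: list[str]) -> None:
        if mat.shape[1]:
            X_blocks.append(mat)
            labels.extend(labs)

    fid = fixed_effect_id
    if fid == 0:
        pass
    elif fid == 1:
        add(*_dummies(df["species"], "species"))
    elif fid == 2:
        add(*_dummies(df["forage_class"], "forage"))
    elif fid == 3:
        add(*_dummies(df["diet"], "diet"))
    elif fid == 4:
        add(*_dummies(df["nest_substrate"], "nest"))
    elif fid == 5:
        add(*_dummies(df["habitat_station"], "land_station"))
    elif fid == 6:
        add(*_dummies(df["habitat_100m"], "land_100m"))
    elif fid == 7:
        add(df[["wetland_area"]].to_numpy(dtype=float), ["wetland_area"])
    elif fid == 8:
        add(df[["latitude"]].to_numpy(dtype=float), ["latitude"])
    elif fid == 9:
        add(df[["mass"]].to_numpy(dtype=float), ["mass"])
    elif fid == 10:
        m = df["mass"].to_numpy(dtype=float)
        add(np.column_stack([m, m**2]), ["mass", "mass^2"])
    elif fid == 11:
        add(*_dummies(df["sex"], "sex"))
    elif fid in (12, 13, 14, 15):
        parts = {
            12: [("forage_class", "forage"), ("diet", "diet")],
            13: [("forage_class", "forage"), ("habitat_100m", "land_100m")],
            14: [("nest_substrate", "nest"), ("diet", "diet")],
            15: [("forage_class", "forage"), ("diet", "diet"), ("nest_substrate", "nest")],
        }[fid]
        blocks = [_dummies(df[col], name) for col, name in parts]
        for mat, labs in blocks:
            add(mat, labs)
        # all 2-way (and 3-way) interaction products
        from itertools import combinations

        for order in range(2, len(blocks) + 1):
            for combo in combinations(blocks, order):
                add(*_interact(list(combo)))

    X = np.column_stack(X_blocks)
    X, labels = _drop_dependent(X, labels)
    return X, labels
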