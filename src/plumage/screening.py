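"""Pre-model data screening and the year × species ANOVA.

Screening keeps after-second-year (ASY) birds only, drops species sampled
below a minimum number of individuals, and drops species flagged as likely
non-local molters (feathers grown on the wintering grounds or during
migration, recognizable by feather δ²H well above the local range).
The flagging rule is operationalized as a configurable upper bound on the
species mean δ²H_f: a species is flagged when its mean lies strictly above
the bound. The default bound of −110‰ sits between the highest local
species mean (≈ −127‰) and the lowest mean among migratory-molt candidates
(≈ −97‰).

The year × species interaction is tested by a two-way fixed-effects ANOVA
with Type-II sums of squares (the design is unbalanced across species).
Species means are also compared against the prediction band of a
precipitation-to-feather transfer function (intercept + slope·δ²H_p ±
residual SD); the coefficients are supplied by configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ScreeningReport",
    "TransferFunction",
    "screen_records",
    "flag_nonlocal_molt",
    "year_species_anova",
    "predict_feather_band",
    "classify_species_mean",
    "DEFAULT_NONLOCAL_BAND",
]

#: (lower, upper) ‰ band of plausible locally grown feather means.
DEFAULT_NONLOCAL_BAND = (-170.0, -110.0)


@dataclass
class ScreeningReport:
    """Counts and per-species summaries from one screening pass."""

    n_input: int
    retained_records: int
    retained_species: list[str]
    excluded_species: dict[str, str]  # species -> reason
    species_stats: pd.DataFrame = field(repr=False)

    def to_json(self, path=None) -> str:
        payload = {
            "n_input": self.n_input,
            "retained_records": self.retained_records,
            "retained_species": self.retained_species,
            "excluded_species": self.excluded_species,
            "species_stats": self.species_stats.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        lines = [
            f"input records:    {self.n_input}",
            f"retained records: {self.retained_records}",
            f"retained species: {len(self.retained_species)} "
            f"({', '.join(self.retained_species)})",
        ]
        for sp, reason in sorted(self.excluded_species.items()):
            lines.append(f"excluded {sp}: {reason}")
        return "\n".join(lines)


def screen_records(
    records: pd.DataFrame,
    min_n: int = 9,
    exclusion_list=(),
) -> tuple[ScreeningReport, pd.DataFrame]:
    """Filter a record table to analysable species.

    Drops non-ASY records, species named in ``exclusion_list``, and species
    with fewer than ``min_n`` ASY individuals. Raises if nothing survives.
    Idempotent: screening the output again changes nothing.
    """
    n_input = len(records)
    excluded: dict[str, str] = {}
    df = records
    if "age" in df.columns:
        df = df[df["age"] == "ASY"]
    exclusion = set(exclusion_list)
    for sp in sorted(exclusion & set(df["species"])):
        excluded[sp] = "in exclusion list (non-local molt)"
    df = df[~df["species"].isin(exclusion)]
    counts = df.groupby("species").size()
    thin = counts[counts < min_n]
    for sp, c in thin.items():
        excluded[sp] = f"only {c} ASY individuals (< {min_n})"
    df = df[~df["species"].isin(set(thin.index))].copy()
    if df.empty:
        raise ValueError(
            "no records remain after screening "
            f"(min_n={min_n}, excluded={sorted(exclusion)})"
        )
    stats = (
        df.groupby("species")["d2hf"]
        .agg(n="size", mean="mean", sd="std")
        .reset_index()
        if "d2hf" in df.columns
        else pd.DataFrame({"species": sorted(df["species"].unique())})
    )
    report = ScreeningReport(
        n_input=n_input,
        retained_records=len(df),
        retained_species=sorted(df["species"].unique()),
        excluded_species=excluded,
        species_stats=stats,
    )
    return report, df.reset_index(drop=True)


def flag_nonlocal_molt(
    species_means, band: tuple[float, float] = DEFAULT_NONLOCAL_BAND
) -> list[str]:
    """Species whose mean δ²H_f lies strictly above the band's upper bound.

    Such feathers are too enriched to have been grown locally and point to
    molt on the wintering grounds or during migration. A mean exactly at
    the bound is not flagged (strict inequality).
    """
    if isinstance(species_means, pd.DataFrame):
        species_means = species_means.set_index("species")["mean"]
    means = pd.Series(species_means, dtype=float)
    upper = band[1]
    return sorted(means.index[means > upper])


def year_species_anova(records: pd.DataFrame) -> pd.DataFrame:
    """Two-way Year × Species ANOVA with interaction, Type-II SS.

    Requires exactly two year labels, at least two species, and at least
    two records per year × species cell. Returns a table with one row per
    effect plus a full-model row (overall regression F) and the residual
    row, since an unbalanced design makes the printed F of an external
    report ambiguous between the two.
    """
    df = records.copy()
    years = sorted(df["year"].unique())
    if len(years) != 2:
        raise ValueError(f"need exactly 2 year labels, got {years}")
    species = sorted(df["species"].unique())
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    cells = df.groupby(["year", "species"]).size()
    for yr in years:
        for sp in species:
            c = cells.get((yr, sp), 0)
            if c == 0:
                raise ValueError(f"empty design cell: year={yr}, species={sp}")
            if c < 2:
                raise ValueError(
                    f"design cell year={yr}, species={sp} has {c} record(s); "
                    "at least 2 are required"
                )
    model = smf.ols("d2hf ~ C(year) * C(species)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = table.reset_index().rename(
        columns={"index": "effect", "PR(>F)": "p", "F": "F", "df": "df"}
    )
    full = pd.DataFrame(
        [
            {
                "effect": "full_model",
                "sum_sq": model.ess,
                "df": model.df_model,
                "F": model.fvalue,
                "p": model.f_pvalue,
            }
        ]
    )
    out = pd.concat([out, full], ignore_index=True)
    return out


@dataclass(frozen=True)
class TransferFunction:
    """δ²H_p → δ²H_f regression: intercept + slope·δ²H_p ± residual SD."""

    intercept: float  # ‰
    slope: float
    resid_sd: float  # ‰
    label: str

    def __post_init__(self) -> None:
        if self.resid_sd <= 0:
            raise ValueError("residual SD must be > 0")

    def predict(self, d2hp: float) -> float:
        return self.intercept + self.slope * d2hp

    def band(self, d2hp: float) -> tuple[float, float]:
        point = self.predict(d2hp)
        return (point - self.resid_sd, point + self.resid_sd)


def predict_feather_band(
    d2hp: float, transfer_functions
) -> dict[str, tuple[float, float]]:
    """Predicted feather δ²H interval per transfer function at one δ²H_p."""
    funcs = list(transfer_functions)
    if not funcs:
        raise ValueError("no transfer functions configured")
    return {tf.label: tf.band(d2hp) for tf in funcs}


def classify_species_mean(mean: float, band: tuple[float, float]) -> str:
    """'local' when the species mean falls inside the predicted band."""
    lo, hi = band
    return "consistent with local molt" if lo <= mean <= hi else "outside predicted band"
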