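"""Synthetic data with the exact covariance structure the model assumes.

The generator inverts the fitted model: given true β, per-species σ_j, λ
and a species correlation matrix, individual δ²H_f values are drawn from
MVN(Xβ, Σ) with Σ built by the same covariance expansion the likelihood
uses. Trees are pure-birth (Yule) rescaled to unit depth — only the shared
path structure matters downstream. Sex, body mass and station are drawn
independently of the response unless the chosen fixed-effect structure puts
them in β, matching the null structure of non-selected covariates. An
optional per-species year offset shifts species means between two year
labels for the year × species experiment.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .design import build_design
from .estimators import expand_to_individuals
from .fixtures import (
    DIET_LEVELS,
    FORAGE_LEVELS,
    HABITAT_LEVELS,
    NEST_LEVELS,
    make_paper_fixture,
    make_synthetic_records,
)
from .phylo import PhyloCorrelation

__all__ = [
    "SimulationConfig",
    "simulate_tree_set",
    "simulate_dataset",
    "make_synthetic_traits",
    "make_synthetic_stations",
    "species_means_beta",
    "default_codes",
    "make_paper_fixture",
    "make_synthetic_records",
]


def default_codes(species_count: int) -> list[str]:
    """Placeholder 4-character species codes SP01, SP02, ..."""
    return [f"SP{i + 1:02d}" for i in range(species_count)]


@dataclass
class SimulationConfig:
    """True parameters of one simulated study.

    ``beta`` is keyed by design-column label for ``fixed_effect_id`` (e.g.
    ``{"Intercept": -145.0, "species[SP02]": 8.0}``); ``sigma`` is a single
    SD (‰) or one per species; ``lam`` is the off-diagonal multiplier in
    [0, 1]. ``year_offsets`` (optional, species code → ‰) shifts species
    means for records assigned to the second of ``years``. The seed fixes
    all randomness.
    """

    species_count: int
    n_per_species: int | list[int]
    beta: dict[str, float]
    sigma: float | list[float]
    lam: float
    fixed_effect_id: int = 1
    tree_count: int = 1
    seed: int = 0
    years: tuple[int, ...] = (2013,)
    year_offsets: dict[str, float] | None = None
    conspecific: str = "shared"

    def __post_init__(self) -> None:
        if self.species_count < 2:
            raise ValueError("species_count must be >= 2")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        sig = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(sig <= 0):
            raise ValueError("all sigma must be > 0")
        if sig.size not in (1, self.species_count):
            raise ValueError("sigma must be scalar or one per species")
        nps = self.n_counts
        if np.any(nps < 1):
            raise ValueError("n_per_species must be >= 1")
        if self.year_offsets is not None and len(self.years) != 2:
            raise ValueError("year_offsets requires exactly two year labels")

    @property
    def n_counts(self) -> np.ndarray:
        counts = np.atleast_1d(np.asarray(self.n_per_species, dtype=int))
        if counts.size == 1:
            counts = np.full(self.species_count, int(counts[0]))
        if counts.size != self.species_count:
            raise ValueError("n_per_species must be scalar or one per species")
        return counts

    @property
    def sigma_vector(self) -> np.ndarray:
        sig = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if sig.size == 1:
            sig = np.full(self.species_count, sig[0])
        return sig


def simulate_tree_set(
    species_count: int,
    tree_count: int,
    seed: int,
    labels: list[str] | None = None,
) -> list[dendropy.Tree]:
    """Sample pure-birth (Yule) trees rescaled to unit depth.

    Each tree carries exactly ``species_count`` leaves labelled by
    ``labels`` (default SP01...); topologies and branch lengths are drawn
    stochastically, and the whole sample is reproducible from the seed.
    """
    if species_count < 2:
        raise ValueError("species_count must be >= 2")
    if tree_count < 1:
        raise ValueError("tree_count must be >= 1")
    if labels is None:
        labels = default_codes(species_count)
    if len(labels) != species_count:
        raise ValueError("labels length must equal species_count")
    rng = _random.Random(seed)
    trees: list[dendropy.Tree] = []
    for _ in range(tree_count):
        tns = dendropy.TaxonNamespace(list(labels))
        tree = treesim.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=species_count,
            rng=rng,
            taxon_namespace=tns,
        )
        # randomize the label→tip assignment so topologies vary per label set
        leaves = list(tree.leaf_node_iter())
        taxa = list(tns)
        rng.shuffle(taxa)
        for leaf, taxon in zip(leaves, taxa):
            leaf.taxon = taxon
        # run the clock past the final birth event (memoryless continuation),
        # keeping the tree ultrametric; also gives the 2-taxon cherry depth
        extra = rng.expovariate(species_count * 1.0)
        for leaf in leaves:
            leaf.edge.length = (leaf.edge.length or 0.0) + extra
        _rescale_unit_depth(tree)
        trees.append(tree)
    return trees


def _rescale_unit_depth(tree: dendropy.Tree) -> None:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth


def make_synthetic_traits(codes: list[str], seed: int = 0) -> pd.DataFrame:
    """Random species trait table over the closed category sets."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "species": codes,
            "forage_substrate": rng.choice(FORAGE_LEVELS, size=len(codes)),
            "diet": rng.choice(DIET_LEVELS, size=len(codes)),
            "nest_substrate": rng.choice(NEST_LEVELS, size=len(codes)),
        }
    )


def make_synthetic_stations(n_stations: int = 8, seed: int = 0) -> pd.DataFrame:
    """Random station covariate table in the study's latitude band."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "station": np.arange(1, n_stations + 1),
            "latitude": np.round(rng.uniform(55.0, 57.5, n_stations), 3),
            "longitude": np.round(rng.uniform(-115.0, -110.7, n_stations), 3),
            "habitat_100m": rng.choice(HABITAT_LEVELS, size=n_stations),
            "habitat_station": rng.choice(HABITAT_LEVELS, size=n_stations),
            "wetland_area": rng.integers(0, 40, n_stations) * 625,
        }
    )


def species_means_beta(means: dict[str, float]) -> dict[str, float]:
    """Treatment-coded β for a species-means structure (fixed_effect_id 1).

    The intercept is the mean of the alphabetically first species; other
    species get contrast coefficients ``species[CODE]``.
    """
    codes = sorted(means)
    ref = codes[0]
    beta = {"Intercept": float(means[ref])}
    for code in codes[1:]:
        beta[f"species[{code}]"] = float(means[code] - means[ref])
    return beta


def simulate_dataset(
    config: SimulationConfig,
    traits: pd.DataFrame,
    stations: pd.DataFrame,
    correlation: PhyloCorrelation,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Draw an individual-level record table from MVN(Xβ, Σ).

    The covariance Σ comes from the same expansion the likelihood uses, so
    simulated data have exactly the model's assumed structure. With
    ``n_replicates > 1`` the covariate layout is drawn once and the
    response is redrawn per replicate (a ``replicate`` column is added);
    useful for distributional checks.
    """
    codes = list(correlation.species)
    if len(codes) != config.species_count:
        raise ValueError(
            f"correlation has {len(codes)} species, config expects "
            f"{config.species_count}"
        )
    missing = set(codes) - set(traits["species"])
    if missing:
        raise ValueError(f"traits table missing species: {sorted(missing)}")

    rng = np.random.default_rng(config.seed)
    n_counts = config.n_counts
    n = int(n_counts.sum())
    species_col = np.repeat(codes, n_counts)
    station_ids = stations["station"].to_numpy()
    years = np.asarray(config.years)

    records = pd.DataFrame(
        {
            "individual": [f"SIM{i + 1:05d}" for i in range(n)],
            "species": species_col,
            "station": rng.choice(station_ids, size=n),
            "year": rng.choice(years, size=n) if len(years) > 1 else years[0],
            "age": "ASY",
            "sex": rng.choice(["M", "F"], size=n),
            "mass": np.round(rng.normal(15.0, 2.5, size=n), 1),
        }
    )

    X, labels = build_design(records, traits, stations, config.fixed_effect_id)
    missing_cols = [lab for lab in labels if lab not in config.beta]
    if missing_cols:
        raise ValueError(
            f"config.beta missing coefficients for design columns: {missing_cols}"
        )
    beta_vec = np.array([config.beta[lab] for lab in labels])
    mean = X @ beta_vec
    if config.year_offsets is not None:
        second = records["year"].to_numpy() == config.years[1]
        offs = records["species"].map(config.year_offsets).fillna(0.0).to_numpy()
        mean = mean + np.where(second, offs, 0.0)

    species_index = np.array([codes.index(s) for s in species_col])
    cov = expand_to_individuals(
        correlation, config.lam, config.sigma_vector, species_index,
        conspecific=config.conspecific,
    ).values
    # eigendecomposition sampling: robust to the σ→0 and λ→1 PSD edge cases
    w, V = np.linalg.eigh(cov)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n_replicates, n))
    ys = mean + z @ root.T

    if n_replicates == 1:
        records["d2hf"] = ys[0]
        return records
    out = pd.concat([records] * n_replicates, ignore_index=True)
    out.insert(0, "replicate", np.repeat(np.arange(n_replicates), n))
    out["d2hf"] = ys.reshape(-1)
    return out
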