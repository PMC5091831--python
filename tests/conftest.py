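import numpy as np
import pandas as pd
import pytest

from plumage.phylo import correlation_from_trees, trees_from_string
from plumage.simulate import (
    SimulationConfig,
    make_synthetic_stations,
    make_synthetic_traits,
    simulate_dataset,
    simulate_tree_set,
)


@pytest.fixture(scope="session")
def worked_tree():
    """The hand-computable 3-taxon tree ((A:1,B:1):1,C:2)."""
    return trees_from_string("((A:1,B:1):1,C:2);")[0]


@pytest.fixture(scope="session")
def small_setup():
    """A 5-species correlation matrix with matching traits and stations."""
    trees = simulate_tree_set(5, 20, seed=2)
    corr = correlation_from_trees(trees)
    codes = list(corr.species)
    return {
        "corr": corr,
        "codes": codes,
        "traits": make_synthetic_traits(codes, seed=2),
        "stations": make_synthetic_stations(seed=2),
    }


@pytest.fixture()
def small_dataset(small_setup):
    """One simulated dataset on the 5-species setup (4 individuals each)."""
    cfg = SimulationConfig(
        species_count=5,
        n_per_species=4,
        beta={"Intercept": -145.0},
        fixed_effect_id=0,
        sigma=[5.0, 7.0, 9.0, 11.0, 13.0],
        lam=0.4,
        seed=7,
    )
    rec = simulate_dataset(
        cfg, small_setup["traits"], small_setup["stations"], small_setup["corr"]
    )
    return cfg, rec


def naive_mvn_loglik(y, mean, cov):
    """Dense-determinant MVN log-density: the brute-force oracle."""
    n = len(y)
    resid = np.asarray(y) - np.asarray(mean)
    sign, logdet = np.linalg.slogdet(cov)
    assert sign > 0
    return -0.5 * (
        n * np.log(2 * np.pi) + logdet + resid @ np.linalg.solve(cov, resid)
    )


@pytest.fixture(scope="session")
def records_toy():
    """Three species with n = (9, 8, 10) ASY records for screening tests."""
    rows = []
    for sp, n in (("AAAA", 9), ("BBBB", 8), ("CCCC", 10)):
        for i in range(n):
            rows.append(
                {
                    "individual": f"{sp}{i}",
                    "species": sp,
                    "station": 1,
                    "year": 2013,
                    "age": "ASY",
                    "sex": "M",
                    "mass": 15.0,
                    "d2hf": -140.0 + i,
                }
            )
    return pd.DataFrame(rows)
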