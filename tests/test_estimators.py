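"""Covariance expansion, exact likelihood, and the ML / data-cloning fits."""

import numpy as np
import pytest

from conftest import naive_mvn_loglik
from plumage.estimators import (
    DataCloningRegressor,
    FittedModel,
    ModelSpec,
    PhyloMVNRegressor,
    expand_to_individuals,
    fit_ml,
    loglik,
)
from plumage.phylo import correlation_from_tree
from plumage.simulate import (
    SimulationConfig,
    simulate_dataset,
    simulate_tree_set,
)
from plumage.phylo import correlation_from_trees


class TestExpandToIndividuals:
    def test_lambda_zero_is_diagonal(self, worked_tree):
        corr = correlation_from_tree(worked_tree)
        cov = expand_to_individuals(corr, 0.0, [1.0, 2.0, 3.0], [0, 0, 1, 2])
        np.testing.assert_allclose(
            cov.values, np.diag([1.0, 1.0, 4.0, 9.0]), atol=1e-14
        )

    def test_single_individuals_lambda_one_is_sigma2_C(self, worked_tree):
        corr = correlation_from_tree(worked_tree)
        cov = expand_to_individuals(corr, 1.0, 2.0, [0, 1, 2])
        np.testing.assert_allclose(cov.values, 4.0 * corr.values, atol=1e-14)

    def test_worked_tree_elementwise_oracle(self, worked_tree):
        """cov = σ_j σ_k t_jk λ evaluated entry by entry by brute force."""
        corr = correlation_from_tree(worked_tree)
        sigma = np.array([1.0, 2.0, 3.0])
        lam = 0.5
        species_index = np.array([0, 0, 1, 1, 2, 2])
        cov = expand_to_individuals(corr, lam, sigma, species_index).values
        t = corr.values
        for i in range(6):
            for j in range(6):
                si, sj = species_index[i], species_index[j]
                if i == j:
                    expected = sigma[si] ** 2
                else:
                    expected = sigma[si] * sigma[sj] * t[si, sj] * lam
                assert cov[i, j] == pytest.approx(expected, abs=1e-14)

    def test_conspecific_independent_switch(self, worked_tree):
        corr = correlation_from_tree(worked_tree)
        cov = expand_to_individuals(
            corr, 0.5, [1.0, 2.0, 3.0], [0, 0, 1, 2],
            conspecific="independent",
        ).values
        assert cov[0, 1] == 0.0  # conspecific pair decoupled
        assert cov[0, 2] == pytest.approx(0.5 * 1 * 2 * corr.values[0, 1])

    def test_invalid_inputs(self, worked_tree):
        corr = correlation_from_tree(worked_tree)
        with pytest.raises(ValueError):
            expand_to_individuals(corr, 1.5, 1.0, [0, 1, 2])
        with pytest.raises(ValueError):
            expand_to_individuals(corr, 0.5, [1.0, 2.0], [0, 1, 2])
        with pytest.raises(ValueError):
            expand_to_individuals(corr, 0.5, [1.0, -2.0, 3.0], [0, 1, 2])


class TestLoglik:
    def test_standard_normal_at_mean(self, worked_tree):
        corr = correlation_from_tree(worked_tree)
        X = np.ones((1, 1))
        val = loglik([3.0], X, [3.0], 1.0, 0.0, corr, [0])
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_lambda_zero_equals_sum_of_univariate_densities(self, worked_tree):
        corr = correlation_from_tree(worked_tree)
        rng = np.random.default_rng(0)
        y = rng.normal(-140, 8, size=6)
        sigma = np.array([5.0, 8.0, 11.0])
        idx = np.array([0, 0, 1, 1, 2, 2])
        X = np.ones((6, 1))
        val = loglik(y, X, [-140.0], sigma, 0.0, corr, idx)
        uni = sum(
            -0.5 * (np.log(2 * np.pi * sigma[s] ** 2) + (yi + 140.0) ** 2 / sigma[s] ** 2)
            for yi, s in zip(y, idx)
        )
        assert val == pytest.approx(uni, abs=1e-10)

    def test_agrees_with_dense_oracle(self, worked_tree):
        corr = correlation_from_tree(worked_tree)
        rng = np.random.default_rng(1)
        idx = np.array([0, 0, 1, 1, 2, 2])
        X = np.column_stack([np.ones(6), rng.normal(size=6)])
        for _ in range(5):
            beta = rng.normal(size=2)
            sigma = rng.uniform(1, 5, size=3)
            lam = rng.uniform(0, 1)
            y = rng.normal(size=6)
            ours = loglik(y, X, beta, sigma, lam, corr, idx)
            cov = expand_to_individuals(corr, lam, sigma, idx).values
            assert ours == pytest.approx(
                naive_mvn_loglik(y, X @ beta, cov), abs=1e-10
            )

    def test_record_permutation_invariance(self, worked_tree):
        corr = correlation_from_tree(worked_tree)
        rng = np.random.default_rng(2)
        idx = np.array([0, 0, 1, 1, 2, 2])
        y = rng.normal(size=6)
        X = np.ones((6, 1))
        base = loglik(y, X, [0.0], [1.0, 2.0, 3.0], 0.6, corr, idx)
        perm = rng.permutation(6)
        permuted = loglik(y[perm], X, [0.0], [1.0, 2.0, 3.0], 0.6, corr, idx[perm])
        assert permuted == pytest.approx(base, abs=1e-12)


class TestMLFit:
    def test_iid_closed_form(self, small_setup, small_dataset):
        """Intercept-only, hom σ, λ fixed 0 → sample mean and ML variance."""
        _, rec = small_dataset
        y = rec["d2hf"].to_numpy()
        est = PhyloMVNRegressor(
            small_setup["corr"], variance="hom", estimate_lambda=False, lam=0.0
        ).fit(np.ones((len(y), 1)), y, species=rec["species"].to_numpy())
        assert est.beta_[0] == pytest.approx(y.mean(), abs=1e-8)
        assert est.sigma_[0] ** 2 == pytest.approx(
            np.mean((y - y.mean()) ** 2), abs=1e-8
        )

    def test_grid_search_oracle_tiny_instance(self, worked_tree):
        """Maximized loglik within 1e-3 of a dense (σ, λ) grid search."""
        corr = correlation_from_tree(worked_tree)
        rng = np.random.default_rng(3)
        idx = np.array([0, 0, 1, 1, 2, 2])
        cov_true = expand_to_individuals(corr, 0.5, 8.0, idx).values
        y = -145.0 + np.linalg.cholesky(cov_true) @ rng.standard_normal(6)
        X = np.ones((6, 1))
        sp = np.array(corr.species)[idx]

        est = PhyloMVNRegressor(corr, variance="hom").fit(X, y, species=sp)

        best = -np.inf
        for sig in np.linspace(1.0, 20.0, 150):
            for lam in np.linspace(0.0, 0.999, 120):
                cov = expand_to_individuals(corr, lam, sig, idx).values
                cinv = np.linalg.inv(cov)
                beta = (X.T @ cinv @ y).item() / (X.T @ cinv @ X).item()
                ll = naive_mvn_loglik(y, beta * np.ones(6), cov)
                best = max(best, float(ll))
        assert est.loglik_ >= best - 1e-3
        assert abs(est.loglik_ - best) < 1e-2

    def test_pgls_limit_matches_direct_gls(self):
        """1 individual/species, hom σ, λ = 1 → textbook phylogenetic GLS."""
        trees = simulate_tree_set(8, 30, seed=6)
        corr = correlation_from_trees(trees)
        C = corr.values
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(8), rng.normal(size=8)])
        y = rng.normal(-140, 10, size=8)
        est = PhyloMVNRegressor(
            corr, variance="hom", estimate_lambda=False, lam=1.0
        ).fit(X, y, species=np.array(corr.species))
        cinv = np.linalg.inv(C)
        beta_gls = np.linalg.inv(X.T @ cinv @ X) @ X.T @ cinv @ y
        np.testing.assert_allclose(est.beta_, beta_gls, atol=1e-6)

    def test_nesting_of_maximized_likelihoods(self, small_setup):
        """Richer mean/variance structures cannot fit worse."""
        cfg = SimulationConfig(
            species_count=5, n_per_species=8, beta={"Intercept": -145.0},
            fixed_effect_id=0, sigma=[4.0, 6.0, 9.0, 13.0, 18.0], lam=0.3,
            seed=23,
        )
        rec = simulate_dataset(
            cfg, small_setup["traits"], small_setup["stations"],
            small_setup["corr"],
        )
        fits = {
            (fid, var): fit_ml(
                ModelSpec(fid, var), rec, small_setup["traits"],
                small_setup["stations"], small_setup["corr"], n_starts=2,
            )
            for fid in (2, 3, 12)
            for var in ("hom", "het")
        }
        tol = 1e-6
        for var in ("hom", "het"):
            assert fits[(12, var)].loglik >= fits[(2, var)].loglik - tol
            assert fits[(12, var)].loglik >= fits[(3, var)].loglik - tol
        for fid in (2, 3, 12):
            assert fits[(fid, "het")].loglik >= fits[(fid, "hom")].loglik - tol

    def test_bias_shrinks_with_per_species_sample_size(self):
        """λ̂ and σ̂ (known mean) approach truth as n/species grows."""
        S, lam_true, sig_true = 8, 0.6, 10.0
        trees = simulate_tree_set(S, 30, seed=8)
        corr = correlation_from_trees(trees)
        from plumage.simulate import make_synthetic_stations, make_synthetic_traits

        traits = make_synthetic_traits(list(corr.species), seed=8)
        stations = make_synthetic_stations(seed=8)
        bias = {}
        for n_per in (5, 50):
            lams, sigs = [], []
            for rep in range(10):
                cfg = SimulationConfig(
                    species_count=S, n_per_species=n_per,
                    beta={"Intercept": -145.0}, fixed_effect_id=0,
                    sigma=sig_true, lam=lam_true, seed=100 * n_per + rep,
                )
                rec = simulate_dataset(cfg, traits, stations, corr)
                y = rec["d2hf"].to_numpy() + 145.0
                est = PhyloMVNRegressor(corr, variance="hom", n_starts=2).fit(
                    np.empty((len(y), 0)), y, species=rec["species"].to_numpy()
                )
                lams.append(est.lam_)
                sigs.append(est.sigma_[0])
            bias[n_per] = (
                abs(np.mean(lams) - lam_true),
                abs(np.mean(sigs) - sig_true),
            )
        assert bias[50][0] <= bias[5][0] + 0.02
        assert bias[50][1] <= bias[5][1] + 0.05

    def test_fit_is_deterministic(self, small_setup, small_dataset):
        _, rec = small_dataset
        y = rec["d2hf"].to_numpy()
        X = np.ones((len(y), 1))
        sp = rec["species"].to_numpy()
        a = PhyloMVNRegressor(small_setup["corr"], variance="het", random_state=1).fit(X, y, species=sp)
        b = PhyloMVNRegressor(small_setup["corr"], variance="het", random_state=1).fit(X, y, species=sp)
        assert a.loglik_ == b.loglik_
        np.testing.assert_array_equal(a.sigma_, b.sigma_)

    def test_sklearn_param_interface(self, small_setup):
        est = PhyloMVNRegressor(small_setup["corr"], variance="het")
        params = est.get_params()
        assert params["variance"] == "het"
        est.set_params(n_starts=2)
        assert est.n_starts == 2


class TestFittedModel:
    def test_json_round_trip(self, small_setup, small_dataset):
        _, rec = small_dataset
        fit = fit_ml(
            ModelSpec(0, "hom"), rec, small_setup["traits"],
            small_setup["stations"], small_setup["corr"],
        )
        back = FittedModel.from_json(fit.to_json())
        assert back.spec == fit.spec
        assert back.loglik == pytest.approx(fit.loglik)
        assert back.k == fit.k and back.n == fit.n

    def test_k_counts_parameters(self, small_setup, small_dataset):
        _, rec = small_dataset
        hom = fit_ml(
            ModelSpec(0, "hom"), rec, small_setup["traits"],
            small_setup["stations"], small_setup["corr"],
        )
        het = fit_ml(
            ModelSpec(0, "het"), rec, small_setup["traits"],
            small_setup["stations"], small_setup["corr"],
        )
        assert hom.k == 1 + 1 + 1  # intercept + σ + λ
        assert het.k == 1 + 5 + 1  # intercept + σ_j per species + λ


class TestDataCloning:
    def test_same_seed_identical_chains(self, small_setup, small_dataset):
        _, rec = small_dataset
        y = rec["d2hf"].to_numpy()
        X = np.ones((len(y), 1))
        sp = rec["species"].to_numpy()
        kwargs = dict(
            variance="hom", n_clones=4, n_iter=2000, burn_in=500, random_state=9
        )
        a = DataCloningRegressor(small_setup["corr"], **kwargs).fit(X, y, species=sp)
        b = DataCloningRegressor(small_setup["corr"], **kwargs).fit(X, y, species=sp)
        assert a.lam_ == b.lam_
        np.testing.assert_array_equal(a.beta_, b.beta_)
        assert a.clone_variances_ == b.clone_variances_

    def test_mixing_diagnostics_reported(self, small_setup, small_dataset):
        _, rec = small_dataset
        y = rec["d2hf"].to_numpy()
        est = DataCloningRegressor(
            small_setup["corr"], variance="hom", n_clones=4,
            n_iter=3000, burn_in=1000, random_state=0,
        ).fit(np.ones((len(y), 1)), y, species=rec["species"].to_numpy())
        assert 0.0 < est.acceptance_rate_ < 1.0
        assert set(est.clone_variances_) == {"beta[0]", "log_sigma[0]", "logit_lam"}

    def test_invalid_clone_count(self, small_setup):
        with pytest.raises(ValueError):
            DataCloningRegressor(small_setup["corr"], n_clones=0).fit(
                np.ones((2, 1)), np.zeros(2), species=["SP01", "SP02"]
            )
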