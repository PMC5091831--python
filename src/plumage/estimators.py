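"""Phylogenetic multivariate-normal mixed models with per-species variances.

The response vector y stacks δ²H_f measurements over individuals. Fixed
effects enter the mean (Xβ); phylogeny and species enter the covariance:

    var(y_ij)          = σ_j²
    cov(y_ij, y_ik)    = σ_j σ_k t_jk λ        (j ≠ k, or distinct
                                                conspecific individuals)

where t_jk is the species correlation (shared evolutionary path length on a
unit-depth ultrametric tree; t_jj = 1) and λ ∈ [0, 1] is the Pagel
multiplier on the off-diagonal. With σ and the individual→species map this
expands to the n×n covariance Σ = D[(1−λ)I + λG]D, D = diag(σ_species(i)),
G the expanded correlation. The variance may be a single σ (homoscedastic)
or one σ_j per species (heteroscedastic).

Estimation is maximum likelihood: β is profiled by generalized least
squares at each (σ, λ); the remaining parameters are optimized on
(log σ, logit λ) by multi-start L-BFGS-B with analytic gradients. Under the
homoscedastic model σ is additionally profiled in closed form, leaving a
one-dimensional search over λ. A data-cloning estimator (random-walk
Metropolis on the K-fold cloned likelihood) is provided as an independent
cross-check of the optimizer: as K grows the cloned posterior concentrates
at the MLE and K × posterior variance approaches the asymptotic ML
variance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from sklearn.base import BaseEstimator, RegressorMixin

from .design import FIXED_EFFECT_NAMES, build_design
from .phylo import PhyloCorrelation
from .selection import aicc

__all__ = [
    "ModelSpec",
    "FittedModel",
    "CovarianceMatrix",
    "expand_to_individuals",
    "loglik",
    "PhyloMVNRegressor",
    "DataCloningRegressor",
    "fit_ml",
    "fit_dataclone",
]

_LOGIT_BOUND = 13.0  # λ confined to (~2e-6, 1-2e-6) during optimization


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return float(np.log(p / (1 - p)))


def _expit(z: np.ndarray | float):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass(frozen=True)
class ModelSpec:
    """One candidate: a fixed-effect structure × a variance structure."""

    fixed_effect_id: int
    variance: str = "hom"  # "hom" or "het"
    estimate_lambda: bool = True

    def __post_init__(self) -> None:
        if self.fixed_effect_id not in FIXED_EFFECT_NAMES:
            raise ValueError(f"unknown fixed-effect id {self.fixed_effect_id}")
        if self.variance not in ("hom", "het"):
            raise ValueError("variance must be 'hom' or 'het'")

    @property
    def label(self) -> str:
        prefix = "Het" if self.variance == "het" else "Hom"
        return f"{prefix}{self.fixed_effect_id}"

    @property
    def fixed_effects(self) -> str:
        return FIXED_EFFECT_NAMES[self.fixed_effect_id]


@dataclass
class FittedModel:
    """Maximum-likelihood fit of one candidate model."""

    spec: ModelSpec
    beta: np.ndarray
    beta_labels: list[str]
    sigma: np.ndarray  # per-species SDs (length S), or length 1 when hom
    lam: float
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    species_order: tuple[str, ...] = ()
    diagnostics: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "spec": asdict(self.spec),
            "label": self.spec.label,
            "beta": np.asarray(self.beta).tolist(),
            "beta_labels": list(self.beta_labels),
            "sigma": np.asarray(self.sigma).tolist(),
            "lam": self.lam,
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "aicc": self.aicc,
            "converged": self.converged,
            "species_order": list(self.species_order),
            "diagnostics": self.diagnostics,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        return cls(
            spec=ModelSpec(**d["spec"]),
            beta=np.asarray(d["beta"], dtype=float),
            beta_labels=list(d["beta_labels"]),
            sigma=np.asarray(d["sigma"], dtype=float),
            lam=float(d["lam"]),
            loglik=float(d["loglik"]),
            k=int(d["k"]),
            n=int(d["n"]),
            aicc=float(d["aicc"]),
            converged=bool(d["converged"]),
            species_order=tuple(d.get("species_order", ())),
            diagnostics=d.get("diagnostics", {}),
        )


@dataclass(frozen=True)
class CovarianceMatrix:
    """Individual-level covariance with its individual→species index map."""

    values: np.ndarray
    species_index: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _expanded_correlation(
    correlation: np.ndarray, species_index: np.ndarray, conspecific: str
) -> np.ndarray:
    """n×n unit-diagonal matrix G with G[i,i'] = t_{s(i)s(i')}.

    ``conspecific="shared"`` applies the covariance formula literally at
    j = k, so distinct conspecific individuals get off-diagonal t_jj = 1
    (hence covariance λσ_j²). ``conspecific="independent"`` zeroes the
    conspecific off-diagonal instead.
    """
    G = correlation[np.ix_(species_index, species_index)]
    if conspecific == "independent":
        same = species_index[:, None] == species_index[None, :]
        G = np.where(same, 0.0, G)
    elif conspecific != "shared":
        raise ValueError("conspecific must be 'shared' or 'independent'")
    np.fill_diagonal(G, 1.0)
    return G


def _sigma_per_individual(sigma, species_index: np.ndarray, n_species: int):
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    if sigma.size == 1:
        sigma = np.full(n_species, sigma[0])
    if sigma.size != n_species:
        raise ValueError(
            f"sigma has length {sigma.size}, expected 1 or {n_species}"
        )
    if np.any(sigma <= 0):
        raise ValueError("all sigma must be > 0")
    return sigma[species_index], sigma


def expand_to_individuals(
    correlation: PhyloCorrelation | np.ndarray,
    lam: float,
    sigma,
    species_index,
    conspecific: str = "shared",
) -> CovarianceMatrix:
    """Expand species-level correlation to the individual-level covariance.

    Entry for individuals of species j and k is σ_j σ_k t_jk λ off the
    diagonal (including distinct conspecific individuals, where t_jj = 1)
    and σ_j² on the diagonal.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = correlation.values if isinstance(correlation, PhyloCorrelation) else np.asarray(correlation, float)
    species_index = np.asarray(species_index, dtype=int)
    s_ind, _ = _sigma_per_individual(sigma, species_index, C.shape[0])
    G = _expanded_correlation(C, species_index, conspecific)
    n = len(species_index)
    A = lam * G + (1.0 - lam) * np.eye(n)
    cov = np.outer(s_ind, s_ind) * A
    min_eig = float(np.linalg.eigvalsh(cov)[0])
    if min_eig < -1e-8 * float(np.max(np.diag(cov))):
        raise FloatingPointError(
            f"expanded covariance is not PSD (min eigenvalue {min_eig:.3g})"
        )
    return CovarianceMatrix(cov, species_index)


def loglik(
    y,
    design,
    beta,
    sigma,
    lam,
    correlation: PhyloCorrelation | np.ndarray,
    species_index,
    conspecific: str = "shared",
) -> float:
    """Exact MVN log-density of y at mean Xβ, covariance from the model.

    Computed through a Cholesky factorization; raises on a singular
    covariance, naming the offending species block when identifiable.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    mean = X @ np.asarray(beta, dtype=float)
    cov = expand_to_individuals(correlation, lam, sigma, species_index, conspecific)
    return _mvn_loglik_chol(y - mean, cov.values, cov.species_index)


def _mvn_loglik_chol(resid: np.ndarray, cov: np.ndarray, species_index=None) -> float:
    try:
        c, low = cho_factor(cov, lower=True)
    except LinAlgError as exc:
        msg = "singular covariance matrix"
        if species_index is not None:
            counts = np.bincount(species_index)
            dup = np.nonzero(counts > 1)[0]
            if dup.size:
                msg += f" (species blocks with >1 individual: {dup.tolist()})"
        raise LinAlgError(msg) from exc
    alpha = cho_solve((c, low), resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    n = resid.size
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + float(resid @ alpha))


class PhyloMVNRegressor(RegressorMixin, BaseEstimator):
    """ML estimator for the phylogenetic MVN mixed model.

    Parameters
    ----------
    correlation : PhyloCorrelation
        Species-level correlation matrix; its species order defines the
        meaning of the ``species`` labels passed to :meth:`fit`.
    variance : {"hom", "het"}
        Single residual SD shared by all species, or one SD per species.
    estimate_lambda : bool
        Estimate the off-diagonal multiplier λ by ML; otherwise fix it at
        ``lam``.
    lam : float
        Fixed λ used when ``estimate_lambda=False``.
    conspecific : {"shared", "independent"}
        Whether distinct conspecific individuals share covariance λσ_j²
        (literal reading of the covariance formula, default) or are
        conditionally independent.
    n_starts : int
        Multi-start count for the quasi-Newton search; starts are
        stratified over λ and jittered in log σ.
    tol : float
        Convergence tolerance on the log-likelihood.
    random_state : int or None
        Seed for the start-point jitter, making fits reproducible.

    Fitted attributes (trailing underscore): ``beta_``, ``sigma_`` (per
    species), ``lam_``, ``loglik_``, ``k_``, ``n_``, ``aicc_``,
    ``converged_``.
    """

    def __init__(
        self,
        correlation: PhyloCorrelation,
        variance: str = "hom",
        estimate_lambda: bool = True,
        lam: float = 1.0,
        conspecific: str = "shared",
        n_starts: int = 4,
        tol: float = 1e-8,
        max_iter: int = 500,
        random_state: int | None = 0,
    ):
        self.correlation = correlation
        self.variance = variance
        self.estimate_lambda = estimate_lambda
        self.lam = lam
        self.conspecific = conspecific
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- shared setup -------------------------------------------------

    def _prepare(self, X, y, species):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent shapes")
        species = np.asarray(species)
        order = list(self.correlation.species)
        if species.dtype.kind in "iu":
            idx = species.astype(int)
            if idx.min() < 0 or idx.max() >= len(order):
                raise ValueError("species index out of range")
        else:
            lookup = {code: i for i, code in enumerate(order)}
            missing = sorted({s for s in species if s not in lookup})
            if missing:
                raise ValueError(f"species not in correlation matrix: {missing}")
            idx = np.array([lookup[s] for s in species], dtype=int)
        present = np.unique(idx)
        # restrict the correlation to the species actually observed
        sub_order = [order[i] for i in present]
        C = self.correlation.values[np.ix_(present, present)]
        remap = {old: new for new, old in enumerate(present)}
        idx = np.array([remap[i] for i in idx], dtype=int)
        if self.variance == "het":
            counts = np.bincount(idx, minlength=len(sub_order))
            if np.any(counts < 2):
                thin = [sub_order[i] for i in np.nonzero(counts < 2)[0]]
                warnings.warn(
                    "heteroscedastic variance with <2 individuals for "
                    f"species {thin}; their σ_j is weakly identified",
                    stacklevel=3,
                )
        G = _expanded_correlation(C, idx, self.conspecific)
        return X, y, idx, tuple(sub_order), C, G

    # -- likelihood machinery ------------------------------------------

    @staticmethod
    def _profile_beta(X, y, cov):
        """GLS β̂ and derived quantities at a fixed covariance."""
        c, low = cho_factor(cov, lower=True)
        W = cho_solve((c, low), np.column_stack([X, y]))
        Wx, wy = W[:, :-1], W[:, -1]
        if X.shape[1] == 0:  # known (pre-subtracted) mean: no free β
            beta = np.empty(0)
            resid = y
            alpha = wy
        else:
            xtsx = X.T @ Wx
            xtsy = X.T @ wy
            beta = np.linalg.solve(xtsx, xtsy)
            resid = y - X @ beta
            alpha = wy - Wx @ beta  # Σ^{-1} r
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        return beta, resid, alpha, logdet, (c, low)

    def _nll_het(self, theta, X, y, idx, G, n_species, counts):
        """Negative profiled loglik and gradient on (log σ_j..., [logit λ])."""
        log_sigma = theta[:n_species]
        if self.estimate_lambda:
            z = theta[n_species]
            lam = float(_expit(z))
        else:
            lam = float(self.lam)
        sigma = np.exp(np.clip(log_sigma, -20.0, 20.0))
        s_ind = sigma[idx]
        n = len(y)
        A = lam * G + (1.0 - lam) * np.eye(n)
        cov = np.outer(s_ind, s_ind) * A
        try:
            beta, resid, alpha, logdet, cf = self._profile_beta(X, y, cov)
        except (LinAlgError, np.linalg.LinAlgError):
            return 1e12, np.zeros_like(theta)
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet + float(resid @ alpha))
        grad = np.zeros_like(theta)
        ar = alpha * resid
        grad[:n_species] = -(np.bincount(idx, weights=ar, minlength=n_species) - counts)
        if self.estimate_lambda:
            Sinv = cho_solve(cf, np.eye(n))
            B = np.outer(s_ind, s_ind) * (G - np.eye(n))
            dl_dlam = -0.5 * float(np.sum(Sinv * B)) + 0.5 * float(alpha @ (B @ alpha))
            grad[n_species] = -dl_dlam * lam * (1.0 - lam)
        return -ll, grad

    def _nll_hom(self, theta, X, y, G):
        """Profile both β and σ²; optimize over logit λ alone."""
        z = theta[0]
        lam = float(_expit(z))
        n = len(y)
        V = lam * G + (1.0 - lam) * np.eye(n)
        try:
            beta, resid, alpha_v, logdetV, cf = self._profile_beta(X, y, V)
        except (LinAlgError, np.linalg.LinAlgError):
            return 1e12, np.zeros_like(theta)
        q = float(resid @ alpha_v)  # r' V^{-1} r
        sigma2 = q / n
        if sigma2 <= 0:
            return 1e12, np.zeros_like(theta)
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetV + n)
        Vinv = cho_solve(cf, np.eye(n))
        Bv = G - np.eye(n)
        # envelope: ∂ℓ/∂λ at profiled (β̂, σ̂²), Σ = σ̂² V
        tr_term = float(np.sum(Vinv * Bv))
        quad = float(alpha_v @ (Bv @ alpha_v))
        dl_dlam = -0.5 * tr_term + 0.5 * quad / sigma2
        grad = np.array([-dl_dlam * lam * (1.0 - lam)])
        return -ll, grad

    def _hom_closed_form(self, X, y, G, lam):
        n = len(y)
        V = lam * G + (1.0 - lam) * np.eye(n)
        beta, resid, alpha_v, logdetV, _ = self._profile_beta(X, y, V)
        sigma2 = float(resid @ alpha_v) / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetV + n)
        return beta, np.sqrt(sigma2), ll

    def _het_at_sigma(self, X, y, idx, G, sigma, lam):
        s_ind = sigma[idx]
        n = len(y)
        cov = np.outer(s_ind, s_ind) * (lam * G + (1.0 - lam) * np.eye(n))
        beta, resid, alpha, logdet, _ = self._profile_beta(X, y, cov)
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet + float(resid @ alpha))
        return beta, ll

    # -- fitting --------------------------------------------------------

    def fit(self, X, y, species=None):
        if species is None:
            raise ValueError("fit requires species labels (species=...)")
        X, y, idx, sub_order, C, G = self._prepare(X, y, species)
        n, p = X.shape
        n_species = len(sub_order)
        counts = np.bincount(idx, minlength=n_species).astype(float)
        rng = np.random.default_rng(self.random_state)

        # moment-based starting values: per-species ML SDs of OLS residuals
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        r_ols = y - X @ beta_ols
        ss = np.bincount(idx, weights=r_ols**2, minlength=n_species)
        pooled = max(float(np.sum(r_ols**2) / n), 1e-6)
        sd0 = np.sqrt(np.where(counts > 0, ss / np.maximum(counts, 1), pooled))
        sd0 = np.clip(sd0, np.sqrt(pooled) * 1e-2, None)

        lam_grid = [0.25, 0.6, 0.05, 0.9, 0.45, 0.75, 0.15, 0.35]
        best = None
        n_starts = max(1, int(self.n_starts)) if self.estimate_lambda else max(
            1, min(int(self.n_starts), 3)
        )
        for start in range(n_starts):
            if self.variance == "hom":
                if not self.estimate_lambda:
                    beta, sd, ll = self._hom_closed_form(X, y, G, float(self.lam))
                    cand = (ll, beta, np.full(n_species, sd), float(self.lam), True)
                else:
                    z0 = np.array([_logit(lam_grid[start % len(lam_grid)])])
                    res = optimize.minimize(
                        self._nll_hom, z0, args=(X, y, G), jac=True,
                        method="L-BFGS-B",
                        bounds=[(-_LOGIT_BOUND, _LOGIT_BOUND)],
                        options={"maxiter": self.max_iter, "ftol": self.tol,
                                 "gtol": 1e-10},
                    )
                    lam_hat = float(_expit(res.x[0]))
                    beta, sd, ll = self._hom_closed_form(X, y, G, lam_hat)
                    cand = (ll, beta, np.full(n_species, sd), lam_hat, res.success)
            else:
                log_sd = np.log(sd0)
                if start > 0:
                    log_sd = log_sd + rng.normal(0.0, 0.15, size=n_species)
                if self.estimate_lambda:
                    theta0 = np.concatenate(
                        [log_sd, [_logit(lam_grid[start % len(lam_grid)])]]
                    )
                    bounds = [(-20.0, 20.0)] * n_species + [
                        (-_LOGIT_BOUND, _LOGIT_BOUND)
                    ]
                else:
                    theta0 = log_sd
                    bounds = [(-20.0, 20.0)] * n_species
                res = optimize.minimize(
                    self._nll_het, theta0, args=(X, y, idx, G, n_species, counts),
                    jac=True, method="L-BFGS-B", bounds=bounds,
                    options={"maxiter": self.max_iter, "ftol": self.tol,
                             "gtol": 1e-10},
                )
                sigma_hat = np.exp(res.x[:n_species])
                lam_hat = (
                    float(_expit(res.x[n_species]))
                    if self.estimate_lambda else float(self.lam)
                )
                beta, ll = self._het_at_sigma(X, y, idx, G, sigma_hat, lam_hat)
                cand = (ll, beta, sigma_hat, lam_hat, res.success)
            if best is None or cand[0] > best[0]:
                best = cand

        assert best is not None
        ll, beta, sigma, lam_hat, success = best
        self.beta_ = np.asarray(beta, dtype=float)
        self.sigma_ = np.asarray(sigma, dtype=float)
        self.lam_ = float(lam_hat)
        self.loglik_ = float(ll)
        self.converged_ = bool(success and np.isfinite(ll))
        self.species_order_ = sub_order
        self.species_index_ = idx
        self.n_ = n
        self.n_features_in_ = p
        k = p + (n_species if self.variance == "het" else 1)
        if self.estimate_lambda:
            k += 1
        self.k_ = k
        self.aicc_ = aicc(self.loglik_, k, n) if n > k + 1 else float("nan")
        return self

    def predict(self, X):
        if not hasattr(self, "beta_"):
            raise AttributeError("estimator is not fitted")
        return np.asarray(X, dtype=float) @ self.beta_

    def covariance_(self) -> CovarianceMatrix:
        """Fitted individual-level covariance matrix."""
        sub = PhyloCorrelation(
            self.species_order_,
            self.correlation.reorder(list(self.species_order_)).values,
        )
        return expand_to_individuals(
            sub, self.lam_, self.sigma_, self.species_index_, self.conspecific
        )


class DataCloningRegressor(PhyloMVNRegressor):
    """Data-cloning ML estimator: Metropolis sampling of the K-cloned model.

    The likelihood of K identical copies of the data is K times the
    log-likelihood, so the cloned posterior concentrates around the MLE at
    rate 1/K; posterior means are reported as the ML estimates and
    K × posterior variance per parameter is reported as a diagnostic that
    must stabilize in K at the asymptotic ML variance.

    Extra fitted attributes: ``clone_variances_`` (dict of K-scaled
    posterior variances), ``acceptance_rate_``, ``mixing_ok_``.
    """

    def __init__(
        self,
        correlation: PhyloCorrelation,
        variance: str = "hom",
        estimate_lambda: bool = True,
        lam: float = 1.0,
        conspecific: str = "shared",
        n_clones: int = 16,
        n_iter: int = 8000,
        burn_in: int = 3000,
        prior_scale_beta: float = 1e3,
        random_state: int | None = 0,
    ):
        super().__init__(
            correlation=correlation,
            variance=variance,
            estimate_lambda=estimate_lambda,
            lam=lam,
            conspecific=conspecific,
            random_state=random_state,
        )
        self.n_clones = n_clones
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.prior_scale_beta = prior_scale_beta

    def _log_post(self, theta, X, y, idx, G, n_species, p, n):
        beta = theta[:p]
        log_sigma = theta[p : p + (n_species if self.variance == "het" else 1)]
        if self.estimate_lambda:
            lam = float(_expit(theta[-1]))
        else:
            lam = float(self.lam)
        sigma = np.exp(np.clip(log_sigma, -20, 20))
        if self.variance == "hom":
            s_ind = np.full(n, sigma[0])
        else:
            s_ind = sigma[idx]
        cov = np.outer(s_ind, s_ind) * (lam * G + (1 - lam) * np.eye(n))
        try:
            ll = _mvn_loglik_chol(y - X @ beta, cov)
        except (LinAlgError, np.linalg.LinAlgError):
            return -np.inf
        # proper but diffuse priors; their influence vanishes as K grows
        lp = -0.5 * float(beta @ beta) / self.prior_scale_beta**2
        lp += -0.5 * float(log_sigma @ log_sigma) / 10.0**2
        if self.estimate_lambda:
            lp += -0.5 * float(theta[-1] ** 2) / 4.0**2
        return self.n_clones * ll + lp

    def fit(self, X, y, species=None):
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        X, y, idx, sub_order, C, G = self._prepare(X, y, species)
        n, p = X.shape
        n_species = len(sub_order)
        n_sig = n_species if self.variance == "het" else 1
        rng = np.random.default_rng(self.random_state)

        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta0
        pooled = max(float(np.sum(r**2) / n), 1e-6)
        if self.variance == "het":
            counts = np.bincount(idx, minlength=n_species).astype(float)
            ss = np.bincount(idx, weights=r**2, minlength=n_species)
            log_sd0 = 0.5 * np.log(
                np.clip(np.where(counts > 0, ss / np.maximum(counts, 1), pooled),
                        pooled * 1e-4, None)
            )
        else:
            log_sd0 = np.array([0.5 * np.log(pooled)])
        theta = np.concatenate(
            [beta0, log_sd0, [0.0]] if self.estimate_lambda else [beta0, log_sd0]
        )
        dim = theta.size

        # random-walk Metropolis with global scale adaptation during burn-in
        base = np.concatenate(
            [
                np.full(p, max(np.sqrt(pooled), 1e-3)),
                np.full(n_sig, 0.3),
                [0.6] if self.estimate_lambda else [],
            ]
        ) / np.sqrt(self.n_clones)
        scale = 1.0
        lp = self._log_post(theta, X, y, idx, G, n_species, p, n)
        samples = np.empty((self.n_iter - self.burn_in, dim))
        accepted = 0
        window_acc = 0
        for it in range(self.n_iter):
            prop = theta + scale * base * rng.standard_normal(dim)
            lp_prop = self._log_post(prop, X, y, idx, G, n_species, p, n)
            if np.log(rng.random()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                accepted += 1
                window_acc += 1
            if it < self.burn_in and (it + 1) % 100 == 0:
                rate = window_acc / 100.0
                scale *= float(np.exp(1.2 * (rate - 0.3)))
                window_acc = 0
            if it >= self.burn_in:
                samples[it - self.burn_in] = theta

        acc_rate = accepted / self.n_iter
        beta_s = samples[:, :p]
        sigma_s = np.exp(samples[:, p : p + n_sig])
        lam_s = (
            _expit(samples[:, -1]) if self.estimate_lambda
            else np.full(len(samples), float(self.lam))
        )

        self.beta_ = beta_s.mean(axis=0)
        sigma_mean = sigma_s.mean(axis=0)
        self.sigma_ = (
            np.full(n_species, sigma_mean[0]) if self.variance == "hom" else sigma_mean
        )
        self.lam_ = float(lam_s.mean())
        self.species_order_ = sub_order
        self.species_index_ = idx
        self.n_ = n
        self.n_features_in_ = p
        k = p + n_sig + (1 if self.estimate_lambda else 0)
        self.k_ = k
        # loglik evaluated at the reported (posterior-mean) estimates
        s_ind = self.sigma_[idx]
        cov = np.outer(s_ind, s_ind) * (self.lam_ * G + (1 - self.lam_) * np.eye(n))
        self.loglik_ = _mvn_loglik_chol(y - X @ self.beta_, cov)
        self.aicc_ = aicc(self.loglik_, k, n) if n > k + 1 else float("nan")
        self.acceptance_rate_ = acc_rate
        self.mixing_ok_ = 0.05 <= acc_rate <= 0.8
        self.converged_ = bool(self.mixing_ok_)
        # K-scaled posterior variances on the sampling scale (β, log σ,
        # logit λ), where the cloned posterior is closest to Gaussian and
        # the 1/K shrinkage law is accurate at small K
        kvar = {
            f"beta[{i}]": self.n_clones * float(np.var(beta_s[:, i]))
            for i in range(p)
        }
        for i in range(n_sig):
            kvar[f"log_sigma[{i}]"] = self.n_clones * float(
                np.var(samples[:, p + i])
            )
        if self.estimate_lambda:
            kvar["logit_lam"] = self.n_clones * float(np.var(samples[:, -1]))
        self.clone_variances_ = kvar
        return self


# -- record-table wrappers (the module-level surface) ----------------------


def _assemble(spec, records, traits, stations, correlation):
    X, labels = build_design(records, traits, stations, spec.fixed_effect_id)
    y = records["d2hf"].to_numpy(dtype=float)
    species = records["species"].to_numpy()
    present = sorted(pd.unique(species))
    corr = correlation.reorder(present)
    return X, labels, y, species, corr


def fit_ml(
    spec: ModelSpec,
    records: pd.DataFrame,
    traits: pd.DataFrame | None,
    stations: pd.DataFrame | None,
    correlation: PhyloCorrelation,
    **estimator_kwargs,
) -> FittedModel:
    """Fit one candidate model by maximum likelihood on a record table."""
    X, labels, y, species, corr = _assemble(spec, records, traits, stations, correlation)
    est = PhyloMVNRegressor(
        correlation=corr,
        variance=spec.variance,
        estimate_lambda=spec.estimate_lambda,
        **estimator_kwargs,
    ).fit(X, y, species=species)
    return FittedModel(
        spec=spec,
        beta=est.beta_,
        beta_labels=labels,
        sigma=est.sigma_,
        lam=est.lam_,
        loglik=est.loglik_,
        k=est.k_,
        n=est.n_,
        aicc=est.aicc_,
        converged=est.converged_,
        species_order=est.species_order_,
    )


def fit_dataclone(
    spec: ModelSpec,
    records: pd.DataFrame,
    traits: pd.DataFrame | None,
    stations: pd.DataFrame | None,
    correlation: PhyloCorrelation,
    n_clones: int = 16,
    n_iter: int = 8000,
    burn_in: int = 3000,
    seed: int | None = 0,
) -> FittedModel:
    """Fit one candidate by data cloning (Metropolis on the cloned model)."""
    X, labels, y, species, corr = _assemble(spec, records, traits, stations, correlation)
    est = DataCloningRegressor(
        correlation=corr,
        variance=spec.variance,
        estimate_lambda=spec.estimate_lambda,
        n_clones=n_clones,
        n_iter=n_iter,
        burn_in=burn_in,
        random_state=seed,
    ).fit(X, y, species=species)
    return FittedModel(
        spec=spec,
        beta=est.beta_,
        beta_labels=labels,
        sigma=est.sigma_,
        lam=est.lam_,
        loglik=est.loglik_,
        k=est.k_,
        n=est.n_,
        aicc=est.aicc_,
        converged=est.converged_,
        species_order=est.species_order_,
        diagnostics={
            "acceptance_rate": est.acceptance_rate_,
            "mixing_ok": est.mixing_ok_,
            "clone_scaled_variances": est.clone_variances_,
            "n_clones": n_clones,
        },
    )
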