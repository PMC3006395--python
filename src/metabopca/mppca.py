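"""Mixtures of PPCA models (MPPCA): simultaneous clustering and dimension reduction.

With probability pi_g an observation follows a PPCA model with group-specific
loadings W_g and mean mu_g, so the marginal density is the finite mixture

    p(x_i) = sum_g pi_g N_p(x_i; mu_g, W_g W_g^T + sigma2 I),

the noise variance sigma2 being shared across groups for parsimony.  Fitting
uses the two-cycle AECM algorithm: the first cycle treats the group labels z
as the missing data and updates (pi, mu_g); the second treats (z, u) as
missing and updates (W_g, sigma2).  At convergence the posterior membership
probabilities z_hat cluster the observations by maximum a posteriori
assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .datasets import SpectralDataset
from .ppca import (
    ConvergenceWarning,
    FitOptions,
    FitResult,
    _aitken_converged,
    _gaussian_logpdf_rows,
    _map_sigma2,
    canonicalize_loadings,
    ppca_closed_form,
)

__all__ = [
    "MPPCAModel",
    "Responsibilities",
    "mixture_loglik",
    "responsibilities",
    "fit_mppca",
    "cross_tabulate",
]


class EmptyComponentError(RuntimeError):
    """A mixture component collapsed below the minimum supportable size."""


@dataclass
class MPPCAModel:
    """Mixture parameters: proportions ``pi``, per-group ``W_g``/``mu_g``, shared ``sigma2``."""

    pi: np.ndarray
    W: np.ndarray  # G x p x q
    mu: np.ndarray  # G x p
    sigma2: float

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.sigma2 = float(self.sigma2)
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.W.ndim != 3:
            raise ValueError("W must be G x p x q")
        if not (np.all(self.pi >= 0) and np.isclose(self.pi.sum(), 1.0)):
            raise ValueError("mixing proportions must be nonnegative and sum to 1")

    @property
    def G(self) -> int:
        return self.pi.shape[0]

    @property
    def p(self) -> int:
        return self.W.shape[1]

    @property
    def q(self) -> int:
        return self.W.shape[2]


@dataclass
class Responsibilities:
    """Posterior membership probabilities and the induced hard clustering."""

    z_hat: np.ndarray  # n x G, rows sum to 1
    labels: np.ndarray  # argmax per row (ties -> lowest group index)


def _component_logdens(model: MPPCAModel, X: np.ndarray) -> np.ndarray:
    """n x G matrix of log [pi_g N(x_i; mu_g, W_g W_g^T + sigma2 I)]."""
    parts = [
        np.log(model.pi[g]) + _gaussian_logpdf_rows(X - model.mu[g], model.W[g], model.sigma2)
        if model.pi[g] > 0
        else np.full(X.shape[0], -np.inf)
        for g in range(model.G)
    ]
    return np.column_stack(parts)


def mixture_loglik(model: MPPCAModel, data: SpectralDataset | np.ndarray) -> float:
    """Observed-data log-likelihood sum_i log sum_g pi_g N(x_i; mu_g, Sigma_g)."""
    X = data.values if isinstance(data, SpectralDataset) else np.asarray(data, dtype=float)
    if X.shape[1] != model.p:
        raise ValueError("dimension mismatch between data and model")
    return float(logsumexp(_component_logdens(model, X), axis=1).sum())


def responsibilities(model: MPPCAModel, data: SpectralDataset | np.ndarray) -> Responsibilities:
    """Posterior membership z_hat_ig, via Bayes' rule on the component densities."""
    X = data.values if isinstance(data, SpectralDataset) else np.asarray(data, dtype=float)
    logd = _component_logdens(model, X)
    if not np.all(np.isfinite(logsumexp(logd, axis=1))):
        raise ValueError("non-finite component density")
    z = np.exp(logd - logsumexp(logd, axis=1, keepdims=True))
    return Responsibilities(z_hat=z, labels=np.argmax(z, axis=1))


def _init_responsibilities(
    X: np.ndarray, G: int, init: str, rng: np.random.Generator
) -> np.ndarray:
    n = X.shape[0]
    if G == 1:
        return np.ones((n, 1))
    if init == "kmeans":
        km = KMeans(n_clusters=G, n_init=3, random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(X)
        z = np.full((n, G), 0.05 / max(G - 1, 1))
        z[np.arange(n), labels] = 0.95
    elif init == "random":
        z = rng.dirichlet(np.ones(G), size=n)
    else:
        raise ValueError(f"unknown init {init!r}")
    return z / z.sum(axis=1, keepdims=True)


def _aecm_single(
    X: np.ndarray,
    q: int,
    G: int,
    z: np.ndarray | None,
    opts: FitOptions,
    model0: MPPCAModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[MPPCAModel, list[float], bool, int]:
    """One AECM run from an initial responsibility matrix (or a warm-start model)."""
    n, p = X.shape
    Iq = np.eye(q)
    if model0 is not None:
        model = MPPCAModel(
            pi=model0.pi.copy(), W=model0.W.copy(), mu=model0.mu.copy(), sigma2=model0.sigma2
        )
    else:
        # initial parameters from the initial partition; per-group loadings come
        # from each group's own members (the pooled PCA directions mostly track
        # between-group separation, a poor start for within-group structure)
        rng = rng or np.random.default_rng()
        pi = z.sum(axis=0) / n
        mu = (z.T @ X) / z.sum(axis=0)[:, None]
        W = np.empty((G, p, q))
        hard = np.argmax(z, axis=1)
        pooled = ppca_closed_form(X, min(q, n - 2)) if min(q, n - 2) >= 1 else None
        sig_parts = []
        for g in range(G):
            members = X[hard == g] - mu[g]
            q_eff = min(q, members.shape[0] - 2)
            if q_eff >= 1:
                cf = ppca_closed_form(members, q_eff)
                Wg, s2g = cf.W, cf.sigma2
            else:
                Wg, s2g = pooled.W[:, :0], pooled.sigma2
                q_eff = 0
            W[g, :, :q_eff] = Wg
            if q_eff < q:
                # fill unsupported columns with small noise so EM can grow them
                scale = 0.01 * np.sqrt(max(s2g, 1e-6))
                W[g, :, q_eff:] = scale * rng.standard_normal((p, q - q_eff))
            sig_parts.append(s2g)
        # small-group closed forms underestimate sigma2 badly when n_g << p;
        # the pooled residual scale is a safer starting noise level
        s2_init = max(float(np.median(sig_parts)), pooled.sigma2 if pooled else 0.0)
        model = MPPCAModel(pi=pi, W=W, mu=mu, sigma2=max(s2_init, opts.sigma2_floor))

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        # --- cycle 1: missing data = z; update pi, mu_g
        logd = _component_logdens(model, X)
        ll = logsumexp(logd, axis=1)
        trace.append(float(ll.sum()))
        z = np.exp(logd - ll[:, None])
        n_g = z.sum(axis=0)
        if np.any(n_g < 2.0):
            raise EmptyComponentError(f"component with effective size {n_g.min():.2f}")
        model.pi = n_g / n
        model.mu = (z.T @ X) / n_g[:, None]
        # --- cycle 2: missing data = (z, u); update W_g, sigma2
        logd = _component_logdens(model, X)
        z = np.exp(logd - logsumexp(logd, axis=1, keepdims=True))
        n_g = z.sum(axis=0)
        if np.any(n_g < 2.0):
            raise EmptyComponentError(f"component with effective size {n_g.min():.2f}")
        rss = 0.0
        W_new = np.empty_like(model.W)
        for g in range(G):
            Wg = model.W[g]
            Mg = Wg.T @ Wg + model.sigma2 * Iq
            Mginv = np.linalg.inv(Mg)
            Xc = X - model.mu[g]
            Xi = (Xc @ Wg) @ Mginv  # n x q
            wXi = z[:, g : g + 1] * Xi
            Suu = n_g[g] * model.sigma2 * Mginv + Xi.T @ wXi
            A = Xc.T @ wXi  # p x q
            Wg_new = np.linalg.solve(Suu.T, A.T).T
            rss += (
                float(np.sum(z[:, g] * np.sum(Xc**2, axis=1)))
                - 2.0 * float(np.sum((Xc @ Wg_new) * wXi))
                + float(np.sum(Suu * (Wg_new.T @ Wg_new)))
            )
            W_new[g] = Wg_new
        model.W = W_new
        sigma2 = _map_sigma2(rss, n * p, opts.sigma2_prior)
        model.sigma2 = max(sigma2, opts.sigma2_floor)
        if _aitken_converged(trace, opts.tol):
            converged = True
            break
    trace.append(mixture_loglik(model, X))
    return model, trace, converged, it


def fit_mppca(
    data: SpectralDataset | np.ndarray, q: int, G: int, opts: FitOptions | None = None
) -> FitResult:
    """Fit an MPPCA model by AECM, returning the best of ``opts.n_starts`` starts.

    Initialization is k-means on the data by default (``init="random"`` draws
    Dirichlet responsibilities instead).  A start whose components collapse
    below two effective observations is abandoned and redrawn; the fit fails
    only if every start collapses repeatedly.
    """
    opts = opts or FitOptions()
    X = data.values if isinstance(data, SpectralDataset) else np.asarray(data, dtype=float)
    n, p = X.shape
    if G < 1:
        raise ValueError("G must be >= 1")
    if n < G:
        raise ValueError(f"cannot fit {G} groups to {n} samples")
    rng = np.random.default_rng(opts.seed)
    if opts.warm_start is not None:
        model, trace, converged, it = _aecm_single(
            X, q, G, None, opts, model0=opts.warm_start
        )
        for g in range(model.G):
            model.W[g], _ = canonicalize_loadings(model.W[g])
        return FitResult(
            model=model, loglik_trace=np.asarray(trace), converged=converged, n_iter=it
        )
    n_starts = 1 if G == 1 else opts.n_starts
    best: tuple[MPPCAModel, list[float], bool, int] | None = None
    attempts = 0
    max_attempts = max(4 * n_starts, 20)
    starts_done = 0
    while starts_done < n_starts and attempts < max_attempts:
        attempts += 1
        init = opts.init if opts.init in {"kmeans", "random"} else "kmeans"
        z0 = _init_responsibilities(X, G, init, rng)
        try:
            fitted = _aecm_single(X, q, G, z0, opts, rng=rng)
        except EmptyComponentError:
            continue
        starts_done += 1
        if best is None or fitted[1][-1] > best[1][-1]:
            best = fitted
    if best is None:
        raise EmptyComponentError(
            f"all {attempts} AECM starts collapsed to an empty component (G={G}, q={q})"
        )
    model, trace, converged, it = best
    if not converged:
        warnings.warn(f"AECM did not converge in {opts.max_iter} iterations", ConvergenceWarning)
    for g in range(model.G):
        model.W[g], _ = canonicalize_loadings(model.W[g])
    return FitResult(
        model=model,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
    )


def cross_tabulate(labels: np.ndarray, truth: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Contingency table of estimated clusters vs known classes, plus the ARI.

    Mirrors the usual cluster-validation summary: a perfect recovery gives a
    (permuted) diagonal table and adjusted Rand index 1.
    """
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape[0] != truth.shape[0]:
        raise ValueError("labels and truth must have equal length")
    table = pd.crosstab(
        pd.Series(labels, name="cluster"), pd.Series(truth, name="class")
    )
    ari = float(adjusted_rand_score(truth, labels))
    return table, ari
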