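"""Probabilistic principal components and covariates analysis (PPCCA).

PPCCA extends PPCA by letting subject covariates shift the latent-score
distribution: u_i ~ N_q(delta_i, I) with delta_i = alpha C_i, where C_i is
the (L+1)-vector (1, c_i1, ..., c_iL) and alpha a q x (L+1) regression
matrix.  Conditionally on u_i the spectrum is generated exactly as in PPCA,
so marginally

    x_i ~ N_p(W delta_i + mu, W W^T + sigma2 I)

and the latent posterior gains a covariate shift:

    u_i | x_i ~ N_q(M^-1 [W^T (x_i - mu) + sigma2 delta_i], sigma2 M^-1).

Row k of alpha is interpreted like a regression of latent dimension k on the
covariates: the intercept locates the scores, the slopes quantify how each
covariate moves subjects along that principal direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import CovariateTable, SpectralDataset
from .ppca import (
    ConvergenceWarning,
    FitOptions,
    FitResult,
    LatentPosterior,
    PPCAModel,
    _aitken_converged,
    _center,
    _map_sigma2,
    _posterior_ellipses,
    canonicalize_loadings,
    ppca_closed_form,
)

__all__ = ["PPCCAModel", "fit_ppcca", "latent_means", "ppcca_scores"]


@dataclass
class PPCCAModel(PPCAModel):
    """PPCA parameters plus the q x (L+1) covariate-regression matrix ``alpha``.

    ``covariate_scaling`` records the standardization (means/sds) the
    covariates were fitted under; scoring refuses covariates prepared with a
    different scaling, since alpha is only meaningful on that scale.
    """

    alpha: np.ndarray = None
    covariate_scaling: dict = None

    def __post_init__(self) -> None:
        super().__post_init__()
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        if self.alpha.shape[0] != self.q:
            raise ValueError("alpha must have one row per latent dimension")
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("alpha contains non-finite values")

    @property
    def L(self) -> int:
        return self.alpha.shape[1] - 1


def _check_scaling(model: PPCCAModel, covs: CovariateTable) -> None:
    sc = model.covariate_scaling or {}
    if "means" not in sc:
        raise ValueError("model carries no covariate scaling record; cannot score")
    if covs.L != model.L:
        raise ValueError(f"model expects {model.L} covariates, got {covs.L}")
    if not (
        np.allclose(sc["means"], covs.means)
        and np.allclose(sc["sds"], covs.sds)
        and bool(sc.get("standardize", True)) == covs.standardize
    ):
        raise ValueError(
            "covariates were standardized differently from the model's stored scaling"
        )


def latent_means(model: PPCCAModel, covs: CovariateTable) -> np.ndarray:
    """The latent prior means delta_i = alpha C_i, one row per sample."""
    _check_scaling(model, covs)
    return covs.design @ model.alpha.T


def fit_ppcca(
    data: SpectralDataset | np.ndarray,
    covs: CovariateTable,
    q: int,
    opts: FitOptions | None = None,
) -> FitResult:
    """Fit PPCCA by EM (expectation / conditional-maximization steps).

    The E-step computes the covariate-shifted posterior moments of u_i, and W
    and sigma2 follow the usual expected-complete-data (Q-function) updates.
    The alpha and mu updates instead maximize the observed likelihood directly
    (an ECME scheme): because Sigma^-1 W = W M^-1, the GLS regression of the
    spectra on the covariates through W has the closed form

        alpha = (W^T W)^-1 W^T (X - mu)^T C (C^T C)^-1,

    i.e. a least-squares regression of the data's projections onto the
    principal subspace.  A Q-based alpha step would move alpha by only
    O(sigma2) per iteration — prohibitively slow precisely in the low-noise
    regime spectral data live in — while the ECME step shares its fixed
    points, preserves monotonicity, and converges in tens of iterations.
    After convergence W is canonicalized to principal axes and alpha is
    rotated by the same orthogonal transform, leaving every delta_i invariant.
    """
    opts = opts or FitOptions()
    X = data.values if isinstance(data, SpectralDataset) else np.asarray(data, dtype=float)
    n, p = X.shape
    if covs.n != n:
        raise ValueError(f"covariate rows ({covs.n}) do not match samples ({n})")
    if not 1 <= q < min(n, p):
        raise ValueError(f"q={q} must satisfy 1 <= q < min(n, p) = {min(n, p)}")
    C = covs.design  # n x (L+1)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        warnings.warn("rank-deficient covariate design; alpha resolved by pseudoinverse")
    Cpinv = np.linalg.pinv(C)  # (L+1) x n

    if opts.warm_start is not None:
        m0 = opts.warm_start
        W = np.array(m0.W, dtype=float)
        mu = np.array(m0.mu, dtype=float)
        sigma2 = float(m0.sigma2)
        alpha = np.array(m0.alpha, dtype=float)
    else:
        if opts.init == "random":
            rng = np.random.default_rng(opts.seed)
            W = rng.standard_normal((p, q))
            mu = X.mean(axis=0)
            sigma2 = float(np.var(X - mu))
            scores0 = np.linalg.solve(W.T @ W + sigma2 * np.eye(q), ((X - mu) @ W).T).T
            alpha = (Cpinv @ scores0).T
        else:
            # moment-matched start: within the principal subspace the model says
            # scores t_i = B alpha C_i + N(0, B B^T + sigma2 I), so regressing the
            # PC scores on the design and factoring the residual covariance gives
            # near-MLE values of (W, alpha) that EM only has to polish
            start = ppca_closed_form(X, q)
            mu, sigma2 = start.mu, start.sigma2
            norms = np.linalg.norm(start.W, axis=0)
            Uq = start.W / np.where(norms > 0, norms, 1.0)
            T = (X - mu) @ Uq
            beta = (Cpinv @ T).T  # q x (L+1) regression of scores on design
            resid = T - C @ beta.T
            Omega = resid.T @ resid / n - sigma2 * np.eye(q)
            evals, evecs = np.linalg.eigh(0.5 * (Omega + Omega.T))
            B = evecs @ np.diag(np.sqrt(np.maximum(evals, 1e-8))) @ evecs.T
            W = Uq @ B
            alpha = np.linalg.solve(B, beta)
            mu = X.mean(axis=0) - (C @ alpha.T).mean(axis=0) @ W.T

    Iq = np.eye(q)
    trace: list[float] = []
    converged = False
    floored = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        M = W.T @ W + sigma2 * Iq
        Minv = np.linalg.inv(M)
        Delta = C @ alpha.T  # n x q
        Xc = X - mu
        trace.append(_ppcca_loglik(Xc, Delta, W, sigma2))
        # E-step moments at the current parameters
        Xi = (Xc @ W + sigma2 * Delta) @ Minv  # n x q posterior means
        Suu = n * sigma2 * Minv + Xi.T @ Xi  # sum_i E(u_i u_i^T)
        # Q-based CM-steps for W and sigma2
        W_new = np.linalg.solve(Suu.T, (Xc.T @ Xi).T).T  # (Xc^T Xi) Suu^-1
        rss = (
            float(np.sum(Xc**2))
            - 2.0 * float(np.sum((Xc @ W_new) * Xi))
            + float(np.sum(Suu * (W_new.T @ W_new)))
        )
        sigma2 = _map_sigma2(rss, n * p, opts.sigma2_prior)
        if sigma2 < opts.sigma2_floor:
            sigma2 = opts.sigma2_floor
            floored = True
        # ECME CM-step: given the subspace of W_new and sigma2, maximize the
        # observed likelihood exactly over (column scale, alpha, mu)
        W, alpha, mu = _subspace_cm_step(X, C, Cpinv, W_new, sigma2)
        if _aitken_converged(trace, opts.tol):
            converged = True
            break
    trace.append(_ppcca_loglik(X - mu, C @ alpha.T, W, sigma2))
    if not converged:
        warnings.warn(
            f"PPCCA EM did not converge in {opts.max_iter} iterations", ConvergenceWarning
        )
    W, R = canonicalize_loadings(W)
    alpha = R.T @ alpha  # delta_i = alpha C_i is invariant under (W R, R^T alpha)
    model = PPCCAModel(
        W=W,
        mu=mu,
        sigma2=sigma2,
        alpha=alpha,
        covariate_scaling={
            "means": np.array(covs.means),
            "sds": np.array(covs.sds),
            "standardize": covs.standardize,
        },
    )
    return FitResult(
        model=model,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
        sigma2_floored=floored,
    )


def _subspace_cm_step(
    X: np.ndarray,
    C: np.ndarray,
    Cpinv: np.ndarray,
    W: np.ndarray,
    sigma2: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact conditional maximizer of the observed likelihood within span(W).

    Writing W = Q B (Q orthonormal), the model restricted to the principal
    subspace says Q^T(x_i - mu) ~ N(B alpha C_i, B B^T + sigma2 I_q), an
    ordinary multivariate regression whose MLE is the least-squares
    coefficient beta = B alpha and the residual covariance; the MLE of the
    positive-semidefinite B B^T is the residual covariance minus sigma2,
    eigenvalue-clipped at zero.  EM alone approaches this solution at rate
    O(sigma2) per iteration — prohibitively slow in the low-noise regime
    spectral data live in — so this step replaces the crawl with its limit.
    """
    n, q = X.shape[0], W.shape[1]
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    Q = U  # p x q orthonormal basis of the principal subspace
    xbar = X.mean(axis=0)
    T = (X - xbar) @ Q  # n x q subspace scores
    beta = (Cpinv @ T).T  # q x (L+1), = B alpha
    R = T - C @ beta.T
    Omega = R.T @ R / n
    evals, evecs = np.linalg.eigh(0.5 * (Omega + Omega.T))
    core = np.sqrt(np.maximum(evals - sigma2, 1e-12))
    B = (evecs * core) @ evecs.T
    W_new = Q @ B
    alpha = np.linalg.lstsq(B, beta, rcond=None)[0]
    mu = xbar - W_new @ (alpha @ C.mean(axis=0))
    return W_new, alpha, mu


def _ppcca_loglik(Xc: np.ndarray, Delta: np.ndarray, W: np.ndarray, sigma2: float) -> float:
    """sum_i log N_p(x_i; W delta_i + mu, W W^T + sigma2 I), in q-space."""
    n, p = Xc.shape
    q = W.shape[1]
    D = Xc - Delta @ W.T
    M = W.T @ W + sigma2 * np.eye(q)
    sign, logdetM = np.linalg.slogdet(M)
    if sign <= 0:
        return -np.inf
    logdetC = (p - q) * np.log(sigma2) + logdetM
    DW = D @ W
    sol = np.linalg.solve(M, DW.T).T
    quad = (np.sum(D**2, axis=1) - np.sum(sol * DW, axis=1)) / sigma2
    return float(-0.5 * (n * (p * np.log(2.0 * np.pi) + logdetC) + quad.sum()))


def log_likelihood(model: PPCCAModel, data: SpectralDataset | np.ndarray, covs: CovariateTable) -> float:
    """Marginal PPCCA log-likelihood of ``data`` given covariates."""
    X = data.values if isinstance(data, SpectralDataset) else np.asarray(data, dtype=float)
    _check_scaling(model, covs)
    Delta = covs.design @ model.alpha.T
    return _ppcca_loglik(X - model.mu, Delta, model.W, model.sigma2)


def ppcca_scores(
    model: PPCCAModel,
    data: SpectralDataset | np.ndarray,
    covs: CovariateTable,
    level: float = 0.95,
    dims: tuple[int, int] = (0, 1),
) -> LatentPosterior:
    """Covariate-aware scores: the PPCCA latent posterior.

    E(u_i) = M^-1 [W^T (x_i - mu) + sigma2 delta_i] blends the spectrum with
    the subject's covariates; the posterior covariance sigma2 M^-1 is shared
    across samples exactly as in PPCA.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    X = data.values if isinstance(data, SpectralDataset) else np.asarray(data, dtype=float)
    _check_scaling(model, covs)
    Delta = covs.design @ model.alpha.T
    M = model.M
    means = np.linalg.solve(M, ((X - model.mu) @ model.W + model.sigma2 * Delta).T).T
    cov = model.sigma2 * np.linalg.inv(M)
    cov = 0.5 * (cov + cov.T)
    ellipses = _posterior_ellipses(means, cov, level, dims)
    return LatentPosterior(means=means, covariance=cov, level=level, ellipses=ellipses)
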