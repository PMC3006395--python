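"""Probabilistic PCA: closed-form MLE, EM fitting, likelihood, latent posterior.

The model for a p-vector x_i with a q-dimensional latent score u_i is

    x_i = W u_i + mu + eps_i,     u_i ~ N_q(0, I),   eps_i ~ N_p(0, sigma2 I),

so marginally x_i ~ N_p(mu, C) with C = W W^T + sigma2 I.  The maximum
likelihood W spans the conventional PCA subspace; here every fitted W is
canonicalized to the principal-axes form (columns = eigvec * sqrt(eigval -
sigma2), ordered by decreasing eigenvalue, sign fixed) so that loadings read
exactly like conventional PCA loadings.

All likelihood algebra works in the q-dimensional space through the matrix
M = W^T W + sigma2 I (Woodbury / matrix-determinant lemma); no dense p x p
covariance is ever formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datasets import SpectralDataset

__all__ = [
    "PPCAModel",
    "LatentPosterior",
    "FitOptions",
    "FitResult",
    "ppca_closed_form",
    "fit_ppca",
    "log_likelihood",
    "posterior_latent",
    "align_loadings",
    "canonicalize_loadings",
]

SIGMA2_FLOOR = 1e-10


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class PPCAModel:
    """Fitted PPCA parameters: loadings ``W`` (p x q), mean ``mu``, noise ``sigma2``."""

    W: np.ndarray
    mu: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = float(self.sigma2)
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.W.shape[0] != self.mu.shape[0]:
            raise ValueError("W row count must match mu length")

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def q(self) -> int:
        return self.W.shape[1]

    @property
    def M(self) -> np.ndarray:
        """The q x q matrix W^T W + sigma2 I governing the latent posterior."""
        return self.W.T @ self.W + self.sigma2 * np.eye(self.q)


@dataclass
class LatentPosterior:
    """Posterior of the latent scores: per-sample means and the shared covariance.

    ``ellipses`` holds, per sample, the centre / semi-axes / angle (radians) of
    the 2-D posterior set at the requested level in the first two latent
    dimensions (or the chosen pair); with q = 1 the "ellipse" degenerates to an
    interval half-width.
    """

    means: np.ndarray
    covariance: np.ndarray
    level: float
    ellipses: list[dict] = field(default_factory=list)


@dataclass
class FitOptions:
    """EM controls shared by every fitter in the package.

    ``tol`` is the Aitken-acceleration threshold |l_A - l|; ``init`` is
    ``"eigen"`` (closed-form start, deterministic) or ``"random"``.  When
    ``sigma2_prior`` is set (an inverse-gamma prior), the sigma2 M-step uses
    the posterior mode instead of the conditional MLE, giving the MAP fit used
    by the regularized BIC.
    """

    max_iter: int = 1000
    tol: float = 1e-4
    seed: int | None = None
    init: str = "eigen"
    sigma2_floor: float = SIGMA2_FLOOR
    sigma2_prior: object | None = None  # selection.Sigma2Prior
    n_starts: int = 10  # mixture fits only
    warm_start: object | None = None  # model to initialize from (jackknife)


@dataclass
class FitResult:
    model: object
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    bic: float | None = None
    modified_bic: float | None = None
    prop_var: float | None = None
    sigma2_floored: bool = False
    scores: np.ndarray | None = None

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _center(data: SpectralDataset | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = data.values if isinstance(data, SpectralDataset) else np.asarray(data, dtype=float)
    mu = X.mean(axis=0)
    return X - mu, mu


def _sample_eigs(Xc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of the (1/n divisor) sample covariance via thin SVD of Xc."""
    n = Xc.shape[0]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    return (s**2) / n, Vt.T


def ppca_closed_form(data: SpectralDataset | np.ndarray, q: int) -> PPCAModel:
    """Exact maximum-likelihood PPCA via the sample-covariance eigendecomposition.

    sigma2 is the mean of the p - q discarded eigenvalues (zeros included when
    n - 1 < p) and column k of W is eigvec_k * sqrt(eigval_k - sigma2).  Serves
    both as the default EM initializer and as the oracle the EM fit must match.
    """
    Xc, mu = _center(data)
    n, p = Xc.shape
    evals, evecs = _sample_eigs(Xc)
    rank = int(np.sum(evals > max(evals[0], 1.0) * 1e-12)) if evals.size else 0
    if not 1 <= q < min(n, p):
        raise ValueError(f"q={q} must satisfy 1 <= q < min(n, p) = {min(n, p)}")
    if q > rank:
        raise ValueError(f"q={q} exceeds the rank {rank} of the centered data")
    if not np.all(np.isfinite(evals)):
        raise ValueError("non-finite eigenvalues in sample covariance")
    # include the p - (n-1) structurally-zero eigenvalues in the noise average
    tail = np.concatenate([evals[q:], np.zeros(max(p - evals.size, 0))])
    sigma2 = float(max(tail.mean(), SIGMA2_FLOOR))
    scale = np.sqrt(np.maximum(evals[:q] - sigma2, 0.0))
    W = evecs[:, :q] * scale
    W = _fix_signs(W)
    return PPCAModel(W=W, mu=mu, sigma2=sigma2)


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def canonicalize_loadings(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate ``W`` to principal-axes form; return (W_canonical, R) with W_canonical = W R.

    EM converges to W R for an arbitrary orthogonal R; the SVD W = U L V^T
    yields the canonical representative U L (columns ordered by singular
    value, signs fixed), which matches the closed-form solution.
    """
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    Wc = U * s
    idx = np.argmax(np.abs(Wc), axis=0)
    signs = np.sign(Wc[idx, np.arange(Wc.shape[1])])
    signs[signs == 0] = 1.0
    return Wc * signs, Vt.T * signs


def _aitken_converged(trace: list[float], tol: float) -> bool:
    """Aitken's acceleration stopping rule on the log-likelihood sequence."""
    if len(trace) < 3:
        return False
    l0, l1, l2 = trace[-3], trace[-2], trace[-1]
    denom = l1 - l0
    if denom == 0:
        return True
    c = (l2 - l1) / denom
    if not np.isfinite(c) or c >= 1:
        return abs(l2 - l1) < tol
    l_inf = l1 + (l2 - l1) / (1.0 - c)
    return abs(l_inf - l2) < tol


def _map_sigma2(rss: float, weight: float, prior) -> float:
    """Posterior-mode sigma2 under an inverse-gamma(shape, scale) prior.

    ``weight`` is the total residual count (n*p for a single component);
    the conditional MLE rss/weight is recovered as the prior flattens.
    """
    if prior is None:
        return rss / weight
    return (rss / 2.0 + prior.scale) / (weight / 2.0 + prior.shape + 1.0)


def fit_ppca(data: SpectralDataset | np.ndarray, q: int, opts: FitOptions | None = None) -> FitResult:
    """Fit PPCA by EM with Aitken-accelerated convergence assessment.

    The mean has closed-form MLE mu = column mean and is held there; W and
    sigma2 follow the standard coupled updates driven by the latent posterior
    moments E(u_i) and E(u_i u_i^T).  The returned W is canonicalized to
    principal-axes form so it agrees with :func:`ppca_closed_form`.
    """
    opts = opts or FitOptions()
    Xc, mu = _center(data)
    n, p = Xc.shape
    if not 1 <= q < min(n, p):
        raise ValueError(f"q={q} must satisfy 1 <= q < min(n, p) = {min(n, p)}")
    trace_sq = float(np.sum(Xc**2))
    tr_S = trace_sq / n

    if opts.warm_start is not None:
        W = np.array(opts.warm_start.W, dtype=float)
        sigma2 = float(opts.warm_start.sigma2)
    elif opts.init == "random":
        rng = np.random.default_rng(opts.seed)
        W = rng.standard_normal((p, q))
        sigma2 = tr_S / p
    elif opts.init == "eigen":
        start = ppca_closed_form(Xc, q)
        W, sigma2 = start.W, start.sigma2
    else:
        raise ValueError(f"unknown init {opts.init!r}")

    floored = False
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        M = W.T @ W + sigma2 * np.eye(q)
        Minv = np.linalg.inv(M)
        XW = Xc @ W  # n x q
        SW = Xc.T @ XW / n  # p x q = S W
        trace.append(_loglik_from_parts(n, p, q, sigma2, M, tr_S, XW, Minv))
        # M-step: W_new = S W (sigma2 I + M^-1 W^T S W)^-1
        G = sigma2 * np.eye(q) + Minv @ (W.T @ SW)
        W_new = np.linalg.solve(G.T, SW.T).T
        rss = n * (tr_S - float(np.sum((SW @ Minv) * W_new)))
        sigma2 = _map_sigma2(rss, n * p, opts.sigma2_prior)
        if sigma2 < opts.sigma2_floor:
            sigma2 = opts.sigma2_floor
            floored = True
        W = W_new
        if _aitken_converged(trace, opts.tol):
            converged = True
            break
    M = W.T @ W + sigma2 * np.eye(q)
    trace.append(_loglik_from_parts(n, p, q, sigma2, M, tr_S, Xc @ W, np.linalg.inv(M)))
    if not converged:
        warnings.warn(
            f"PPCA EM did not converge in {opts.max_iter} iterations", ConvergenceWarning
        )
    Wc, _ = canonicalize_loadings(W)
    model = PPCAModel(W=Wc, mu=mu, sigma2=sigma2)
    return FitResult(
        model=model,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
        sigma2_floored=floored,
    )


def _loglik_from_parts(
    n: int,
    p: int,
    q: int,
    sigma2: float,
    M: np.ndarray,
    tr_S: float,
    XW: np.ndarray,
    Minv: np.ndarray,
) -> float:
    """Gaussian log-likelihood of centered data under C = W W^T + sigma2 I.

    Uses log|C| = (p-q) log sigma2 + log|M| and
    tr(C^-1 S) = (tr S - tr(M^-1 W^T S W)) / sigma2.
    """
    sign, logdetM = np.linalg.slogdet(M)
    if sign <= 0:
        return -np.inf
    logdetC = (p - q) * np.log(sigma2) + logdetM
    tr_WSW = float(np.sum((XW @ Minv) * XW)) / n
    tr_CinvS = (tr_S - tr_WSW) / sigma2
    return -0.5 * n * (p * np.log(2.0 * np.pi) + logdetC + tr_CinvS)


def log_likelihood(model: PPCAModel, data: SpectralDataset | np.ndarray) -> float:
    """Marginal log-likelihood sum_i log N_p(x_i; mu, W W^T + sigma2 I)."""
    X = data.values if isinstance(data, SpectralDataset) else np.asarray(data, dtype=float)
    if X.shape[1] != model.p:
        raise ValueError(f"data has {X.shape[1]} bins but model expects {model.p}")
    D = X - model.mu
    return _gaussian_loglik_lowrank(D, model.W, model.sigma2)


def _gaussian_loglik_lowrank(D: np.ndarray, W: np.ndarray, sigma2: float) -> float:
    """Sum of log N(d_i; 0, W W^T + sigma2 I) over rows of D, in q-space."""
    n, p = D.shape
    q = W.shape[1]
    M = W.T @ W + sigma2 * np.eye(q)
    sign, logdetM = np.linalg.slogdet(M)
    logdetC = (p - q) * np.log(sigma2) + logdetM
    DW = D @ W
    sol = np.linalg.solve(M, DW.T).T
    quad = (np.sum(D**2, axis=1) - np.sum(sol * DW, axis=1)) / sigma2
    return float(-0.5 * (n * (p * np.log(2.0 * np.pi) + logdetC) + quad.sum()))


def _gaussian_logpdf_rows(D: np.ndarray, W: np.ndarray, sigma2: float) -> np.ndarray:
    """Per-row log N(d_i; 0, W W^T + sigma2 I) (used by the mixture model)."""
    n, p = D.shape
    q = W.shape[1]
    M = W.T @ W + sigma2 * np.eye(q)
    sign, logdetM = np.linalg.slogdet(M)
    logdetC = (p - q) * np.log(sigma2) + logdetM
    DW = D @ W
    sol = np.linalg.solve(M, DW.T).T
    quad = (np.sum(D**2, axis=1) - np.sum(sol * DW, axis=1)) / sigma2
    return -0.5 * (p * np.log(2.0 * np.pi) + logdetC + quad)


def posterior_latent(
    model: PPCAModel,
    data: SpectralDataset | np.ndarray,
    level: float = 0.95,
    dims: tuple[int, int] = (0, 1),
) -> LatentPosterior:
    """Latent posterior p(u_i | x_i) = N_q(M^-1 W^T (x_i - mu), sigma2 M^-1).

    ``ellipses`` carries the per-sample boundary of the 2-D posterior set in
    latent dimensions ``dims`` at probability ``level`` (chi-square quantile on
    2 df), quantifying score uncertainty.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    X = data.values if isinstance(data, SpectralDataset) else np.asarray(data, dtype=float)
    D = X - model.mu
    M = model.M
    means = np.linalg.solve(M, (D @ model.W).T).T
    cov = model.sigma2 * np.linalg.inv(M)
    cov = 0.5 * (cov + cov.T)
    ellipses = _posterior_ellipses(means, cov, level, dims)
    return LatentPosterior(means=means, covariance=cov, level=level, ellipses=ellipses)


def _posterior_ellipses(
    means: np.ndarray, cov: np.ndarray, level: float, dims: tuple[int, int]
) -> list[dict]:
    q = cov.shape[0]
    if q == 1:
        half = float(np.sqrt(stats.chi2.ppf(level, 1) * cov[0, 0]))
        return [{"center": (float(m[0]),), "halfwidth": half} for m in means]
    a, b = dims
    if not (0 <= a < q and 0 <= b < q and a != b):
        raise ValueError(f"invalid latent dimension pair {dims} for q={q}")
    sub = cov[np.ix_([a, b], [a, b])]
    evals, evecs = np.linalg.eigh(sub)
    r = np.sqrt(stats.chi2.ppf(level, 2) * np.maximum(evals, 0.0))
    angle = float(np.arctan2(evecs[1, 1], evecs[0, 1]))  # major axis orientation
    return [
        {
            "center": (float(m[a]), float(m[b])),
            "semi_axes": (float(r[1]), float(r[0])),
            "angle": angle,
        }
        for m in means
    ]


def align_loadings(
    W: np.ndarray, reference: np.ndarray, sign_only: bool = False
) -> np.ndarray:
    """Resolve rotation/sign indeterminacy by aligning ``W`` to ``reference``.

    Returns W Q with Q the orthogonal Procrustes rotation minimizing
    ||W Q - reference||_F, or, with ``sign_only``, Q restricted to a diagonal
    of +-1 chosen per column.  Needed wherever loadings from different fits are
    compared entrywise (jackknife replicates, EM vs closed form).
    """
    W = np.asarray(W, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if W.shape != reference.shape:
        raise ValueError("shape mismatch between W and reference")
    if sign_only:
        signs = np.sign(np.sum(W * reference, axis=0))
        signs[signs == 0] = 1.0
        return W * signs
    cross = W.T @ reference
    if np.linalg.matrix_rank(cross) < cross.shape[0]:
        warnings.warn("rank-deficient cross-product; falling back to sign matching")
        return align_loadings(W, reference, sign_only=True)
    U, _, Vt = np.linalg.svd(cross)
    return W @ (U @ Vt)
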