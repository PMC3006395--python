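"""Synthetic datasets drawn from each generative model, with known ground truth.

Every generator is a pure function of its arguments (the seed included), and
returns both the data and a :class:`GroundTruth` record of the parameters it
was drawn from.  Two named fixtures emulate the shapes of the NMR studies the
package is aimed at: an 18 x 189 urine-like two-treatment-group dataset with
a handful of planted effect bins and a weight covariate acting on the second
latent dimension, and a 33 x 164 brain-like dataset with four well-separated
regions of origin.

Loadings matrices are built by orthonormalizing a Gaussian matrix and scaling
its columns to chosen norms, which gives exact control of the population
eigen-spectrum (eigenvalue k of W W^T + sigma2 I is norm_k^2 + sigma2) — the
property the model-selection tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import CovariateTable, SpectralDataset, make_covariate_table

__all__ = [
    "GroundTruth",
    "generate_ppca",
    "generate_ppcca",
    "generate_mppca",
    "generate_urine_like",
    "generate_brain_like",
]


@dataclass
class GroundTruth:
    """The generating parameters of a synthetic dataset."""

    kind: str
    W: np.ndarray | None = None
    mu: np.ndarray | None = None
    sigma2: float | None = None
    alpha: np.ndarray | None = None
    pi: np.ndarray | None = None
    group_labels: np.ndarray | None = None
    covariates: np.ndarray | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)


def _random_loadings(
    p: int, q: int, norms: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Orthonormal columns scaled to the requested norms, in canonical form.

    The result is already in principal-axes form (orthogonal columns ordered
    by decreasing norm, sign fixed), so fitted canonical loadings are directly
    comparable to it entrywise.
    """
    A = rng.standard_normal((p, q))
    Q, _ = np.linalg.qr(A)
    W = Q * np.asarray(norms, dtype=float)
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(q)])
    signs[signs == 0] = 1.0
    return W * signs


def _column_norms(q: int, sigma2: float, eigengap: float) -> np.ndarray:
    """Decreasing column norms; the smallest signal eigenvalue is ``eigengap``.

    The norms are fixed on the data scale (not tied to sigma2) so that the
    signal subspace survives the noiseless limit; at the default sigma2 = 1,
    ``eigengap`` reads directly as the signal-to-noise eigenvalue ratio.
    """
    return np.sqrt(eigengap * np.arange(q, 0, -1))


def _ids(n: int) -> list[str]:
    return [f"s{i + 1:03d}" for i in range(n)]


def _labels(p: int) -> list[str]:
    """ppm-style bin labels on a 0.04 grid, skipping the 4.0-6.0 water region."""
    labels: list[str] = []
    ppm = 0.30
    while len(labels) < p:
        if not 4.0 <= ppm <= 6.0:
            labels.append(f"{ppm:.2f}")
        ppm += 0.04
    return labels


def generate_ppca(
    n: int,
    p: int,
    q: int,
    sigma2: float = 1.0,
    eigengap: float = 10.0,
    seed: int | None = None,
) -> tuple[SpectralDataset, GroundTruth]:
    """Draw u_i ~ N_q(0, I), then x_i = W u_i + mu + eps_i with eps ~ N(0, sigma2 I)."""
    if n < 2 or p < 2 or not 1 <= q < p:
        raise ValueError("invalid dimensions")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    W = _random_loadings(p, q, _column_norms(q, sigma2, eigengap), rng)
    mu = rng.standard_normal(p)
    U = rng.standard_normal((n, q))
    X = U @ W.T + mu + np.sqrt(sigma2) * rng.standard_normal((n, p))
    data = SpectralDataset(X, _ids(n), _labels(p))
    truth = GroundTruth(kind="ppca", W=W, mu=mu, sigma2=sigma2, seed=seed, extra={"U": U})
    return data, truth


def generate_ppcca(
    n: int,
    p: int,
    q: int,
    L: int,
    alpha: np.ndarray,
    sigma2: float = 1.0,
    eigengap: float = 10.0,
    seed: int | None = None,
) -> tuple[SpectralDataset, CovariateTable, GroundTruth]:
    """PPCCA draw: covariates ~ N(0,1); u_i ~ N_q(alpha C_i, I); x as PPCA.

    The covariates are standard normal, hence standardized by construction,
    so ``alpha`` is interpreted on the same scale the fitters use.
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    if alpha.shape != (q, L + 1):
        raise ValueError(f"alpha must be q x (L+1) = {q} x {L + 1}, got {alpha.shape}")
    rng = np.random.default_rng(seed)
    W = _random_loadings(p, q, _column_norms(q, sigma2, eigengap), rng)
    mu = rng.standard_normal(p)
    Craw = rng.standard_normal((n, L))
    covs = make_covariate_table(Craw, [f"c{j + 1}" for j in range(L)], standardize=True)
    Delta = covs.design @ alpha.T
    U = Delta + rng.standard_normal((n, q))
    X = U @ W.T + mu + np.sqrt(sigma2) * rng.standard_normal((n, p))
    data = SpectralDataset(X, _ids(n), _labels(p))
    truth = GroundTruth(
        kind="ppcca", W=W, mu=mu, sigma2=sigma2, alpha=alpha,
        covariates=Craw, seed=seed, extra={"U": U},
    )
    return data, covs, truth


def _simplex_means(G: int, p: int, distance: float, rng: np.random.Generator) -> np.ndarray:
    """G means in R^p with all pairwise distances equal to ``distance``."""
    if G == 1:
        return np.zeros((1, p))
    V = np.eye(G) - 1.0 / G  # centered regular simplex in G-1 dims
    # pairwise distance of rows of V is sqrt(2); embed via random orthonormal map
    B = rng.standard_normal((p, G))
    Q, _ = np.linalg.qr(B)  # p x G, orthonormal columns
    return (distance / np.sqrt(2.0)) * V @ Q.T


def generate_mppca(
    n_per_group: tuple[int, ...],
    p: int,
    q: int,
    separation: float = 10.0,
    sigma2: float = 1.0,
    eigengap: float = 5.0,
    seed: int | None = None,
) -> tuple[SpectralDataset, GroundTruth]:
    """Mixture draw with equidistant group means and per-group random loadings.

    ``separation`` is the pairwise distance between group means in units of
    the noise standard deviation sqrt(sigma2).
    """
    n_per_group = tuple(int(m) for m in n_per_group)
    G = len(n_per_group)
    if G < 1:
        raise ValueError("need at least one group")
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    rng = np.random.default_rng(seed)
    mus = _simplex_means(G, p, separation * np.sqrt(sigma2), rng)
    norms = _column_norms(q, sigma2, eigengap)
    n = sum(n_per_group)
    X = np.empty((n, p))
    labels = np.empty(n, dtype=int)
    Ws = np.empty((G, p, q))
    row = 0
    for g, m in enumerate(n_per_group):
        Ws[g] = _random_loadings(p, q, norms, rng)
        U = rng.standard_normal((m, q))
        X[row : row + m] = U @ Ws[g].T + mus[g] + np.sqrt(sigma2) * rng.standard_normal((m, p))
        labels[row : row + m] = g
        row += m
    data = SpectralDataset(X, _ids(n), _labels(p))
    truth = GroundTruth(
        kind="mppca", W=Ws, mu=mus, sigma2=sigma2,
        pi=np.asarray(n_per_group) / n, group_labels=labels, seed=seed,
    )
    return data, truth


def generate_urine_like(
    seed: int | None = None,
    n_effect_bins: int = 17,
    treatment_gap: float = 6.0,
    weight_slope: float = 3.0,
) -> tuple[SpectralDataset, np.ndarray, CovariateTable, GroundTruth]:
    """An 18 x 189 two-treatment-group fixture with a weight covariate.

    Nine treated and nine control spectra over 189 bins.  The treatment
    effect is planted on the first latent dimension, which loads on
    ``n_effect_bins`` designated bins only; an animal-weight covariate drives
    the second latent dimension (slope ``weight_slope`` per standardized
    unit), which loads on a disjoint block of bins.  Intensities are
    exponentiated Gaussians — positive and mildly skewed like NMR bin data —
    so the linear-Gaussian model holds only approximately; this is a
    deliberate model-misspecification stressor.

    Returns (dataset, treatment labels, covariate table, ground truth); the
    ground truth lists the planted effect bins and the covariate-affected
    latent dimension.
    """
    n, p, q = 18, 189, 2
    sigma2 = 0.05
    rng = np.random.default_rng(seed)
    groups = np.repeat([0, 1], n // 2)
    weight_raw = 20.0 + 2.0 * rng.standard_normal(n)  # grams-scale body weights
    covs = make_covariate_table(weight_raw[:, None], ["weight"], standardize=True)
    c = covs.standardized[:, 0]

    effect_bins = rng.choice(p, size=n_effect_bins, replace=False)
    remaining = np.setdiff1d(np.arange(p), effect_bins)
    weight_bins = rng.choice(remaining, size=30, replace=False)
    W = np.zeros((p, q))
    W[effect_bins, 0] = rng.uniform(1.0, 2.0, size=n_effect_bins) * rng.choice(
        [-1.0, 1.0], size=n_effect_bins
    )
    W[weight_bins, 1] = rng.uniform(0.6, 1.0, size=30) * rng.choice([-1.0, 1.0], size=30)

    u1 = treatment_gap * (groups - 0.5) + rng.standard_normal(n)
    u2 = weight_slope * c + rng.standard_normal(n)
    U = np.column_stack([u1, u2])
    Z = U @ W.T + np.sqrt(sigma2) * rng.standard_normal((n, p))
    # positive, log-normal-ish intensities; the 0.05 scale keeps exp() nearly
    # affine so the planted linear structure survives in the fitted loadings
    X = np.exp(2.0 + 0.05 * Z)
    ids = [f"{'ctl' if g == 0 else 'trt'}{i + 1}" for i, g in enumerate(groups)]
    data = SpectralDataset(X, ids, _labels(p))
    truth = GroundTruth(
        kind="ppcca", W=W, mu=np.full(p, 2.0), sigma2=sigma2,
        alpha=np.array([[0.0, 0.0], [0.0, weight_slope]]),
        group_labels=groups, covariates=weight_raw[:, None], seed=seed,
        extra={
            "effect_bins": np.sort(effect_bins),
            "effect_bin_labels": [data.bin_labels[j] for j in np.sort(effect_bins)],
            "weight_bins": np.sort(weight_bins),
            "covariate_dimension": 2,
            "treatment_gap": treatment_gap,
        },
    )
    return data, groups, covs, truth


def generate_brain_like(
    seed: int | None = None, separation: float = 12.0
) -> tuple[SpectralDataset, GroundTruth]:
    """A 33 x 164 four-group fixture (8, 8, 9, 8 spectra per region).

    Emulates spectra from four tissue regions with strong between-region
    separation, the setting in which a mixture of PPCA models should recover
    the regions exactly while a single PPCA model obscures them.
    """
    return generate_mppca(
        (8, 8, 9, 8), p=164, q=2, separation=separation, sigma2=1.0, eigengap=5.0, seed=seed
    )
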