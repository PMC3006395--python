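"""BIC and MAP-regularized BIC model selection over q (and G for mixtures).

The criterion is BIC = 2 l - K ln(n), higher is better, with l the maximized
log-likelihood, K the number of free parameters and n the sample count.  In
spectral-bin data n << p, and the plain maximum-likelihood fit can drive
sigma2 towards zero for some q or G, leaving the BIC undefined or erratic.
The modified BIC therefore evaluates the likelihood at the maximum a
posteriori fit obtained by placing a conjugate inverse-gamma prior on sigma2
and replacing the sigma2 M-step with the posterior mode

    sigma2_MAP = (RSS/2 + scale) / (n p / 2 + shape + 1),

which keeps sigma2 away from zero, smooths the criterion, and coincides with
the plain BIC whenever singularities are absent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import log

import numpy as np
import pandas as pd

from .datasets import CovariateTable, SpectralDataset
from . import mppca as _mppca
from . import ppca as _ppca
from . import ppcca as _ppcca

__all__ = [
    "Sigma2Prior",
    "default_prior",
    "bic",
    "count_params",
    "modified_bic",
    "select_model",
    "proportion_variance",
]


@dataclass(frozen=True)
class Sigma2Prior:
    """Inverse-gamma prior on sigma2 (density ∝ sigma2^-(shape+1) exp(-scale/sigma2))."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not self.shape > 1:
            raise ValueError("prior shape must exceed 1 (finite prior mean)")
        if not self.scale > 0:
            raise ValueError("prior scale must be positive")


def default_prior(data: SpectralDataset | np.ndarray) -> Sigma2Prior:
    """Weakly informative default: shape 3, scale 2 * mean per-bin variance.

    The prior mode then sits at half the average bin variance — the scale the
    noise floor of centred spectral data typically lives on — while shape 3
    keeps the prior broad enough to wash out once n*p is moderately large.
    """
    X = data.values if isinstance(data, SpectralDataset) else np.asarray(data, dtype=float)
    vbar = float(np.var(X - X.mean(axis=0), axis=0).mean())
    return Sigma2Prior(shape=3.0, scale=2.0 * max(vbar, 1e-12))


def bic(loglik: float, K: int, n: int) -> float:
    """BIC = 2 l - K ln(n); the model with the highest value is preferred."""
    if n < 1 or K < 0:
        raise ValueError("need n >= 1 and K >= 0")
    if not np.isfinite(loglik):
        raise ValueError("log-likelihood must be finite")
    return 2.0 * loglik - K * log(n)


def count_params(
    kind: str, p: int, q: int, L: int = 0, G: int = 1, convention: str = "raw"
) -> int:
    """Free-parameter count K for each model family.

    ``raw`` counts every entry of the loadings (p*q per group) plus means and
    the shared noise variance; ``rotation-corrected`` subtracts the q(q-1)/2
    rotational redundancies of each loadings matrix.
    """
    if convention not in {"raw", "rotation-corrected"}:
        raise ValueError(f"unknown K convention {convention!r}")
    correction = q * (q - 1) // 2 if convention == "rotation-corrected" else 0
    if kind == "ppca":
        return p * q + p + 1 - correction
    if kind == "ppcca":
        return p * q + p + 1 + q * (L + 1) - correction
    if kind == "mppca":
        return (G - 1) + G * (p * q + p - correction) + 1
    raise ValueError(f"unknown model kind {kind!r}")


def _fit(kind, data, covs, q, G, opts):
    if kind == "ppca":
        return _ppca.fit_ppca(data, q, opts)
    if kind == "ppcca":
        if covs is None:
            raise ValueError("PPCCA selection requires covariates")
        return _ppcca.fit_ppcca(data, covs, q, opts)
    if kind == "mppca":
        return _mppca.fit_mppca(data, q, G, opts)
    raise ValueError(f"unknown model kind {kind!r}")


def modified_bic(
    data: SpectralDataset | np.ndarray,
    kind: str = "ppca",
    q: int = 1,
    G: int = 1,
    L: int = 0,
    prior: Sigma2Prior | None = None,
    opts: _ppca.FitOptions | None = None,
    covs: CovariateTable | None = None,
    convention: str = "raw",
) -> float:
    """2 l(theta_MAP) - K ln(n): the BIC evaluated at the MAP-sigma2 fit."""
    prior = prior or default_prior(data)
    opts = replace(opts or _ppca.FitOptions(), sigma2_prior=prior)
    X = data.values if isinstance(data, SpectralDataset) else np.asarray(data, dtype=float)
    n, p = X.shape
    fit = _fit(kind, data, covs, q, G, opts)
    K = count_params(kind, p, q, L=covs.L if covs is not None else L, G=G, convention=convention)
    return bic(fit.loglik, K, n)


def proportion_variance(data: SpectralDataset | np.ndarray, q: int) -> float:
    """Cumulative eigenvalue ratio: variance explained by the top q components."""
    Xc, _ = _ppca._center(data)
    n, p = Xc.shape
    evals, _ = _ppca._sample_eigs(Xc)
    evals = np.concatenate([evals, np.zeros(max(p - evals.size, 0))])
    pos = int(np.sum(evals > evals[0] * 1e-12))
    if q > pos:
        raise ValueError(f"q={q} exceeds the {pos} positive eigenvalues")
    if q >= pos:
        return 1.0
    return float(evals[:q].sum() / evals.sum())


def select_model(
    data: SpectralDataset | np.ndarray,
    covs: CovariateTable | None = None,
    kind: str = "ppca",
    q_range=range(1, 9),
    G_range=(1,),
    prior: Sigma2Prior | None = None,
    opts: _ppca.FitOptions | None = None,
    convention: str = "raw",
) -> pd.DataFrame:
    """Fit every (q, G) on the grid and tabulate BIC / modified BIC.

    Each cell is fitted twice: once at the MLE (plain BIC) and once warm-started
    from it with the MAP sigma2 update (modified BIC).  The returned table has
    one row per model with ``best_bic`` / ``best_modified`` flags; the modified
    BIC is the selection criterion of record.
    """
    prior = prior or default_prior(data)
    base_opts = opts or _ppca.FitOptions()
    X = data.values if isinstance(data, SpectralDataset) else np.asarray(data, dtype=float)
    n, p = X.shape
    rows = []
    for G in G_range:
        for q in q_range:
            row = {"model_kind": kind, "q": q, "G": G}
            try:
                ml_fit = _fit(kind, data, covs, q, G, replace(base_opts, sigma2_prior=None))
                map_opts = replace(base_opts, sigma2_prior=prior, warm_start=ml_fit.model)
                map_fit = _fit(kind, data, covs, q, G, map_opts)
                L = covs.L if (covs is not None and kind == "ppcca") else 0
                K = count_params(kind, p, q, L=L, G=G, convention=convention)
                row.update(
                    loglik=ml_fit.loglik,
                    K=K,
                    bic=bic(ml_fit.loglik, K, n) if not ml_fit.sigma2_floored else np.nan,
                    modified_bic=bic(map_fit.loglik, K, n),
                    prop_var=proportion_variance(data, q),
                    converged=bool(ml_fit.converged and map_fit.converged),
                    failed=False,
                )
            except (ValueError, _mppca.EmptyComponentError) as exc:
                row.update(
                    loglik=np.nan, K=np.nan, bic=np.nan, modified_bic=np.nan,
                    prop_var=np.nan, converged=False, failed=True, error=str(exc),
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    if table["modified_bic"].isna().all():
        raise RuntimeError("every model fit on the grid failed; see per-cell errors")
    table["best_bic"] = False
    table["best_modified"] = False
    if table["bic"].notna().any():
        table.loc[table["bic"].idxmax(), "best_bic"] = True
    table.loc[table["modified_bic"].idxmax(), "best_modified"] = True
    return table
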