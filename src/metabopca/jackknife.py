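"""Jackknife uncertainty for loadings and covariate effects, and downstream
bin selection.

Leave-one-out refits give per-parameter standard errors

    SE(w_jk) = sqrt( (n-1)/n * sum_i (w_jk^{-i} - wbar_jk)^2 ),

from which 95% confidence intervals (estimate +- 1.96 SE by default) flag
loadings that differ significantly from zero.  Because a loadings matrix is
identified only up to column signs (and, in principle, rotation), every
leave-one-out W is aligned to the full-data W before the SEs are pooled;
without this step the SEs are inflated by arbitrary sign flips rather than
sampling variability.

The module also provides the workflow that turns significant loadings into a
sparse marker list: an absolute-loading frequency/retention curve to choose a
cutoff, and per-bin Welch t-tests with Benjamini-Hochberg correction to test
group differences on the selected bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import CovariateTable, SpectralDataset
from .ppca import FitOptions, FitResult, align_loadings, fit_ppca
from .ppcca import PPCCAModel, fit_ppcca

__all__ = [
    "JackknifeResult",
    "jackknife_se",
    "jackknife_model",
    "significant_loadings",
    "cutoff_frequency",
    "group_bin_tests",
]


@dataclass
class JackknifeResult:
    """Per-loading jackknife SEs, confidence intervals and significance flags.

    ``alpha_*`` fields are populated only for PPCCA fits, giving the same
    treatment to the covariate-regression parameters.
    """

    estimate: np.ndarray  # p x q full-data loadings
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray  # CI excludes zero
    bin_labels: list[str]
    level: float
    n_refits: int
    n_excluded: int = 0
    alpha_estimate: np.ndarray | None = None
    alpha_se: np.ndarray | None = None
    alpha_ci_low: np.ndarray | None = None
    alpha_ci_high: np.ndarray | None = None
    alpha_significant: np.ndarray | None = None

    def loadings_table(self) -> pd.DataFrame:
        """Long-format loadings table (bin, PC, loading, se, ci, significant)."""
        p, q = self.estimate.shape
        rows = []
        for k in range(q):
            for j in range(p):
                rows.append(
                    {
                        "bin_label": self.bin_labels[j],
                        "pc": k + 1,
                        "loading": self.estimate[j, k],
                        "se": self.se[j, k],
                        "ci_low": self.ci_low[j, k],
                        "ci_high": self.ci_high[j, k],
                        "significant": bool(self.significant[j, k]),
                    }
                )
        return pd.DataFrame(rows)


def jackknife_se(leave_one_out_values: np.ndarray, axis: int = 0) -> np.ndarray | float:
    """SE = sqrt((n-1)/n * sum_i (v_i - vbar)^2) over the leave-one-out axis.

    For n = 2 this reduces algebraically to |a - b| / 2.
    """
    v = np.asarray(leave_one_out_values, dtype=float)
    n = v.shape[axis]
    if n < 2:
        raise ValueError("jackknife needs at least 2 leave-one-out values")
    if not np.all(np.isfinite(v)):
        raise ValueError("leave-one-out values must be finite")
    centered = v - v.mean(axis=axis, keepdims=True)
    out = np.sqrt((n - 1) / n * np.sum(centered**2, axis=axis))
    return float(out) if np.ndim(out) == 0 else out


def _z_crit(level: float, df: int, use_t: bool) -> float:
    tail = 0.5 + level / 2.0
    return float(stats.t.ppf(tail, df)) if use_t else float(stats.norm.ppf(tail))


def jackknife_model(
    data: SpectralDataset,
    q: int,
    full_fit: FitResult,
    covs: CovariateTable | None = None,
    opts: FitOptions | None = None,
    align: str = "sign",
    level: float = 0.95,
    ci: str = "normal",
    warm: bool = True,
) -> JackknifeResult:
    """Jackknife SEs/CIs for a fitted PPCA or PPCCA model.

    Each of the n refits drops one observation and is warm-started at the
    full-data estimates (which cuts the EM iteration count dramatically); its
    loadings are aligned to the full-data W (per-column sign matching by
    default, ``align="procrustes"`` for a full rotation) before the SE
    formula is applied.  For PPCCA the sign flips are propagated to the alpha
    rows so the covariate effects stay in the full-data parameterization.
    """
    if data.n < 3:
        raise ValueError("jackknife needs at least 3 samples")
    if not full_fit.converged:
        raise ValueError("refusing to jackknife around a non-converged fit")
    if align not in {"sign", "procrustes"}:
        raise ValueError(f"unknown alignment {align!r}")
    opts = opts or FitOptions()
    model = full_fit.model
    is_ppcca = isinstance(model, PPCCAModel)
    if is_ppcca and covs is None:
        raise ValueError("PPCCA jackknife requires the covariate table")
    n = data.n
    refit_opts = replace(opts, warm_start=model if warm else None)
    W_stack = np.empty((n, model.p, q))
    A_stack = np.empty((n, q, covs.L + 1)) if is_ppcca else None
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sub = data.subset(mask)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if is_ppcca:
                    fit_i = fit_ppcca(sub, covs.subset(mask), q, refit_opts)
                else:
                    fit_i = fit_ppca(sub, q, refit_opts)
        except (np.linalg.LinAlgError, ValueError):
            keep[i] = False
            continue
        if not fit_i.converged:
            keep[i] = False
            continue
        W_i = fit_i.model.W
        if align == "sign":
            signs = np.sign(np.sum(W_i * model.W, axis=0))
            signs[signs == 0] = 1.0
            W_i = W_i * signs
            if is_ppcca:
                A_stack[i] = signs[:, None] * fit_i.model.alpha
        else:
            W_i = align_loadings(W_i, model.W)
            if is_ppcca:
                # recover the applied rotation to carry alpha along
                Q = np.linalg.lstsq(fit_i.model.W, W_i, rcond=None)[0]
                A_stack[i] = Q.T @ fit_i.model.alpha
        W_stack[i] = W_i
    n_bad = int(np.sum(~keep))
    if n_bad > 0:
        if n_bad > 0.05 * n:
            raise RuntimeError(
                f"{n_bad}/{n} leave-one-out refits failed to converge; aborting jackknife"
            )
        warnings.warn(f"excluding {n_bad}/{n} non-converged leave-one-out refits")
    W_kept = W_stack[keep]
    se = jackknife_se(W_kept, axis=0)
    crit = _z_crit(level, n - 1, ci == "jackknife-t")
    ci_low = model.W - crit * se
    ci_high = model.W + crit * se
    significant = (ci_low > 0) | (ci_high < 0)
    result = JackknifeResult(
        estimate=model.W.copy(),
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        significant=significant,
        bin_labels=list(data.bin_labels),
        level=level,
        n_refits=int(np.sum(keep)),
        n_excluded=n_bad,
    )
    if is_ppcca:
        A_kept = A_stack[keep]
        a_se = jackknife_se(A_kept, axis=0)
        result.alpha_estimate = model.alpha.copy()
        result.alpha_se = a_se
        result.alpha_ci_low = model.alpha - crit * a_se
        result.alpha_ci_high = model.alpha + crit * a_se
        result.alpha_significant = (result.alpha_ci_low > 0) | (result.alpha_ci_high < 0)
    return result


def significant_loadings(
    jk: JackknifeResult, pc: int, cutoff: float = 0.0
) -> list[tuple[str, float, tuple[float, float]]]:
    """Bins on principal component ``pc`` whose CI excludes 0 and |loading| > cutoff.

    Returned as (bin_label, loading, (ci_low, ci_high)) sorted by decreasing
    |loading| — the sparse marker list of the loading-selection workflow.
    """
    q = jk.estimate.shape[1]
    if not 1 <= pc <= q:
        raise ValueError(f"pc must be in 1..{q}")
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    k = pc - 1
    rows = [
        (jk.bin_labels[j], float(jk.estimate[j, k]), (float(jk.ci_low[j, k]), float(jk.ci_high[j, k])))
        for j in range(jk.estimate.shape[0])
        if jk.significant[j, k] and abs(jk.estimate[j, k]) > cutoff
    ]
    rows.sort(key=lambda r: abs(r[1]), reverse=True)
    return rows


def cutoff_frequency(
    estimates: np.ndarray, significant: np.ndarray, n_bins: int = 20
) -> pd.DataFrame:
    """Histogram of |loading| over significant bins plus the retention curve.

    The retention column counts how many significant bins survive each
    candidate threshold; a steep drop while loading values stay flat marks a
    natural cutoff.  No cutoff is chosen automatically — the table informs the
    analyst's choice.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    estimates = np.asarray(estimates, dtype=float)
    significant = np.asarray(significant, dtype=bool)
    vals = np.abs(estimates[significant])
    if vals.size == 0:
        warnings.warn("no significant bins; cutoff table is empty")
        return pd.DataFrame(columns=["threshold", "count", "retained"])
    counts, edges = np.histogram(vals, bins=n_bins)
    thresholds = edges[:-1]
    retained = np.array([(vals > t).sum() for t in thresholds])
    return pd.DataFrame({"threshold": thresholds, "count": counts, "retained": retained})


def group_bin_tests(
    data: SpectralDataset,
    groups: np.ndarray,
    bins: list[str] | np.ndarray | None = None,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Welch two-sample t-tests per bin with multiplicity correction.

    ``groups`` is a binary label vector over samples; ``bins`` selects the
    bins to test (labels or indices; all bins by default).  The adjusted
    p-values are corrected across exactly the listed bins, and ``direction``
    is the sign of (group2 mean - group1 mean).
    """
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {levels.size}")
    m0 = groups == levels[0]
    m1 = groups == levels[1]
    if m0.sum() < 2 or m1.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    if bins is None:
        idx = np.arange(data.p)
    elif len(bins) and isinstance(bins[0], (str, np.str_)):
        lookup = {b: j for j, b in enumerate(data.bin_labels)}
        idx = np.array([lookup[b] for b in bins])
    else:
        idx = np.asarray(bins, dtype=int)
    X = data.values
    rows = []
    for j in idx:
        a, b = X[m0, j], X[m1, j]
        if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
            t, pval = 0.0, 1.0
        else:
            t, pval = stats.ttest_ind(b, a, equal_var=False)
        diff = float(b.mean() - a.mean())
        rows.append(
            {
                "bin_label": data.bin_labels[j],
                "t": float(t),
                "p": float(pval),
                "direction": int(np.sign(diff)),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p"].to_numpy(), method=adjust)[1]
    return table[["bin_label", "t", "p", "p_adjusted", "direction"]]
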