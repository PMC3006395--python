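"""Spectral-bin matrices and covariate tables: reading, validation, preprocessing.

The central container is :class:`SpectralDataset`, an ``n x p`` matrix of
bin intensities (rows = spectra/samples, columns = spectral-bin regions
labelled by their ppm centre).  Covariates live in :class:`CovariateTable`,
whose ``design`` matrix carries a leading intercept column.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDataset",
    "CovariateTable",
    "read_spectra",
    "write_spectra",
    "read_covariates",
    "make_covariate_table",
    "preprocess",
]


class DataValidationError(ValueError):
    """Raised when an input table violates the dataset contract."""


@dataclass
class SpectralDataset:
    """An ``n x p`` spectral-bin intensity matrix with row/column labels.

    Parameters
    ----------
    values
        Real matrix of bin intensities, one row per spectrum.
    sample_ids
        ``n`` unique sample identifiers.
    bin_labels
        ``p`` unique bin labels (conventionally the ppm centre, e.g. ``"3.30"``).
    preprocessing
        Record of centering/scaling already applied to ``values``.
    """

    values: np.ndarray
    sample_ids: list[str]
    bin_labels: list[str]
    preprocessing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.bin_labels = [str(b) for b in self.bin_labels]
        if self.values.ndim != 2:
            raise DataValidationError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise DataValidationError(f"need at least 2 samples and 2 bins, got {n} x {p}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DataValidationError(
                f"non-finite value at sample {self.sample_ids[i]!r}, bin {self.bin_labels[j]!r}"
            )
        if len(self.sample_ids) != n:
            raise DataValidationError("sample_ids length does not match row count")
        if len(self.bin_labels) != p:
            raise DataValidationError("bin_labels length does not match column count")
        if len(set(self.sample_ids)) != n:
            dup = _first_duplicate(self.sample_ids)
            raise DataValidationError(f"duplicate sample ID {dup!r}")
        if len(set(self.bin_labels)) != p:
            dup = _first_duplicate(self.bin_labels)
            raise DataValidationError(f"duplicate bin label {dup!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.bin_labels)

    def subset(self, rows: np.ndarray) -> "SpectralDataset":
        """Row subset (boolean mask or integer index array), preprocessing kept."""
        rows = np.asarray(rows)
        idx = np.flatnonzero(rows) if rows.dtype == bool else rows
        return SpectralDataset(
            self.values[idx],
            [self.sample_ids[i] for i in idx],
            list(self.bin_labels),
            dict(self.preprocessing),
        )


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    raise AssertionError("no duplicate present")


@dataclass
class CovariateTable:
    """Subject covariates matched to the rows of a :class:`SpectralDataset`.

    ``design`` is the ``n x (L+1)`` regression design matrix with a leading
    intercept column of ones followed by the (optionally standardized)
    covariates.  The standardization constants are retained so that new
    samples can be scored on the scale the model was fitted on.
    """

    raw: np.ndarray
    names: list[str]
    standardized: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    standardize: bool = True

    def __post_init__(self) -> None:
        self.raw = np.atleast_2d(np.asarray(self.raw, dtype=float))
        self.standardized = np.atleast_2d(np.asarray(self.standardized, dtype=float))
        if self.raw.shape != self.standardized.shape:
            raise DataValidationError("raw and standardized covariates differ in shape")
        if self.raw.shape[1] != len(self.names):
            raise DataValidationError("covariate name count does not match column count")
        if not np.all(np.isfinite(self.raw)):
            raise DataValidationError("covariates contain non-finite values")

    @property
    def n(self) -> int:
        return self.raw.shape[0]

    @property
    def L(self) -> int:
        return self.raw.shape[1]

    @property
    def design(self) -> np.ndarray:
        return np.column_stack([np.ones(self.n), self.standardized])

    def rescale(self, raw: np.ndarray) -> np.ndarray:
        """Standardize new raw covariates with the stored means/sds."""
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        if not self.standardize:
            return raw.copy()
        return (raw - self.means) / self.sds

    def subset(self, rows: np.ndarray) -> "CovariateTable":
        """Row subset keeping the full-table standardization constants."""
        rows = np.asarray(rows)
        idx = np.flatnonzero(rows) if rows.dtype == bool else rows
        return CovariateTable(
            self.raw[idx],
            list(self.names),
            self.standardized[idx],
            self.means,
            self.sds,
            self.standardize,
        )


def make_covariate_table(
    raw: np.ndarray, names: list[str] | None = None, standardize: bool = True
) -> CovariateTable:
    """Build a :class:`CovariateTable`, standardizing columns to mean 0 / sd 1.

    A constant column has sd 0; it is centred only (yielding an all-zero
    standardized column) rather than producing a divide-by-zero, so that a
    degenerate covariate reduces the downstream model to its covariate-free
    form.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.shape[0] == 1 and raw.shape[1] > 1 and names is not None and len(names) == 1:
        raw = raw.T
    n, L = raw.shape
    if names is None:
        names = [f"c{j + 1}" for j in range(L)]
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=1) if n > 1 else np.ones(L)
    sds = np.where(sds > 0, sds, 1.0)
    standardized = (raw - means) / sds if standardize else raw.copy()
    return CovariateTable(raw, list(names), standardized, means, sds, standardize)


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_spectra(path: str | Path, delimiter: str | None = None) -> SpectralDataset:
    """Read a spectral-bin matrix from CSV/TSV.

    The first row must hold bin labels, the first column sample IDs, and
    every body cell must be numeric; a non-numeric cell is reported by its
    sample and bin rather than silently coerced.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectral matrix not found: {path}")
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DataValidationError(f"duplicate sample ID {dup!r} in {path.name}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        cells = df[col].to_numpy()
        for i, cell in enumerate(cells):
            try:
                v = float(cell)  # correctly-rounded parse, unlike pd.to_numeric
            except (TypeError, ValueError):
                v = np.nan
            if not np.isfinite(v):
                raise DataValidationError(
                    f"non-numeric cell at sample {df.index[i]!r}, bin {col!r} in {path.name}"
                )
            values[i, j] = v
    return SpectralDataset(values, list(df.index), list(df.columns))


def write_spectra(data: SpectralDataset, path: str | Path, delimiter: str | None = None) -> None:
    """Write a dataset so that :func:`read_spectra` round-trips it exactly."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = data.to_frame()
    # repr formatting preserves every float bit-for-bit through the round trip
    df.to_csv(path, sep=sep, float_format=lambda v: repr(float(v)))


def read_covariates(
    path: str | Path, delimiter: str | None = None, standardize: bool = True
) -> CovariateTable:
    """Read a covariate table (first column = sample IDs, one column per covariate)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"covariate table not found: {path}")
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        raw = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataValidationError(f"non-numeric covariate in {path.name}: {exc}") from exc
    return make_covariate_table(raw, list(df.columns), standardize=standardize)


def preprocess(
    data: SpectralDataset,
    center: bool = True,
    scaling: str = "none",
    normalize_total: bool = False,
) -> SpectralDataset:
    """Column centering and optional scaling of a spectral-bin matrix.

    Parameters
    ----------
    center
        Subtract each bin's mean.  The probabilistic models absorb location
        through their mean parameter, so this is the default and is idempotent.
    scaling
        ``"none"``, ``"unit"`` (divide by the column standard deviation) or
        ``"pareto"`` (divide by its square root — common metabolomics practice
        that tempers the dominance of high-intensity bins).
    normalize_total
        Divide each spectrum by its total intensity before anything else
        (probabilistic quotient-style row normalization is out of scope).
    """
    if scaling not in {"none", "unit", "pareto"}:
        raise ValueError(f"unknown scaling {scaling!r}")
    values = data.values.copy()
    if normalize_total:
        totals = values.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise DataValidationError("cannot normalize a spectrum with zero total intensity")
        values = values / totals
    if center:
        values = values - values.mean(axis=0)
    if scaling != "none":
        sd = values.std(axis=0, ddof=1)
        if np.any(sd == 0):
            j = int(np.argmax(sd == 0))
            raise DataValidationError(
                f"zero-variance bin {data.bin_labels[j]!r} cannot be {scaling}-scaled"
            )
        values = values / (sd if scaling == "unit" else np.sqrt(sd))
    record = dict(data.preprocessing)
    record.update(center=center, scaling=scaling, normalize_total=normalize_total)
    return dataclasses.replace(data, values=values, preprocessing=record)
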