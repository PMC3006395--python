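import numpy as np
import pytest

from metabopca.datasets import SpectralDataset, make_covariate_table


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_dataset(rng):
    """A well-conditioned 12 x 6 dataset with labelled bins."""
    X = rng.standard_normal((12, 6)) * np.array([3.0, 2.0, 1.5, 1.0, 0.7, 0.5])
    return SpectralDataset(
        X, [f"s{i}" for i in range(12)], [f"{0.5 + 0.04 * j:.2f}" for j in range(6)]
    )


def dataset_from(X, prefix="s"):
    n, p = X.shape
    return SpectralDataset(
        X, [f"{prefix}{i}" for i in range(n)], [f"b{j}" for j in range(p)]
    )


def dataset_with_covariance(C, n, rng):
    """Exact-sample-covariance construction: returns centered data whose
    (1/n divisor) sample covariance equals C exactly."""
    p = C.shape[0]
    Z = rng.standard_normal((n, p))
    Z = Z - Z.mean(axis=0)
    S = Z.T @ Z / n
    es, Us = np.linalg.eigh(S)
    whiten = Us @ np.diag(1.0 / np.sqrt(es)) @ Us.T
    ec, Uc = np.linalg.eigh(C)
    color = Uc @ np.diag(np.sqrt(np.maximum(ec, 0))) @ Uc.T
    X = Z @ whiten @ color
    return dataset_from(X)
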