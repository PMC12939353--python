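import numpy as np
import pytest

from lnireg.monotone import RegressionData


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_complete_data(rng, n=60, p=2, r=2, psi_scale=0.3):
    """A complete log-normal regression dataset with known generator."""
    X = np.column_stack([np.ones(n), rng.normal(size=(n, r - 1))])
    B = rng.normal(scale=0.5, size=(r, p))
    Q = rng.normal(size=(p, p))
    Psi = psi_scale * (Q @ Q.T / p + np.eye(p))
    T = X @ B + rng.multivariate_normal(np.zeros(p), Psi, size=n)
    return RegressionData(Y=np.exp(T), X=X), B, Psi


def random_missing_data(rng, n=40, p=3, r=2, miss=0.3):
    """Dataset with i.i.d. missingness (rows never fully column-empty)."""
    data, B, Psi = make_complete_data(rng, n=n, p=p, r=r)
    Y = data.Y.copy()
    mask = rng.uniform(size=(n, p)) < miss
    # keep every column partially observed
    for k in range(p):
        if mask[:, k].all():
            mask[rng.integers(n), k] = False
    Y[mask] = np.nan
    return RegressionData(Y=Y, X=data.X), B, Psi


@pytest.fixture
def complete_data(rng):
    return make_complete_data(rng)


@pytest.fixture
def missing_data(rng):
    return random_missing_data(rng)
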