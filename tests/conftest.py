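import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bfmd.data import OutcomeVector, PredictorMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_xy(rng):
    """Random 10-sample, 6-variable dataset with a real outcome signal."""
    X = rng.standard_normal((10, 6))
    y = X[:, 0] - 0.5 * X[:, 3] + 0.3 * rng.standard_normal(10)
    return PredictorMatrix(X), OutcomeVector(y)


def random_psd(rng, T, rank=None):
    """Random PSD matrix built as Z'Z."""
    rank = rank or T
    Z = rng.standard_normal((rank, T))
    return Z.T @ Z


def balanced_population_cov(pi, beta=1.0, alpha=1.0, T_extra=0):
    """Exact covariances of a single-hub balanced module.

    Members x_i = pi_i*beta*x0 + eps_i with unit-variance hub and errors,
    outcome Y = alpha*x0 + noise; optionally ``T_extra`` independent
    unit-variance variables with zero outcome covariance are appended.
    Returns (Sigma, c) for the full variable set.
    """
    pi = np.asarray(pi, dtype=float)
    m = pi.size
    T = m + T_extra
    Sigma = np.eye(T)
    Sigma[:m, :m] = np.outer(pi, pi) * beta**2 + np.eye(m)
    c = np.zeros(T)
    c[:m] = pi * beta * alpha
    return Sigma, c
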