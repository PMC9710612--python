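"""The "W" comparison method: thresholded Perron eigenvector + 2-means.

This earlier approach operates on the same functional-covariance matrix W
but models sparsity only indirectly: all negative entries of W (unbalanced
pairs) are set to zero, the leading eigenvector of the thresholded matrix is
computed, and its entries are split into two clusters by one-dimensional
2-means; the higher-mean cluster is the detected module.  No sparsity
parameter is required, at the cost of systematically larger modules.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse.linalg
from sklearn.cluster import KMeans

from .balance import balance_kappa_from_cov, compute_xy_cov
from .covariance import build_functional_covariance
from .data import OutcomeVector, PredictorMatrix
from .detect import ModuleSelection

__all__ = ["run_w_baseline"]


def _leading_eigenvector(A: np.ndarray) -> np.ndarray:
    T = A.shape[0]
    if T <= 5:
        _evals, evecs = np.linalg.eigh(A)
        return evecs[:, -1]
    v0 = np.full(T, 1.0 / np.sqrt(T))
    _evals, evecs = scipy.sparse.linalg.eigsh(A, k=1, v0=v0)
    return evecs[:, 0]


def run_w_baseline(
    X: PredictorMatrix,
    Y: OutcomeVector,
    seed: int = 0,
    n_restarts: int = 10,
) -> ModuleSelection:
    """Detect a module with the thresholded-eigenvector + 2-means method.

    Parameters
    ----------
    X, Y : PredictorMatrix, OutcomeVector
        Predictors and outcome.
    seed : int
        Seed for the k-means initializations.
    n_restarts : int
        Random k-means restarts; best within-cluster sum of squares wins.
    """
    fc = build_functional_covariance(X, Y)
    W_plus = np.maximum(fc.W, 0.0)
    if not np.any(W_plus):
        raise ValueError(
            "no functional signal: no variable covaries with outcome"
        )
    vec = _leading_eigenvector(W_plus)
    if vec.sum() < 0:
        vec = -vec
    if np.allclose(vec, vec[0]):
        raise ValueError("degenerate eigenvector, cannot partition")

    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(vec.reshape(-1, 1))
    means = km.cluster_centers_.ravel()
    module_label = int(np.argmax(means))
    indices = np.flatnonzero(labels == module_label)
    assert means[module_label] > means[1 - module_label]

    balance = None
    if indices.size >= 2:
        Xc = X.values - X.values.mean(axis=0)
        sub = Xc[:, indices]
        Sigma = sub.T @ sub / (X.n - 1)
        balance = balance_kappa_from_cov(Sigma, compute_xy_cov(X, Y)[indices])

    return ModuleSelection(
        indices=indices,
        names=[X.names[i] for i in indices],
        k_opt=None,
        loadings=None,
        balance=balance,
        method_tag="W",
    )
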