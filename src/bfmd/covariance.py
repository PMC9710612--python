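"""The functional-covariance matrix W and its factorization.

Given predictors X (n x T) and outcome Y, the matrix

    W = Z'Z,   Z = H diag(c),   H = column-centered X,   c_i = Cov(x_i, Y)

highlights pairs of variables that are correlated with each other *and* both
associated with the outcome: elementwise, W is (n-1) times the Hadamard
product of the sample covariance of X with the outer product c c'.  A
balanced functional module — a sign-consistent set of variables jointly
driving Y — appears as an entrywise-positive submatrix of W, whose Perron
eigenvector is therefore positive on the module and (ideally) zero off it.

Only sample moments are used (denominator n-1 throughout); Y is centered but
never standardized, since the construction works with covariances rather
than correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import OutcomeVector, PredictorMatrix

__all__ = [
    "compute_xy_cov",
    "build_functional_covariance",
    "hadamard_form",
    "FunctionalCovariance",
]


def _check_lengths(X: PredictorMatrix, Y: OutcomeVector) -> None:
    if X.n != Y.n:
        raise ValueError(
            f"predictor matrix has {X.n} samples but outcome has {Y.n}"
        )


def compute_xy_cov(X: PredictorMatrix, Y: OutcomeVector) -> np.ndarray:
    """Sample covariance of each predictor column with the outcome.

    Returns the length-T vector c with c_i = Cov(x_i, Y), denominator n-1.
    """
    _check_lengths(X, Y)
    Xc = X.values - X.values.mean(axis=0)
    Yc = Y.values - Y.values.mean()
    return Xc.T @ Yc / (X.n - 1)


@dataclass
class FunctionalCovariance:
    """W = Z'Z together with its factor Z and the outcome covariances.

    Attributes
    ----------
    Z : ndarray (n, T)
        Centered predictors scaled columnwise by Cov(x_i, Y).
    xy_cov : ndarray (T,)
        Sample covariance of each column with the outcome.
    xy_sign : ndarray (T,)
        Signs of ``xy_cov`` with exact zeros mapped to +1.
    names : list of str
        Variable names carried along for reporting.
    """

    Z: np.ndarray
    xy_cov: np.ndarray
    xy_sign: np.ndarray
    names: list[str]
    #: per-variable covariance scale sd(x_i)*sd(Y), for zero-signal detection
    xy_scale: np.ndarray | None = field(default=None, repr=False)
    _W: np.ndarray | None = field(default=None, repr=False)
    _eig: tuple | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def T(self) -> int:
        return self.Z.shape[1]

    @property
    def W(self) -> np.ndarray:
        """The dense T x T matrix Z'Z (materialized on first access)."""
        if self._W is None:
            self._W = self.Z.T @ self.Z
        return self._W

    def matvec(self, q: np.ndarray) -> np.ndarray:
        """W @ q computed through the factor Z (O(nT) instead of O(T^2))."""
        return self.Z.T @ (self.Z @ q)

    def is_zero(self, rtol: float = 1e-12) -> bool:
        """True when no variable meaningfully covaries with the outcome.

        Compares each |Cov(x_i, Y)| against ``rtol`` times its scale
        sd(x_i)*sd(Y), so floating-point dust from an exactly orthogonal
        outcome is treated as zero.
        """
        if not np.any(self.Z):
            return True
        if self.xy_scale is None:
            return False
        return bool(np.all(np.abs(self.xy_cov) <= rtol * self.xy_scale))

    def top_eigenvectors(self, m: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Top-m eigenpairs of W, via the n x n Gram matrix when n < T.

        Returns (vectors, values) with vectors of shape (T, m), leading
        eigenvector first.
        """
        n, T = self.Z.shape
        m = min(m, min(n, T))
        if self._eig is None:
            if n < T:
                G = self.Z @ self.Z.T
                evals, evecs = np.linalg.eigh(G)
                # map Gram eigenvectors u to eigenvectors of W: v = Z'u
                vecs = self.Z.T @ evecs[:, ::-1]
                norms = np.linalg.norm(vecs, axis=0)
                norms[norms == 0] = 1.0
                self._eig = (vecs / norms, evals[::-1])
            else:
                evals, evecs = np.linalg.eigh(self.W)
                self._eig = (evecs[:, ::-1], evals[::-1])
        vecs, vals = self._eig
        return vecs[:, :m], vals[:m]

    def leading_eigenvector(self) -> tuple[np.ndarray, float]:
        vecs, vals = self.top_eigenvectors(1)
        return vecs[:, 0], float(vals[0])


def build_functional_covariance(
    X: PredictorMatrix, Y: OutcomeVector
) -> FunctionalCovariance:
    """Assemble Z = H diag(Cov(X, Y)) and hence W = Z'Z from data."""
    c = compute_xy_cov(X, Y)
    H = X.values - X.values.mean(axis=0)
    Z = H * c[np.newaxis, :]
    sign = np.where(c >= 0.0, 1.0, -1.0)
    scale = X.values.std(axis=0, ddof=1) * Y.values.std(ddof=1)
    return FunctionalCovariance(
        Z=Z, xy_cov=c, xy_sign=sign, names=list(X.names), xy_scale=scale
    )


def hadamard_form(X: PredictorMatrix, Y: OutcomeVector) -> np.ndarray:
    """Elementwise product SampleCov(X) * (c c'), with c = Cov(X, Y).

    Equals W / (n-1) from :func:`build_functional_covariance` up to floating
    point error; exposed separately because the Hadamard form makes the
    module-times-functionality interpretation explicit.
    """
    c = compute_xy_cov(X, Y)
    S = np.cov(X.values, rowvar=False)
    return S * np.outer(c, c)
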