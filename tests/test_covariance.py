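import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bfmd.covariance import (
    build_functional_covariance,
    compute_xy_cov,
    hadamard_form,
)
from bfmd.data import OutcomeVector, PredictorMatrix


def _toy():
    # n=3, T=2; covariances expanded by hand from sum((x-xbar)(y-ybar))/(n-1)
    X = PredictorMatrix(np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 3.0]]))
    Y = OutcomeVector(np.array([1.0, 2.0, 3.0]))
    return X, Y


class TestXYCov:
    def test_hand_expanded_toy(self):
        X, Y = _toy()
        # col0 == Y so Cov = Var(Y) = 1; col1: ((0)(-1)+(-1)(0)+(1)(1))/2
        np.testing.assert_allclose(compute_xy_cov(X, Y), [1.0, 0.5])

    def test_column_equal_to_outcome_gives_outcome_variance(self, rng):
        y = rng.standard_normal(20)
        X = PredictorMatrix(np.column_stack([y, rng.standard_normal(20)]))
        Y = OutcomeVector(y)
        assert compute_xy_cov(X, Y)[0] == pytest.approx(y.var(ddof=1))

    def test_orthogonal_column_gives_zero(self, rng):
        y = rng.standard_normal(21)
        yc = y - y.mean()
        x = rng.standard_normal(21)
        x -= (x - x.mean()) @ yc / (yc @ yc) * yc  # remove the Y component
        X = PredictorMatrix(np.column_stack([x, y]))
        assert compute_xy_cov(X, OutcomeVector(y))[0] == pytest.approx(0.0, abs=1e-12)

    def test_dimension_mismatch_names_both_lengths(self, rng):
        X = PredictorMatrix(rng.standard_normal((10, 2)))
        Y = OutcomeVector(rng.standard_normal(8))
        with pytest.raises(ValueError, match="10.*8"):
            compute_xy_cov(X, Y)


class TestFunctionalCovariance:
    def test_factorization_matches_hadamard_oracle(self, rng):
        """Z'Z must equal (n-1) * (SampleCov(X) o c c') elementwise."""
        X = PredictorMatrix(rng.standard_normal((10, 6)))
        Y = OutcomeVector(rng.standard_normal(10))
        fc = build_functional_covariance(X, Y)
        oracle = (X.n - 1) * np.cov(X.values, rowvar=False) * np.outer(
            fc.xy_cov, fc.xy_cov
        )
        np.testing.assert_allclose(fc.W, oracle, rtol=1e-10, atol=1e-12)

    def test_outcome_orthogonal_to_all_columns_gives_zero_w(self, rng):
        X = PredictorMatrix(rng.standard_normal((12, 4)))
        Xc = X.values - X.values.mean(axis=0)
        # build Y in the orthogonal complement of the centered columns
        q, _ = np.linalg.qr(np.column_stack([Xc, np.ones(12)]))
        y = rng.standard_normal(12)
        y -= q @ (q.T @ y)
        fc = build_functional_covariance(X, OutcomeVector(y))
        np.testing.assert_allclose(fc.W, 0.0, atol=1e-20)
        assert fc.is_zero() or np.allclose(fc.Z, 0, atol=1e-12)

    def test_psd(self, rng):
        X = PredictorMatrix(rng.standard_normal((15, 8)))
        Y = OutcomeVector(rng.standard_normal(15))
        evals = np.linalg.eigvalsh(build_functional_covariance(X, Y).W)
        assert evals.min() >= -1e-8 * evals.max()

    def test_matvec_agrees_with_dense(self, rng):
        X = PredictorMatrix(rng.standard_normal((9, 5)))
        Y = OutcomeVector(rng.standard_normal(9))
        fc = build_functional_covariance(X, Y)
        q = rng.standard_normal(5)
        np.testing.assert_allclose(fc.matvec(q), fc.W @ q, rtol=1e-10)


class TestHadamardForm:
    def test_identity_covariance_design(self, rng):
        """Uncorrelated unit-variance design: result ~ diag(c^2)."""
        X = PredictorMatrix(rng.standard_normal((2000, 4)))
        Y = OutcomeVector(rng.standard_normal(2000) + X.values[:, 0])
        H = hadamard_form(X, Y)
        c = compute_xy_cov(X, Y)
        np.testing.assert_allclose(H, np.diag(c**2), atol=0.15)
        np.testing.assert_allclose(H, H.T)

    def test_matches_w_up_to_sample_scale(self, rng):
        X = PredictorMatrix(rng.standard_normal((11, 5)))
        Y = OutcomeVector(rng.standard_normal(11))
        fc = build_functional_covariance(X, Y)
        np.testing.assert_allclose(hadamard_form(X, Y), fc.W / (X.n - 1), rtol=1e-9)


class TestInvariances:
    @given(st.floats(min_value=0.1, max_value=50.0), st.integers(min_value=0, max_value=2**31 - 1))
    def test_outcome_scaling_scales_w_quadratically(self, a, seed):
        rng = np.random.default_rng(seed)
        X = PredictorMatrix(rng.standard_normal((8, 4)))
        y = rng.standard_normal(8)
        W1 = build_functional_covariance(X, OutcomeVector(y)).W
        W2 = build_functional_covariance(X, OutcomeVector(a * y)).W
        np.testing.assert_allclose(W2, a**2 * W1, rtol=1e-8, atol=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_column_permutation_permutes_w(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((9, 5))
        y = rng.standard_normal(9)
        perm = rng.permutation(5)
        W = build_functional_covariance(
            PredictorMatrix(X), OutcomeVector(y)
        ).W
        Wp = build_functional_covariance(
            PredictorMatrix(X[:, perm]), OutcomeVector(y)
        ).W
        np.testing.assert_allclose(Wp, W[np.ix_(perm, perm)], rtol=1e-9, atol=1e-12)
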