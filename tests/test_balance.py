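import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bfmd.balance import (
    balance_kappa,
    balance_kappa_from_cov,
    balance_score,
    kappa_from_sign_vectors,
    select_k_by_balance,
)
from bfmd.covariance import build_functional_covariance
from bfmd.data import OutcomeVector, PredictorMatrix
from bfmd.sim import SimConfig, simulate

from .conftest import balanced_population_cov


class TestKappaCore:
    def test_perfect_two_set_structure_scores_one(self):
        """Exact promoter/suppressor sign structure gives Kappa = 1."""
        pi = np.array([1, 1, -1, 1, -1, -1.0])
        Sigma, c = balanced_population_cov(pi)
        rep = balance_kappa_from_cov(Sigma, c)
        assert rep.kappa == 1.0
        assert rep.agreement == 1.0
        np.testing.assert_array_equal(rep.set_A, [0, 1, 3])
        np.testing.assert_array_equal(rep.set_B, [2, 4, 5])
        assert rep.n_pairs == 15

    def test_single_discordant_pair_theorem_pattern(self):
        # two variables, opposite outcome signs, negative covariance: balanced
        Sigma = np.array([[1.0, -0.5], [-0.5, 1.0]])
        c = np.array([0.8, -0.7])
        rep = balance_kappa_from_cov(Sigma, c)
        assert rep.kappa == 1.0

    def test_degenerate_constant_raters(self):
        # both sign vectors constant +: expected agreement 1 -> rule applies
        kappa, po = kappa_from_sign_vectors(np.ones(5), np.ones(5))
        assert (kappa, po) == (1.0, 1.0)
        # constant but conflicting: kappa 0 by the convention
        kappa, _ = kappa_from_sign_vectors(np.ones(5), -np.ones(5))
        assert kappa == 0.0

    def test_permutation_null_centers_on_zero(self, rng):
        """Independent sign raters give mean Kappa ~ 0."""
        n_pairs = 45
        base = rng.choice([-1.0, 1.0], size=n_pairs)
        other = rng.choice([-1.0, 1.0], size=n_pairs)
        kappas = []
        for _ in range(1000):
            kappas.append(kappa_from_sign_vectors(base, rng.permutation(other))[0])
        assert abs(np.mean(kappas)) < 0.05

    def test_module_too_small_rejected(self):
        with pytest.raises(ValueError, match="size >= 2"):
            balance_kappa_from_cov(np.eye(1), np.array([1.0]))

    def test_sample_kappa_on_simulated_module_near_one(self):
        """Large-sample SIM module: empirical signs match the balance pattern."""
        ds = simulate(SimConfig(n=5000, r_m=0.5, snr=0.5, random_signs=True, seed=3))
        idx = ds.functional_indices
        rep = balance_kappa(ds.X.subset(idx), ds.Y)
        assert rep.kappa > 0.95


class TestKappaInvariances:
    @given(
        st.floats(min_value=0.2, max_value=5.0),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_invariant_to_positive_rescaling(self, a, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((15, 5))
        y = X[:, 0] - X[:, 2] + 0.5 * rng.standard_normal(15)
        r1 = balance_kappa(PredictorMatrix(X), OutcomeVector(y))
        r2 = balance_kappa(PredictorMatrix(X * a), OutcomeVector(y * a))
        assert r1.kappa == pytest.approx(r2.kappa)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_agreement_invariant_to_flipping_one_variable(self, seed):
        """Flipping x_i flips both raters on the same pairs.

        The observed agreement is therefore invariant (Kappa itself is not:
        its chance-correction term depends on the rater marginals, which a
        flip changes); perfect balance stays perfect under flips.
        """
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((15, 5))
        y = X[:, 0] - X[:, 2] + 0.5 * rng.standard_normal(15)
        r1 = balance_kappa(PredictorMatrix(X), OutcomeVector(y))
        Xf = X.copy()
        Xf[:, 1] *= -1
        r2 = balance_kappa(PredictorMatrix(Xf), OutcomeVector(y))
        assert r1.agreement == pytest.approx(r2.agreement)
        assert (r1.kappa == 1.0) == (r2.kappa == 1.0)


class TestBalanceScore:
    def test_penalizes_few_pairs(self):
        # perfect agreement on 1 pair must not outrank near-perfect on many
        assert balance_score(1.0, 0.5, 1) < balance_score(0.95, 0.5, 190)

    def test_recovers_kappa_ordering_for_large_modules(self):
        # same size, same chance level: ordering follows agreement
        assert balance_score(0.9, 0.5, 500) > balance_score(0.8, 0.5, 500)


class TestSelectK:
    def test_singleton_range_returns_it(self, rng):
        ds = simulate(SimConfig(n=60, n_modules=2, n_noise=20, n_independent=2,
                                r_m=0.6, snr=1.0, seed=5))
        fc = build_functional_covariance(ds.X, ds.Y)
        k_opt, table = select_k_by_balance(fc, ds.X, ds.Y, [20])
        assert k_opt == 20
        assert list(table.columns) == ["k", "kappa", "score", "objective", "support_size"]
        assert len(table) == 1

    def test_no_signal_still_returns_a_k(self, rng):
        X = PredictorMatrix(rng.standard_normal((40, 30)))
        Y = OutcomeVector(rng.standard_normal(40))
        fc = build_functional_covariance(X, Y)
        k_opt, table = select_k_by_balance(fc, X, Y, range(2, 15))
        assert k_opt in range(2, 15)
        # selection-biased supports inflate Kappa at tiny k, but without a
        # real module the agreement decays toward chance as k grows
        assert table["kappa"].iloc[-1] < 0.5
        assert table["score"].max() < 0.5

    def test_brackets_true_module_size(self):
        """Moderate-signal SIMs select k near the true module size of 20."""
        hits = 0
        reps = 8
        for rep in range(reps):
            ds = simulate(SimConfig(n=400, r_m=0.5, snr=0.5, random_signs=True,
                                    seed=100 + rep))
            fc = build_functional_covariance(ds.X, ds.Y)
            k_opt, _ = select_k_by_balance(fc, ds.X, ds.Y, range(2, 41))
            hits += 15 <= k_opt <= 30
        assert hits >= 0.9 * reps
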