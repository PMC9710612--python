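"""Balance of a candidate module, measured by Cohen's Kappa.

A balanced module splits into two camps A and B: within-camp covariances are
positive, between-camp covariances negative, and each variable's covariance
with the outcome has the camp's common sign (A positive, B negative).  For
every unordered pair (i, j) inside the module this implies

    sign( Cov(x_i, Y) * Cov(x_j, Y) )  ==  sign( Cov(x_i, x_j) ).

Flattening both sign patterns over the m(m-1)/2 pairs gives two binary
raters; Cohen's Kappa between them is the balance score (1 = perfectly
balanced, ~0 = sign agreement at chance level).  The same Kappa drives the
choice of the sparsity level k in the detection sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .covariance import FunctionalCovariance, compute_xy_cov
from .data import OutcomeVector, PredictorMatrix
from .sparse_pca import sparse_positive_pc

__all__ = [
    "BalanceReport",
    "balance_kappa",
    "balance_kappa_from_cov",
    "select_k_by_balance",
]


@dataclass
class BalanceReport:
    """Balance diagnostics for one module candidate.

    ``set_A``/``set_B`` partition the module by the sign of each variable's
    outcome covariance (promoters vs suppressors); ``agreement`` is the raw
    proportion of sign-concordant pairs before chance correction; ``score``
    is the size-aware selection criterion used to compare candidates of
    different cardinality (see :func:`balance_score`).
    """

    kappa: float
    agreement: float
    set_A: np.ndarray
    set_B: np.ndarray
    n_pairs: int
    zero_covariances: bool = False
    score: float = float("nan")


def _signs(a: np.ndarray) -> np.ndarray:
    """Entrywise sign with exact zeros mapped to +1 (deterministic)."""
    return np.where(np.asarray(a) >= 0.0, 1.0, -1.0)


def kappa_from_sign_vectors(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Cohen's Kappa between two +/-1 vectors, with the degenerate case.

    When the expected agreement is 1 (both raters constant and equal) Kappa
    is 0/0; a perfectly agreeing constant pattern is then scored 1, any
    other 0.  Returns (kappa, observed agreement).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    po = float(np.mean(a == b))
    pa = float(np.mean(a > 0))
    pb = float(np.mean(b > 0))
    pe = pa * pb + (1.0 - pa) * (1.0 - pb)
    if pe >= 1.0 - 1e-15:
        return (1.0 if po == 1.0 else 0.0), po
    return float(cohen_kappa_score(a, b)), po


def _wilson_lower(p: float, n: int, z: float = 1.96) -> float:
    """Wilson lower confidence bound for a binomial proportion."""
    if n <= 0:
        return 0.0
    denom = 1.0 + z * z / n
    center = p + z * z / (2 * n)
    half = z * np.sqrt(p * (1.0 - p) / n + z * z / (4 * n * n))
    return float((center - half) / denom)


def balance_score(po: float, pe: float, n_pairs: int, z: float = 1.96) -> float:
    """Size-aware balance criterion: chance-corrected agreement margin.

    Computes ``wilson_lower(po, n_pairs) - pe``: the lower confidence bound
    of the observed pairwise sign agreement minus the agreement expected by
    chance.  Unlike Kappa itself this is comparable across candidate
    modules of different size — a handful of concordant pairs scores a
    perfect Kappa too easily, so raw Kappa cannot arbitrate between a lucky
    pair and a large genuinely balanced module.  The bound penalty vanishes
    as the number of pairs grows, so in the population limit ranking by
    this score agrees with ranking by Kappa; it also remains defined (and
    monotone in module size) in the degenerate single-camp case where
    Kappa is 0/0.

    In that degenerate case (both raters constant, expected agreement 1)
    the marginal-based chance term carries no information — it would brand
    a genuinely balanced single-camp module as pure chance — so the chance
    level reverts to the sign coin-flip value 1/2.
    """
    if pe >= 1.0 - 1e-15:
        pe = 0.5
    return _wilson_lower(po, n_pairs, z=z) - pe


def _pair_sign_vectors(
    Sigma_sub: np.ndarray, c_sub: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    m = c_sub.size
    iu = np.triu_indices(m, k=1)
    cs = _signs(c_sub)
    z_signs = (cs[:, None] * cs[None, :])[iu]
    cov_signs = _signs(Sigma_sub)[iu]
    had_zero = bool(np.any(c_sub == 0.0) or np.any(Sigma_sub[iu] == 0.0))
    return z_signs, cov_signs, had_zero


def balance_kappa_from_cov(Sigma_sub: np.ndarray, c_sub: np.ndarray) -> BalanceReport:
    """Balance Kappa from a module's covariance matrix and outcome covariances.

    This is the exact (population) entry point: feed it true covariances to
    evaluate balance without sampling noise.
    """
    Sigma_sub = np.asarray(Sigma_sub, dtype=float)
    c_sub = np.asarray(c_sub, dtype=float).ravel()
    m = c_sub.size
    if m < 2:
        raise ValueError(f"balance needs a module of size >= 2, got {m}")
    if Sigma_sub.shape != (m, m):
        raise ValueError(
            f"covariance block shape {Sigma_sub.shape} does not match {m} variables"
        )
    z_signs, cov_signs, had_zero = _pair_sign_vectors(Sigma_sub, c_sub)
    kappa, po = kappa_from_sign_vectors(z_signs, cov_signs)
    pa = float(np.mean(z_signs > 0))
    pb = float(np.mean(cov_signs > 0))
    pe = pa * pb + (1.0 - pa) * (1.0 - pb)
    n_pairs = m * (m - 1) // 2
    pos = _signs(c_sub) > 0
    return BalanceReport(
        kappa=kappa,
        agreement=po,
        set_A=np.flatnonzero(pos),
        set_B=np.flatnonzero(~pos),
        n_pairs=n_pairs,
        zero_covariances=had_zero,
        score=balance_score(po, pe, n_pairs),
    )


def balance_kappa(X_sub: PredictorMatrix, Y: OutcomeVector) -> BalanceReport:
    """Balance Kappa of a module given its data columns and the outcome."""
    if X_sub.T < 2:
        raise ValueError(f"balance needs a module of size >= 2, got {X_sub.T}")
    c = compute_xy_cov(X_sub, Y)
    Sigma = np.cov(X_sub.values, rowvar=False)
    return balance_kappa_from_cov(Sigma, c)


# ---------------------------------------------------------------------------
# sparsity selection


def _sample_kappa_fn(X: PredictorMatrix, Y: OutcomeVector):
    Xc = X.values - X.values.mean(axis=0)
    Yc = Y.values - Y.values.mean()
    c = Xc.T @ Yc / (X.n - 1)

    def kappa_of(support: np.ndarray) -> BalanceReport:
        sub = Xc[:, support]
        Sigma = sub.T @ sub / (X.n - 1)
        return balance_kappa_from_cov(Sigma, c[support])

    return kappa_of


def _population_kappa_fn(Sigma: np.ndarray, c: np.ndarray):
    def kappa_of(support: np.ndarray) -> BalanceReport:
        return balance_kappa_from_cov(Sigma[np.ix_(support, support)], c[support])

    return kappa_of


def sweep_k(W, kappa_of, k_range, max_iter=None, tol=None) -> list[dict]:
    """Run the sparse positive PC for each k and score each support's balance.

    Each k is attempted both from the default dense-eigenvector start and
    warm-started from the previous k's solution; the higher objective wins,
    which also makes the objective non-decreasing in k.
    """
    kwargs = {}
    if max_iter is not None:
        kwargs["max_iter"] = max_iter
    if tol is not None:
        kwargs["tol"] = tol
    records: list[dict] = []
    prev_q: np.ndarray | None = None
    for k in sorted(k_range):
        # warm chaining explores the support path; one eigenvector start
        # per k keeps the sweep linear-time in the k grid
        cold = sparse_positive_pc(W, k, n_eig_inits=1, **kwargs)
        best = cold
        if prev_q is not None:
            warm = sparse_positive_pc(W, k, q0=prev_q, **kwargs)
            if warm.objective > best.objective:
                best = warm
        prev_q = best.loadings
        report = kappa_of(best.support) if best.support.size >= 2 else None
        if report is not None:
            kappa = report.kappa
            score = report.score
        else:
            report = None
            kappa = float("nan")
            score = float("nan")
        records.append(
            {
                "k": k,
                "kappa": kappa,
                "score": score,
                "objective": best.objective,
                "support_size": int(best.support.size),
                "loading": best,
                "report": report,
            }
        )
    return records


def pick_optimal(records: list[dict]) -> dict:
    """Most balanced solution: max balance score, ties to larger support.

    Candidates are ranked by :func:`balance_score`, which corrects the raw
    Kappa for how much sign agreement a module of that size could show by
    chance.  Preferring the larger support among equally balanced solutions
    returns the *complete* balanced module rather than an arbitrary
    sign-consistent fragment; the final tie-break on k is for determinism.
    """
    scored = [r for r in records if np.isfinite(r["score"])]
    if not scored:
        raise ValueError("no candidate k produced a module of size >= 2")
    return max(scored, key=lambda r: (r["score"], r["support_size"], -r["k"]))


def select_k_by_balance(
    W: FunctionalCovariance,
    X: PredictorMatrix,
    Y: OutcomeVector,
    k_range,
    max_iter=None,
    tol=None,
) -> tuple[int, pd.DataFrame]:
    """Choose the sparsity level k maximizing the balance Kappa.

    Returns the optimal k and the full per-k diagnostic table
    (columns: k, kappa, objective, support_size).
    """
    records = sweep_k(W, _sample_kappa_fn(X, Y), k_range, max_iter=max_iter, tol=tol)
    best = pick_optimal(records)
    table = pd.DataFrame(
        [{key: r[key] for key in ("k", "kappa", "score", "objective", "support_size")} for r in records]
    )
    return int(best["k"]), table
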