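"""Cardinality-constrained nonnegative leading principal component of W.

The module extracts a unit-norm vector q >= 0 with at most k nonzero
entries approximately maximizing q' W q, by truncated power iteration with
a nonnegativity projection:

    q  <-  normalize( top-k( max(W q, 0) ) )

For a positive semidefinite W this projection step is the exact maximizer of
the linearized objective over the feasible set {q >= 0, |q|_2 = 1,
card(q) <= k}, so the objective q' W q is non-decreasing across iterations.
For an entrywise-positive W and k = T the fixed point is the Perron
eigenvector, which is why a balanced module surfaces as the sparse positive
leading component of the functional-covariance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .covariance import FunctionalCovariance

__all__ = ["SparseLoading", "sparse_positive_pc", "feasible_k_range"]

#: relative objective-change tolerance and iteration cap for the power scheme
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000

#: consecutive iterations with an unchanged active set before the iteration
#: is restricted to the support (fixed point re-verified on the full matrix)
_SUPPORT_LOCK_PATIENCE = 3


@dataclass
class SparseLoading:
    """Result of one sparse positive PC extraction.

    Attributes
    ----------
    loadings : ndarray (T,)
        Nonnegative unit-norm vector, at most ``k`` nonzeros.
    k : int
        Requested cardinality.
    support : ndarray of int
        Indices of nonzero loadings (sorted ascending).
    objective : float
        q' W q at the returned vector.
    n_iter : int
        Power iterations performed.
    converged : bool
        Whether the relative objective change fell below tolerance.
    objective_path : list of float
        Objective after each iteration (monotone non-decreasing).
    """

    loadings: np.ndarray
    k: int
    support: np.ndarray
    objective: float
    n_iter: int
    converged: bool
    objective_path: list


def feasible_k_range(
    T: int, n: int, k_min: int = 2, k_max: int | None = None
) -> list[int]:
    """Candidate module sizes to sweep: the inclusive range [k_min, k_max].

    By default k_max = min(T, n): a module larger than the sample size is not
    estimable, and it can never exceed the number of variables.
    """
    if k_max is None:
        k_max = min(T, n)
    k_max = min(int(k_max), T)
    k_min = int(k_min)
    if k_min < 1:
        raise ValueError(f"k_min must be >= 1, got {k_min}")
    if k_min > k_max:
        raise ValueError(f"k_min={k_min} exceeds k_max={k_max}")
    return list(range(k_min, k_max + 1))


def _as_operator(W):
    """Return (matvec, T, top_eigenvectors_fn, is_zero) for W.

    Accepts a :class:`FunctionalCovariance` (matvec through the factor Z) or
    a dense symmetric PSD ndarray.
    """
    if isinstance(W, FunctionalCovariance):
        return W.matvec, W.T, W.top_eigenvectors, W.is_zero()
    A = np.asarray(W, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"W must be square, got shape {A.shape}")

    cache: list = []

    def top(m=1):
        m = min(m, A.shape[0])
        if not cache:
            evals, evecs = np.linalg.eigh(A)
            cache.append((evecs[:, ::-1], evals[::-1]))
        evecs, evals = cache[0]
        return evecs[:, :m], evals[:m]

    return (lambda q: A @ q), A.shape[0], top, not np.any(A)


def _project_topk_nonneg(v: np.ndarray, k: int) -> np.ndarray:
    """Clamp negatives to zero and keep the k largest entries.

    Ties at the k-th entry keep the lower variable index (stable sort on the
    negated values), making the projection deterministic.
    """
    w = np.maximum(v, 0.0)
    nnz = np.count_nonzero(w)
    if nnz > k:
        keep = np.argsort(-w, kind="stable")[:k]
        out = np.zeros_like(w)
        out[keep] = w[keep]
        return out
    return w


def _normalized_or_none(v: np.ndarray, k: int) -> np.ndarray | None:
    q = _project_topk_nonneg(v, k)
    norm = np.linalg.norm(q)
    return q / norm if norm > 0 else None


def _default_inits(
    W, top_eigenvectors, T: int, k: int, n_eig_inits: int = 6
) -> list[np.ndarray]:
    """Deterministic starting vectors for the power scheme.

    Primary starts: the top few dense eigenvectors with negatives clamped
    (both orientations, since an eigenvector's sign is arbitrary).  A start
    on the k largest diagonal entries of W guards against cases where the
    dense eigenvectors point away from the best sparse support; a uniform
    positive vector is the last-resort fallback.
    """
    inits: list[np.ndarray] = []
    vecs, _lams = top_eigenvectors(n_eig_inits)
    for j in range(vecs.shape[1]):
        for cand in (vecs[:, j], -vecs[:, j]):
            q = _normalized_or_none(cand, k)
            if q is not None:
                inits.append(q)
    diag = _diagonal(W)
    top = np.argsort(-diag, kind="stable")[:k]
    e = np.zeros(T)
    e[top] = 1.0
    q = _normalized_or_none(e, k)
    if q is not None:
        inits.append(q)
    if not inits:
        e = np.zeros(T)
        e[:k] = 1.0
        inits.append(e / np.linalg.norm(e))
    return inits


def _diagonal(W) -> np.ndarray:
    if isinstance(W, FunctionalCovariance):
        return np.einsum("ij,ij->j", W.Z, W.Z)
    return np.diag(np.asarray(W, dtype=float)).copy()


def sparse_positive_pc(
    W,
    k: int,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int | None = None,
    q0: np.ndarray | None = None,
    n_eig_inits: int = 6,
) -> SparseLoading:
    """Extract a sparse nonnegative leading principal component of W.

    Parameters
    ----------
    W : FunctionalCovariance or ndarray
        PSD matrix (or its factored form) to analyze.
    k : int
        Maximum number of nonzero loadings (1 <= k <= T).
    max_iter, tol : int, float
        Iteration cap and relative objective-change tolerance.
    seed : int, optional
        Accepted for interface stability; the default path is deterministic.
    q0 : ndarray, optional
        Warm-start vector (projected onto the feasible set before use).
    n_eig_inits : int
        How many dense eigenvectors (both orientations each) to try as
        starting points alongside the diagonal start.
    """
    matvec, T, leading, is_zero = _as_operator(W)
    if not 1 <= k <= T:
        raise ValueError(f"k must be in [1, {T}], got {k}")
    if is_zero:
        raise ValueError(
            "no functional signal: W is identically zero "
            "(no variable covaries with the outcome)"
        )

    if q0 is not None:
        q = _normalized_or_none(np.asarray(q0, dtype=float), k)
        inits = (
            [q]
            if q is not None
            else _default_inits(W, leading, T, k, n_eig_inits)
        )
    else:
        inits = _default_inits(W, leading, T, k, n_eig_inits)

    best: SparseLoading | None = None
    for q_init in inits:
        res = _run_from(W, matvec, T, k, q_init, max_iter, tol)
        if best is None or res.objective > best.objective:
            best = res
    return best


def _run_from(
    W, matvec, T: int, k: int, q: np.ndarray, max_iter: int, tol: float
) -> SparseLoading:
    """Iterate the projected power scheme from one starting vector."""
    p = matvec(q)
    obj = float(q @ p)
    path: list[float] = []
    converged = False
    n_iter = 0
    support = np.flatnonzero(q)
    stable_count = 0

    # restricted-iteration state: columns of the active set only
    sub_cols: np.ndarray | None = None
    sub_matvec = None

    while n_iter < max_iter:
        n_iter += 1
        if sub_cols is None:
            w = _project_topk_nonneg(p, k)
            norm = np.linalg.norm(w)
            if norm == 0.0:
                # degenerate: W q has no positive entry; restart uniformly
                w = np.zeros(T)
                w[:k] = 1.0
                norm = np.linalg.norm(w)
            q = w / norm
            p = matvec(q)
            new_obj = float(q @ p)
            new_support = np.flatnonzero(q)
            if new_support.size == support.size and np.array_equal(
                new_support, support
            ):
                stable_count += 1
            else:
                stable_count = 0
            support = new_support
            path.append(new_obj)
            if abs(new_obj - obj) <= tol * max(abs(obj), np.finfo(float).tiny):
                converged = True
                obj = new_obj
                break
            obj = new_obj
            if stable_count >= _SUPPORT_LOCK_PATIENCE and support.size:
                sub_cols = support
                sub_matvec = _restricted_matvec(W, sub_cols)
        else:
            # iterate on the locked support, then re-verify on the full matrix
            qs = q[sub_cols]
            ps = sub_matvec(qs)
            inner_converged = False
            for _ in range(max_iter - n_iter):
                n_iter += 1
                ws = np.maximum(ps, 0.0)
                norm = np.linalg.norm(ws)
                if norm == 0.0:
                    break
                qs = ws / norm
                ps = sub_matvec(qs)
                new_obj = float(qs @ ps)
                path.append(new_obj)
                if abs(new_obj - obj) <= tol * max(
                    abs(obj), np.finfo(float).tiny
                ):
                    inner_converged = True
                    obj = new_obj
                    break
                obj = new_obj
            q = np.zeros(T)
            q[sub_cols] = qs
            p = matvec(q)
            # fixed point of the full iteration iff the projection of W q
            # stays on the locked support
            w_full = _project_topk_nonneg(p, k)
            full_support = np.flatnonzero(w_full)
            if inner_converged and np.array_equal(full_support, np.flatnonzero(q)):
                converged = True
                obj = float(q @ p)
                break
            sub_cols = None
            sub_matvec = None
            stable_count = 0

    support = np.flatnonzero(q)
    objective = float(q @ matvec(q))
    if not path:
        path = [objective]
    return SparseLoading(
        loadings=q,
        k=k,
        support=support,
        objective=objective,
        n_iter=n_iter,
        converged=converged,
        objective_path=path,
    )


def _restricted_matvec(W, cols: np.ndarray):
    """Matvec of the principal submatrix W[cols, cols]."""
    if isinstance(W, FunctionalCovariance):
        Zs = W.Z[:, cols]
        return lambda v: Zs.T @ (Zs @ v)
    A = np.asarray(W, dtype=float)[np.ix_(cols, cols)]
    return lambda v: A @ v
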