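"""Core data containers and delimited-text IO.

A :class:`PredictorMatrix` holds an ``n x T`` numeric matrix of samples by
variables (e.g. genes) with one name per column; an :class:`OutcomeVector`
holds the matching univariate outcome (one value per sample).  Both validate
eagerly so that downstream covariance algebra can assume clean input:
no missing values, no constant columns, at least 3 samples and 2 variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PredictorMatrix",
    "OutcomeVector",
    "read_predictor_matrix",
    "read_outcome",
    "write_matrix_tsv",
]


@dataclass(frozen=True)
class PredictorMatrix:
    """Samples-by-variables numeric matrix with column names.

    Parameters
    ----------
    values : ndarray of shape (n, T)
        Numeric data, one row per sample, one column per variable.
    names : list of str
        Variable identifiers, length T.
    """

    values: np.ndarray
    names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"predictor matrix must be 2-D, got shape {values.shape}")
        n, T = values.shape
        if n < 3:
            raise ValueError(f"need at least 3 samples, got n={n}")
        if T < 2:
            raise ValueError(f"need at least 2 variables, got T={T}")
        if not np.all(np.isfinite(values)):
            raise ValueError("predictor matrix contains missing or non-finite values")
        names = self.names
        if names is None:
            names = [f"x{i}" for i in range(T)]
        names = [str(nm) for nm in names]
        if len(names) != T:
            raise ValueError(
                f"got {len(names)} variable names for {T} columns"
            )
        variances = values.var(axis=0)
        constant = np.flatnonzero(variances == 0.0)
        if constant.size:
            bad = ", ".join(names[i] for i in constant[:10])
            raise ValueError(
                f"constant column(s) with zero sample variance: {bad}"
                + (" ..." if constant.size > 10 else "")
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.values.shape[0]

    @property
    def T(self) -> int:
        """Number of variables."""
        return self.values.shape[1]

    def subset(self, indices) -> "PredictorMatrix":
        """Restrict to the given variable columns (keeps order given)."""
        idx = np.asarray(indices, dtype=int)
        return PredictorMatrix(self.values[:, idx], [self.names[i] for i in idx])


@dataclass(frozen=True)
class OutcomeVector:
    """Univariate outcome, one value per sample."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        if values.size < 3:
            raise ValueError(f"outcome needs at least 3 samples, got {values.size}")
        if not np.all(np.isfinite(values)):
            raise ValueError("outcome contains missing or non-finite values")
        if values.var() == 0.0:
            raise ValueError("outcome has zero sample variance")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.size


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_predictor_matrix(path) -> PredictorMatrix:
    """Read a samples x variables table from TSV/CSV.

    The first row must be variable names; a leading non-numeric column is
    treated as sample identifiers and dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] and not pd.api.types.is_numeric_dtype(df.iloc[:, 0]):
        df = df.set_index(df.columns[0])
    return PredictorMatrix(df.to_numpy(dtype=float), list(df.columns))


def read_outcome(path) -> OutcomeVector:
    """Read a single-column outcome from TSV/CSV.

    Accepts an optional header line and an optional leading sample-id column;
    exactly one numeric column must remain.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None)
    # drop a header row if the first row does not parse as numbers
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:].reset_index(drop=True)
    # drop a leading sample-id column if it is non-numeric
    if df.shape[1] > 1:
        col0 = pd.to_numeric(df.iloc[:, 0], errors="coerce")
        if col0.isna().any():
            df = df.iloc[:, 1:]
    if df.shape[1] != 1:
        raise ValueError(
            f"outcome file {path} must contain exactly one numeric column, "
            f"found {df.shape[1]}"
        )
    return OutcomeVector(df.iloc[:, 0].astype(float).to_numpy())


def write_matrix_tsv(matrix: np.ndarray, names, path) -> None:
    """Write a square named matrix (e.g. W) as TSV — diagnostic output."""
    pd.DataFrame(np.asarray(matrix), index=list(names), columns=list(names)).to_csv(
        Path(path), sep="\t"
    )
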