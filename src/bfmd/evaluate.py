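"""Scoring detected modules against ground truth, and grid aggregation.

Metrics per selection: sensitivity (true positives over true module size),
false discovery rate (false positives over selected), detected module size,
and the normalized Hamming distance

    100 * (false positives + false negatives) / T,

which is 0 for perfect concordance and 100 for complete discordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import PredictorMatrix
from .detect import ModuleSelection
from .sim import SimDataset

__all__ = [
    "EvalResult",
    "score_selection",
    "aggregate",
    "load_external_selection",
]


@dataclass
class EvalResult:
    sensitivity: float
    fdr: float
    hamming_norm: float
    module_size: int
    method_tag: str = ""
    scenario: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "method": self.method_tag,
            "sensitivity": self.sensitivity,
            "fdr": self.fdr,
            "hamming_norm": self.hamming_norm,
            "module_size": self.module_size,
        }
        row.update(self.scenario)
        return row


def _truth_mask(truth, T_hint: int | None = None) -> np.ndarray:
    if isinstance(truth, SimDataset):
        return truth.functional_mask
    mask = np.asarray(truth)
    if mask.dtype != bool:
        # index array
        idx = mask.astype(int)
        if T_hint is None:
            raise ValueError("need total variable count to interpret index truth")
        mask = np.zeros(T_hint, dtype=bool)
        mask[idx] = True
    return mask


def score_selection(sel, truth, scenario: dict | None = None) -> EvalResult:
    """Score one selection against the true module membership.

    Parameters
    ----------
    sel : ModuleSelection or array of indices
    truth : SimDataset or boolean mask over all T variables
    scenario : dict, optional
        Metadata (e.g. n, snr, r_m) carried into the result.
    """
    if isinstance(sel, ModuleSelection):
        indices = np.asarray(sel.indices, dtype=int)
        tag = sel.method_tag
    else:
        indices = np.asarray(sel, dtype=int)
        tag = ""
    if indices.size == 0:
        raise ValueError("empty selection cannot be scored")
    mask = _truth_mask(truth)
    T = mask.size
    selected = np.zeros(T, dtype=bool)
    selected[indices] = True
    tp = int(np.sum(selected & mask))
    fp = int(np.sum(selected & ~mask))
    fn = int(np.sum(~selected & mask))
    true_size = int(mask.sum())
    sensitivity = tp / true_size if true_size else float("nan")
    fdr = fp / indices.size
    hamming = 100.0 * (fp + fn) / T
    return EvalResult(
        sensitivity=sensitivity,
        fdr=fdr,
        hamming_norm=hamming,
        module_size=int(indices.size),
        method_tag=tag,
        scenario=dict(scenario or {}),
    )


_METRICS = ("sensitivity", "fdr", "hamming_norm", "module_size")


def aggregate(results, groupby=None) -> pd.DataFrame:
    """Median and quartiles of each metric per (method, scenario) cell.

    Pass ``groupby`` to control pooling, e.g. drop ``"r_m"`` to pool the
    correlation grid.  Quartiles use linear interpolation (type 7), recorded
    in ``DataFrame.attrs['quantile_method']``.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to aggregate")
    df = pd.DataFrame([r.to_row() for r in results])
    if groupby is None:
        groupby = ["method"] + [
            col for col in ("n", "snr", "r_m", "random_signs") if col in df.columns
        ]
    long = df.melt(
        id_vars=[c for c in groupby if c in df.columns],
        value_vars=[m for m in _METRICS if m in df.columns],
        var_name="metric",
    )
    out = (
        long.groupby([c for c in groupby if c in long.columns] + ["metric"])["value"]
        .agg(
            q25=lambda s: s.quantile(0.25),
            median="median",
            q75=lambda s: s.quantile(0.75),
            n_obs="count",
        )
        .reset_index()
    )
    out.attrs["quantile_method"] = "linear interpolation (type 7)"
    return out


def load_external_selection(
    path, X: PredictorMatrix, method_tag: str = "external"
) -> ModuleSelection:
    """Load a selection produced elsewhere: one variable name per line.

    Lets module selections from external tools (e.g. co-expression
    clustering pipelines) be scored on the same footing.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"selection file {path} is empty")
    lookup = {name: i for i, name in enumerate(X.names)}
    unknown = [nm for nm in lines if nm not in lookup]
    if unknown:
        raise ValueError(
            "unknown variable name(s) in selection file: " + ", ".join(unknown[:10])
        )
    indices = np.array(sorted(lookup[nm] for nm in lines), dtype=int)
    return ModuleSelection(
        indices=indices,
        names=[X.names[i] for i in indices],
        k_opt=None,
        loadings=None,
        balance=None,
        method_tag=method_tag,
    )
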