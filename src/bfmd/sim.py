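"""Synthetic single-input-module (SIM) data generator.

A SIM is a network motif in which one transcription factor (the hub) drives
a set of target genes.  It is modeled as a latent factor: for each module,
an unobserved hub x0 ~ N(0, 1) generates observed members

    x_i = pi_i * beta * x0 + eps_i,      eps_i ~ N(0, 1),

with pi_i in {-1, +1} the edge sign and beta = sqrt(r_m / (1 - r_m)), so
that in population |corr(x_i, x_j)| = r_m and corr(x_i, x0) = sqrt(r_m).
Tracing paths shows a SIM is a *balanced* functional module: members whose
correlation with the outcome shares a sign are positively correlated with
each other, members with opposite outcome signs are negatively correlated.

Exactly one module is functional: its hub drives the outcome

    Y = alpha * x0 + sum_j alpha * v_j + delta,     delta ~ N(0, sigma_d^2),

with alpha = 1; the v_j are a handful of independent outcome-associated
variables representing nonmodular influences, each entering Y with the
hub's coefficient so its signal-to-noise ratio matches the hub's.  SNR is
defined as alpha * sd(x0) / sigma_d, hence sigma_d = alpha / snr.  The
remaining variables are pure noise, variance-matched to module members
(variance 1 + beta^2) so no method can select on marginal variance alone.
Columns are shuffled; ground-truth labels track the shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import OutcomeVector, PredictorMatrix

__all__ = ["SimConfig", "SimDataset", "simulate", "scenario_grid"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset.

    Defaults reproduce the standard study design: 5 modules of 20 members,
    1000 irrelevant noise variables and 5 independent outcome-associated
    variables, for 1105 variables in total, with only the first module
    functional.
    """

    n: int = 100
    n_modules: int = 5
    module_size: int = 20
    n_noise: int = 1000
    n_independent: int = 5
    r_m: float = 0.5
    snr: float = 0.3
    random_signs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("n", "n_modules", "module_size", "n_noise", "n_independent"):
            if getattr(self, attr) < 0 or (
                attr in ("n", "n_modules", "module_size") and getattr(self, attr) <= 0
            ):
                raise ValueError(f"{attr} must be positive, got {getattr(self, attr)}")
        if not 0.0 < self.r_m < 1.0:
            raise ValueError(f"r_m must be in (0, 1), got {self.r_m}")
        if self.snr <= 0.0:
            raise ValueError(f"snr must be positive, got {self.snr}")

    @property
    def n_variables(self) -> int:
        return self.n_modules * self.module_size + self.n_noise + self.n_independent

    @property
    def beta(self) -> float:
        """Hub loading giving intramodular correlation r_m in population."""
        return float(np.sqrt(self.r_m / (1.0 - self.r_m)))


@dataclass
class SimDataset:
    """Generated data plus ground truth.

    ``truth`` has one row per (shuffled) column of X with columns
    ``name``, ``role`` in {functional, inert, noise, independent},
    ``module`` (index or -1) and ``sign`` (pi_i, 0 for non-members).
    """

    X: PredictorMatrix
    Y: OutcomeVector
    truth: pd.DataFrame
    config: SimConfig

    @property
    def functional_mask(self) -> np.ndarray:
        return (self.truth["role"] == "functional").to_numpy()

    @property
    def functional_indices(self) -> np.ndarray:
        return np.flatnonzero(self.functional_mask)


def simulate(config: SimConfig) -> SimDataset:
    """Draw one SIM dataset.  Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    beta = config.beta
    alpha = 1.0
    sigma_delta = alpha / config.snr

    columns: list[np.ndarray] = []
    names: list[str] = []
    roles: list[str] = []
    modules: list[int] = []
    signs: list[float] = []

    y_hub = None
    for m in range(config.n_modules):
        hub = rng.standard_normal(n)
        if m == 0:
            y_hub = hub
        if config.random_signs:
            pi = rng.choice([-1.0, 1.0], size=config.module_size)
        else:
            pi = np.ones(config.module_size)
        eps = rng.standard_normal((n, config.module_size))
        members = np.outer(hub, pi * beta) + eps
        for j in range(config.module_size):
            columns.append(members[:, j])
            names.append(f"mod{m + 1}_g{j + 1:03d}")
            roles.append("functional" if m == 0 else "inert")
            modules.append(m)
            signs.append(float(pi[j]))

    noise_sd = float(np.sqrt(1.0 + beta**2))
    noise = rng.standard_normal((n, config.n_noise)) * noise_sd
    for j in range(config.n_noise):
        columns.append(noise[:, j])
        names.append(f"noise_{j + 1:04d}")
        roles.append("noise")
        modules.append(-1)
        signs.append(0.0)

    indep = rng.standard_normal((n, config.n_independent))
    for j in range(config.n_independent):
        columns.append(indep[:, j])
        names.append(f"indep_{j + 1}")
        roles.append("independent")
        modules.append(-1)
        signs.append(0.0)

    delta = rng.standard_normal(n) * sigma_delta
    y = alpha * y_hub + alpha * indep.sum(axis=1) + delta

    Xmat = np.column_stack(columns)
    perm = rng.permutation(Xmat.shape[1])
    Xmat = Xmat[:, perm]
    truth = pd.DataFrame(
        {
            "name": [names[i] for i in perm],
            "role": [roles[i] for i in perm],
            "module": [modules[i] for i in perm],
            "sign": [signs[i] for i in perm],
        }
    )
    X = PredictorMatrix(Xmat, list(truth["name"]))
    return SimDataset(X=X, Y=OutcomeVector(y), truth=truth, config=config)


def scenario_grid(
    snr_list,
    r_m_list,
    n_list,
    sign_modes,
    n_reps: int,
    base_seed: int = 0,
):
    """Deterministically enumerate configs for a full scenario grid.

    Yields ``SimConfig`` objects for every combination of sample size, SNR,
    intramodular correlation and sign mode, ``n_reps`` replicates each, with
    per-replicate seeds derived reproducibly from ``base_seed``.
    """
    snr_list = list(snr_list)
    r_m_list = list(r_m_list)
    n_list = list(n_list)
    sign_modes = list(sign_modes)
    if not (snr_list and r_m_list and n_list and sign_modes and n_reps > 0):
        raise ValueError("scenario lists must be nonempty and n_reps positive")
    scenario_idx = 0
    for n in n_list:
        for snr in snr_list:
            for r_m in r_m_list:
                for random_signs in sign_modes:
                    for rep in range(n_reps):
                        ss = np.random.SeedSequence(
                            entropy=base_seed, spawn_key=(scenario_idx, rep)
                        )
                        seed = int(ss.generate_state(1)[0] % (2**31))
                        yield SimConfig(
                            n=n,
                            snr=snr,
                            r_m=r_m,
                            random_signs=bool(random_signs),
                            seed=seed,
                        )
                    scenario_idx += 1


def write_dataset(ds: SimDataset, prefix) -> None:
    """Write X, Y and the truth labels as TSV files under ``prefix``."""
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ds.X.values, columns=ds.X.names).to_csv(
        f"{prefix}_X.tsv", sep="\t", index=False
    )
    pd.DataFrame({"Y": ds.Y.values}).to_csv(f"{prefix}_Y.tsv", sep="\t", index=False)
    ds.truth.to_csv(f"{prefix}_truth.tsv", sep="\t", index=False)
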