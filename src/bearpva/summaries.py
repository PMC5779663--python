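"""Trajectory summaries and train/holdout partitioning.

Turns simulated trajectories into the analysis rows used by the
classification stage: a binary persistence label (extant at the end of the
horizon), short-window mean predictors, and reproducible disjoint
training/holdout partitions of the trajectory table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .projection import Trajectory

EXTINCT = "EXTINCT"
EXTANT = "EXTANT"

#: Short-term predictors derived from the first ``window`` projection years.
SHORT_TERM_VARS: tuple[str, ...] = ("Nbar5", "phibar5", "lambdabar5")


def label_extant(trajectory: Trajectory) -> str:
    """Label a trajectory ``EXTANT`` iff its final abundance is >= 1."""
    return EXTANT if trajectory.N[-1] >= 1 else EXTINCT


def five_year_means(trajectory: Trajectory, window: int = 5) -> tuple[float, float, float]:
    """Mean abundance, survival and growth rate over years ``1..window``.

    Abundance averages ``N_1..N_window`` (the initial abundance ``N_0`` is
    excluded — it is a configuration input, not an observed outcome). The
    rate means use the latent annual rates, which remain defined even after
    the population hits zero, and the growth-rate mean is computed from
    ``lambda_t = phi_t + f_t`` rather than abundance ratios so it never
    divides by zero at extinction.
    """
    if window > trajectory.T:
        raise ValueError(f"window {window} exceeds trajectory horizon {trajectory.T}")
    if window < 1:
        raise ValueError("window must be >= 1")
    nbar = float(trajectory.N[1 : window + 1].mean())
    phibar = float(trajectory.phi_annual[:window].mean())
    lambdabar = float(trajectory.lambda_annual[:window].mean())
    return nbar, phibar, lambdabar


@dataclass
class DataPartition:
    """Disjoint training/holdout split of a trajectory table."""

    train: pd.DataFrame
    holdout: pd.DataFrame
    train_indices: np.ndarray
    holdout_indices: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_indices, self.holdout_indices).size:
            raise ValueError("training and holdout indices overlap")


def build_datasets(
    table: pd.DataFrame,
    n_train: int,
    n_holdout: int,
    rng: np.random.Generator | int | None = None,
) -> DataPartition:
    """Sample disjoint training and holdout sets from a trajectory table.

    Training rows are drawn without replacement; holdout rows are drawn
    without replacement from the remaining rows. Row positions (not index
    labels) are recorded for audit.
    """
    seed = rng if isinstance(rng, int) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(table)
    if n_train < 0 or n_holdout < 0:
        raise ValueError("partition sizes must be nonnegative")
    if n_train + n_holdout > n:
        raise ValueError(
            f"cannot draw n_train={n_train} plus n_holdout={n_holdout} from {n} rows"
        )
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    holdout_idx = np.sort(perm[n_train : n_train + n_holdout])
    return DataPartition(
        train=table.iloc[train_idx].reset_index(drop=True),
        holdout=table.iloc[holdout_idx].reset_index(drop=True),
        train_indices=train_idx,
        holdout_indices=holdout_idx,
        seed=seed,
    )
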