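"""Headline analyses at the package's standard scaled-down design.

The reference experiment simulates 2,000 parameter combinations x 500
trajectories (1e6 rows) per subpopulation; the functions here default to a
1/10-scale design (400 x 250 = 100,000 rows, 50,000 training / 10,000
holdout) that preserves combination-level replication and runs in minutes
on one core. They are the computations behind the two headline numbers:

* the persistence probability of trajectories whose 5-year mean apparent
  survival exceeds a candidate trigger, and
* the survival-only monitoring threshold extracted from a single
  conditional classification tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .citree import grow_tree
from .design_space import load_param_ranges
from .projection import DEFAULT_N0, SimulationConfig, run_experiment
from .summaries import SHORT_TERM_VARS, build_datasets
from .thresholds import enumerate_scenarios, min_survival_threshold, reliable_scenarios

DEFAULT_N_COMBOS = 400
DEFAULT_N_TRAJ = 250
DEFAULT_N_TRAIN = 50_000
DEFAULT_N_HOLDOUT = 10_000


def simulate_subpopulation(
    subpopulation: str,
    seed: int | np.random.SeedSequence,
    n_combos: int = DEFAULT_N_COMBOS,
    n_traj: int = DEFAULT_N_TRAJ,
    n0: int | None = None,
    horizon: int = 100,
) -> pd.DataFrame:
    """Simulate the scaled-down Monte-Carlo design for one subpopulation."""
    ranges = load_param_ranges(subpopulation)
    config = SimulationConfig(
        N0=DEFAULT_N0[subpopulation] if n0 is None else n0,
        T=horizon,
        n_traj=n_traj,
    )
    return run_experiment(ranges, n_combos, config, seed=seed)


@dataclass(frozen=True)
class ConditionalPersistence:
    """Persistence among trajectories whose phibar5 exceeds a trigger."""

    trigger: float
    n_above: int
    n_extant: int

    @property
    def percent_extant(self) -> float:
        return 100.0 * self.n_extant / self.n_above


def conditional_persistence(
    table: pd.DataFrame,
    trigger: float = 0.91,
) -> ConditionalPersistence:
    """Fraction of trajectories with ``phibar5 > trigger`` extant at horizon."""
    above = table[table["phibar5"] > trigger]
    if len(above) == 0:
        raise ValueError(f"no trajectories with phibar5 > {trigger}")
    return ConditionalPersistence(
        trigger=trigger,
        n_above=len(above),
        n_extant=int(above["extant"].sum()),
    )


@dataclass(frozen=True)
class SurvivalThresholdResult:
    threshold: float | None
    n_train: int
    n_scenarios: int
    n_reliable: int


def survival_threshold_from_table(
    table: pd.DataFrame,
    seed: int | np.random.SeedSequence,
    n_train: int = DEFAULT_N_TRAIN,
    n_holdout: int = DEFAULT_N_HOLDOUT,
    maxdepth: int = 4,
    min_persistence: float = 0.95,
) -> SurvivalThresholdResult:
    """Grow the single short-term tree and extract the survival trigger.

    Partitions the table, grows one conditional tree on the 5-year mean
    predictors (all three tested at every split), enumerates leaf
    scenarios, filters to those with persistence >= ``min_persistence``
    and returns the minimum survival-only lower bound.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_part, s_tree = ss.spawn(2)
    partition = build_datasets(
        table, n_train, n_holdout, rng=np.random.Generator(np.random.PCG64(s_part))
    )
    tree = grow_tree(
        partition.train[list(SHORT_TERM_VARS)],
        partition.train["extant"].to_numpy(),
        maxdepth=maxdepth,
        mtry=len(SHORT_TERM_VARS),
        rng=np.random.Generator(np.random.PCG64(s_tree)),
    )
    scenarios = enumerate_scenarios(tree)
    reliable = reliable_scenarios(scenarios, min_persistence)
    return SurvivalThresholdResult(
        threshold=min_survival_threshold(reliable),
        n_train=len(partition.train),
        n_scenarios=len(scenarios),
        n_reliable=len(reliable),
    )
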