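"""Configuration, file round-trips and the one-call full pipeline.

The pipeline chains: simulate trajectories -> summarise/partition ->
forests on long-term (generating parameters) and short-term (5-year mean)
predictors with importance and holdout error rates -> single short-term
tree -> scenario enumeration -> survival threshold. All artifacts are
plain CSV/JSON plus a provenance manifest; a fixed master seed makes every
artifact byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .citree import (
    classification_error,
    forest_to_dict,
    grow_forest,
    grow_tree,
    permutation_importance,
    predict,
    tree_to_dict,
)
from .design_space import PARAM_NAMES, load_param_ranges
from .projection import (
    DEFAULT_F_MAX,
    DEFAULT_N0,
    TABLE_COLUMNS,
    SimulationConfig,
    run_experiment,
)
from .summaries import SHORT_TERM_VARS, build_datasets
from .thresholds import (
    enumerate_scenarios,
    min_survival_threshold,
    reliable_scenarios,
    render_tree,
    scenarios_to_dict,
)

logger = logging.getLogger("bearpva")

LONG_TERM_VARS: tuple[str, ...] = PARAM_NAMES


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one end-to-end run."""

    subpopulation: str
    seed: int
    n_combos: int = 400
    n_traj: int = 250
    n0: int | None = None  # None -> packaged default for the subpopulation
    horizon: int = 100
    n_train: int = 50_000
    n_holdout: int = 10_000
    window: int = 5
    param_overrides: dict | None = None
    ntree: int = 100
    mtry_long: int = 5
    mtry_short: int = 3
    maxdepth: int = 4
    alpha: float = 0.05
    minsplit: int = 20
    minbucket: int = 7
    subsample_fraction: float = 0.632
    min_persistence: float = 0.95
    N_max: int = 100_000
    f_max: float = DEFAULT_F_MAX
    write_trajectories: bool = True

    def resolved_n0(self) -> int:
        return DEFAULT_N0[self.subpopulation] if self.n0 is None else self.n0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: config file must contain a mapping")
    return PipelineConfig.from_dict(payload)


def config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


# ---------------------------------------------------------------------------
# file round-trips
# ---------------------------------------------------------------------------


def write_trajectory_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_trajectory_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing trajectory-table columns {missing}")
    return table


def save_json(payload, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_json(path: str | Path):
    text = Path(path).read_text()
    try:
        return json.loads(text)
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: malformed JSON at line {e.lineno} column {e.colno}: {e.msg}") from e


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _fit_forest_stage(
    partition,
    predictors,
    mtry: int,
    config: PipelineConfig,
    rng: np.random.Generator,
):
    train_X = partition.train[list(predictors)]
    train_y = partition.train["extant"].to_numpy()
    forest = grow_forest(
        train_X,
        train_y,
        ntree=config.ntree,
        mtry=mtry,
        maxdepth=config.maxdepth,
        subsample_fraction=config.subsample_fraction,
        alpha=config.alpha,
        minsplit=config.minsplit,
        minbucket=config.minbucket,
        rng=rng,
    )
    importance = permutation_importance(forest, train_X, train_y, rng=rng)
    pred, _ = predict(forest, partition.holdout[list(predictors)])
    errors = classification_error(pred, partition.holdout["extant"].to_numpy())
    return forest, importance, errors


def run_full_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write all artifacts under ``out_dir``.

    Returns a dict with the in-memory results and the artifact paths.
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    # named substreams, fixed order: simulate, partition, forest_long,
    # forest_short, tree
    s_sim, s_part, s_flong, s_fshort, s_tree = ss.spawn(5)
    results: dict = {"artifacts": {}}

    def _artifact(name: str, path: Path) -> None:
        results["artifacts"][name] = str(path)

    stage = "simulate"
    try:
        ranges = load_param_ranges(config.subpopulation, config.param_overrides)
        sim_config = SimulationConfig(
            N0=config.resolved_n0(),
            T=config.horizon,
            n_traj=config.n_traj,
            N_max=config.N_max,
            f_max=config.f_max,
        )
        table = run_experiment(
            ranges, config.n_combos, sim_config, seed=s_sim, window=config.window
        )
        logger.info("simulate: %d trajectories (%s)", len(table), config.subpopulation)
        if config.write_trajectories:
            path = out / "trajectories.csv"
            write_trajectory_table(table, path)
            _artifact("trajectories", path)
        results["table"] = table

        stage = "partition"
        partition = build_datasets(
            table,
            config.n_train,
            config.n_holdout,
            rng=np.random.Generator(np.random.PCG64(s_part)),
        )
        logger.info("partition: %d train / %d holdout", len(partition.train), len(partition.holdout))
        idx = pd.DataFrame(
            {
                "row": np.concatenate([partition.train_indices, partition.holdout_indices]),
                "set": ["train"] * len(partition.train_indices)
                + ["holdout"] * len(partition.holdout_indices),
            }
        )
        path = out / "partition_indices.csv"
        idx.to_csv(path, index=False)
        _artifact("partition_indices", path)
        results["partition"] = partition

        stage = "forest_long_term"
        forest_l, imp_l, err_l = _fit_forest_stage(
            partition,
            LONG_TERM_VARS,
            config.mtry_long,
            config,
            np.random.Generator(np.random.PCG64(s_flong)),
        )
        logger.info(
            "forest_long_term: overall error %.3f, type II %s", err_l.overall, err_l.type2
        )

        stage = "forest_short_term"
        forest_s, imp_s, err_s = _fit_forest_stage(
            partition,
            SHORT_TERM_VARS,
            config.mtry_short,
            config,
            np.random.Generator(np.random.PCG64(s_fshort)),
        )
        logger.info(
            "forest_short_term: overall error %.3f, type II %s", err_s.overall, err_s.type2
        )
        for name, imp, err, forest in (
            ("long_term", imp_l, err_l, forest_l),
            ("short_term", imp_s, err_s, forest_s),
        ):
            path = out / f"importance_{name}.csv"
            imp.rename_axis("variable").to_csv(path)
            _artifact(f"importance_{name}", path)
            path = out / f"errors_{name}.json"
            save_json(
                {
                    "overall": err.overall,
                    "type2": err.type2,
                    "confusion": {
                        "extinct_correct": err.extinct_correct,
                        "extinct_predicted_extant": err.extinct_predicted_extant,
                        "extant_predicted_extinct": err.extant_predicted_extinct,
                        "extant_correct": err.extant_correct,
                    },
                },
                path,
            )
            _artifact(f"errors_{name}", path)
        path = out / "forest_short_term.json"
        save_json(forest_to_dict(forest_s), path)
        _artifact("forest_short_term", path)
        results.update(
            forest_long=forest_l,
            forest_short=forest_s,
            importance_long=imp_l,
            importance_short=imp_s,
            errors_long=err_l,
            errors_short=err_s,
        )

        stage = "tree"
        tree = grow_tree(
            partition.train[list(SHORT_TERM_VARS)],
            partition.train["extant"].to_numpy(),
            alpha=config.alpha,
            maxdepth=config.maxdepth,
            minsplit=config.minsplit,
            minbucket=config.minbucket,
            mtry=config.mtry_short,
            rng=np.random.Generator(np.random.PCG64(s_tree)),
        )
        path = out / "tree.json"
        save_json(tree_to_dict(tree), path)
        _artifact("tree", path)
        path = out / "tree.txt"
        path.write_text(render_tree(tree) + "\n")
        _artifact("tree_text", path)
        results["tree"] = tree

        stage = "scenarios"
        scenarios = enumerate_scenarios(tree)
        reliable = reliable_scenarios(scenarios, config.min_persistence)
        path = out / "scenarios.json"
        save_json(
            {
                "all": scenarios_to_dict(scenarios),
                "reliable": scenarios_to_dict(reliable),
                "min_persistence": config.min_persistence,
            },
            path,
        )
        _artifact("scenarios", path)
        results["scenarios"] = scenarios
        results["reliable"] = reliable
        logger.info("scenarios: %d total, %d reliable", len(scenarios), len(reliable))

        stage = "thresholds"
        threshold = min_survival_threshold(reliable)
        path = out / "thresholds.json"
        save_json(
            {
                "survival_threshold": threshold,
                "survival_threshold_rounded": None if threshold is None else round(threshold, 2),
                "min_persistence": config.min_persistence,
            },
            path,
        )
        _artifact("thresholds", path)
        results["survival_threshold"] = threshold
        logger.info("thresholds: survival-only trigger %s", threshold)

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "config_sha256": config_hash(config),
            "package_version": __version__,
            "rows": len(table),
            "artifacts": sorted(results["artifacts"]),
        }
        path = out / "manifest.json"
        save_json(manifest, path)
        _artifact("manifest", path)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        logger.error("stage '%s' failed: %s", stage, e)
        raise PipelineError(stage, e) from e
    return results
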