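"""Conditional-inference classification trees and forests, from scratch.

Recursive partitioning in which split *variables* are chosen by permutation
tests of independence between each candidate predictor and the binary
response, with Bonferroni adjustment over the candidates tested at a node.
This separates variable selection from split-point search and avoids the
selection bias toward many-valued predictors that exhaustive-search trees
(CART-style) suffer from.

The test statistic at a node is the linear association statistic

    T = sum_i x_i * 1(y_i = 1)

standardised by its exact permutation moments: with ``n`` rows of which
``m`` have ``y = 1``,

    E[T]   = m * mean(x)
    Var[T] = m (n - m) / (n - 1) * mean((x - mean(x))^2)

Asymptotically ``z = (T - E)/sqrt(Var)`` is standard normal; for small
nodes the permutation distribution is enumerated exactly (or sampled by
Monte Carlo when enumeration is infeasible), with the two-sided p-value
``P(|T* - E| >= |T - E|)``.

Forests grow ``ntree`` such trees on without-replacement subsamples, with
``mtry`` candidate variables per split, and score variables by the mean
out-of-bag accuracy drop under per-variable permutation.

The response is encoded 0 = EXTINCT, 1 = EXTANT throughout; prediction
ties at probability 0.5 resolve to EXTANT so that any ambiguity surfaces
as a Type II error (predicting persistence for an extinct trajectory)
rather than being hidden.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

EXTINCT, EXTANT = 0, 1

#: Node sizes below which the exact/Monte-Carlo permutation distribution is
#: used instead of the normal approximation.
EXACT_NODE_SIZE = 30

#: Largest number of distinct labelings enumerated exhaustively before
#: falling back to Monte-Carlo permutation sampling.
_MAX_ENUMERATION = 200_000


# ---------------------------------------------------------------------------
# independence test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitTestResult:
    """Outcome of one variable-vs-response permutation test."""

    statistic: float
    p_raw: float
    p_adjusted: float


def _permutation_moments(x: np.ndarray, m: int) -> tuple[float, float]:
    n = len(x)
    xbar = x.mean()
    var_x = np.mean((x - xbar) ** 2)
    mean_T = m * xbar
    # Var[sum_{i in S} x_i] over uniform m-subsets S = m(n-m)/(n-1) * (1/n) sum (x_i - xbar)^2
    var_T = m * (n - m) / (n - 1) * var_x
    return float(mean_T), float(var_T)


def independence_test(
    x: Sequence[float] | np.ndarray,
    y: Sequence[int] | np.ndarray,
    mode: str = "asymptotic",
    rng: np.random.Generator | None = None,
    n_perm: int = 9_999,
    n_adjust: int = 1,
) -> SplitTestResult:
    """Permutation test of independence between ``x`` and binary ``y``.

    Parameters
    ----------
    mode
        ``"asymptotic"`` uses the standard-normal reference for the
        standardised statistic; ``"exact"`` enumerates all labelings when
        feasible, otherwise samples ``n_perm`` random labelings.
    n_adjust
        Number of candidate variables over which the caller is testing;
        ``p_adjusted = min(1, p_raw * n_adjust)`` (Bonferroni).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"x and y must have equal length, got {x.shape} vs {y.shape}")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    m = int(np.sum(y == 1))

    def _result(stat: float, p: float) -> SplitTestResult:
        return SplitTestResult(stat, p, min(1.0, p * max(1, n_adjust)))

    if m == 0 or m == n or np.all(x == x[0]):
        return _result(0.0, 1.0)

    T = float(x[y == 1].sum())
    mean_T, var_T = _permutation_moments(x, m)
    z = (T - mean_T) / math.sqrt(var_T)

    if mode == "asymptotic":
        p = 2.0 * float(norm.sf(abs(z)))
        return _result(z, min(1.0, p))
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")

    obs_dev = abs(T - mean_T)
    tol = 1e-9 * (1.0 + obs_dev)
    if math.comb(n, m) <= _MAX_ENUMERATION:
        count = 0
        total = 0
        for subset in combinations(range(n), m):
            total += 1
            if abs(x[list(subset)].sum() - mean_T) >= obs_dev - tol:
                count += 1
        p = count / total
    else:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        # sample m-subsets via random keys; vectorised over permutations
        keys = rng.random((n_perm, n))
        subsets = np.argsort(keys, axis=1)[:, :m]
        Ts = x[subsets].sum(axis=1)
        count = int(np.sum(np.abs(Ts - mean_T) >= obs_dev - tol))
        p = (1 + count) / (1 + n_perm)
    return _result(z, min(1.0, p))


# ---------------------------------------------------------------------------
# split selection
# ---------------------------------------------------------------------------


def select_split_variable(
    X: Mapping[str, np.ndarray],
    y: np.ndarray,
    candidate_vars: Sequence[str],
    mtry: int,
    alpha: float,
    rng: np.random.Generator,
    exact_below: int = EXACT_NODE_SIZE,
) -> tuple[str | None, SplitTestResult | None]:
    """Pick the split variable at a node, or signal stop.

    Draws ``mtry`` candidates without replacement (the draw degenerates to
    taking all variables when ``mtry`` covers them all), tests each against
    ``y``, Bonferroni-adjusts over the tested set, and returns the
    minimum-p variable if its adjusted p-value is at most ``alpha``.
    """
    if mtry > len(candidate_vars):
        raise ValueError(f"mtry={mtry} exceeds the {len(candidate_vars)} candidate variables")
    n = len(y)
    m = int(np.sum(y == 1))
    if m == 0 or m == n:
        return None, None

    if mtry == len(candidate_vars):
        tested = list(candidate_vars)
    else:
        idx = rng.choice(len(candidate_vars), size=mtry, replace=False)
        tested = [candidate_vars[i] for i in sorted(idx)]

    mode = "exact" if n < exact_below else "asymptotic"
    best_var: str | None = None
    best: SplitTestResult | None = None
    for var in tested:
        res = independence_test(X[var], y, mode=mode, rng=rng, n_adjust=len(tested))
        if best is None or res.p_raw < best.p_raw:
            best_var, best = var, res
    assert best is not None
    if best.p_adjusted <= alpha:
        return best_var, best
    return None, best


def best_split_point(
    x: np.ndarray,
    y: np.ndarray,
    minbucket: int = 7,
) -> float | None:
    """Best threshold ``c`` for the rule ``x <= c`` on a selected variable.

    Candidates are the observed values of ``x`` whose induced partition
    leaves at least ``minbucket`` rows on each side; the returned threshold
    maximises the absolute standardised two-sample statistic (equivalently
    the hypergeometric z-score of the left-side label count), with ties
    broken toward the smallest threshold. Returns ``None`` when no
    candidate is feasible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n = len(x)
    m = int(np.sum(y == 1))
    if n < 2 * minbucket or m == 0 or m == n:
        return None
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    ys = np.asarray(y[order] == 1, dtype=np.int64)
    boundaries = np.nonzero(np.diff(xs))[0]  # split after position i -> left size i+1
    if boundaries.size == 0:
        return None
    n_left = boundaries + 1
    feasible = (n_left >= minbucket) & (n - n_left >= minbucket)
    if not feasible.any():
        return None
    boundaries = boundaries[feasible]
    n_left = n_left[feasible]
    sum_left = np.cumsum(ys)[boundaries]
    mean_left = n_left * m / n
    var_left = n_left * (n - n_left) * m * (n - m) / (n**2 * (n - 1))
    z = np.abs((sum_left - mean_left) / np.sqrt(var_left))
    best = int(np.argmax(z))  # first max -> smallest threshold on ties
    return float(xs[boundaries[best]])


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Internal node (with ``var``/``threshold``/children) or leaf."""

    depth: int
    n: int
    counts: tuple[int, int]  # (n_extinct, n_extant) of training rows here
    var: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    split_test: SplitTestResult | None = None

    @property
    def is_leaf(self) -> bool:
        return self.var is None

    @property
    def extant_fraction(self) -> float:
        return self.counts[1] / self.n


@dataclass
class ConditionalTree:
    root: TreeNode
    predictors: list[str]
    settings: dict = field(default_factory=dict)

    def depth(self) -> int:
        def _d(node: TreeNode) -> int:
            if node.is_leaf:
                return node.depth
            return max(_d(node.left), _d(node.right))

        return _d(self.root)

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def _walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                _walk(node.left)
                _walk(node.right)

        _walk(self.root)
        return out


@dataclass
class ConditionalForest:
    trees: list[ConditionalTree]
    inbag: list[np.ndarray]  # per-tree in-bag row positions into the training table
    n_train: int
    predictors: list[str]
    settings: dict = field(default_factory=dict)


def _as_matrix(X, predictors: Sequence[str] | None) -> tuple[dict[str, np.ndarray], list[str]]:
    if isinstance(X, pd.DataFrame):
        cols = list(predictors) if predictors is not None else list(X.columns)
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise KeyError(f"unknown predictor names: {missing}")
        return {c: X[c].to_numpy(dtype=float) for c in cols}, cols
    if isinstance(X, Mapping):
        cols = list(predictors) if predictors is not None else list(X)
        missing = [c for c in cols if c not in X]
        if missing:
            raise KeyError(f"unknown predictor names: {missing}")
        return {c: np.asarray(X[c], dtype=float) for c in cols}, cols
    raise TypeError("X must be a DataFrame or a mapping of name -> array")


def _as_generator(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def grow_tree(
    X,
    y: Sequence[int] | np.ndarray,
    predictors: Sequence[str] | None = None,
    alpha: float = 0.05,
    maxdepth: int = 4,
    minsplit: int = 20,
    minbucket: int = 7,
    mtry: int | None = None,
    rng=None,
    exact_below: int = EXACT_NODE_SIZE,
) -> ConditionalTree:
    """Grow one conditional-inference classification tree.

    At each node: stop if the node is pure, at ``maxdepth``, or smaller
    than ``minsplit``; otherwise select a split variable by permutation
    test (Bonferroni-adjusted over the ``mtry`` tested candidates, stop if
    none reaches ``alpha``), find the best threshold honouring
    ``minbucket``, and recurse. The root is at depth 0, so ``maxdepth = 4``
    allows at most four levels of splits.
    """
    cols, names = _as_matrix(X, predictors)
    y = np.asarray(y, dtype=np.int64)
    n = len(y)
    if n == 0:
        raise ValueError("empty training set")
    for c in names:
        if len(cols[c]) != n:
            raise ValueError(f"predictor {c!r} has length {len(cols[c])}, expected {n}")
    mtry_eff = len(names) if mtry is None else mtry
    rng = _as_generator(rng)

    def _node(idx: np.ndarray, depth: int) -> TreeNode:
        yi = y[idx]
        n_i = len(idx)
        counts = (int(np.sum(yi == 0)), int(np.sum(yi == 1)))
        node = TreeNode(depth=depth, n=n_i, counts=counts)
        if counts[0] == 0 or counts[1] == 0:  # pure
            return node
        if depth >= maxdepth or n_i < minsplit:
            return node
        sub = {c: cols[c][idx] for c in names}
        var, test = select_split_variable(
            sub, yi, names, mtry_eff, alpha, rng, exact_below=exact_below
        )
        if var is None:
            return node
        thr = best_split_point(sub[var], yi, minbucket=minbucket)
        if thr is None:
            return node
        mask = sub[var] <= thr
        node.var = var
        node.threshold = thr
        node.split_test = test
        node.left = _node(idx[mask], depth + 1)
        node.right = _node(idx[~mask], depth + 1)
        return node

    root = _node(np.arange(n), 0)
    return ConditionalTree(
        root=root,
        predictors=names,
        settings={
            "alpha": alpha,
            "maxdepth": maxdepth,
            "minsplit": minsplit,
            "minbucket": minbucket,
            "mtry": mtry_eff,
        },
    )


def _tree_proba(tree: ConditionalTree, cols: Mapping[str, np.ndarray], n: int) -> np.ndarray:
    proba = np.empty(n, dtype=float)
    stack: list[tuple[TreeNode, np.ndarray]] = [(tree.root, np.arange(n))]
    while stack:
        node, idx = stack.pop()
        if idx.size == 0:
            continue
        if node.is_leaf:
            proba[idx] = node.extant_fraction
        else:
            mask = cols[node.var][idx] <= node.threshold
            stack.append((node.left, idx[mask]))
            stack.append((node.right, idx[~mask]))
    return proba


def predict(model: ConditionalTree | ConditionalForest, X) -> tuple[np.ndarray, np.ndarray]:
    """Predict classes and extant probabilities for rows of ``X``.

    Trees route each row to a leaf and report the leaf's extant fraction;
    forests average the tree probabilities. Class is 1 (EXTANT) when the
    probability is >= 0.5 — the tie goes to EXTANT deliberately.
    """
    if isinstance(model, ConditionalTree):
        cols, _ = _as_matrix(X, model.predictors)
        n = len(next(iter(cols.values())))
        proba = _tree_proba(model, cols, n)
    elif isinstance(model, ConditionalForest):
        cols, _ = _as_matrix(X, model.predictors)
        n = len(next(iter(cols.values())))
        proba = np.zeros(n, dtype=float)
        for tree in model.trees:
            proba += _tree_proba(tree, cols, n)
        proba /= len(model.trees)
    else:
        raise TypeError("model must be a ConditionalTree or ConditionalForest")
    classes = (proba >= 0.5).astype(np.int64)
    return classes, proba


def grow_forest(
    X,
    y: Sequence[int] | np.ndarray,
    predictors: Sequence[str] | None = None,
    ntree: int = 100,
    mtry: int | None = None,
    maxdepth: int = 4,
    subsample_fraction: float = 0.632,
    alpha: float = 0.05,
    minsplit: int = 20,
    minbucket: int = 7,
    rng=None,
) -> ConditionalForest:
    """Grow a forest of conditional trees on without-replacement subsamples.

    Each tree sees ``ceil(subsample_fraction * n)`` distinct rows; the
    in-bag row positions are stored so out-of-bag accuracy and importance
    are exactly reproducible.
    """
    cols, names = _as_matrix(X, predictors)
    y = np.asarray(y, dtype=np.int64)
    n = len(y)
    if n == 0:
        raise ValueError("empty training set")
    if not (0 < subsample_fraction <= 1):
        raise ValueError("subsample_fraction must be in (0, 1]")
    rng = _as_generator(rng)
    size = int(math.ceil(subsample_fraction * n))
    trees: list[ConditionalTree] = []
    inbag: list[np.ndarray] = []
    streams = rng.spawn(ntree)
    for t in range(ntree):
        r = streams[t]
        idx = np.sort(r.choice(n, size=size, replace=False))
        sub = {c: cols[c][idx] for c in names}
        tree = grow_tree(
            sub,
            y[idx],
            predictors=names,
            alpha=alpha,
            maxdepth=maxdepth,
            minsplit=minsplit,
            minbucket=minbucket,
            mtry=mtry,
            rng=r,
        )
        trees.append(tree)
        inbag.append(idx)
    return ConditionalForest(
        trees=trees,
        inbag=inbag,
        n_train=n,
        predictors=names,
        settings={
            "ntree": ntree,
            "mtry": len(names) if mtry is None else mtry,
            "maxdepth": maxdepth,
            "subsample_fraction": subsample_fraction,
            "alpha": alpha,
            "minsplit": minsplit,
            "minbucket": minbucket,
        },
    )


def permutation_importance(
    forest: ConditionalForest,
    X,
    y: Sequence[int] | np.ndarray,
    rng=None,
) -> pd.Series:
    """Out-of-bag permutation variable importance.

    For each tree and each variable: the tree's out-of-bag accuracy minus
    its accuracy after permuting that variable's values among the
    out-of-bag rows; scores are averaged over trees. Variables the forest
    never relies on score near zero; the sign can go slightly negative by
    chance.
    """
    cols, names = _as_matrix(X, forest.predictors)
    y = np.asarray(y, dtype=np.int64)
    n = forest.n_train
    rng = _as_generator(rng)
    totals = {c: 0.0 for c in names}
    used = 0
    for tree, idx in zip(forest.trees, forest.inbag):
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        n_oob = int(oob.sum())
        if n_oob == 0:
            continue
        used += 1
        sub = {c: cols[c][oob] for c in names}
        y_oob = y[oob]
        base = float(np.mean((_tree_proba(tree, sub, n_oob) >= 0.5).astype(np.int64) == y_oob))
        for c in names:
            perm = rng.permutation(n_oob)
            shuffled = dict(sub)
            shuffled[c] = sub[c][perm]
            acc = float(np.mean((_tree_proba(tree, shuffled, n_oob) >= 0.5).astype(np.int64) == y_oob))
            totals[c] += base - acc
    if used == 0:
        raise ValueError("forest has no out-of-bag rows; cannot compute importance")
    return pd.Series({c: totals[c] / used for c in names}, name="importance")


# ---------------------------------------------------------------------------
# error rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorRates:
    """Confusion table and the two headline rates.

    ``type2`` is the fraction of truly extinct trajectories predicted
    extant — the costly mistake for endangered-species decisions — with the
    truly-extinct count as denominator. It is ``None`` (not 0) when no
    truly extinct rows exist.
    """

    extinct_correct: int
    extinct_predicted_extant: int
    extant_predicted_extinct: int
    extant_correct: int

    @property
    def n(self) -> int:
        return (
            self.extinct_correct
            + self.extinct_predicted_extant
            + self.extant_predicted_extinct
            + self.extant_correct
        )

    @property
    def overall(self) -> float:
        return (self.extinct_predicted_extant + self.extant_predicted_extinct) / self.n

    @property
    def type2(self) -> float | None:
        denom = self.extinct_correct + self.extinct_predicted_extant
        if denom == 0:
            return None
        return self.extinct_predicted_extant / denom


def classification_error(predictions: np.ndarray, truth: np.ndarray) -> ErrorRates:
    """Confusion-table error rates for 0/1 (EXTINCT/EXTANT) labels."""
    predictions = np.asarray(predictions, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    if predictions.size == 0:
        raise ValueError("empty predictions")
    return ErrorRates(
        extinct_correct=int(np.sum((truth == 0) & (predictions == 0))),
        extinct_predicted_extant=int(np.sum((truth == 0) & (predictions == 1))),
        extant_predicted_extinct=int(np.sum((truth == 1) & (predictions == 0))),
        extant_correct=int(np.sum((truth == 1) & (predictions == 1))),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _node_to_dict(node: TreeNode) -> dict:
    d: dict = {"depth": node.depth, "n": node.n, "counts": list(node.counts)}
    if not node.is_leaf:
        d.update(
            var=node.var,
            threshold=node.threshold,
            left=_node_to_dict(node.left),
            right=_node_to_dict(node.right),
        )
    return d


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(depth=d["depth"], n=d["n"], counts=tuple(d["counts"]))
    if "var" in d:
        node.var = d["var"]
        node.threshold = d["threshold"]
        node.left = _node_from_dict(d["left"])
        node.right = _node_from_dict(d["right"])
    return node


def tree_to_dict(tree: ConditionalTree) -> dict:
    return {
        "kind": "conditional_tree",
        "predictors": tree.predictors,
        "settings": tree.settings,
        "root": _node_to_dict(tree.root),
    }


def tree_from_dict(d: dict) -> ConditionalTree:
    if d.get("kind") != "conditional_tree":
        raise ValueError(f"not a conditional_tree payload: kind={d.get('kind')!r}")
    return ConditionalTree(
        root=_node_from_dict(d["root"]),
        predictors=list(d["predictors"]),
        settings=dict(d["settings"]),
    )


def forest_to_dict(forest: ConditionalForest) -> dict:
    return {
        "kind": "conditional_forest",
        "predictors": forest.predictors,
        "settings": forest.settings,
        "n_train": forest.n_train,
        "inbag": [idx.tolist() for idx in forest.inbag],
        "trees": [tree_to_dict(t) for t in forest.trees],
    }


def forest_from_dict(d: dict) -> ConditionalForest:
    if d.get("kind") != "conditional_forest":
        raise ValueError(f"not a conditional_forest payload: kind={d.get('kind')!r}")
    return ConditionalForest(
        trees=[tree_from_dict(t) for t in d["trees"]],
        inbag=[np.asarray(i, dtype=np.int64) for i in d["inbag"]],
        n_train=int(d["n_train"]),
        predictors=list(d["predictors"]),
        settings=dict(d["settings"]),
    )
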