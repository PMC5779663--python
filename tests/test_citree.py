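import numpy as np
import pandas as pd
import pytest
from scipy.stats import permutation_test

from bearpva.citree import (
    best_split_point,
    classification_error,
    forest_from_dict,
    forest_to_dict,
    grow_forest,
    grow_tree,
    independence_test,
    permutation_importance,
    predict,
    select_split_variable,
    tree_from_dict,
    tree_to_dict,
)
from conftest import make_separable
from helpers import oracle_first_split


class TestIndependenceTest:
    def test_exact_worked_example(self):
        # x=[1,2,3,4], y=[0,0,1,1]: T=7, permutation mean 5, only T in {3,7}
        # as extreme among the 6 labelings -> two-sided p = 2/6
        res = independence_test([1, 2, 3, 4], [0, 0, 1, 1], mode="exact")
        assert res.p_raw == pytest.approx(1 / 3)
        assert res.statistic == pytest.approx(2 / np.sqrt(5 / 3))

    def test_constant_predictor_is_null(self):
        res = independence_test([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_one_class_response_is_null(self):
        res = independence_test([1.0, 2.0, 3.0], [1, 1, 1])
        assert res.p_raw == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            independence_test([1, 2, 3], [0, 1])

    def test_bonferroni_adjustment(self):
        res = independence_test([1, 2, 3, 4], [0, 0, 1, 1], mode="exact", n_adjust=5)
        assert res.p_adjusted == pytest.approx(min(1.0, res.p_raw * 5))

    def test_asymptotic_agrees_with_monte_carlo_oracle(self, rng):
        # moderate mean shift at n = 500: normal approximation vs scipy's
        # Monte-Carlo permutation test of the group-sum statistic
        n = 500
        y = rng.integers(0, 2, n)
        x = rng.normal(0, 1, n) + 0.13 * y
        res = independence_test(x, y, mode="asymptotic")

        def stat(a, b):
            return np.mean(a) - np.mean(b)

        oracle = permutation_test(
            (x[y == 1], x[y == 0]),
            stat,
            permutation_type="independent",
            n_resamples=10_000,
            alternative="two-sided",
            rng=np.random.default_rng(5),
        )
        assert 0.001 < res.p_raw < 0.5  # the comparison is informative
        assert abs(res.p_raw - oracle.pvalue) < 0.01

    def test_monte_carlo_fallback_agrees_with_asymptotic(self):
        # 26 choose 13 exceeds the enumeration cap, forcing the sampled
        # permutation path; at this n it should sit close to the normal
        # approximation and be reproducible under a fixed stream
        rng = np.random.default_rng(3)
        y = np.tile([0, 1], 13)
        x = rng.normal(size=26) + 0.8 * y
        mc1 = independence_test(x, y, mode="exact", rng=np.random.default_rng(0))
        mc2 = independence_test(x, y, mode="exact", rng=np.random.default_rng(0))
        asym = independence_test(x, y, mode="asymptotic")
        assert mc1.p_raw == mc2.p_raw
        assert abs(mc1.p_raw - asym.p_raw) < 0.05

    def test_exact_null_p_values_super_uniform(self):
        # discrete permutation p-values under the null: P(p <= t) <= t (+MC slack)
        reps = 300
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(reps):
            x = rng.normal(size=10)
            y = np.array([0] * 5 + [1] * 5)
            rng.shuffle(y)
            pvals.append(independence_test(x, y, mode="exact").p_raw)
        pvals = np.asarray(pvals)
        for t in (0.05, 0.1, 0.25, 0.5):
            slack = 3 * np.sqrt(t * (1 - t) / reps)
            assert np.mean(pvals <= t) <= t + slack


class TestSplitSelection:
    def test_pure_node_stops(self, rng):
        X = {"a": np.arange(10.0)}
        var, _ = select_split_variable(X, np.ones(10, dtype=int), ["a"], 1, 0.05, rng)
        assert var is None

    def test_informative_variable_beats_noise(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 1000
            y = rng.integers(0, 2, n)
            X = {
                "signal": rng.normal(0, 1, n) + 1.0 * y,
                "noise1": rng.normal(0, 1, n),
                "noise2": rng.normal(0, 1, n),
            }
            var, _ = select_split_variable(X, y, list(X), 3, 0.05, rng)
            hits += var == "signal"
        assert hits >= 19

    def test_null_acceptance_rate_bounded_by_alpha(self):
        # all-noise nodes: a split should be accepted in <= ~5% of repetitions
        reps = 300
        accepted = 0
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            n = 60
            y = rng.integers(0, 2, n)
            X = {f"v{j}": rng.normal(size=n) for j in range(3)}
            var, _ = select_split_variable(X, y, list(X), 3, 0.05, rng)
            accepted += var is not None
        rate = accepted / reps
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_best_split_separates_cleanly(self):
        x = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        assert best_split_point(x, y, minbucket=1) == 3.0

    def test_minbucket_can_forbid_all_candidates(self):
        x = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1])
        assert best_split_point(x, y, minbucket=4) is None

    def test_split_statistic_ties_break_to_smallest_threshold(self):
        # symmetric configuration: thresholds 1 and 3 give |z| = 1 each
        x = np.array([1, 2, 3, 4], dtype=float)
        y = np.array([1, 0, 0, 1])
        assert best_split_point(x, y, minbucket=1) == 1.0


class TestTreeGrowth:
    def test_pure_response_yields_single_leaf(self):
        X = pd.DataFrame({"a": np.arange(30.0)})
        tree = grow_tree(X, np.zeros(30, dtype=int), rng=0)
        assert tree.root.is_leaf and tree.depth() == 0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            grow_tree(pd.DataFrame({"a": []}), np.array([], dtype=int), rng=0)

    @pytest.mark.parametrize("maxdepth", [1, 2, 4])
    def test_depth_never_exceeds_limit(self, maxdepth):
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.normal(size=n)
        y = (x + rng.normal(0, 0.7, n) > 0).astype(int)
        X = pd.DataFrame({"x": x, "z": rng.normal(size=n)})
        tree = grow_tree(X, y, maxdepth=maxdepth, rng=1)
        assert 1 <= tree.depth() <= maxdepth

    def test_separable_data_classified_perfectly(self, separable):
        X, y = separable
        tree = grow_tree(X, y, rng=0)
        classes, proba = predict(tree, X)
        assert np.array_equal(classes, y)
        assert np.all((proba == 0.0) | (proba == 1.0))

    def test_first_split_matches_exhaustive_oracle(self):
        # small instances, exact permutation mode: the grown root split must
        # equal the brute-force (variable, threshold) enumeration
        checked = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.array([0] * 6 + [1] * 6)
            X = pd.DataFrame(
                {
                    "a": rng.normal(0, 1, 12) + 1.2 * y,
                    "b": rng.normal(0, 1, 12),
                }
            )
            var, p, thr = oracle_first_split(X, y)
            if p > 0.4:
                continue
            tree = grow_tree(X, y, alpha=0.9, maxdepth=1, minsplit=2, minbucket=1, rng=0)
            assert not tree.root.is_leaf
            assert tree.root.var == var
            assert tree.root.threshold == pytest.approx(thr)
            checked += 1
        assert checked >= 5

    def test_row_order_permutation_invariance(self, separable):
        X, y = separable
        perm = np.random.default_rng(9).permutation(len(y))
        t1 = grow_tree(X, y, rng=0)
        t2 = grow_tree(X.iloc[perm].reset_index(drop=True), y[perm], rng=0)
        assert tree_to_dict(t1) == tree_to_dict(t2)

    def test_leaf_probability_equals_count_ratio(self, separable):
        X, y = separable
        tree = grow_tree(X, y, rng=0)
        for leaf in tree.leaves():
            assert leaf.extant_fraction == leaf.counts[1] / leaf.n
            assert sum(leaf.counts) == leaf.n


class TestPrediction:
    def test_single_leaf_tree_predicts_majority_everywhere(self):
        X = pd.DataFrame({"a": np.arange(40.0)})
        y = np.array([1] * 30 + [0] * 10)
        tree = grow_tree(X, y, alpha=1e-9, rng=0)  # stringent alpha -> leaf
        assert tree.root.is_leaf
        classes, proba = predict(tree, X)
        assert np.all(classes == 1) and np.all(proba == 0.75)

    def test_probability_tie_resolves_to_extant(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        tree = grow_tree(X, np.array([0, 1]), rng=0)
        classes, proba = predict(tree, X)
        assert proba[0] == 0.5 and classes[0] == 1

    def test_degenerate_forest_equals_single_tree(self, separable):
        X, y = separable
        forest = grow_forest(X, y, ntree=1, subsample_fraction=1.0, rng=3)
        tree = forest.trees[0]
        np.testing.assert_array_equal(predict(forest, X)[1], predict(tree, X)[1])

    def test_unknown_predictor_names_rejected(self, separable):
        X, y = separable
        tree = grow_tree(X, y, rng=0)
        with pytest.raises(KeyError):
            predict(tree, pd.DataFrame({"wrong": [1.0]}))


class TestForest:
    def test_holdout_accuracy_on_separable_fixture(self):
        X, y = make_separable(seed=1)
        Xh, yh = make_separable(seed=2, shrink=0.1)
        forest = grow_forest(X, y, ntree=20, rng=4)
        classes, _ = predict(forest, Xh)
        assert np.array_equal(classes, yh)

    def test_matches_sklearn_random_forest_on_separable_fixture(self):
        from sklearn.ensemble import RandomForestClassifier

        X, y = make_separable(seed=3)
        Xh, yh = make_separable(seed=4, shrink=0.1)
        ours, _ = predict(grow_forest(X, y, ntree=20, rng=5), Xh)
        sk = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y).predict(Xh)
        assert np.mean(ours == yh) == np.mean(sk == yh) == 1.0

    def test_every_row_out_of_bag_with_expected_frequency(self):
        n = 200
        X, y = make_separable(n=n, seed=5)
        forest = grow_forest(X, y, ntree=100, subsample_fraction=0.632, rng=6)
        oob_counts = np.full(n, 100)
        for idx in forest.inbag:
            oob_counts[idx] -= 1
        # per-row OOB count ~ Binomial(100, 0.368): mean 36.8
        assert oob_counts.min() >= 1
        assert 33 < oob_counts.mean() < 41

    def test_importance_ranks_informative_variable_first(self):
        wins = 0
        for seed in range(10):
            X, y = make_separable(n=300, seed=seed)
            forest = grow_forest(X, y, ntree=30, rng=seed)
            imp = permutation_importance(forest, X, y, rng=seed)
            wins += imp.idxmax() == "informative"
        assert wins >= 9

    def test_noise_variable_importance_near_zero(self):
        X, y = make_separable(n=300, seed=7)
        forest = grow_forest(X, y, ntree=30, rng=8)
        imp = permutation_importance(forest, X, y, rng=9)
        assert abs(imp["noise0"]) < 0.02 and abs(imp["noise1"]) < 0.02

    def test_shuffled_labels_kill_all_importance(self):
        X, y = make_separable(n=300, seed=10)
        y_shuffled = np.random.default_rng(11).permutation(y)
        forest = grow_forest(X, y_shuffled, ntree=100, rng=12)
        imp = permutation_importance(forest, X, y_shuffled, rng=13)
        assert np.all(np.abs(imp.to_numpy()) < 0.02)


class TestErrorRates:
    def test_confusion_table_arithmetic(self):
        truth = np.array([1] * 80 + [0] * 20)
        pred = truth.copy()
        pred[:5] = 0  # 5 extant -> extinct
        pred[80:85] = 1  # 5 extinct -> extant
        err = classification_error(pred, truth)
        assert err.overall == pytest.approx(0.10)
        assert err.type2 == pytest.approx(0.25)
        assert err.n == 100

    def test_perfect_predictions(self):
        truth = np.array([0, 1, 1, 0])
        err = classification_error(truth, truth)
        assert err.overall == 0.0 and err.type2 == 0.0

    def test_type2_undefined_without_extinct_rows(self):
        err = classification_error(np.ones(5, dtype=int), np.ones(5, dtype=int))
        assert err.type2 is None and err.overall == 0.0


class TestSerialization:
    def test_tree_round_trip_preserves_predictions(self, separable):
        X, y = separable
        tree = grow_tree(X, y, rng=0)
        restored = tree_from_dict(tree_to_dict(tree))
        np.testing.assert_array_equal(predict(tree, X)[1], predict(restored, X)[1])

    def test_forest_round_trip_preserves_predictions(self, separable):
        X, y = separable
        forest = grow_forest(X, y, ntree=5, rng=1)
        restored = forest_from_dict(forest_to_dict(forest))
        np.testing.assert_array_equal(predict(forest, X)[1], predict(restored, X)[1])

    def test_wrong_payload_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            tree_from_dict({"kind": "something_else"})


def test_survival_driven_extinction_ranks_survival_variables_first():
    """Positive control for the whole importance chain: when the sampling
    ranges pin recruitment low and nearly constant, extinction must be
    survival-driven, and the forests should rank mean survival (long-term)
    and 5-year mean survival (short-term) as the top variables."""
    from bearpva.design_space import PARAM_NAMES, load_param_ranges
    from bearpva.projection import SimulationConfig, run_experiment
    from bearpva.summaries import SHORT_TERM_VARS, build_datasets

    ranges = load_param_ranges(
        "TRB",
        overrides={
            "beta0f": (-2.2, -1.8),
            "beta1f": (-1e-4, -1e-5),
            "sigma_f": (0.1, 0.3),
        },
    )
    table = run_experiment(ranges, 150, SimulationConfig(N0=50, T=60, n_traj=60), seed=3)
    assert 0.2 < table["extant"].mean() < 0.95  # both classes well represented
    part = build_datasets(table, 6_000, 2_000, rng=np.random.default_rng(4))
    y = part.train["extant"].to_numpy()
    for vars_, mtry, expected_top in (
        (list(PARAM_NAMES), 5, "mu_phi"),
        (list(SHORT_TERM_VARS), 3, "phibar5"),
    ):
        forest = grow_forest(part.train[vars_], y, ntree=50, mtry=mtry, rng=np.random.default_rng(5))
        imp = permutation_importance(forest, part.train[vars_], y, rng=np.random.default_rng(6))
        assert imp.idxmax() == expected_top
        assert imp[expected_top] > 3 * imp.drop(expected_top).abs().max()
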