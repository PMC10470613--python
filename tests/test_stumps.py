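"""Decision stumps: oracle equivalence, CV mechanics, worst-rank aggregation."""

import numpy as np
import pandas as pd
import pytest

from strainpheno import (
    GenotypeSimSpec,
    PlantedFeature,
    build_feature_table,
    evaluate_features,
    fit_stump,
    join_phenotypes,
    kfold_evaluate,
    mean_threshold,
    partition_strains,
    rank_features,
    simulate_genotype_phenotype,
    stump_predict,
)
from strainpheno.stumps import FoldEvaluation, fit_stumps_matrix, rank_dataset


def brute_force_stump(x, Y):
    """Independent enumeration of every midpoint split (the oracle)."""
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    order = np.argsort(x, kind="stable")
    xs, Ys = x[order], Y[order]
    best = None
    for i in range(len(xs) - 1):
        if xs[i + 1] <= xs[i]:
            continue
        thr = 0.5 * (xs[i] + xs[i + 1])
        left, right = Ys[: i + 1], Ys[i + 1 :]
        loss = float(
            np.sum((left - left.mean(axis=0)) ** 2)
            + np.sum((right - right.mean(axis=0)) ** 2)
        )
        if best is None or loss < best[1]:
            best = (thr, loss)
    return best  # None when the feature is constant


class TestFitStump:
    def test_step_output_worked_example(self):
        """x=(1,2,3,4), Y=(0,0,1,1): threshold 2.5 splits perfectly."""
        stump = fit_stump([1, 2, 3, 4], [0.0, 0.0, 1.0, 1.0])
        assert stump.threshold == 2.5
        np.testing.assert_array_equal(stump.left_mean, [0.0])
        np.testing.assert_array_equal(stump.right_mean, [1.0])
        assert stump.train_sse == 0.0

    def test_constant_feature_is_degenerate(self):
        Y = np.array([[0.1, 0.9], [0.5, 0.5], [0.9, 0.1]])
        stump = fit_stump([2, 2, 2], Y)
        assert stump.is_degenerate
        np.testing.assert_allclose(stump.left_mean, Y.mean(axis=0))
        assert stump.train_sse == pytest.approx(
            float(np.sum((Y - Y.mean(axis=0)) ** 2))
        )

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            fit_stump([1.0], [[0.5]])

    def test_matches_brute_force_enumeration_exactly(self):
        """100 random instances, 4 outputs: loss and threshold bit-identical."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 31))
            x = rng.choice([0.0, 1, 2, 3], size=n) if rng.random() < 0.5 else rng.normal(size=n)
            Y = rng.normal(size=(n, 4))
            oracle = brute_force_stump(x, Y)
            stump = fit_stump(x, Y)
            if oracle is None:
                assert stump.is_degenerate
                continue
            assert stump.threshold == oracle[0]
            assert stump.train_sse == oracle[1]

    def test_matches_sklearn_regression_tree(self):
        """Independent cross-check against a depth-1 sklearn tree."""
        from sklearn.tree import DecisionTreeRegressor

        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            Y = rng.normal(size=(n, 4))
            stump = fit_stump(x, Y)
            tree = DecisionTreeRegressor(max_depth=1).fit(x[:, None], Y)
            sk_pred = tree.predict(x[:, None])
            sk_sse = float(np.sum((sk_pred - Y) ** 2))
            assert stump.train_sse == pytest.approx(sk_sse, rel=1e-9)

    def test_variance_bound(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=25)
        Y = rng.normal(size=(25, 4))
        stump = fit_stump(x, Y)
        grand_sse = float(np.sum((Y - Y.mean(axis=0)) ** 2))
        assert stump.train_sse <= grand_sse


class TestStumpPredict:
    def test_value_at_threshold_goes_right(self):
        stump = fit_stump([1, 2, 3, 4], [0.0, 0.0, 1.0, 1.0])
        pred = stump_predict(stump, np.array([2.5]))
        np.testing.assert_array_equal(pred, [[1.0]])

    def test_training_predictions_reproduce_leaf_means_and_sse(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        Y = rng.normal(size=(30, 4))
        stump = fit_stump(x, Y)
        pred = stump_predict(stump, x)
        left = x < stump.threshold
        assert np.allclose(pred[left], stump.left_mean)
        assert np.allclose(pred[~left], stump.right_mean)
        assert float(np.sum((pred - Y) ** 2)) == pytest.approx(stump.train_sse)


class TestMatrixPath:
    def test_matrix_fit_equals_scalar_fit_per_column(self):
        rng = np.random.default_rng(1)
        X = np.column_stack(
            [rng.normal(size=40), rng.integers(0, 3, 40).astype(float),
             np.full(40, 7.0), rng.normal(size=40)]
        )
        Y = rng.normal(size=(40, 4))
        thr, lm, rm, deg = fit_stumps_matrix(X, Y)
        for j in range(X.shape[1]):
            stump = fit_stump(X[:, j], Y)
            if stump.is_degenerate:
                assert deg[j]
                continue
            assert thr[j] == pytest.approx(stump.threshold, rel=1e-12)
            np.testing.assert_allclose(lm[j], stump.left_mean, rtol=1e-9)
            np.testing.assert_allclose(rm[j], stump.right_mean, rtol=1e-9)


class TestKFold:
    def test_folds_partition_rows_with_near_equal_sizes(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=23)
        Y = rng.normal(size=(23, 4))
        evals = kfold_evaluate(x, Y, k=5, seed=0)
        assert len(evals) == 5
        from strainpheno.stumps import kfold_folds

        folds = kfold_folds(23, k=5, seed=0)
        test_idx = np.concatenate([t for _, t in folds])
        assert sorted(test_idx) == list(range(23))
        sizes = [len(t) for _, t in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_perfect_binary_separator_has_zero_test_error(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        Y = np.tile(np.where(x[:, None] > 0.5, 0.9, 0.1), (1, 4))
        evals = kfold_evaluate(x, Y, k=5, seed=0)
        assert all(e.test_error == pytest.approx(0.0, abs=1e-30) for e in evals)

    def test_noise_features_overfit_on_average(self):
        """Test error exceeds train error for pure-noise features."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=20)
            Y = rng.normal(size=(20, 4))
            evals = kfold_evaluate(x, Y, k=5, seed=seed)
            if np.mean([e.test_error for e in evals]) >= np.mean(
                [e.train_error for e in evals]
            ):
                hits += 1
        assert hits >= 45

    def test_fewer_rows_than_folds_rejected(self):
        with pytest.raises(ValueError):
            kfold_evaluate(np.arange(3.0), np.zeros((3, 1)), k=5)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        Y = rng.normal(size=(30, 4))
        assert kfold_evaluate(x, Y, seed=42) == kfold_evaluate(x, Y, seed=42)


class TestMeanThreshold:
    def _evals(self, thresholds, degenerate=None):
        degenerate = degenerate or [False] * len(thresholds)
        return [
            FoldEvaluation(i + 1, 0.0, 0.0, t, d)
            for i, (t, d) in enumerate(zip(thresholds, degenerate))
        ]

    def test_arithmetic_mean(self):
        assert mean_threshold(self._evals([1, 2, 3, 4, 5])) == 3.0
        assert mean_threshold(self._evals([2.5] * 5)) == 2.5

    def test_degenerate_folds_excluded(self):
        evals = self._evals([1, 2, 3, 4, np.nan],
                            [False, False, False, False, True])
        with pytest.warns(UserWarning, match="degenerate fold"):
            assert mean_threshold(evals) == 2.5

    def test_all_degenerate_undefined(self):
        evals = self._evals([np.nan] * 5, [True] * 5)
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(mean_threshold(evals))


class TestRanking:
    def test_single_feature_all_ranks_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"only": rng.normal(size=10)})
        ranking = rank_dataset(X, rng.normal(size=(10, 4)), seed=0)
        row = ranking.loc["only"]
        assert row["train_rank"] == row["test_rank"] == row["worst_rank"] == 1

    def test_tied_errors_share_minimum_rank_and_order_by_name(self):
        errors = pd.DataFrame(
            {
                "mean_train_error": [0.5, 0.5, 0.1],
                "mean_test_error": [0.5, 0.5, 0.9],
            },
            index=pd.Index(["b_feat", "a_feat", "c_feat"], name="feature"),
        )
        ranking = rank_features(errors)
        assert ranking.loc["a_feat", "worst_rank"] == ranking.loc["b_feat", "worst_rank"]
        ordered = list(ranking.index)
        assert ordered.index("a_feat") < ordered.index("b_feat")

    def test_planted_feature_attains_worst_rank_one(self):
        spec = GenotypeSimSpec(
            n_genomes=80, n_noise_features=500,
            planted_features=(
                PlantedFeature("osmotic stress cluster", 0.5, (0.1, 0, 0, 0)),
            ),
            noise_sd=0.05, seed=17,
        )
        ann, tax, phen = simulate_genotype_phenotype(spec)
        ds = join_phenotypes(build_feature_table(ann, tax), phen)
        ranking = rank_dataset(ds.features, ds.outputs, k=5, seed=17)
        assert ranking.loc["Subsystem Name = osmotic stress cluster", "worst_rank"] == 1


class TestPartition:
    def test_indicator_split_at_half(self):
        X = pd.DataFrame(
            {"ind": [0, 0, 1, 1]},
            index=pd.Index([f"g{i}" for i in range(4)], name="genome_name"),
        )
        Y = pd.DataFrame({"o1": [0.1, 0.2, 0.8, 0.9]}, index=X.index)
        part = partition_strains(X, Y, "ind", 0.5)
        assert part.below == ["g0", "g1"]
        assert part.at_or_above == ["g2", "g3"]
        means = part.summaries.set_index("group")["mean"]
        assert means["at_or_above"] > means["below"]
        assert part.summaries["n"].iloc[:1].sum() + part.summaries["n"].iloc[-1:].sum() <= 4

    def test_group_sizes_sum_to_n(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(
            {"f": rng.normal(size=12)},
            index=pd.Index([f"g{i}" for i in range(12)]),
        )
        Y = pd.DataFrame({"o1": rng.normal(size=12)}, index=X.index)
        part = partition_strains(X, Y, "f", float(np.median(X["f"])))
        assert len(part.below) + len(part.at_or_above) == 12

    def test_empty_side_warns(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=pd.Index(list("abc")))
        Y = pd.DataFrame({"o1": [0.1, 0.2, 0.3]}, index=X.index)
        with pytest.warns(UserWarning, match="empty side"):
            partition_strains(X, Y, "f", 0.0)
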