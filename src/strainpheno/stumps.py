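"""Exhaustive single-feature decision-stump ranking with K-fold CV.

A decision stump is a one-level regression tree: a single numeric feature
and a threshold split the rows into a left leaf (value < threshold) and a
right leaf (value >= threshold), each predicting the mean of its training
rows for every output jointly.  The threshold is chosen among midpoints of
consecutive distinct sorted feature values to minimize the total squared
error over both leaves, all rows, and all outputs (L2 loss with leaf-mean
prediction, i.e. variance reduction).

Feature quality is estimated by K-fold cross-validation with one shared
shuffle for all features: per fold, the per-row squared error on the
training and held-out partitions; fold means are averaged, features are
ranked separately by mean train and mean test error, and the final score
is each feature's worst (maximum) rank across the two — a feature must do
well on both to rank high.  For downstream binary partitions the decision
threshold is the mean of the per-fold fitted thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold

__all__ = [
    "DecisionStump",
    "FoldEvaluation",
    "Partition",
    "fit_stump",
    "fit_stumps_matrix",
    "stump_predict",
    "kfold_evaluate",
    "evaluate_features",
    "rank_features",
    "mean_threshold",
    "partition_strains",
]


@dataclass(frozen=True)
class DecisionStump:
    """A fitted one-level regression tree on one feature.

    Degenerate stumps (constant feature: no valid split) keep a NaN
    threshold and predict the grand mean everywhere; their train_sse is
    the total variance about the grand mean.
    """

    feature: str
    threshold: float
    left_mean: np.ndarray
    right_mean: np.ndarray
    train_sse: float
    is_degenerate: bool = False


def fit_stump(x, Y, feature: str = "") -> DecisionStump:
    """Fit a multi-output decision stump on one feature.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values of ``x``; the winner minimizes the summed squared deviation of
    every row's outputs from its leaf mean, ties resolving to the smallest
    threshold.  The reported loss is recomputed directly at the chosen
    split so it is bit-comparable with a naive enumeration.
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and x.size > 1:
        Y = Y.T
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 rows to fit a stump")
    if Y.shape[0] != n or not np.all(np.isfinite(Y)):
        raise ValueError("outputs must be finite with one row per sample")

    order = np.argsort(x, kind="stable")
    xs, Ys = x[order], Y[order]
    grand_mean = Ys.mean(axis=0)
    grand_sse = float(np.sum((Ys - grand_mean) ** 2))
    valid = xs[1:] > xs[:-1]
    if not valid.any():
        return DecisionStump(feature, np.nan, grand_mean, grand_mean,
                             grand_sse, is_degenerate=True)

    # O(n) split scan via cumulative sums; final loss recomputed directly
    cs = np.cumsum(Ys, axis=0)
    tot = cs[-1]
    tot2 = float(np.sum(Ys**2))
    nl = np.arange(1, n, dtype=float)
    sse = (
        tot2
        - np.sum(cs[:-1] ** 2, axis=1) / nl
        - np.sum((tot - cs[:-1]) ** 2, axis=1) / (n - nl)
    )
    sse[~valid] = np.inf
    i = int(np.argmin(sse))  # first minimum = smallest threshold
    threshold = 0.5 * (xs[i] + xs[i + 1])
    left, right = Ys[: i + 1], Ys[i + 1 :]
    left_mean, right_mean = left.mean(axis=0), right.mean(axis=0)
    train_sse = float(
        np.sum((left - left_mean) ** 2) + np.sum((right - right_mean) ** 2)
    )
    return DecisionStump(feature, float(threshold), left_mean, right_mean, train_sse)


def stump_predict(stump: DecisionStump, x) -> np.ndarray:
    """Leaf-mean prediction: left for value < threshold, else right."""
    x = np.asarray(x, dtype=float)
    if stump.is_degenerate:
        return np.broadcast_to(stump.left_mean, (x.size, stump.left_mean.size)).copy()
    side = x[:, None] < stump.threshold
    return np.where(side, stump.left_mean[None, :], stump.right_mean[None, :])


def fit_stumps_matrix(X: np.ndarray, Y: np.ndarray):
    """Vectorized stump fit of every feature column of X at once.

    Returns ``(thresholds, left_means, right_means, degenerate)`` arrays
    of shapes (p,), (p, q), (p, q), (p,).  Equivalent to calling
    :func:`fit_stump` column by column (a tested invariant), but O(n p q)
    in numpy so whole annotation tables rank quickly.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    q = Y.shape[1]
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    Ys = Y[order]  # (n, p, q)
    cs = np.cumsum(Ys, axis=0)
    tot = cs[-1]  # (p, q)
    tot2 = np.sum(Y**2)
    nl = np.arange(1, n, dtype=float)[:, None]
    sse = (
        tot2
        - np.sum(cs[:-1] ** 2, axis=2) / nl
        - np.sum((tot[None] - cs[:-1]) ** 2, axis=2) / (n - nl)
    )  # (n-1, p)
    valid = Xs[1:] > Xs[:-1]
    sse[~valid] = np.inf
    best = np.argmin(sse, axis=0)  # (p,)
    cols = np.arange(p)
    degenerate = ~valid.any(axis=0)
    thresholds = 0.5 * (Xs[best, cols] + Xs[best + 1, cols])
    n_left = (best + 1).astype(float)[:, None]
    left_means = cs[best, cols] / n_left
    right_means = (tot - cs[best, cols]) / (n - n_left)
    if degenerate.any():
        grand = tot / n
        thresholds[degenerate] = np.nan
        left_means[degenerate] = grand[degenerate]
        right_means[degenerate] = grand[degenerate]
    return thresholds, left_means, right_means, degenerate


def _predict_matrix(X, thresholds, left_means, right_means, degenerate):
    """(m, p, q) predictions for every feature at once."""
    side = X[:, :, None] < np.where(np.isnan(thresholds), np.inf, thresholds)[None, :, None]
    pred = np.where(side, left_means[None], right_means[None])
    if degenerate.any():
        pred[:, degenerate, :] = left_means[degenerate][None]
    return pred


@dataclass(frozen=True)
class FoldEvaluation:
    """Per-fold stump diagnostics for one feature."""

    fold: int
    train_error: float  # squared error per row on the training partitions
    test_error: float  # squared error per row on the held-out partition
    threshold: float
    is_degenerate: bool


def kfold_folds(n: int, k: int = 5, seed: int = 0):
    """One shared shuffled K-fold partition of ``n`` rows."""
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def kfold_evaluate(x, Y, k: int = 5, seed: int = 0,
                   folds=None, feature: str = "") -> list[FoldEvaluation]:
    """K-fold CV of a single-feature stump.

    Rows are shuffled once by ``seed`` and split into K near-equal folds;
    each fold serves once as the held-out partition for a stump fitted on
    the rest.  Errors are squared error per row (summed over outputs) so
    unequal fold sizes do not bias fold means.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if folds is None:
        folds = kfold_folds(x.size, k=k, seed=seed)
    out = []
    for i, (train_idx, test_idx) in enumerate(folds, start=1):
        stump = fit_stump(x[train_idx], Y[train_idx], feature=feature)
        pred_train = stump_predict(stump, x[train_idx])
        pred_test = stump_predict(stump, x[test_idx])
        train_err = float(np.sum((pred_train - Y[train_idx]) ** 2)) / len(train_idx)
        test_err = float(np.sum((pred_test - Y[test_idx]) ** 2)) / len(test_idx)
        out.append(FoldEvaluation(i, train_err, test_err,
                                  stump.threshold, stump.is_degenerate))
    return out


def mean_threshold(evaluations: Sequence[FoldEvaluation]) -> float:
    """Mean fitted threshold across folds, excluding degenerate fits.

    All-degenerate folds leave the threshold undefined (NaN, flagged by a
    warning); a partly degenerate feature averages the remaining folds.
    """
    values = [e.threshold for e in evaluations if not e.is_degenerate]
    n_deg = sum(e.is_degenerate for e in evaluations)
    if not values:
        warnings.warn("all folds degenerate; mean threshold undefined", stacklevel=2)
        return float("nan")
    if n_deg:
        warnings.warn(
            f"{n_deg} degenerate fold(s) excluded from the mean threshold",
            stacklevel=2,
        )
    return float(np.mean(values))


def evaluate_features(
    features: pd.DataFrame, outputs: pd.DataFrame | np.ndarray,
    k: int = 5, seed: int = 0,
) -> pd.DataFrame:
    """Fold-averaged stump errors and mean thresholds for every feature.

    All features share one shuffled K-fold partition so their fold means
    are comparable.  Returns a DataFrame indexed like ``features.columns``
    with mean_train_error, mean_test_error, mean_threshold, and
    n_degenerate_folds.
    """
    X = features.to_numpy(dtype=float)
    Y = np.asarray(outputs, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    folds = kfold_folds(n, k=k, seed=seed)
    train_err = np.zeros((len(folds), p))
    test_err = np.zeros((len(folds), p))
    thresholds = np.zeros((len(folds), p))
    degenerate = np.zeros((len(folds), p), dtype=bool)
    for f, (train_idx, test_idx) in enumerate(folds):
        thr, lm, rm, deg = fit_stumps_matrix(X[train_idx], Y[train_idx])
        thresholds[f], degenerate[f] = thr, deg
        pred = _predict_matrix(X[train_idx], thr, lm, rm, deg)
        train_err[f] = np.sum(
            (pred - Y[train_idx][:, None, :]) ** 2, axis=(0, 2)
        ) / len(train_idx)
        pred = _predict_matrix(X[test_idx], thr, lm, rm, deg)
        test_err[f] = np.sum(
            (pred - Y[test_idx][:, None, :]) ** 2, axis=(0, 2)
        ) / len(test_idx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_thr = np.nanmean(np.where(degenerate, np.nan, thresholds), axis=0)
    return pd.DataFrame(
        {
            "mean_train_error": train_err.mean(axis=0),
            "mean_test_error": test_err.mean(axis=0),
            "mean_threshold": mean_thr,
            "n_degenerate_folds": degenerate.sum(axis=0),
        },
        index=pd.Index(features.columns, name="feature"),
    )


def rank_features(errors: pd.DataFrame) -> pd.DataFrame:
    """Worst-rank aggregation of train and test error rankings.

    Features are ranked ascending by mean train error and mean test error
    (ties share the minimum rank); worst_rank is the maximum of the two.
    The returned frame is ordered by (worst_rank, test_rank, feature name).
    """
    out = errors.reset_index()
    if "feature" not in out.columns:
        out = out.rename(columns={out.columns[0]: "feature"})
    out["feature"] = out["feature"].astype(str)
    out["train_rank"] = rankdata(out["mean_train_error"], method="min").astype(int)
    out["test_rank"] = rankdata(out["mean_test_error"], method="min").astype(int)
    out["worst_rank"] = out[["train_rank", "test_rank"]].max(axis=1)
    out = out.sort_values(["worst_rank", "test_rank", "feature"], kind="stable")
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out.set_index("feature")


def rank_dataset(
    features: pd.DataFrame, outputs, k: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Convenience: evaluate_features then rank_features."""
    return rank_features(evaluate_features(features, outputs, k=k, seed=seed))


@dataclass
class Partition:
    """Binary split of the dataset at a feature's (mean) threshold."""

    feature: str
    threshold: float
    below: list[str]
    at_or_above: list[str]
    summaries: pd.DataFrame  # per group x output: n, mean, std, median, q1, q3


def partition_strains(
    features: pd.DataFrame, outputs: pd.DataFrame, feature: str, threshold: float
) -> Partition:
    """Split genomes at a threshold and summarize outputs per group.

    Rows with feature value < threshold form the "below" (absence) group,
    the rest the "at_or_above" (presence) group; either side may be empty
    (flagged by a warning).  Summaries feed boxplot-style exports.
    """
    if feature not in features.columns:
        raise KeyError(f"feature {feature!r} not in dataset")
    x = features[feature].to_numpy(dtype=float)
    below = list(features.index[x < threshold])
    above = list(features.index[x >= threshold])
    if not below or not above:
        warnings.warn(f"partition of {feature!r} has an empty side", stacklevel=2)
    rows = []
    for group, members in (("below", below), ("at_or_above", above)):
        sub = outputs.loc[members]
        for col in outputs.columns:
            v = sub[col].to_numpy(dtype=float)
            rows.append(
                (group, col, len(v),
                 float(np.mean(v)) if len(v) else np.nan,
                 float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                 float(np.median(v)) if len(v) else np.nan,
                 float(np.percentile(v, 25)) if len(v) else np.nan,
                 float(np.percentile(v, 75)) if len(v) else np.nan)
            )
    summaries = pd.DataFrame(
        rows, columns=["group", "output", "n", "mean", "std", "median", "q1", "q3"]
    )
    return Partition(feature, threshold, below, above, summaries)
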