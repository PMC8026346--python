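"""Cross-market generalization of the forecasting signal.

Train a standardized linear max-margin classifier on one market's group
trial table and test it on the other market, after balanced downsampling so
chance is exactly 50%.  Accuracy is reported with a normal-approximation
95% CI and a two-sided exact binomial test against 0.5.  The
permutation-null protocol retrains the classifier on training data whose
stock prices have been randomized (by default: the within-stock sequence of
daily changes is permuted, preserving each stock's marginal volatility while
destroying its temporal structure) and tests on the untouched test market —
training on random prices should forecast at chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .features import aggregate_group, compute_indicators, exclude_activity_outliers
from .simulate import Market, StockSeries, _as_generator

__all__ = [
    "FEATURE_SETS",
    "ClassifierResult",
    "PermNullResult",
    "DegenerateNullError",
    "DirectionClassifier",
    "downsample_balanced",
    "train_linear_classifier",
    "evaluate_classifier",
    "test_classifier",
    "cross_market_forecast",
    "binomial_vs_chance",
    "permutation_null",
]

#: feature columns per named set; *_x_prev are built as products with prev_dir
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "combined": (
        "slope",
        "volatility",
        "prev_dir",
        "choice_mean",
        "nacc_mean",
        "ains_mean",
        "mpfc_mean",
        "nacc_x_prev",
        "ains_x_prev",
        "mpfc_x_prev",
    ),
    "reduced": ("ains_mean", "prev_dir", "ains_x_prev"),
}

_PRODUCTS = {
    "nacc_x_prev": ("nacc_mean", "prev_dir"),
    "ains_x_prev": ("ains_mean", "prev_dir"),
    "mpfc_x_prev": ("mpfc_mean", "prev_dir"),
}


class DegenerateNullError(ValueError):
    """The permutation-null accuracies have zero variance; t is undefined."""


def _resolve_features(feature_set: str | Sequence[str]) -> tuple[str, ...]:
    if isinstance(feature_set, str):
        try:
            return FEATURE_SETS[feature_set]
        except KeyError:
            raise ValueError(
                f"unknown feature set {feature_set!r}; choose from {sorted(FEATURE_SETS)}"
            ) from None
    return tuple(feature_set)


def _feature_matrix(records: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    cols = []
    for name in names:
        if name in _PRODUCTS:
            a, b = _PRODUCTS[name]
            cols.append(records[a].to_numpy(float) * records[b].to_numpy(float))
        else:
            cols.append(records[name].to_numpy(float))
    return np.column_stack(cols)


def _analysis_records(records: pd.DataFrame) -> pd.DataFrame:
    if "excluded" in records.columns:
        records = records.loc[~records["excluded"].astype(bool)]
    return records


def downsample_balanced(
    records: pd.DataFrame, rng: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Equalize next-day increase/decrease counts by random majority removal.

    Returns ``2·min(class sizes)`` records: the full minority class plus a
    uniformly drawn (without replacement) subset of the majority, in
    original row order.  Deterministic for a given seed/generator state.
    """
    gen = _as_generator(rng)
    data = _analysis_records(records)
    up = data.index[data["next_dir"] == 1].to_numpy()
    down = data.index[data["next_dir"] == -1].to_numpy()
    if len(up) == 0 or len(down) == 0:
        raise ValueError("both outcome classes must be present to balance")
    n = min(len(up), len(down))
    minority, majority = (up, down) if len(up) <= len(down) else (down, up)
    kept_majority = majority if len(majority) == n else gen.choice(
        majority, size=n, replace=False
    )
    keep = np.sort(np.concatenate([minority, kept_majority]))
    return data.loc[keep]


class DirectionClassifier(BaseEstimator, ClassifierMixin):
    """Linear max-margin classifier of next-day price direction.

    Features are standardized to the training set's mean and SD (parameters
    stored with the model and reused verbatim at test time, so no statistic
    of the test market enters training).  The core is a linear-kernel SVM
    with the regularization cost fixed at 1 by default — no tuning.
    Zero-variance features are dropped with a warning.

    Parameters
    ----------
    feature_set
        ``"combined"``, ``"reduced"``, or an explicit column list.
    C
        SVM regularization cost.

    Attributes
    ----------
    feature_names_ : list of retained feature names
    mean_, scale_ : per-feature training standardization parameters
    svm_ : the fitted :class:`sklearn.svm.SVC`
    coef_, intercept_ : hyperplane in standardized feature space
    classes_ : ``[-1, 1]`` (decrease, increase)
    """

    def __init__(self, feature_set: str | Sequence[str] = "reduced", C: float = 1.0):
        self.feature_set = feature_set
        self.C = C

    def fit(self, records: pd.DataFrame, y=None) -> "DirectionClassifier":
        data = _analysis_records(records)
        names = list(_resolve_features(self.feature_set))
        X = _feature_matrix(data, names)
        outcome = data["next_dir"].to_numpy(int)
        if set(np.unique(outcome)) - {-1, 1}:
            raise ValueError("next_dir must be coded +1/-1 on analysis records")
        variable = X.std(axis=0) > 0
        if not variable.all():
            dropped = [n for n, keep in zip(names, variable) if not keep]
            warnings.warn(
                f"dropping zero-variance features: {dropped}", stacklevel=2
            )
            names = [n for n, keep in zip(names, variable) if keep]
            X = X[:, variable]
        if X.shape[1] == 0:
            raise ValueError("no informative features remain after variance filter")
        self.feature_names_ = names
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        Z = (X - self.mean_) / self.scale_
        self.svm_ = SVC(kernel="linear", C=self.C)
        self.svm_.fit(Z, outcome)
        self.coef_ = self.svm_.coef_.copy()
        self.intercept_ = self.svm_.intercept_.copy()
        self.classes_ = self.svm_.classes_
        return self

    def _transform(self, records: pd.DataFrame) -> np.ndarray:
        data = _analysis_records(records)
        X = _feature_matrix(data, self.feature_names_)
        return (X - self.mean_) / self.scale_

    def decision_function(self, records: pd.DataFrame) -> np.ndarray:
        return self.svm_.decision_function(self._transform(records))

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        return self.svm_.predict(self._transform(records))

    def score(self, records: pd.DataFrame, y=None) -> float:
        data = _analysis_records(records)
        return float(
            np.mean(self.predict(data) == data["next_dir"].to_numpy(int))
        )


def train_linear_classifier(
    records: pd.DataFrame, feature_set: str | Sequence[str] = "reduced", C: float = 1.0
) -> DirectionClassifier:
    """Train a :class:`DirectionClassifier` on (balanced) records."""
    return DirectionClassifier(feature_set=feature_set, C=C).fit(records)


def binomial_vs_chance(n_correct: int, n: int) -> float:
    """Two-sided exact binomial p-value of ``n_correct``/``n`` against 0.5."""
    return float(stats.binomtest(n_correct, n, 0.5, alternative="two-sided").pvalue)


@dataclass(frozen=True)
class ClassifierResult:
    """Out-of-sample accuracy with CI and exact binomial chance test."""

    train_market: str
    test_market: str
    feature_set: str
    accuracy: float
    n_test: int
    n_correct: int
    ci95_halfwidth: float
    binom_p: float

    def to_dict(self) -> dict:
        return {
            "train_market": self.train_market,
            "test_market": self.test_market,
            "feature_set": self.feature_set,
            "accuracy": self.accuracy,
            "n_test": self.n_test,
            "n_correct": self.n_correct,
            "ci95_halfwidth": self.ci95_halfwidth,
            "binom_p": self.binom_p,
        }


def evaluate_classifier(
    model: DirectionClassifier,
    records: pd.DataFrame,
    *,
    train_market: str = "train",
    test_market: str = "test",
) -> ClassifierResult:
    """Accuracy of a trained classifier on balanced test records.

    The test features are transformed with the standardization parameters
    stored at training time.  Reports a normal-approximation 95% CI
    (``1.96·sqrt(acc(1−acc)/n)``) and the two-sided exact binomial test
    against 50% chance.
    """
    data = _analysis_records(records)
    if len(data) == 0:
        raise ValueError("empty test set")
    counts = data["next_dir"].value_counts()
    if len(counts) == 2 and counts.iloc[0] != counts.iloc[1]:
        warnings.warn(
            "test records are not class-balanced; chance is not exactly 50%",
            stacklevel=2,
        )
    pred = model.predict(data)
    truth = data["next_dir"].to_numpy(int)
    n = len(data)
    n_correct = int(np.sum(pred == truth))
    acc = n_correct / n
    half = 1.96 * np.sqrt(acc * (1.0 - acc) / n)
    feature_set = (
        model.feature_set if isinstance(model.feature_set, str) else "custom"
    )
    return ClassifierResult(
        train_market=train_market,
        test_market=test_market,
        feature_set=feature_set,
        accuracy=float(acc),
        n_test=n,
        n_correct=n_correct,
        ci95_halfwidth=float(half),
        binom_p=binomial_vs_chance(n_correct, n),
    )


# spec-facing alias (the operation is named after what it does to the model)
test_classifier = evaluate_classifier


def cross_market_forecast(
    train_records: pd.DataFrame,
    test_records: pd.DataFrame,
    feature_set: str | Sequence[str] = "reduced",
    *,
    rng: int | np.random.Generator | None = None,
    train_market: str = "train",
    test_market: str = "test",
    C: float = 1.0,
) -> ClassifierResult:
    """Train on one market, test on the other, both class-balanced.

    Swapping the train and test tables changes only which records are
    transformed — the pipeline path is symmetric.
    """
    gen = _as_generator(rng)
    train_bal = downsample_balanced(train_records, gen)
    test_bal = downsample_balanced(test_records, gen)
    model = train_linear_classifier(train_bal, feature_set, C=C)
    return evaluate_classifier(
        model, test_bal, train_market=train_market, test_market=test_market
    )


@dataclass(frozen=True)
class PermNullResult:
    """Distribution of null accuracies and its one-sample t-test vs 0.5."""

    accuracies: np.ndarray
    mean_acc: float
    t_stat: float
    p: float
    strategy: str

    @property
    def n_perm(self) -> int:
        return int(len(self.accuracies))


def _permute_changes(closes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rebuild a price path from a permuted sequence of its daily changes."""
    changes = np.diff(closes)
    permuted = rng.permutation(changes)
    return np.concatenate([[closes[0]], closes[0] + np.cumsum(permuted)])


def _randomize_market_records(
    stocks: Sequence[StockSeries],
    subject_means: pd.DataFrame,
    window_len: int,
    n_updates: int,
    strategy: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One randomized-price replicate of the training trial table."""
    if strategy in ("permute_changes", "shuffle_closes"):
        randomized = []
        for stock in stocks:
            if strategy == "permute_changes":
                closes = _permute_changes(stock.closes, rng)
            else:
                closes = rng.permutation(stock.closes)
            randomized.append(StockSeries(stock_id=stock.stock_id, closes=closes))
        indicators = compute_indicators(randomized, window_len, n_updates)
        records = indicators.merge(subject_means, on=["stock_id", "update_idx"])
        return records
    if strategy == "shuffle_labels":
        indicators = compute_indicators(stocks, window_len, n_updates)
        records = indicators.merge(subject_means, on=["stock_id", "update_idx"])
        records["next_dir"] = rng.permutation(records["next_dir"].to_numpy())
        return records
    raise ValueError(f"unknown randomization strategy {strategy!r}")


def permutation_null(
    train_market: Market,
    test_records: pd.DataFrame,
    feature_set: str | Sequence[str] = "reduced",
    n_perm: int = 500,
    *,
    rng: int | np.random.Generator | None = None,
    strategy: str = "permute_changes",
    outlier_k: float = 4.0,
    C: float = 1.0,
    max_retries: int = 5,
) -> PermNullResult:
    """Null distribution of cross-market accuracy under randomized prices.

    Per replicate the order of daily price changes is permuted within each
    training stock (preserving the multiset of changes), the stock's closes,
    indicators, and outcome labels are rebuilt, the classifier is retrained
    on the balanced randomized table, and tested on the untouched, balanced
    test records.  Group-averaged subject activity and choices are fixed —
    only their coupling to prices is destroyed.  Returns all ``n_perm``
    accuracies plus a one-sample t-test against 50% chance.

    Raises
    ------
    DegenerateNullError
        If the null accuracies have zero variance (t undefined).
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    gen = _as_generator(rng)
    cfg = train_market.config
    kept, _ = exclude_activity_outliers(train_market.subject_trials, k=outlier_k)
    invest = (kept["choice"] == "invest").astype(float)
    subject_means = (
        kept.assign(_invest=invest)
        .groupby(["stock_id", "update_idx"], sort=True)
        .agg(
            choice_mean=("_invest", "mean"),
            nacc_mean=("nacc", "mean"),
            ains_mean=("ains", "mean"),
            mpfc_mean=("mpfc", "mean"),
        )
        .reset_index()
    )
    test_bal = downsample_balanced(test_records, gen)

    accuracies = np.empty(n_perm)
    for i in range(n_perm):
        for attempt in range(max_retries):
            records = _randomize_market_records(
                train_market.stocks,
                subject_means,
                cfg.window_len,
                cfg.n_updates,
                strategy,
                gen,
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    train_bal = downsample_balanced(records, gen)
                    model = train_linear_classifier(train_bal, feature_set, C=C)
                accuracies[i] = evaluate_classifier(model, test_bal).accuracy
                break
            except ValueError:
                if attempt == max_retries - 1:
                    raise
    if np.std(accuracies) == 0:
        raise DegenerateNullError(
            "all permutation-null accuracies identical; one-sample t vs 0.5 "
            "is undefined"
        )
    t_res = stats.ttest_1samp(accuracies, 0.5)
    return PermNullResult(
        accuracies=accuracies,
        mean_acc=float(accuracies.mean()),
        t_stat=float(t_res.statistic),
        p=float(t_res.pvalue),
        strategy=strategy,
    )
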