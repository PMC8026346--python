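"""Group-level trial table construction.

This module turns raw price series and per-subject trial tables into the
stock × update records on which all forecasting models operate:

* window-level stock indicators — the OLS slope (``slope``) and residual sum
  of squares (``volatility``) of each displayed 21-point trend line against
  its integer time index;
* outcome codes — the previous day's price move (``prev_dir``), the next
  day's move (``next_dir``), and whether the latter reverses the former
  (``inflection``), with trials flagged ``stable_price`` when either daily
  change is exactly zero and therefore cannot be signed;
* activity-outlier exclusion — trials whose lagged VOI activity deviates
  ``k`` (default 4) or more standard deviations from that subject's own
  VOI mean are dropped before aggregation;
* aggregation — choices and VOI activities averaged over surviving subjects
  within each stock × update cell.

Excluded records are carried through with flags rather than silently dropped,
so exclusion counts are auditable downstream (model fitting filters on the
``excluded`` column).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VOI_COLUMNS",
    "TRIAL_TABLE_COLUMNS",
    "MissingDataError",
    "fit_window_ols",
    "window_ols_matrix",
    "code_outcomes",
    "exclude_activity_outliers",
    "aggregate_group",
    "compute_indicators",
    "build_trial_table",
]

#: per-trial scalar volumes of interest (lagged activity columns)
VOI_COLUMNS = ("nacc", "ains", "mpfc")

#: canonical column order of the group trial table
TRIAL_TABLE_COLUMNS = (
    "stock_id",
    "update_idx",
    "prev_dir",
    "slope",
    "volatility",
    "choice_mean",
    "nacc_mean",
    "ains_mean",
    "mpfc_mean",
    "next_dir",
    "inflection",
    "excluded",
    "exclude_reason",
)


class MissingDataError(ValueError):
    """A stock × update cell has no surviving subjects to average over."""


def fit_window_ols(values: Sequence[float]) -> tuple[float, float]:
    """Least-squares slope and residual sum of squares of a price window.

    The window is regressed on its integer time index ``0..n-1`` (units:
    trading-day updates), so for z-scored display windows the slope is in
    z-units per update and the RSS in squared z-units.

    Parameters
    ----------
    values
        Ordered numeric window with at least 3 finite points.

    Returns
    -------
    slope, rss
        OLS slope and residual sum of squares of the fitted line.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError(f"window needs at least 3 points, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("window contains non-finite values")
    slope, rss = window_ols_matrix(y[None, :])
    return float(slope[0]), float(rss[0])


def window_ols_matrix(windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`fit_window_ols` over rows of a 2-D window array."""
    w = np.asarray(windows, dtype=float)
    if w.ndim != 2 or w.shape[1] < 3:
        raise ValueError("expected a 2-D array of windows with >= 3 columns")
    n = w.shape[1]
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    denom = float(tc @ tc)
    wc = w - w.mean(axis=1, keepdims=True)
    slope = wc @ tc / denom
    resid = wc - slope[:, None] * tc
    rss = np.einsum("ij,ij->i", resid, resid)
    # collinear windows can yield tiny negative rounding residue
    return slope, np.maximum(rss, 0.0)


def code_outcomes(
    closes: Sequence[float], window_len: int = 20, n_updates: int = 10
) -> pd.DataFrame:
    """Code previous/next daily price moves for every displayed update.

    Update ``k`` (1-based) displays the window ending at close index
    ``k + window_len - 1`` (0-based).  Its previous move is the daily change
    ending at that newest point — always defined because every window carries
    ``window_len`` prior updates — and its outcome is the following day's
    change, so the series must carry ``window_len + n_updates + 1`` closes.

    Trials where either change is exactly zero cannot be signed as an
    increase or decrease and are flagged ``stable_price`` (an exclusion, not
    an error).

    Returns
    -------
    DataFrame with columns ``update_idx, prev_dir, next_dir, inflection,
    excluded, exclude_reason``; directions are ``+1``/``-1`` (``0`` only on
    excluded rows).
    """
    c = np.asarray(closes, dtype=float)
    needed = window_len + n_updates + 1
    if c.size < needed:
        raise ValueError(
            f"need {needed} closes for {n_updates} updates with "
            f"window_len={window_len} plus one outcome day, got {c.size}"
        )
    newest = np.arange(n_updates) + window_len  # 0-based index of displayed newest close
    prev_change = c[newest] - c[newest - 1]
    next_change = c[newest + 1] - c[newest]
    prev_dir = np.sign(prev_change).astype(int)
    next_dir = np.sign(next_change).astype(int)
    stable = (prev_dir == 0) | (next_dir == 0)
    inflection = np.where(~stable & (next_dir != prev_dir), 1, 0)
    return pd.DataFrame(
        {
            "update_idx": np.arange(1, n_updates + 1),
            "prev_dir": prev_dir,
            "next_dir": next_dir,
            "inflection": inflection,
            "excluded": stable,
            "exclude_reason": np.where(stable, "stable_price", "none"),
        }
    )


def _outlier_mask(values: np.ndarray, k: float) -> np.ndarray:
    """Flag entries deviating >= k sample SDs from their own mean.

    A zero-variance sample carries no outlier information and flags nothing.
    """
    if values.size < 2:
        raise ValueError("need at least 2 trials per subject x VOI")
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros(values.shape, dtype=bool)
    return np.abs(values - values.mean()) >= k * sd


def exclude_activity_outliers(
    subject_trials: pd.DataFrame, k: float = 4.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trials with extreme lagged VOI activity before aggregation.

    A trial is dropped for a subject when any VOI value deviates ``k`` or
    more sample standard deviations from that subject's mean for the same
    VOI (the boundary counts as an outlier).  SDs are computed within
    subject × VOI across that subject's trials, matching the within-voxel
    normalization of the upstream activity preprocessing.

    Returns
    -------
    kept, dropped
        ``kept`` is the surviving subset of ``subject_trials``; ``dropped``
        logs one row per removed trial × flagged VOI with its z-score.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    df = subject_trials
    drop_rows: list[pd.DataFrame] = []
    trial_flag = pd.Series(False, index=df.index)
    for voi in VOI_COLUMNS:
        grouped = df.groupby("subject_id", sort=False)[voi]
        mean = grouped.transform("mean")
        size = grouped.transform("size")
        dev = df[voi] - mean
        # sample SD from exact squared-deviation sums so the >= k boundary
        # is honored bit-for-bit on exactly representable inputs
        ssd = dev.pow(2).groupby(df["subject_id"], sort=False).transform("sum")
        sd = np.sqrt(ssd / (size - 1).clip(lower=1))
        z = dev.abs() / sd.where(sd > 0)
        flag = (z >= k).fillna(False) & (sd > 0) & size.ge(2)
        if flag.any():
            log = df.loc[flag, ["subject_id", "stock_id", "update_idx"]].copy()
            log["voi"] = voi
            log["value"] = df.loc[flag, voi]
            log["zscore"] = z[flag]
            drop_rows.append(log)
        trial_flag |= flag
    dropped = (
        pd.concat(drop_rows, ignore_index=True)
        if drop_rows
        else pd.DataFrame(
            columns=["subject_id", "stock_id", "update_idx", "voi", "value", "zscore"]
        )
    )
    kept = df.loc[~trial_flag].copy()
    lost = set(df["subject_id"].unique()) - set(kept["subject_id"].unique())
    for subject in sorted(lost):
        warnings.warn(
            f"all trials dropped for subject {subject!r}; "
            "subject excluded from aggregation",
            stacklevel=2,
        )
    return kept, dropped


def compute_indicators(
    stocks: Iterable, window_len: int = 20, n_updates: int = 10
) -> pd.DataFrame:
    """Per stock × update indicator table: slope, volatility, outcome codes.

    ``stocks`` is an iterable of objects with ``stock_id`` and ``closes``
    attributes (:class:`~neuromarket.simulate.StockSeries` or same-shaped).
    Slope and volatility come from the OLS fit of each z-scored display
    window; outcome codes from :func:`code_outcomes` on the raw closes.
    """
    from .simulate import make_display_windows  # deferred: avoids import cycle

    frames = []
    for stock in stocks:
        windows = make_display_windows(stock.closes, window_len, n_updates)
        slope, rss = window_ols_matrix(windows)
        out = code_outcomes(stock.closes, window_len, n_updates)
        out.insert(0, "stock_id", stock.stock_id)
        out["slope"] = slope
        out["volatility"] = rss
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def aggregate_group(
    subject_trials: pd.DataFrame, indicators: pd.DataFrame
) -> pd.DataFrame:
    """Average subject choices and VOI activity within stock × update cells.

    Parameters
    ----------
    subject_trials
        Long table with ``subject_id, stock_id, update_idx, choice`` and the
        VOI columns (typically after :func:`exclude_activity_outliers`).
    indicators
        Output of :func:`compute_indicators` for the same stocks.

    Returns
    -------
    Group trial table with columns :data:`TRIAL_TABLE_COLUMNS`, one row per
    stock × update, excluded rows carried with flags.

    Raises
    ------
    MissingDataError
        If any indicator cell has no surviving subject to average over.
    """
    invest = (subject_trials["choice"] == "invest").astype(float)
    df = subject_trials.assign(_invest=invest)
    agg = (
        df.groupby(["stock_id", "update_idx"], sort=True)
        .agg(
            choice_mean=("_invest", "mean"),
            nacc_mean=("nacc", "mean"),
            ains_mean=("ains", "mean"),
            mpfc_mean=("mpfc", "mean"),
            n_subjects=("subject_id", "nunique"),
        )
        .reset_index()
    )
    merged = indicators.merge(agg, on=["stock_id", "update_idx"], how="left")
    empty = merged["n_subjects"].isna()
    if empty.any():
        first = merged.loc[empty, ["stock_id", "update_idx"]].iloc[0]
        raise MissingDataError(
            f"no surviving subjects for stock {first['stock_id']!r} "
            f"update {int(first['update_idx'])}"
        )
    merged = merged.sort_values(["stock_id", "update_idx"], kind="stable")
    return merged.loc[:, list(TRIAL_TABLE_COLUMNS)].reset_index(drop=True)


def build_trial_table(
    stocks: Iterable,
    subject_trials: pd.DataFrame,
    *,
    window_len: int = 20,
    n_updates: int = 10,
    outlier_k: float = 4.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full raw-inputs -> group trial table pipeline.

    Applies activity-outlier exclusion, computes indicators and outcome
    codes, and aggregates over subjects.  Returns the trial table together
    with the dropped-trial log.
    """
    kept, dropped = exclude_activity_outliers(subject_trials, k=outlier_k)
    indicators = compute_indicators(stocks, window_len, n_updates)
    records = aggregate_group(kept, indicators)
    return records, dropped
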