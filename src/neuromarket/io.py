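"""CSV/JSON/YAML formats for every pipeline table.

All CSVs are UTF-8 with a mandatory header row and period decimal separator;
currency is stored as decimal dollars; dates are ISO-8601.  Daily-close
files mimic exported finance data (one file per ticker, or long format with
a ``ticker`` column); subject-trial and group trial tables round-trip
through :func:`pandas.read_csv` with documented column orders.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .features import TRIAL_TABLE_COLUMNS
from .simulate import StockSeries

__all__ = [
    "SUBJECT_TRIAL_COLUMNS",
    "read_daily_closes",
    "write_daily_closes",
    "read_subject_trials",
    "write_subject_trials",
    "read_trial_table",
    "write_trial_table",
    "write_model_summary",
    "file_digest",
    "save_manifest",
    "load_manifest",
]

SUBJECT_TRIAL_COLUMNS = (
    "subject_id",
    "stock_id",
    "update_idx",
    "choice",
    "payoff",
    "balance",
    "nacc",
    "ains",
    "mpfc",
)


def _find_column(columns: Sequence[str], name: str) -> str | None:
    for col in columns:
        if col.strip().lower() == name:
            return col
    return None


def _series_from_frame(df: pd.DataFrame, ticker: str, path: Path) -> StockSeries:
    date_col = _find_column(df.columns, "date")
    close_col = _find_column(df.columns, "close")
    if date_col is None or close_col is None:
        raise ValueError(f"{path}: header must contain 'date' and 'close' columns")
    dates = pd.to_datetime(df[date_col], format="ISO8601", errors="coerce")
    bad = dates.isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header + 1-based
        raise ValueError(f"{path}: unparseable date at line {line}")
    closes = pd.to_numeric(df[close_col], errors="coerce")
    bad = closes.isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValueError(f"{path}: non-numeric close at line {line}")
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0].date()
        raise ValueError(f"{path}: duplicate date {dup} for ticker {ticker!r}")
    order = np.argsort(dates.to_numpy(), kind="stable")
    return StockSeries(stock_id=ticker, closes=closes.to_numpy()[order])


def read_daily_closes(path: str | Path) -> list[StockSeries]:
    """Read daily closing prices into stock series.

    ``path`` may be a directory of per-ticker CSVs (stock id taken from the
    file stem), a single per-ticker CSV, or a long-format CSV with a
    ``ticker`` column.  Rows are sorted by date; missing trading days are
    tolerated (the series has sequence semantics, not calendar semantics);
    duplicate dates within a ticker are an error.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise ValueError(f"{path}: no CSV files found")
        return [s for f in files for s in read_daily_closes(f)]
    df = pd.read_csv(path, dtype=str)
    ticker_col = _find_column(df.columns, "ticker")
    if ticker_col is None:
        return [_series_from_frame(df, path.stem, path)]
    out = []
    for ticker, group in df.groupby(ticker_col, sort=True):
        out.append(_series_from_frame(group.reset_index(drop=True), str(ticker), path))
    return out


def write_daily_closes(
    stocks: Iterable[StockSeries],
    out_dir: str | Path,
    *,
    start_date: str = "2015-03-04",
) -> list[Path]:
    """Write one per-ticker CSV (date, close) per stock, business-day dated."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for stock in stocks:
        dates = pd.bdate_range(start=start_date, periods=len(stock.closes))
        frame = pd.DataFrame(
            {"date": dates.strftime("%Y-%m-%d"), "close": stock.closes}
        )
        path = out_dir / f"{stock.stock_id}.csv"
        frame.to_csv(path, index=False)
        paths.append(path)
    return paths


def write_subject_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trials.loc[:, list(SUBJECT_TRIAL_COLUMNS)].to_csv(path, index=False)
    return path


def read_subject_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SUBJECT_TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing subject-trial columns {sorted(missing)}")
    return df.loc[:, list(SUBJECT_TRIAL_COLUMNS)]


def write_trial_table(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.loc[:, list(TRIAL_TABLE_COLUMNS)].to_csv(path, index=False)
    return path


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trial-table columns {sorted(missing)}")
    df["excluded"] = df["excluded"].astype(bool)
    return df.loc[:, list(TRIAL_TABLE_COLUMNS)]


def write_model_summary(fit, csv_path: str | Path, json_path: str | Path) -> None:
    """Tidy per-term CSV plus a scalar-summary JSON blob for one model fit."""
    csv_path, json_path = Path(csv_path), Path(json_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    fit.tidy().to_csv(csv_path, index=False)
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(fit.info(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def save_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def load_manifest(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
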