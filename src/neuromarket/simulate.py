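"""Synthetic market, task, and brain-activity generator.

Emulates the asset pricing task: daily closing-price series per stock, a
stratified selection of 14 stocks spanning six slope × volatility bins,
rolling 21-point display windows (20 prior updates plus the newest) z-scored
to a common vertical axis, per-subject invest/pass choices with ±$1 payoffs
against a $10 per-stock endowment, and trial-level lagged VOI activity
scalars (NAcc, AIns, MPFC) with plantable effects:

* NAcc activity carries a standardized effect ``a`` of the next-day up-move;
* AIns activity carries a standardized effect ``b`` of an upcoming price
  inflection (next move reversing the previous move);
* MPFC activity is pure noise (control region);
* all three receive independent Gaussian noise of scale ``noise_sd``.

Price paths are driftable random walks whose daily change magnitudes are
half-normal and whose change *signs* repeat the previous sign with
probability ``sign_autocorr`` (0.5 = a sign-memoryless market), giving
independent control over the lag-1 sign autocorrelation that confounded the
first market.  Activity is generated directly as lagged trial-level scalars;
no BOLD time series is simulated, since every downstream stage consumes only
the lagged scalar.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .features import code_outcomes, fit_window_ols, window_ols_matrix

__all__ = [
    "SimConfig",
    "StockSeries",
    "Market",
    "InfeasibleSelectionError",
    "simulate_price_series",
    "stratify_select",
    "make_display_windows",
    "simulate_subjects",
    "simulate_market",
    "simulate_always_invest_payoffs",
]

SLOPE_BINS = ("positive", "negative")
VOL_BINS = ("low", "medium", "high")


class InfeasibleSelectionError(ValueError):
    """A slope × volatility bin cannot supply the stocks stratification needs."""


def _as_generator(rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class StockSeries:
    """One stock's ordered daily closing prices plus selection metadata."""

    stock_id: str
    closes: np.ndarray
    slope_bin: str | None = None
    vol_bin: str | None = None

    def __post_init__(self) -> None:
        closes = np.asarray(self.closes, dtype=float)
        object.__setattr__(self, "closes", closes)
        if closes.ndim != 1 or closes.size < 3:
            raise ValueError("closes must be a 1-D series of at least 3 prices")
        if not np.all(np.isfinite(closes)) or np.any(closes <= 0):
            raise ValueError(f"stock {self.stock_id!r}: closes must be finite and > 0")
        if self.slope_bin is not None and self.slope_bin not in SLOPE_BINS:
            raise ValueError(f"unknown slope_bin {self.slope_bin!r}")
        if self.vol_bin is not None and self.vol_bin not in VOL_BINS:
            raise ValueError(f"unknown vol_bin {self.vol_bin!r}")

    def __len__(self) -> int:  # pragma: no cover - trivial
        return int(self.closes.size)


@dataclass(frozen=True)
class SimConfig:
    """Generator knobs defining one synthetic market's study conditions.

    Parameters
    ----------
    n_stocks, n_updates, window_len
        Task geometry: 14 stocks × 10 displayed updates over 21-point
        rolling windows.
    n_days
        Closes per stock; one more than ``window_len + n_updates`` so the
        final update has a next-day outcome.
    pool_size
        Size of the candidate pool stratified selection draws from.
    n_subjects
        Scanned subjects per market.
    p_invest_base
        Baseline invest probability (choices run ~54-55% invest).
    choice_weight
        Momentum-following weight on the displayed window slope in the
        choice policy (log-odds units per z-unit/update); keeps behavior
        non-degenerate yet uninformative about next-day moves.
    sign_autocorr
        Probability a daily change repeats the previous change's sign
        (0.5 = none).
    drift, daily_vol, start_price
        Price-path shape: additive drift per day (currency units), the
        half-normal scale of change magnitudes, and the initial close.
    effect_nacc, effect_ains
        Planted standardized effects (units of ``noise_sd``) of the next-day
        up-move on NAcc and of the upcoming inflection on AIns activity.
    noise_sd
        Trial-level Gaussian noise scale of every VOI.
    endowment, stake
        Per-stock starting balance and per-trial investment amount (USD).
    """

    n_stocks: int = 14
    n_updates: int = 10
    window_len: int = 20
    n_days: int = 31
    pool_size: int = 60
    n_subjects: int = 39
    p_invest_base: float = 0.55
    choice_weight: float = 0.3
    sign_autocorr: float = 0.5
    drift: float = 0.0
    daily_vol: float = 1.0
    start_price: float = 100.0
    effect_nacc: float = 0.10
    effect_ains: float = 0.12
    noise_sd: float = 1.0
    endowment: float = 10.0
    stake: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_stocks", "n_updates", "window_len", "n_days", "pool_size", "n_subjects"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("p_invest_base", "sign_autocorr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.p_invest_base < 1.0:
            raise ValueError("p_invest_base must lie strictly in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.daily_vol <= 0:
            raise ValueError("daily_vol must be > 0")
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2 (OLS needs >= 3 points)")
        if self.n_days < self.window_len + self.n_updates + 1:
            raise ValueError(
                "n_days must cover window_len + n_updates displayed closes "
                "plus one outcome day"
            )

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class Market:
    """A simulated (or imported) market: stocks plus per-subject trials."""

    label: str
    stocks: list[StockSeries]
    subject_trials: pd.DataFrame
    config: SimConfig = field(default_factory=SimConfig)

    @property
    def stock_ids(self) -> list[str]:
        return [s.stock_id for s in self.stocks]


def _simulate_changes(
    n_series: int,
    n_changes: int,
    drift: float,
    daily_vol: float,
    sign_autocorr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Daily change matrix: half-normal magnitudes, φ-persistent signs."""
    mags = np.abs(rng.normal(0.0, daily_vol, size=(n_series, n_changes)))
    first = rng.choice((-1.0, 1.0), size=(n_series, 1))
    repeat = np.where(
        rng.random(size=(n_series, n_changes - 1)) < sign_autocorr, 1.0, -1.0
    )
    signs = first * np.cumprod(np.hstack([np.ones((n_series, 1)), repeat]), axis=1)
    return signs * mags + drift


def simulate_price_series(
    n_days: int = 31,
    drift: float = 0.0,
    daily_vol: float = 1.0,
    sign_autocorr: float = 0.5,
    *,
    start_price: float = 100.0,
    stock_id: str = "S000",
    rng: int | np.random.Generator | None = None,
) -> StockSeries:
    """Simulate one stock's daily closing-price path.

    The sign of the change at day ``t`` repeats the sign at ``t − 1`` with
    probability ``sign_autocorr``; change magnitudes are half-normal with
    scale ``daily_vol``.  With ``sign_autocorr=0.5`` successive change signs
    are independent; 1.0 makes every sign equal the first and 0.0 makes
    signs strictly alternate.  A non-zero ``drift`` is added to each change
    afterwards, so the exact sign-persistence guarantee holds at drift 0.
    """
    if n_days < 21:
        raise ValueError(f"n_days must be >= 21, got {n_days}")
    if daily_vol <= 0:
        raise ValueError("daily_vol must be > 0")
    if not 0.0 <= sign_autocorr <= 1.0:
        raise ValueError("sign_autocorr must lie in [0, 1]")
    gen = _as_generator(rng)
    changes = _simulate_changes(1, n_days - 1, drift, daily_vol, sign_autocorr, gen)[0]
    closes = start_price + np.concatenate([[0.0], np.cumsum(changes)])
    if np.any(closes <= 0):
        raise ValueError(
            "price path hit zero; increase start_price or reduce daily_vol/drift"
        )
    return StockSeries(stock_id=stock_id, closes=closes)


def make_display_windows(
    series: StockSeries | Sequence[float],
    window_len: int = 20,
    n_updates: int = 10,
) -> np.ndarray:
    """Rolling z-scored display windows: 20 prior updates plus the newest.

    Prices are z-scored once per stock over the displayed span (the first
    ``window_len + n_updates`` closes) so all windows share a common
    vertical axis; window ``k`` (1-based) then holds z-scores of closes
    ``k .. k + window_len``.

    Returns
    -------
    ndarray of shape ``(n_updates, window_len + 1)``.
    """
    closes = series.closes if isinstance(series, StockSeries) else np.asarray(series, float)
    span = window_len + n_updates
    if closes.size < span:
        raise ValueError(
            f"need at least {span} closes for {n_updates} windows of "
            f"{window_len + 1} points, got {closes.size}"
        )
    shown = closes[:span]
    sd = shown.std(ddof=1)
    if sd == 0:
        raise ValueError("z-score undefined: constant price series")
    z = (shown - shown.mean()) / sd
    idx = np.arange(n_updates)[:, None] + np.arange(window_len + 1)[None, :]
    return z[idx]


def _full_series_ols(stock: StockSeries) -> tuple[float, float]:
    return fit_window_ols(stock.closes)


def stratify_select(
    pool: Sequence[StockSeries],
    n_total: int = 14,
    exclude_ids: Iterable[str] = (),
    *,
    rng: int | np.random.Generator | None = None,
) -> list[StockSeries]:
    """Randomly select a slope × volatility stratified set of stocks.

    Each candidate's full price series is OLS-regressed on its time index;
    the slope sign (positive/negative) and the tercile of the residual sum
    of squares within the candidate pool (low/medium/high volatility) define
    six bins.  Two or three stocks are drawn from every bin to total
    ``n_total`` (default 14), none among ``exclude_ids``.

    Raises
    ------
    InfeasibleSelectionError
        Naming the first under-populated bin when the stratification cannot
        be satisfied.
    """
    if not 2 * len(SLOPE_BINS) * len(VOL_BINS) <= n_total <= 3 * len(SLOPE_BINS) * len(VOL_BINS):
        raise ValueError("n_total must allow 2-3 stocks per each of 6 bins")
    gen = _as_generator(rng)
    excluded = set(exclude_ids)
    candidates = [s for s in pool if s.stock_id not in excluded]
    if not candidates:
        raise InfeasibleSelectionError("no candidates remain after exclusions")
    stats = np.array([_full_series_ols(s) for s in candidates])
    slopes, rss = stats[:, 0], stats[:, 1]
    order = np.argsort(rss, kind="stable")
    tercile = np.empty(len(candidates), dtype=object)
    thirds = np.array_split(order, 3)
    for name, idx in zip(VOL_BINS, thirds):
        tercile[idx] = name
    bins: dict[tuple[str, str], list[int]] = {
        (sb, vb): [] for sb in SLOPE_BINS for vb in VOL_BINS
    }
    for i in range(len(candidates)):
        sb = "positive" if slopes[i] > 0 else "negative"
        bins[(sb, tercile[i])].append(i)

    for key in sorted(bins):
        if len(bins[key]) < 2:
            raise InfeasibleSelectionError(
                f"bin slope={key[0]}/volatility={key[1]} holds "
                f"{len(bins[key])} candidate(s); need at least 2"
            )
    counts = {key: 2 for key in bins}
    n_extra = n_total - 2 * len(bins)
    eligible = sorted(key for key in bins if len(bins[key]) >= 3)
    if n_extra > len(eligible):
        short = sorted(set(bins) - set(eligible))[0]
        raise InfeasibleSelectionError(
            f"bin slope={short[0]}/volatility={short[1]} holds only "
            f"{len(bins[short])} candidates; cannot place {n_extra} extra picks"
        )
    if n_extra:
        for key_idx in gen.choice(len(eligible), size=n_extra, replace=False):
            counts[eligible[int(key_idx)]] += 1

    selected: list[StockSeries] = []
    for key in sorted(bins):
        members = bins[key]
        picks = gen.choice(len(members), size=counts[key], replace=False)
        for p in sorted(int(x) for x in picks):
            stock = candidates[members[p]]
            selected.append(
                dataclasses.replace(stock, slope_bin=key[0], vol_bin=key[1])
            )
    return selected


def simulate_subjects(
    stocks: Sequence[StockSeries],
    config: SimConfig,
    *,
    rng: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate per-subject invest/pass choices, payoffs, and VOI activity.

    Per subject × stock × update: the invest probability is
    ``logistic(logit(p_invest_base) + w · window_slope)`` (mild momentum
    following); an investment pays ``±stake`` with the next-day move, a pass
    pays nothing; the balance starts at the per-stock endowment and
    accumulates payoffs within the block.  Lagged VOI activity is
    ``nacc = a·1[next up] + ε``, ``ains = b·1[inflection] + ε``,
    ``mpfc = ε`` with independent ``ε ~ N(0, noise_sd)``.

    Returns a long DataFrame with one row per subject × stock × update.
    """
    gen = _as_generator(rng if rng is not None else config.seed)
    frames = []
    base_logit = logit(config.p_invest_base)
    subj_ids = [f"sub{j + 1:02d}" for j in range(config.n_subjects)]
    for stock in stocks:
        windows = make_display_windows(stock.closes, config.window_len, config.n_updates)
        slopes, _ = window_ols_matrix(windows)
        out = code_outcomes(stock.closes, config.window_len, config.n_updates)
        next_dir = out["next_dir"].to_numpy()
        next_up = (next_dir == 1).astype(float)
        inflection = out["inflection"].to_numpy(dtype=float)
        p_invest = expit(base_logit + config.choice_weight * slopes)

        shape = (config.n_subjects, config.n_updates)
        invest = gen.random(shape) < p_invest[None, :]
        payoff = np.where(invest, config.stake * next_dir[None, :], 0.0)
        balance = config.endowment + np.cumsum(payoff, axis=1)
        noise = gen.normal(0.0, config.noise_sd, size=(3,) + shape)
        nacc = config.effect_nacc * next_up[None, :] + noise[0]
        ains = config.effect_ains * inflection[None, :] + noise[1]
        mpfc = noise[2]

        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(subj_ids, config.n_updates),
                    "stock_id": stock.stock_id,
                    "update_idx": np.tile(
                        np.arange(1, config.n_updates + 1), config.n_subjects
                    ),
                    "choice": np.where(invest.ravel(), "invest", "pass"),
                    "payoff": payoff.ravel(),
                    "balance": balance.ravel(),
                    "nacc": nacc.ravel(),
                    "ains": ains.ravel(),
                    "mpfc": mpfc.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_market(
    config: SimConfig | None = None,
    *,
    label: str = "exp1",
    exclude_ids: Iterable[str] = (),
    rng: int | np.random.Generator | None = None,
) -> Market:
    """Simulate one full market: stratified stocks plus subject trials.

    A pool of ``config.pool_size`` random-walk stocks is generated, a
    stratified set of ``config.n_stocks`` is selected across the six slope ×
    volatility bins, and subject choices/activity are simulated on it.
    Identical ``config`` + seed gives bit-identical outputs.
    """
    config = config or SimConfig()
    gen = _as_generator(rng if rng is not None else config.seed)
    prefix = f"{label}-S"
    pool = [
        simulate_price_series(
            config.n_days,
            config.drift,
            config.daily_vol,
            config.sign_autocorr,
            start_price=config.start_price,
            stock_id=f"{prefix}{i:03d}",
            rng=gen,
        )
        for i in range(config.pool_size)
    ]
    stocks = stratify_select(pool, config.n_stocks, exclude_ids, rng=gen)
    trials = simulate_subjects(stocks, config, rng=gen)
    return Market(label=label, stocks=stocks, subject_trials=trials, config=config)


def simulate_always_invest_payoffs(
    n_trials: int,
    *,
    sign_autocorr: float = 0.5,
    daily_vol: float = 1.0,
    drift: float = 0.0,
    stake: float = 1.0,
    window_len: int = 20,
    n_updates: int = 10,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Per-trial payoffs of an always-invest policy over fresh price paths.

    Generates as many price series as needed (``n_updates`` scoreable trials
    each) and returns at least ``n_trials`` payoffs of ``±stake`` following
    the next-day move.  Used to check the task's expected-value baseline:
    with ``sign_autocorr=0.5`` the long-run mean payoff per trial is $0.
    """
    gen = _as_generator(rng)
    n_series = -(-n_trials // n_updates)
    n_changes = window_len + n_updates
    changes = _simulate_changes(n_series, n_changes, drift, daily_vol, sign_autocorr, gen)
    next_changes = changes[:, window_len : window_len + n_updates]
    return (stake * np.sign(next_changes)).ravel()[:n_trials]
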