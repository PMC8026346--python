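"""Trial-table construction: indicators, outcome codes, exclusions, means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuromarket import (
    SimConfig,
    StockSeries,
    aggregate_group,
    build_trial_table,
    code_outcomes,
    compute_indicators,
    exclude_activity_outliers,
    fit_window_ols,
    simulate_subjects,
)
from neuromarket.features import MissingDataError, window_ols_matrix

from conftest import make_market_pair
from oracles import ols_normal_equations


class TestWindowOLS:
    @pytest.mark.parametrize(
        "values, slope, rss",
        [
            (np.arange(21.0), 1.0, 0.0),  # exact line
            (np.full(10, 3.7), 0.0, 0.0),  # constant window
            ((1.0, 3.0, 2.0, 5.0, 4.0), 0.8, 3.6),  # normal equations by hand
        ],
    )
    def test_known_windows(self, values, slope, rss):
        s, r = fit_window_ols(values)
        assert s == pytest.approx(slope, abs=1e-10)
        assert r == pytest.approx(rss, abs=1e-10)

    def test_matches_normal_equation_oracle_on_random_windows(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            values = rng.normal(0, rng.uniform(0.1, 10), n)
            s, r = fit_window_ols(values)
            s0, r0 = ols_normal_equations(values)
            assert s == pytest.approx(s0, abs=1e-8)
            assert r == pytest.approx(r0, abs=1e-8)
            assert r >= 0

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e4, max_value=1e4, allow_nan=False),
            min_size=3,
            max_size=30,
        )
    )
    def test_oracle_agreement_property(self, values):
        s, r = fit_window_ols(values)
        s0, r0 = ols_normal_equations(values)
        assert s == pytest.approx(s0, abs=1e-6)
        assert r == pytest.approx(r0, rel=1e-6, abs=1e-6)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(5)
        windows = rng.normal(size=(25, 21))
        slopes, rss = window_ols_matrix(windows)
        for i in range(25):
            s, r = fit_window_ols(windows[i])
            assert slopes[i] == pytest.approx(s, abs=1e-12)
            assert rss[i] == pytest.approx(r, abs=1e-10)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            fit_window_ols([1.0, 2.0])


class TestOutcomeCoding:
    def test_continuation_after_increase(self):
        out = code_outcomes([8.0, 9.0, 10.0, 11.0, 12.0], window_len=3, n_updates=1)
        row = out.iloc[0]
        assert (row["prev_dir"], row["next_dir"], row["inflection"]) == (1, 1, 0)
        assert not row["excluded"]

    def test_inflection_decrease_after_increase(self):
        out = code_outcomes([8.0, 9.0, 10.0, 11.0, 9.0], window_len=3, n_updates=1)
        row = out.iloc[0]
        assert (row["prev_dir"], row["next_dir"], row["inflection"]) == (1, -1, 1)

    def test_stable_price_flagged_not_errored(self):
        out = code_outcomes([8.0, 9.0, 10.0, 10.0, 12.0], window_len=3, n_updates=1)
        row = out.iloc[0]
        assert row["excluded"] and row["exclude_reason"] == "stable_price"
        out = code_outcomes([8.0, 9.0, 10.0, 11.0, 11.0], window_len=3, n_updates=1)
        assert out.iloc[0]["excluded"]  # unchanged next day

    def test_prev_dir_defined_for_first_update(self):
        """Update 1 reads prev_dir off the last two displayed points."""
        closes = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 4.0, 5.0])
        out = code_outcomes(closes, window_len=5, n_updates=1)
        assert out.iloc[0]["prev_dir"] == -1  # last two displayed: 5 -> 4
        assert out.iloc[0]["next_dir"] == 1
        assert out.iloc[0]["inflection"] == 1

    def test_requires_outcome_day(self):
        with pytest.raises(ValueError, match="closes"):
            code_outcomes(np.arange(30.0), window_len=20, n_updates=10)

    def test_partition_inflection_plus_continuation(self, records):
        live = records[~records["excluded"]]
        assert set(live["inflection"].unique()) <= {0, 1}
        expected = (live["next_dir"] != live["prev_dir"]).astype(int)
        np.testing.assert_array_equal(live["inflection"].to_numpy(), expected.to_numpy())
        n_inflect = int(live["inflection"].sum())
        n_continue = int((1 - live["inflection"]).sum())
        assert n_inflect + n_continue == len(live)


def _trials_frame(values_by_voi, subject="sub01"):
    n = len(next(iter(values_by_voi.values())))
    base = {
        "subject_id": subject,
        "stock_id": "S1",
        "update_idx": np.arange(1, n + 1),
        "choice": "pass",
        "payoff": 0.0,
        "balance": 10.0,
    }
    for voi in ("nacc", "ains", "mpfc"):
        base[voi] = np.asarray(values_by_voi.get(voi, np.zeros(n)), float)
    return pd.DataFrame(base)


class TestOutlierExclusion:
    def test_exactly_four_sd_is_dropped(self):
        # 27 dyadic values with sample mean 0 and sample SD exactly 1;
        # the value 4.0 sits at exactly 4 sample SDs and the >= rule drops it
        values = np.array([4.0] + [-0.5] * 8 + [1.0] * 4 + [-1.0] * 4 + [0.0] * 10)
        assert values.mean() == 0.0 and values.std(ddof=1) == 1.0
        kept, dropped = exclude_activity_outliers(_trials_frame({"nacc": values}))
        assert len(dropped) == 1
        assert dropped.iloc[0]["zscore"] == 4.0
        assert len(kept) == 26
        assert 1 not in kept["update_idx"].values  # the 4-SD trial was first

    def test_nothing_within_one_sd_dropped(self):
        values = np.sin(np.arange(12))
        kept, dropped = exclude_activity_outliers(_trials_frame({"ains": values}))
        assert len(dropped) == 0 and len(kept) == 12

    def test_single_spike_among_unit_normal_draws(self):
        rng = np.random.default_rng(42)
        values = rng.normal(size=139)
        values = (values - values.mean()) / values.std(ddof=1)
        spiked = np.concatenate([values, [10.0]])
        kept, dropped = exclude_activity_outliers(_trials_frame({"mpfc": spiked}))
        assert len(dropped) == 1
        assert dropped.iloc[0]["update_idx"] == 140
        assert len(kept) == 139

    def test_subject_losing_all_trials_warns(self):
        df = pd.concat(
            [
                _trials_frame({"nacc": np.arange(4.0)}, subject="subA"),
                _trials_frame({"nacc": np.arange(4.0)}, subject="subB"),
            ],
            ignore_index=True,
        )
        kept, _ = exclude_activity_outliers(df, k=4.0)
        assert set(kept["subject_id"]) == {"subA", "subB"}
        # an absurdly tight threshold removes every trial of both subjects
        with pytest.warns(UserWarning, match="all trials dropped"):
            exclude_activity_outliers(df, k=0.1)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            exclude_activity_outliers(_trials_frame({"nacc": np.arange(5.0)}), k=0)


class TestAggregation:
    def test_mean_of_two_subjects(self):
        df = pd.concat(
            [
                _trials_frame({"nacc": [0.1]}, subject="subA"),
                _trials_frame({"nacc": [0.3]}, subject="subB"),
            ],
            ignore_index=True,
        )
        indicators = pd.DataFrame(
            {
                "stock_id": ["S1"],
                "update_idx": [1],
                "prev_dir": [1],
                "next_dir": [-1],
                "inflection": [1],
                "excluded": [False],
                "exclude_reason": ["none"],
                "slope": [0.2],
                "volatility": [0.5],
            }
        )
        rec = aggregate_group(df, indicators)
        assert rec.loc[0, "nacc_mean"] == pytest.approx(0.2)
        assert rec.loc[0, "choice_mean"] == 0.0

    def test_full_market_yields_140_records(self, records):
        assert len(records) == 140
        assert list(records.columns) == [
            "stock_id", "update_idx", "prev_dir", "slope", "volatility",
            "choice_mean", "nacc_mean", "ains_mean", "mpfc_mean",
            "next_dir", "inflection", "excluded", "exclude_reason",
        ]

    def test_stable_price_trials_flagged_not_dropped(self):
        """Four forced zero-change days leave 136 analyzable of 140 records."""
        cfg = SimConfig(n_subjects=4, seed=31)
        rng = np.random.default_rng(31)
        from neuromarket import simulate_price_series

        stocks = []
        for i in range(14):
            s = simulate_price_series(31, rng=rng, stock_id=f"F{i:02d}")
            closes = s.closes.copy()
            if i < 2:
                closes[20] = closes[19]  # prev-change of update 1 is zero
            elif i < 4:
                closes[30] = closes[29]  # next-change of update 10 is zero
            stocks.append(StockSeries(s.stock_id, closes))
        trials = simulate_subjects(stocks, cfg, rng=rng)
        rec, _ = build_trial_table(stocks, trials)
        assert len(rec) == 140
        assert int(rec["excluded"].sum()) == 4
        assert (rec.loc[rec["excluded"], "exclude_reason"] == "stable_price").all()
        assert int((rec["exclude_reason"] == "none").sum()) == 136

    def test_empty_cell_raises_missing_data(self):
        df = _trials_frame({"nacc": [0.1]})
        indicators = pd.DataFrame(
            {
                "stock_id": ["S1", "S2"],
                "update_idx": [1, 1],
                "prev_dir": [1, 1],
                "next_dir": [1, 1],
                "inflection": [0, 0],
                "excluded": [False, False],
                "exclude_reason": ["none", "none"],
                "slope": [0.0, 0.0],
                "volatility": [0.0, 0.0],
            }
        )
        with pytest.raises(MissingDataError, match="S2"):
            aggregate_group(df, indicators)

    def test_aggregation_invariant_to_subject_relabeling(self, market_pair):
        market = market_pair[0]
        rec, _ = build_trial_table(market.stocks, market.subject_trials)
        relabeled = market.subject_trials.copy()
        ids = relabeled["subject_id"].unique()
        mapping = dict(zip(ids, np.roll(ids, 3)))
        relabeled["subject_id"] = relabeled["subject_id"].map(mapping)
        rec2, _ = build_trial_table(market.stocks, relabeled)
        pd.testing.assert_frame_equal(rec, rec2)

    def test_adding_mean_subject_leaves_means_unchanged(self):
        rng = np.random.default_rng(6)
        frames = [
            _trials_frame({v: rng.normal(size=3) for v in ("nacc", "ains", "mpfc")},
                          subject=f"sub{j}")
            for j in range(4)
        ]
        df = pd.concat(frames, ignore_index=True)
        means = df.groupby("update_idx")[["nacc", "ains", "mpfc"]].mean()
        clone = frames[0].copy()
        clone["subject_id"] = "subMean"
        clone[["nacc", "ains", "mpfc"]] = means.to_numpy()
        indicators = pd.DataFrame(
            {
                "stock_id": "S1",
                "update_idx": [1, 2, 3],
                "prev_dir": 1,
                "next_dir": 1,
                "inflection": 0,
                "excluded": False,
                "exclude_reason": "none",
                "slope": 0.0,
                "volatility": 0.0,
            }
        )
        rec1 = aggregate_group(df, indicators)
        rec2 = aggregate_group(pd.concat([df, clone], ignore_index=True), indicators)
        for col in ("nacc_mean", "ains_mean", "mpfc_mean"):
            np.testing.assert_allclose(rec1[col], rec2[col], atol=1e-12)
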