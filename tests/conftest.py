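import numpy as np
import pandas as pd
import pytest

from neuromarket import SimConfig, build_trial_table, simulate_market


def make_market_pair(seed: int, **overrides):
    """Two stratified markets with disjoint stocks under shared conditions."""
    cfg = SimConfig(**overrides)
    rng = np.random.default_rng(seed)
    m1 = simulate_market(cfg, label="exp1", rng=rng)
    m2 = simulate_market(cfg, label="exp2", exclude_ids=m1.stock_ids, rng=rng)
    return m1, m2


def tables_for(*markets):
    return tuple(build_trial_table(m.stocks, m.subject_trials)[0] for m in markets)


@pytest.fixture(scope="session")
def market_pair():
    """Study-scale pair: 14 stocks x 10 updates, 39 subjects, planted effects."""
    return make_market_pair(seed=11)


@pytest.fixture(scope="session")
def trial_tables(market_pair):
    return tables_for(*market_pair)


@pytest.fixture(scope="session")
def records(trial_tables):
    """One study-scale group trial table (140 stock x update records)."""
    return trial_tables[0]


@pytest.fixture()
def records_40():
    """Deterministic 40-record group trial table for oracle comparisons."""
    rng = np.random.default_rng(3)
    n = 40
    prev = rng.choice([-1, 1], size=n)
    df = pd.DataFrame(
        {
            "stock_id": np.repeat([f"S{i}" for i in range(4)], 10),
            "update_idx": np.tile(np.arange(1, 11), 4),
            "prev_dir": prev,
            "slope": rng.normal(0, 0.1, n),
            "volatility": rng.gamma(2.0, 2.0, n),
            "choice_mean": rng.uniform(0.3, 0.8, n),
            "nacc_mean": rng.normal(0, 0.2, n),
            "ains_mean": rng.normal(0, 0.2, n),
            "mpfc_mean": rng.normal(0, 0.2, n),
            "next_dir": rng.choice([-1, 1], size=n),
            "excluded": False,
            "exclude_reason": "none",
        }
    )
    df["inflection"] = (df["next_dir"] != df["prev_dir"]).astype(int)
    return df
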