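# Methods

## Overview

`neuromarket` is organized as five layers: a synthetic market/task/brain
generator (`simulate`), group trial-table construction (`features`),
logistic forecasting models and post-hoc tests (`models`), cross-market
classification with permutation nulls (`crossmarket`), and formats plus a
CLI/pipeline (`io`, `pipeline`, `cli`).  The model-fitting and
classification stages are scikit-learn-style estimators
(`LogisticForecaster`, `DirectionClassifier`) with `fit`, fitted
trailing-underscore attributes, and `get_params`/`set_params`; the
module-level functions are thin wrappers over them.

## Task geometry and the extra close

Each market holds 14 stocks × 10 displayed updates.  Every update shows a
21-point rolling window (20 prior daily closes plus the newest), z-scored
once per stock over the displayed 30-close span so all windows share one
vertical axis.  Because update *k*'s window ends at close *k* + 20, the
10th update's newest point is close 30 — and its next-day outcome requires
a 31st close.  The generator therefore emits `window_len + n_updates + 1 =
31` closes per stock; the display/z-scoring span remains the first 30.
This mirrors the task itself, where the final trial's feedback reveals one
post-display price.  `make_display_windows` accepts 30-close series (no
outcome needed); `code_outcomes` requires the extra close.

Outcome coding: `prev_dir` is the sign of the daily change ending at the
displayed newest point (always defined, even for update 1, since every
window carries 20 prior updates); `next_dir` is the sign of the following
day's change; `inflection = 1[next_dir ≠ prev_dir]`.  A change of exactly
zero cannot be signed: such trials are flagged `stable_price` and retained
with their flag, then filtered at model time, so exclusion counts stay
auditable.

## The generative model

Prices follow a driftable random walk whose change magnitudes are
half-normal with scale `daily_vol` and whose change signs repeat the
previous sign with probability φ (`sign_autocorr`).  This is the simplest
process giving independent control over lag-1 sign autocorrelation — the
market property that differed between the two study markets — while φ = 0.5
yields a sign-memoryless market in which the ±$1 invest gamble has exactly
zero expected value.  Stocks are drawn from a 60-candidate pool by
stratified selection over six bins (OLS slope sign × residual-sum-of-squares
tercile of the full series), two or three per bin.

Per subject × stock × update, choices follow
`invest ~ Bernoulli(logistic(logit(p_base) + w·slope))`, a mild
momentum-following policy that makes behavior non-degenerate yet carries no
information about next-day moves (the generative analogue of choice
behavior failing to forecast prices).  Payoffs are ±$1 on invest, $0 on
pass, accumulated against a $10 per-stock endowment.  Lagged VOI activity
is generated directly at the trial level:

    nacc = a·1[next move up]   + ε,   ε ~ N(0, σ)
    ains = b·1[next inflects]  + ε
    mpfc = ε                        (control region)

No BOLD time series is simulated: the analysis consumes only the
hemodynamically lagged trial scalar, so a time-series layer would add
nothing testable.  The 6-second lag convention of the original recordings
is embodied in the interpretation of these scalars as activity at trial
onset + 3 TRs.

### Default conditions and why

| parameter | default | rationale |
| --- | --- | --- |
| `n_stocks × n_updates` | 14 × 10 | study task geometry (140 trials) |
| `n_subjects` | 39 | replication-sample size |
| `p_invest_base` | 0.55 | observed ~54–55% invest rate |
| `choice_weight` w | 0.3 | mild momentum; behavior stays chance-level w.r.t. outcomes |
| `sign_autocorr` φ | 0.5 | sign-memoryless market (pipeline default: 0.40 for exp1, 0.50 for exp2, reproducing the first market's anti-persistence confound) |
| `daily_vol` | $1 on a $100 start price | ~1% daily moves, typical of large-cap equities |
| `effect_ains` b | 0.12 | ≈ 0.75 group-level SDs at n = 39 (group noise `σ/√n` ≈ 0.16): strong enough that the interaction is recoverable in ≥ 80% of replicates at α = 0.05, while single-market fits remain noisy |
| `effect_nacc` a | 0.10 | slightly weaker direction effect, same scale |
| `noise_sd` σ | 1.0 | unit trial-level noise after within-voxel normalization |

These defaults are the package's study conditions; they were chosen once
from the design considerations above and are not tuned per analysis.

## Trial-table construction

Activity outliers are removed before aggregation: a trial is dropped for a
subject when any VOI value deviates ≥ 4 sample SDs from that subject's own
mean for that VOI.  The within-subject × VOI reference matches the
within-voxel normalization of the upstream preprocessing; the boundary is
inclusive (exactly 4 SDs is dropped), and the SD is computed from exact
squared-deviation sums so the boundary is honored bit-for-bit.  A
zero-variance subject × VOI sample flags nothing.  Surviving subjects'
choices and activities are averaged within stock × update cells; an empty
cell raises a `MissingDataError` naming the cell.

Window OLS uses the integer time index 0..20 (units: trading-day updates),
so slopes are in z-units/update and volatility in squared z-units.

## Model fitting choices

* Plain fixed-effects logistic ML on the 140 stock × update records,
  predictors on their natural scales (no silent standardization).  By-stock
  cluster-robust (sandwich) SEs are always computed alongside the
  observed-information SEs and reported in the same tidy table
  (`se_cluster`), without asserting which variant is canonical.
* The intercept-only log-likelihood is computed in closed form
  (`n·[p̂ log p̂ + (1−p̂) log(1−p̂)]`), making the McFadden and model-χ²
  identities exact rather than dependent on a second optimizer run.
* Perfect or quasi-separation is flagged (`SeparationWarning`,
  `separated_ = True`) after a BFGS fallback fit rather than failing
  silently; rank-deficient designs raise an error naming the collinear
  terms.
* Post-hoc inflection contrasts default to Student's pooled-variance t
  (df = n₁ + n₂ − 2, matching the df convention of the reported contrasts);
  Welch's correction is available via `equal_var=False`.  Two identical
  constant groups return t = 0, p = 1 rather than NaN.

## Cross-market protocol

Balanced downsampling (uniform random removal from the majority outcome
class) is applied to both the training and the test table, so chance is
exactly 50% on both sides.  Features are standardized to the training
mean/SD only; the stored parameters transform the test market, and no test
statistic enters training.  The core classifier is a linear-kernel SVM with
cost C = 1 and no tuning.  Zero-variance features are dropped with a
warning.  Accuracy is reported with the normal-approximation 95% CI
`1.96·√(acc(1−acc)/n)` and a two-sided exact binomial test against 0.5.

"Randomized stock prices" in the permutation null means, by default,
permuting the within-stock sequence of daily changes and rebuilding the
closes — this preserves each stock's marginal volatility and its multiset
of changes while destroying temporal structure.  Group-averaged activity
and choices stay fixed; only their coupling to prices is destroyed.
Alternative readings (`shuffle_closes`, `shuffle_labels`) are exposed as
named strategies.  Each of the 500 replicates retrains on a freshly
randomized, re-balanced training table and tests on the untouched balanced
test set; the result is the accuracy distribution plus a one-sample t-test
against 0.5.  If every replicate produces the identical accuracy (possible
when the trained hyperplane is insensitive to the randomization) the t is
undefined and a `DegenerateNullError` is raised explicitly.

## Reproducibility

One master seed deterministically spawns named per-stage seeds
(`pipeline.stage_seed`), all below 2³¹, recorded in the run manifest
together with the configuration snapshot, package version, per-stage record
counts (generated / excluded by reason / analyzed), and SHA-256 digests of
every written file.  Re-running with the same configuration and seed
reproduces byte-identical tables.  All CSVs are UTF-8, header-mandatory,
period-decimal; currency is decimal dollars.

## Problem sizes used by the test suite

The statistical acceptance checks simulate 200 market pairs per condition
at study scale (14 stocks × 10 updates × 39 subjects) for parameter
recovery, and one 500-replicate permutation null on a no-effect market
pair; numerical-oracle checks use 1,000 random windows and a fixed
40-record table.  These sizes give Monte-Carlo error comfortably inside
the asserted bands while keeping a full run in the order of a minute.

## What the synthetic data does and does not show

The generator reproduces the study's *design* — trial counts, stratified
stock selection, rolling z-scored displays, near-55% invest rates, zero
expected value, lagged trial-level activity with effects of known sign and
size — so passing tests certify that the pipeline recovers what was
planted, at the planted scale, and stays calibrated when nothing is
planted.  It does not emulate real fMRI noise structure (temporal
autocorrelation, inter-subject variance components, scanner drift),
heavy-tailed return distributions, intraday dynamics, or any dependence of
choices on brain state; effect sizes of real recordings may differ from
the planted defaults.  Conclusions about real markets or real brains
require real data, which can be supplied as same-schema CSVs
(`read_daily_closes`, `read_subject_trials`, `read_trial_table`) and flow
through the identical downstream path.

## Known limitations

* The group-level logistic fits ignore within-stock dependence except via
  the optional cluster-robust SEs; no random-effects machinery is included.
* With only 140 records, the combined model (11 parameters) is prone to
  overfitting — visible as pseudo-R² rising while AIC worsens — which is
  precisely why the cross-market classifier, not the in-sample fit, is the
  headline evaluation.
* Exact-zero daily changes never arise from the continuous price process;
  the `stable_price` exclusion path is exercised via hand-built fixtures.
* The permutation null's t-test treats replicate accuracies as independent
  draws; they share one test set, so the test is conservative about
  between-replicate correlation.
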