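"""Logistic forecasting models and post-hoc tests on the group trial table.

The outcome of every model is the next-day price direction (1 = increase,
0 = decrease) of a stock × update record.  Model specifications mirror the
standard comparison set:

========== =============================================================
name       predictors (all models include an intercept)
========== =============================================================
null       —
market     slope, volatility, prev_dir
behavioral choice_mean
neural     nacc_mean, ains_mean, mpfc_mean
combined   union of the above plus the three VOI × prev_dir interactions
reduced    ains_mean, prev_dir, ains_x_prev
========== =============================================================

Fits are plain maximum-likelihood logistic GLMs on stock × update records
(predictors on their natural scales), with by-stock cluster-robust standard
errors always computed alongside the observed-information ones so both
variants can be reported.  Likelihood-ratio tests compare nested models and
pooled-variance t-tests decompose the AIns × previous-move interaction into
inflection-versus-continuation contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

try:  # sklearn estimator conventions
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    BaseEstimator = object

__all__ = [
    "MODEL_SPECS",
    "ModelSpec",
    "SeparationWarning",
    "LogisticForecaster",
    "LRTestResult",
    "TTestResult",
    "fit_logistic",
    "lr_test",
    "posthoc_inflection_ttest",
    "build_design",
]


class SeparationWarning(UserWarning):
    """The logistic likelihood is (quasi-)separated; estimates are unstable."""


#: interaction terms are products of a group-mean VOI column with prev_dir
INTERACTIONS = {
    "nacc_x_prev": ("nacc_mean", "prev_dir"),
    "ains_x_prev": ("ains_mean", "prev_dir"),
    "mpfc_x_prev": ("mpfc_mean", "prev_dir"),
}

BASE_TERMS = (
    "slope",
    "volatility",
    "prev_dir",
    "choice_mean",
    "nacc_mean",
    "ains_mean",
    "mpfc_mean",
)


@dataclass(frozen=True)
class ModelSpec:
    """A named logistic model: predictor labels (intercept implicit)."""

    name: str
    terms: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        valid = set(BASE_TERMS) | set(INTERACTIONS)
        unknown = [t for t in self.terms if t not in valid]
        if unknown:
            raise ValueError(f"unknown model terms: {unknown}")

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.terms) <= set(other.terms)


MODEL_SPECS: dict[str, ModelSpec] = {
    "null": ModelSpec("null", ()),
    "market": ModelSpec("market", ("slope", "volatility", "prev_dir")),
    "behavioral": ModelSpec("behavioral", ("choice_mean",)),
    "neural": ModelSpec("neural", ("nacc_mean", "ains_mean", "mpfc_mean")),
    "combined": ModelSpec(
        "combined",
        (
            "slope",
            "volatility",
            "prev_dir",
            "choice_mean",
            "nacc_mean",
            "nacc_x_prev",
            "ains_mean",
            "ains_x_prev",
            "mpfc_mean",
            "mpfc_x_prev",
        ),
    ),
    "reduced": ModelSpec("reduced", ("ains_mean", "prev_dir", "ains_x_prev")),
}


def _resolve_spec(spec: str | ModelSpec) -> ModelSpec:
    if isinstance(spec, ModelSpec):
        return spec
    try:
        return MODEL_SPECS[spec]
    except KeyError:
        raise ValueError(
            f"unknown model spec {spec!r}; choose from {sorted(MODEL_SPECS)}"
        ) from None


def _analysis_records(records: pd.DataFrame) -> pd.DataFrame:
    if "excluded" in records.columns:
        records = records.loc[~records["excluded"].astype(bool)]
    return records


def build_design(
    records: pd.DataFrame, terms: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix (with intercept), 0/1 outcome, and column names.

    Interaction columns are built explicitly as products of the group-mean
    VOI column with ``prev_dir``.  Excluded records must be filtered by the
    caller; the outcome is ``next_dir`` recoded 1 = increase, 0 = decrease.
    """
    cols = [np.ones(len(records))]
    names = ["intercept"]
    for term in terms:
        if term in INTERACTIONS:
            a, b = INTERACTIONS[term]
            col = records[a].to_numpy(float) * records[b].to_numpy(float)
        else:
            col = records[term].to_numpy(float)
        cols.append(col)
        names.append(term)
    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite predictor values in design matrix")
    y = (records["next_dir"].to_numpy(int) == 1).astype(float)
    return X, y, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = []
        current = 0
        for j in range(X.shape[1]):
            r = np.linalg.matrix_rank(X[:, : j + 1])
            if r == current:
                collinear.append(names[j])
            current = r
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")


class LogisticForecaster(BaseEstimator):
    """Maximum-likelihood logistic forecaster of next-day price direction.

    scikit-learn-style estimator over a group trial table.  ``fit`` consumes
    a records DataFrame (excluded rows are filtered out), fits the logistic
    GLM of the chosen specification by Newton's method, and exposes the
    fitted quantities as trailing-underscore attributes.

    Parameters
    ----------
    spec
        A :data:`MODEL_SPECS` name or an explicit :class:`ModelSpec`.

    Attributes
    ----------
    params_, bse_, zvalues_, pvalues_ : pandas.Series indexed by term
        Coefficients, observed-information SEs, Wald z, and p-values.
    bse_cluster_ : pandas.Series
        By-stock cluster-robust (sandwich) SEs, reported alongside.
    llf_, ll_null_, aic_, mcfadden_r2_ : float
        Log-likelihood, intercept-only log-likelihood, Akaike information
        criterion ``2k − 2·ll``, and McFadden pseudo-R² ``1 − ll/ll_null``.
    n_obs_ : int
    converged_, separated_ : bool
        Convergence flag and whether (quasi-)separation was detected; a
        :class:`SeparationWarning` is emitted rather than failing silently.
    """

    def __init__(self, spec: str | ModelSpec = "combined"):
        self.spec = spec

    # -- sklearn API ---------------------------------------------------
    def fit(self, records: pd.DataFrame, y=None) -> "LogisticForecaster":
        spec = _resolve_spec(self.spec)
        data = _analysis_records(records)
        X, outcome, names = build_design(data, spec.terms)
        _check_rank(X, names)

        separated = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                result = sm.Logit(outcome, X).fit(disp=0, method="newton", maxiter=100)
            except (PerfectSeparationError, np.linalg.LinAlgError):
                separated = True
                result = sm.Logit(outcome, X).fit(disp=0, method="bfgs", maxiter=500)
        separated = separated or any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        )
        converged = bool(result.mle_retvals.get("converged", False))
        if np.max(np.abs(result.params)) > 30:
            separated = True
        if separated:
            warnings.warn(
                f"(quasi-)separation detected in {spec.name!r} model fit; "
                "coefficients are unstable",
                SeparationWarning,
                stacklevel=2,
            )

        self.spec_ = spec
        self.term_names_ = names
        self.result_ = result
        self.params_ = pd.Series(result.params, index=names)
        self.bse_ = pd.Series(result.bse, index=names)
        self.zvalues_ = pd.Series(result.tvalues, index=names)
        self.pvalues_ = pd.Series(result.pvalues, index=names)
        self.llf_ = float(result.llf)
        # intercept-only log-likelihood in closed form: n·H(p̂) up to sign
        p_hat = outcome.mean()
        if 0.0 < p_hat < 1.0:
            self.ll_null_ = float(
                len(outcome) * (p_hat * np.log(p_hat) + (1 - p_hat) * np.log1p(-p_hat))
            )
        else:  # degenerate all-one-class outcome
            self.ll_null_ = 0.0
        self.aic_ = 2 * len(names) - 2 * self.llf_
        # >= 0 for any ML fit with intercept; clamp float jitter only
        self.mcfadden_r2_ = (
            max(0.0, 1.0 - self.llf_ / self.ll_null_) if self.ll_null_ != 0 else 0.0
        )
        self.n_obs_ = int(len(data))
        self.converged_ = converged and not separated
        self.separated_ = separated
        self.bse_cluster_ = self._cluster_bse(data, X, outcome)
        return self

    def _cluster_bse(
        self, data: pd.DataFrame, X: np.ndarray, outcome: np.ndarray
    ) -> pd.Series | None:
        """By-stock sandwich SEs, reported alongside the plain ones."""
        if "stock_id" not in data.columns or data["stock_id"].nunique() < 2:
            return None
        groups = pd.factorize(data["stock_id"])[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                robust = sm.Logit(outcome, X).fit(
                    disp=0,
                    method="newton",
                    maxiter=100,
                    cov_type="cluster",
                    cov_kwds={"groups": groups},
                )
            except Exception:  # separation etc.: plain SEs remain available
                return None
        return pd.Series(np.asarray(robust.bse), index=self.term_names_)

    def predict_proba(self, records: pd.DataFrame) -> np.ndarray:
        """P(next-day increase) for each non-excluded record."""
        data = _analysis_records(records)
        X, _, _ = build_design(data, self.spec_.terms)
        return self.result_.model.predict(self.result_.params, exog=X)

    # -- reporting ------------------------------------------------------
    def tidy(self) -> pd.DataFrame:
        """Tidy per-term summary (term, estimate, se, se_cluster, z, p)."""
        out = pd.DataFrame(
            {
                "term": self.term_names_,
                "estimate": self.params_.to_numpy(),
                "se": self.bse_.to_numpy(),
                "z": self.zvalues_.to_numpy(),
                "p": self.pvalues_.to_numpy(),
            }
        )
        if self.bse_cluster_ is not None:
            out["se_cluster"] = self.bse_cluster_.to_numpy()
        return out

    def info(self) -> dict:
        """Scalar fit summary: ll, aic, McFadden R², n, convergence."""
        return {
            "model": self.spec_.name,
            "ll": self.llf_,
            "ll_null": self.ll_null_,
            "aic": self.aic_,
            "mcfadden_r2": self.mcfadden_r2_,
            "n_obs": self.n_obs_,
            "converged": self.converged_,
            "separated": self.separated_,
        }


def fit_logistic(records: pd.DataFrame, spec: str | ModelSpec) -> LogisticForecaster:
    """Fit one named logistic specification; returns the fitted forecaster."""
    return LogisticForecaster(spec=spec).fit(records)


class LRTestResult(NamedTuple):
    chi2: float
    df: int
    p: float


def lr_test(nested: LogisticForecaster, full: LogisticForecaster) -> LRTestResult:
    """Likelihood-ratio test of a nested against a fuller logistic model.

    ``chi2 = 2(ll_full − ll_nested)``, df the difference in parameter
    counts.  With the intercept-only model as ``nested`` this is the overall
    model chi-square.  Identical specifications give chi2 = 0, p = 1.
    """
    if not nested.spec_.is_nested_in(full.spec_):
        raise ValueError(
            f"{nested.spec_.name!r} is not nested in {full.spec_.name!r}"
        )
    if nested.n_obs_ != full.n_obs_:
        raise ValueError("models were fit on different record counts")
    chi2 = 2.0 * (full.llf_ - nested.llf_)
    chi2 = max(chi2, 0.0)
    df = len(full.term_names_) - len(nested.term_names_)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LRTestResult(chi2=float(chi2), df=df, p=p)


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int


def posthoc_inflection_ttest(
    records: pd.DataFrame,
    voi: str = "ains_mean",
    *,
    contrast: str = "inflection",
    equal_var: bool = True,
) -> TTestResult:
    """Two-sample t-test of group-mean VOI activity across outcome contrasts.

    ``contrast="inflection"`` compares records preceding a price inflection
    (group *a*) against continuations (group *b*); a positive t means higher
    activity before inflections.  ``contrast="inc_dec_vs_dec_dec"`` is the
    nested decomposition: decreases following an increase versus decreases
    following a decrease.  The default is the Student pooled-variance test
    (df = n_a + n_b − 2); ``equal_var=False`` gives Welch's variant.
    """
    data = _analysis_records(records)
    if contrast == "inflection":
        a = data.loc[data["inflection"] == 1, voi]
        b = data.loc[data["inflection"] == 0, voi]
    elif contrast == "inc_dec_vs_dec_dec":
        dec = data.loc[data["next_dir"] == -1]
        a = dec.loc[dec["prev_dir"] == 1, voi]
        b = dec.loc[dec["prev_dir"] == -1, voi]
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"both groups need >= 2 records (got {len(a)} and {len(b)})"
        )
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        # degenerate but well-defined: identical constant groups differ by 0
        t_val, df_val, p_val = 0.0, float(len(a) + len(b) - 2), 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.ttest_ind(a, b, equal_var=equal_var)
        t_val, df_val, p_val = float(res.statistic), float(res.df), float(res.pvalue)
    return TTestResult(
        t=t_val,
        df=df_val,
        p=p_val,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(len(a)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(len(b)),
    )
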