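"""Stabilized inverse-probability weights for treatment and censoring.

The treatment model is a main-effects logistic regression of arm-A
membership on baseline covariates; its stabilized weight
``P(arm)/p_i`` is constant over a patient's follow-up.  Censoring
models are pooled logistic regressions of a cause-specific censoring
indicator on a time term plus baseline and time-varying covariates
(denominator) or the time term plus baseline covariates only
(numerator); the stabilized censoring weight at month *k* is the
cumulative product of monthly numerator/denominator survival ratios.
Total weights are the product, optionally truncated at an empirical
percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "TreatmentWeightModel",
    "CensoringWeightModel",
    "WeightSet",
    "fit_treatment_model",
    "stabilized_iptw",
    "fit_censoring_model",
    "stabilized_ipcw",
    "combine_and_truncate",
    "weighted_smd",
]

_SEPARATION_BOUND = 15.0  # |log-odds| beyond this flags separation
_TIME_TERMS = {
    "categorical": "C(month_t)",
    "linear": "month_t",
    "quadratic": "month_t + I(month_t**2)",
    "spline": "bs(month_t, df=4)",
}


def _rhs(terms) -> str:
    terms = [t for t in terms if t]
    return " + ".join(terms) if terms else "1"


def _check_separation(result, skip_prefixes=("C(month_t)", "bs(month_t", "Intercept")):
    for name, val in result.params.items():
        if any(name.startswith(p) for p in skip_prefixes):
            continue
        if abs(val) > _SEPARATION_BOUND:
            raise ValueError(
                f"apparent separation: coefficient on {name!r} is {val:.1f}"
            )


class TreatmentWeightModel(BaseEstimator):
    """Propensity model and stabilized IPTW.

    Parameters
    ----------
    covariates : patsy-compatible baseline covariate terms (main
        effects); empty means an intercept-only model, whose stabilized
        weights are exactly 1.
    prob_floor : optional (lo, hi) clip on fitted probabilities; off by
        default so positivity violations fail loudly.

    Attributes (after fit)
    ----------------------
    result_ : statsmodels GLM results.
    marginal_share_ : P(arm A) in the fitting sample.
    propensity_ : fitted P(arm A | X) for the fitting rows.
    coef_, se_ : coefficient table as Series.
    """

    def __init__(self, covariates=(), prob_floor=None):
        self.covariates = covariates
        self.prob_floor = prob_floor

    def _design(self, df):
        if not hasattr(self, "design_info_"):
            X = patsy.dmatrix(_rhs(self.covariates), df, return_type="dataframe")
            self.design_info_ = X.design_info
            return X
        return patsy.build_design_matrices(
            [self.design_info_], df, return_type="dataframe"
        )[0]

    def fit(self, cohort, y=None):
        arms = set(cohort["arm"].unique())
        if arms != {"A", "B"}:
            raise ValueError(f"need both arms present, got {sorted(arms)}")
        target = (cohort["arm"] == "A").astype(float)
        X = self._design(cohort)
        self.result_ = sm.GLM(target, X, family=sm.families.Binomial()).fit()
        _check_separation(self.result_)
        self.marginal_share_ = float(target.mean())
        self.propensity_ = np.asarray(self.result_.predict(X))
        self.coef_ = self.result_.params
        self.se_ = self.result_.bse
        return self

    def predict_proba(self, cohort) -> np.ndarray:
        X = patsy.build_design_matrices(
            [self.design_info_], cohort, return_type="dataframe"
        )[0]
        p = np.asarray(self.result_.predict(X))
        if self.prob_floor is not None:
            lo, hi = self.prob_floor
            p = np.clip(p, lo, hi)
        return p

    def transform(self, cohort) -> np.ndarray:
        """Stabilized IPTW, one value per row of ``cohort``."""
        p = self.predict_proba(cohort)
        eps = np.finfo(float).eps
        if np.any(p <= eps) or np.any(p >= 1 - eps):
            raise ValueError(
                "fitted treatment probabilities reach 0 or 1 (positivity "
                "violation); refine the model or set prob_floor"
            )
        a = (cohort["arm"] == "A").to_numpy()
        share = self.marginal_share_
        return np.where(a, share / p, (1 - share) / (1 - p))

    def fit_transform(self, cohort, y=None):
        return self.fit(cohort).transform(cohort)


class CensoringWeightModel(BaseEstimator):
    """Cause-specific censoring hazard models (denominator + numerator).

    The denominator regresses the censoring indicator on the time term,
    baseline covariates and time-varying covariates over all at-risk
    person-months; the stabilizing numerator uses the time term and
    baseline covariates only — never time-varying ones.

    With zero censoring events of the cause the model degenerates to
    hazard 0 (weights 1) and a warning is recorded.
    """

    def __init__(self, cause="ltfu", baseline_covariates=(), tv_covariates=(),
                 time_form="quadratic"):
        self.cause = cause
        self.baseline_covariates = baseline_covariates
        self.tv_covariates = tv_covariates
        self.time_form = time_form

    @property
    def _flag(self):
        if self.cause not in ("ltfu", "deviation"):
            raise ValueError(f"unknown censoring cause {self.cause!r}")
        return f"censor_{self.cause}"

    def fit(self, pm, y=None):
        if self.time_form not in _TIME_TERMS:
            raise ValueError(f"unknown time_form {self.time_form!r}")
        tt = _TIME_TERMS[self.time_form]
        target = pm[self._flag].astype(float)
        self.degenerate_ = target.sum() == 0
        if self.degenerate_:
            warnings.warn(
                f"no {self.cause} censoring events; censoring weights are 1",
                stacklevel=2,
            )
            return self
        den_rhs = _rhs([tt, *self.baseline_covariates, *self.tv_covariates])
        num_rhs = _rhs([tt, *self.baseline_covariates])
        Xd = patsy.dmatrix(den_rhs, pm, return_type="dataframe")
        Xn = patsy.dmatrix(num_rhs, pm, return_type="dataframe")
        self._den_info, self._num_info = Xd.design_info, Xn.design_info
        self.den_result_ = sm.GLM(target, Xd, family=sm.families.Binomial()).fit()
        self.num_result_ = sm.GLM(target, Xn, family=sm.families.Binomial()).fit()
        _check_separation(self.den_result_)
        return self

    def predict_hazard(self, pm, which="den") -> np.ndarray:
        if self.degenerate_:
            return np.zeros(len(pm))
        info = self._den_info if which == "den" else self._num_info
        res = self.den_result_ if which == "den" else self.num_result_
        X = patsy.build_design_matrices([info], pm, return_type="dataframe")[0]
        return np.asarray(res.predict(X))


@dataclass
class WeightSet:
    """Per person-month weights, aligned to the person-month table rows."""

    frame: pd.DataFrame  # iptw_stab, ipcw_stab_cum, total_weight
    truncation_percentile: object = None
    truncation_cap: float = float("nan")

    @property
    def total(self) -> np.ndarray:
        return self.frame["total_weight"].to_numpy()

    def diagnostics(self) -> pd.DataFrame:
        t = self.total
        return pd.DataFrame(
            {
                "mean": [t.mean()],
                "sd": [t.std(ddof=1)] if len(t) > 1 else [0.0],
                "min": [t.min()],
                "max": [t.max()],
                "cap": [self.truncation_cap],
            }
        )


def fit_treatment_model(cohort, covariate_names=()) -> TreatmentWeightModel:
    return TreatmentWeightModel(covariates=tuple(covariate_names)).fit(cohort)


def stabilized_iptw(model: TreatmentWeightModel, cohort) -> np.ndarray:
    return model.transform(cohort)


def fit_censoring_model(
    pm, cause="ltfu", baseline_covariates=(), tv_covariates=(), time_form="quadratic"
) -> CensoringWeightModel:
    return CensoringWeightModel(
        cause=cause,
        baseline_covariates=tuple(baseline_covariates),
        tv_covariates=tuple(tv_covariates),
        time_form=time_form,
    ).fit(pm)


def stabilized_ipcw(models, pm) -> np.ndarray:
    """Cumulative stabilized IPCW per person-month row.

    ``models`` is one or several fitted :class:`CensoringWeightModel`;
    for per-protocol analyses pass both the loss-to-follow-up and the
    deviation-cause model and their monthly factors multiply.  The
    month-*k* weight is the within-patient cumulative product (months
    0..k inclusive) of ``(1 - numerator hazard) / (1 - denominator
    hazard)``.
    """
    if isinstance(models, CensoringWeightModel):
        models = [models]
    factor = np.ones(len(pm))
    for model in models:
        p_den = model.predict_hazard(pm, "den")
        p_num = model.predict_hazard(pm, "num")
        if np.any(1 - p_den <= 0):
            raise ValueError("denominator censoring probability reaches 1 (positivity)")
        factor *= (1 - p_num) / (1 - p_den)
    order = np.lexsort([pm["month_t"].to_numpy(), pm["patient_id"].to_numpy()])
    pid_sorted = pm["patient_id"].to_numpy()[order]
    cum_sorted = (
        pd.Series(factor[order]).groupby(pid_sorted, sort=False).cumprod().to_numpy()
    )
    cum = np.empty(len(pm))
    cum[order] = cum_sorted
    return cum


def combine_and_truncate(iptw, ipcw, percentile=99, explicit_percentile=None) -> WeightSet:
    """Multiply IPTW and IPCW and cap at an empirical percentile.

    ``percentile`` must be None, 95 or 99; any other value is rejected
    unless passed via ``explicit_percentile`` (open interval (50, 100)).
    The cap is the linear-interpolation empirical quantile of the total
    weights over all person-months.
    """
    iptw = np.asarray(iptw, float)
    ipcw = np.asarray(ipcw, float)
    if iptw.shape != ipcw.shape:
        raise ValueError("iptw and ipcw must be aligned per person-month")
    total = iptw * ipcw
    if not np.all(np.isfinite(total)) or np.any(total <= 0):
        raise ValueError("weights must be finite and positive")
    if explicit_percentile is not None:
        if not (50 < explicit_percentile < 100):
            raise ValueError("explicit_percentile must be in (50, 100)")
        pct = float(explicit_percentile)
    elif percentile is None or (isinstance(percentile, str) and percentile == "none"):
        pct = None
    elif percentile in (95, 99):
        pct = float(percentile)
    else:
        raise ValueError(
            "percentile must be None, 95 or 99; use explicit_percentile for other values"
        )
    if pct is None:
        cap = float("nan")
        capped = total
    else:
        cap = float(np.quantile(total, pct / 100.0, method="linear"))
        capped = np.minimum(total, cap)
    frame = pd.DataFrame(
        {"iptw_stab": iptw, "ipcw_stab_cum": ipcw, "total_weight": capped}
    )
    return WeightSet(frame, percentile if pct is not None else None, cap)


def weighted_smd(cohort, weights, covariates) -> pd.Series:
    """Weighted standardized mean differences between arms.

    The balance diagnostic for IPTW: for each covariate, the difference
    of weighted arm means divided by the pooled (unweighted) standard
    deviation.  Values below 0.1 are conventionally called balanced.
    """
    w = np.asarray(weights, float)
    a = (cohort["arm"] == "A").to_numpy()
    out = {}
    for cov in covariates:
        x = cohort[cov].to_numpy(float)
        m1 = np.average(x[a], weights=w[a])
        m0 = np.average(x[~a], weights=w[~a])
        v1 = np.average((x[a] - m1) ** 2, weights=w[a])
        v0 = np.average((x[~a] - m0) ** 2, weights=w[~a])
        denom = np.sqrt((v1 + v0) / 2)
        out[cov] = (m1 - m0) / denom if denom > 0 else 0.0
    return pd.Series(out, name="smd")
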