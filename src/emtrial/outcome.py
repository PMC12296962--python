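"""Weighted pooled logistic discrete-time hazard model and effect measures.

With rare per-month risks the pooled logistic model approximates a
proportional-hazards model, so exp(arm coefficient) is reported as a
hazard ratio.  Estimation is a weighted independence logistic
regression (GLM with frequency weights) with a patient-clustered
sandwich covariance — the standard marginal-structural-model estimator.
Standardized risk curves follow the g-formula: each patient's monthly
hazard is predicted under both arm assignments, converted to cumulative
incidence, and averaged with stabilized baseline weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .weights import WeightSet, _TIME_TERMS, _check_separation

__all__ = [
    "PooledLogisticHazard",
    "EffectEstimate",
    "fit_pooled_logistic",
    "hazard_ratio",
    "standardized_risk_curves",
    "risk_difference",
]


@dataclass
class EffectEstimate:
    """One estimand x outcome row of a results table."""

    estimand: str
    outcome: str
    hr: float
    hr_ci: tuple
    rd_horizon: float = float("nan")
    rd_ci: tuple = (float("nan"), float("nan"))
    n_events: dict = None
    person_years: dict = None
    incidence_rate: dict = None
    flagged: bool = False

    def to_row(self) -> dict:
        row = {
            "estimand": self.estimand,
            "outcome": self.outcome,
            "hr": self.hr,
            "hr_lo": self.hr_ci[0],
            "hr_hi": self.hr_ci[1],
            "rd_pct": self.rd_horizon,
            "rd_lo": self.rd_ci[0],
            "rd_hi": self.rd_ci[1],
            "flagged": self.flagged,
        }
        for arm in ("A", "B"):
            row[f"events_{arm}"] = (self.n_events or {}).get(arm, np.nan)
            row[f"person_years_{arm}"] = (self.person_years or {}).get(arm, np.nan)
            row[f"rate_{arm}"] = (self.incidence_rate or {}).get(arm, np.nan)
        return row


class PooledLogisticHazard(BaseEstimator):
    """Discrete-time hazard model on person-month records.

    Parameters
    ----------
    time_form : "indicator" (categorical month, default), "linear",
        "quadratic" or "spline" (restricted cubic-ish B-spline, df=4).
    covariates : additional patsy terms (baseline covariates for ITT,
        plus time-varying covariates for PP if configured).

    Attributes (after fit)
    ----------------------
    result_ : statsmodels results with cluster-robust covariance.
    arm_coef_, arm_se_ : arm-A log hazard ratio and its robust SE.
    unidentifiable_ : True when an arm has zero events; ``hazard_ratio``
        then returns (nan, (0, inf)) instead of crashing.
    """

    TIME_TERMS = {**_TIME_TERMS, "indicator": "C(month_t)"}

    def __init__(self, time_form="indicator", covariates=()):
        self.time_form = time_form
        self.covariates = covariates

    def fit(self, pm, sample_weight=None):
        if self.time_form not in self.TIME_TERMS:
            raise ValueError(f"unknown time_form {self.time_form!r}")
        if isinstance(sample_weight, WeightSet):
            sample_weight = sample_weight.total
        data = pm.copy()
        data["arm_a"] = (data["arm"] == "A").astype(float)
        y = data["event"].astype(float)

        ev_by_arm = data.groupby("arm")["event"].sum()
        self.events_per_arm_ = {a: int(ev_by_arm.get(a, 0)) for a in ("A", "B")}
        self.unidentifiable_ = min(self.events_per_arm_.values()) == 0
        if self.unidentifiable_:
            warnings.warn("zero events in one arm; hazard ratio unidentifiable",
                          stacklevel=2)
            return self

        rhs = " + ".join(["arm_a", self.TIME_TERMS[self.time_form], *self.covariates])
        X = patsy.dmatrix(rhs, data, return_type="dataframe")
        self.design_info_ = X.design_info
        self.months_ = np.sort(data["month_t"].unique())
        groups = pd.factorize(data["patient_id"])[0]
        model = sm.GLM(
            y,
            X,
            family=sm.families.Binomial(),
            freq_weights=np.asarray(sample_weight, float)
            if sample_weight is not None
            else None,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # freq-weight df warnings
            self.result_ = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
        _check_separation(self.result_, skip_prefixes=("C(month_t)", "bs(month_t",
                                                       "Intercept"))
        self.params_ = self.result_.params
        self.cov_ = self.result_.cov_params()
        self.arm_coef_ = float(self.params_["arm_a"])
        self.arm_se_ = float(self.result_.bse["arm_a"])
        return self

    def hazard_ratio(self, alpha=0.05):
        """(hr, (lo, hi)) from the arm coefficient and its robust SE."""
        if getattr(self, "unidentifiable_", False):
            return float("nan"), (0.0, float("inf"))
        z = stats.norm.ppf(1 - alpha / 2)
        return (
            float(np.exp(self.arm_coef_)),
            (
                float(np.exp(self.arm_coef_ - z * self.arm_se_)),
                float(np.exp(self.arm_coef_ + z * self.arm_se_)),
            ),
        )

    def predict_hazard(self, pm) -> np.ndarray:
        """Predicted monthly event probability for new person-months."""
        if getattr(self, "unidentifiable_", False):
            raise ValueError("model is unidentifiable (zero events in an arm)")
        data = pm.copy()
        if "arm_a" not in data.columns:
            data["arm_a"] = (data["arm"] == "A").astype(float)
        X = patsy.build_design_matrices([self.design_info_], data,
                                        return_type="dataframe")[0]
        return np.asarray(self.result_.predict(X))


def fit_pooled_logistic(pm, weights=None, time_form="indicator", covariates=()):
    """Thin wrapper returning a fitted :class:`PooledLogisticHazard`."""
    return PooledLogisticHazard(time_form=time_form, covariates=tuple(covariates)).fit(
        pm, sample_weight=weights
    )


def hazard_ratio(model: PooledLogisticHazard, alpha=0.05):
    return model.hazard_ratio(alpha=alpha)


def standardized_risk_curves(
    model: PooledLogisticHazard,
    cohort: pd.DataFrame,
    weights=None,
    horizon: int = 12,
) -> pd.DataFrame:
    """G-formula cumulative incidence per arm, standardized over patients.

    For each arm the model predicts every patient's monthly hazard with
    ``arm`` set to that arm (time-varying covariates, if in the model,
    are held at their baseline values), converts to cumulative incidence
    ``1 - prod(1 - h)``, and averages over patients with the supplied
    stabilized baseline weights (default: unweighted).

    Returns a DataFrame indexed by month 1..horizon with columns "A",
    "B"; both curves are non-decreasing by construction.
    """
    months = getattr(model, "months_", None)
    if months is not None and horizon > len(months):
        raise ValueError(
            f"horizon {horizon} exceeds the fitted time range ({len(months)} months)"
        )
    n = len(cohort)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    base = cohort.reset_index(drop=True)
    rep = base.iloc[np.repeat(np.arange(n), horizon)].reset_index(drop=True)
    rep["month_t"] = np.tile(np.arange(horizon), n)
    curves = {}
    for arm in ("A", "B"):
        cf = rep.copy()
        cf["arm"] = arm
        cf["arm_a"] = float(arm == "A")
        h = model.predict_hazard(cf).reshape(n, horizon)
        surv = np.cumprod(1 - h, axis=1)
        ci = 1 - surv
        curves[arm] = np.average(ci, axis=0, weights=w)
    out = pd.DataFrame(curves, index=pd.RangeIndex(1, horizon + 1, name="month"))
    return out


def risk_difference(
    curves: pd.DataFrame,
    horizon: int,
    bootstrap_reps: int = 0,
    seed: int = 0,
    refit=None,
):
    """Risk difference (arm A - arm B) at ``horizon``, in percentage points.

    A confidence interval is computed by nonparametric bootstrap over
    patients when a ``refit`` callable is supplied: ``refit(rng)`` must
    resample patients, refit weights and model, and return a new curve
    frame.  Percentile CI. Without ``refit`` only the point estimate is
    returned (CI = (nan, nan)).
    """
    if horizon not in curves.index:
        raise ValueError(f"horizon {horizon} not in curves (max {curves.index.max()})")
    rd = 100.0 * (curves.loc[horizon, "A"] - curves.loc[horizon, "B"])
    if refit is None:
        return float(rd), (float("nan"), float("nan"))
    if bootstrap_reps < 2:
        raise ValueError("bootstrap_reps must be >= 2")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(bootstrap_reps):
        c = refit(rng)
        reps.append(100.0 * (c.loc[horizon, "A"] - c.loc[horizon, "B"]))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(rd), (float(lo), float(hi))
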