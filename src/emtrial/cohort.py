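"""Cohort construction: eligibility, grace-period arm assignment, imputation.

Eligibility is an ordered list of named rules applied sequentially, so
the resulting :class:`EligibilityReport` reads like the attrition
flowchart of a study-selection diagram.  Rules consume precomputed
boolean flags (claims-code to flag mapping is out of scope) plus the
fills and events tables for the washout and outcome-free criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = [
    "EligibilityReport",
    "apply_eligibility",
    "assign_treatment_arm",
    "default_rules",
    "ChainedEquationsImputer",
    "impute_missing",
]

DAYS_PER_MONTH = 30


@dataclass
class EligibilityReport:
    """Ordered attrition table: one row per applied criterion."""

    rows: pd.DataFrame  # columns: criterion, n_before, n_excluded, n_after

    def __post_init__(self):
        r = self.rows
        if len(r):
            if not (r["n_after"] == r["n_before"] - r["n_excluded"]).all():
                raise ValueError("report rows do not balance")
            if not (r["n_before"].iloc[1:].to_numpy() == r["n_after"].iloc[:-1].to_numpy()).all():
                raise ValueError("report rows do not chain")

    @property
    def final_n(self) -> int:
        return int(self.rows["n_after"].iloc[-1]) if len(self.rows) else 0

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def __str__(self) -> str:
        lines = ["Attrition:"]
        for _, r in self.rows.iterrows():
            lines.append(
                f"  {r.criterion:<28s} {r.n_before:>8d} -> {r.n_after:>8d}"
                f"  (excluded {r.n_excluded})"
            )
        return "\n".join(lines)


# ------------------------------------------------------------- rules


def _need(patients: pd.DataFrame, field: str, rule: str) -> pd.Series:
    if field not in patients.columns:
        raise ValueError(f"eligibility rule {rule!r} references absent field {field!r}")
    return patients[field]


def _keep_min_age(patients, fills, events, min_age=66):
    return _need(patients, "age_at_index", "min_age") >= min_age


def _keep_prior_cancer(patients, fills, events):
    return _need(patients, "cancer_type", "prior_cancer").notna()


def _keep_continuous_enrollment(patients, fills, events):
    return _need(patients, "continuous_enrollment", "continuous_enrollment").astype(bool)


def _keep_score_threshold(patients, fills, events, threshold=2):
    if threshold in (None, "all"):
        return pd.Series(True, index=patients.index)
    return _need(patients, "cha2ds2_vasc", "score_threshold") >= int(threshold)


def _keep_oac_washout(patients, fills, events):
    prior = fills.loc[fills["day"] < 0, "patient_id"].unique()
    return ~_need(patients, "patient_id", "oac_washout").isin(prior)


def _flag_rule(field):
    def rule(patients, fills, events):
        return ~_need(patients, field, field).astype(bool)

    return rule


def _keep_outcome_free(patients, fills, events, outcome=None):
    """Exclude patients with the outcome before treatment start.

    ``outcome`` may be a single name (per-outcome reading, the default
    pipeline behaviour) or a list of names (the global reading).
    """
    start = _need(patients, "treatment_start_day", "outcome_free")
    names = [outcome] if isinstance(outcome, str) else list(outcome or [])
    if not names:
        raise ValueError("outcome_free rule needs an 'outcome' parameter")
    ev = events[events["event_type"].isin(names)]
    merged = ev.merge(
        patients[["patient_id", "treatment_start_day"]], on="patient_id", how="inner"
    )
    bad = merged.loc[merged["day"] < merged["treatment_start_day"], "patient_id"].unique()
    return ~patients["patient_id"].isin(bad)


RULE_REGISTRY = {
    "min_age": _keep_min_age,
    "prior_cancer": _keep_prior_cancer,
    "continuous_enrollment": _keep_continuous_enrollment,
    "score_threshold": _keep_score_threshold,
    "oac_washout": _keep_oac_washout,
    "no_contraindication": _flag_rule("contraindication"),
    "no_recent_stroke": _flag_rule("recent_stroke_14d"),
    "no_recent_bleed": _flag_rule("recent_bleed_30d"),
    "no_renal_failure": _flag_rule("renal_failure_esrd"),
    "initiated_within_grace": lambda p, f, e: _need(p, "arm", "initiated_within_grace")
    .isin(["A", "B"]),
    "outcome_free": _keep_outcome_free,
}


def default_rules(score_threshold=2, outcome=None, outcome_free_global=False):
    """The shipped criterion list, in protocol order."""
    rules = [
        {"name": "min_age", "min_age": 66},
        {"name": "prior_cancer"},
        {"name": "continuous_enrollment"},
        {"name": "score_threshold", "threshold": score_threshold},
        {"name": "oac_washout"},
        {"name": "no_contraindication"},
        {"name": "no_recent_stroke"},
        {"name": "no_recent_bleed"},
        {"name": "no_renal_failure"},
        {"name": "initiated_within_grace"},
    ]
    if outcome is not None:
        rules.append(
            {
                "name": "outcome_free",
                "outcome": list(outcome) if outcome_free_global and not isinstance(outcome, str) else outcome,
            }
        )
    return rules


def apply_eligibility(patients, fills, events, rules):
    """Apply ordered eligibility rules; return (cohort, EligibilityReport).

    Each rule is a mapping with a ``name`` key (see ``RULE_REGISTRY``)
    plus rule-specific parameters.  Rules are applied sequentially; the
    report row for rule *i* counts exclusions among patients who passed
    rules 0..i-1, reproducing an attrition flowchart.
    """
    current = patients.copy()
    rows = []
    for rule in rules:
        params = dict(rule)
        name = params.pop("name")
        if name not in RULE_REGISTRY:
            raise ValueError(f"unknown eligibility rule {name!r}")
        keep = RULE_REGISTRY[name](current, fills, events, **params).astype(bool)
        n_before = len(current)
        current = current[keep.to_numpy()]
        rows.append(
            {
                "criterion": name,
                "n_before": n_before,
                "n_excluded": int(n_before - len(current)),
                "n_after": len(current),
            }
        )
    report = EligibilityReport(pd.DataFrame(rows, columns=["criterion", "n_before", "n_excluded", "n_after"]))
    return current.reset_index(drop=True), report


# ---------------------------------------------------- arm assignment


def assign_treatment_arm(
    patients,
    fills,
    grace_period_months: int,
    same_day_tie: str = "error",
    keep_unassigned: bool = False,
):
    """Assign each patient to the class of their first qualifying fill.

    A fill qualifies if ``0 <= day < 30 * grace_period_months``.  The
    follow-up clock starts at that fill's day (``treatment_start_day``).
    Patients without a qualifying fill get arm ``"none"`` and are
    dropped unless ``keep_unassigned``.

    ``same_day_tie`` controls first-day fills of both classes:
    ``"error"`` (default) raises; ``"comparator"`` deterministically
    assigns arm B.
    """
    if grace_period_months < 1:
        raise ValueError("grace_period_months must be >= 1")
    if same_day_tie not in ("error", "comparator"):
        raise ValueError("same_day_tie must be 'error' or 'comparator'")
    window = fills[
        (fills["day"] >= 0) & (fills["day"] < DAYS_PER_MONTH * grace_period_months)
    ]
    first_day = window.groupby("patient_id")["day"].min()
    first = window.merge(first_day.rename("first_day"), on="patient_id")
    first = first[first["day"] == first["first_day"]]
    n_classes = first.groupby("patient_id")["drug_class"].nunique()
    ties = n_classes[n_classes > 1].index
    if len(ties) and same_day_tie == "error":
        raise ValueError(
            f"patients {list(ties[:5])} have first-day fills of both classes; "
            "set same_day_tie='comparator' to break ties deterministically"
        )
    assignment = (
        first.sort_values(["patient_id", "drug_class"])
        .groupby("patient_id")
        .agg(arm=("drug_class", "max" if same_day_tie == "comparator" else "first"),
             treatment_start_day=("day", "first"))
    )
    # max of {'A','B'} is 'B' => comparator wins ties; unambiguous
    # patients have a single class so either aggregator is exact
    out = patients.drop(
        columns=[c for c in ("arm", "treatment_start_day") if c in patients.columns]
    ).merge(assignment, on="patient_id", how="left")
    out["arm"] = out["arm"].fillna("none")
    if not keep_unassigned:
        out = out[out["arm"] != "none"].reset_index(drop=True)
        out["treatment_start_day"] = out["treatment_start_day"].astype(int)
    return out


# -------------------------------------------------------- imputation


class ChainedEquationsImputer(BaseEstimator):
    """Multiple imputation by fully conditional specification.

    Each incomplete variable is regressed on all other covariates;
    binary variables are imputed by logistic draws, continuous variables
    by predictive mean matching (PMM) with ``k_pmm`` donor candidates,
    so imputed continuous values always equal some observed value.
    Deterministic given ``random_state``.

    Parameters
    ----------
    n_imputations : number of completed datasets to return.
    max_iter : chained-equation sweeps per imputation.
    k_pmm : PMM donor pool size.
    covariates : columns eligible for imputation (default: any column
        with missing values, after checking the protected fields).
    random_state : seed.
    """

    PROTECTED = ("patient_id", "arm", "treatment_start_day", "index_day")

    def __init__(self, n_imputations=1, max_iter=10, k_pmm=5, covariates=None,
                 random_state=0):
        self.n_imputations = n_imputations
        self.max_iter = max_iter
        self.k_pmm = k_pmm
        self.covariates = covariates
        self.random_state = random_state

    # -- internals ---------------------------------------------------
    @staticmethod
    def _design(df, target, cols):
        X = df[[c for c in cols if c != target]]
        X = pd.get_dummies(X, drop_first=True, dtype=float)
        X = sm.add_constant(X, has_constant="add")
        return X.to_numpy(float)

    def _impute_one(self, df, incomplete, predictors, rng):
        work = df.copy()
        masks = {v: work[v].isna().to_numpy() for v in incomplete}
        # initialise by random draws from the observed distribution
        for v in incomplete:
            obs = work.loc[~masks[v], v].to_numpy()
            work.loc[masks[v], v] = rng.choice(obs, size=masks[v].sum(), replace=True)
        for _ in range(self.max_iter):
            for v in incomplete:
                m = masks[v]
                obs_vals = df.loc[~m, v]
                X = self._design(work, v, predictors)
                y = work[v].to_numpy(float)
                binary = obs_vals.nunique() <= 2
                try:
                    if binary:
                        lo, hi = sorted(obs_vals.unique())
                        fit = sm.GLM((y == hi)[~m].astype(float), X[~m],
                                     family=sm.families.Binomial()).fit()
                        p = fit.predict(X[m])
                        work.loc[m, v] = np.where(rng.random(m.sum()) < p, hi, lo)
                    else:
                        fit = sm.OLS(y[~m], X[~m]).fit()
                        pred_obs = fit.predict(X[~m])
                        pred_mis = fit.predict(X[m])
                        order = np.argsort(pred_obs)
                        sorted_pred = pred_obs[order]
                        sorted_obs = y[~m][order]
                        pos = np.searchsorted(sorted_pred, pred_mis)
                        k = self.k_pmm
                        picks = np.empty(m.sum())
                        for j, pz in enumerate(pos):
                            lo_i = max(0, pz - k)
                            hi_i = min(len(sorted_obs), pz + k)
                            donors = sorted_obs[lo_i:hi_i]
                            picks[j] = donors[rng.integers(len(donors))]
                        work.loc[m, v] = picks
                except Exception:  # separation / degenerate fit
                    obs = df.loc[~m, v].to_numpy()
                    work.loc[m, v] = rng.choice(obs, size=m.sum(), replace=True)
        return work

    # -- sklearn-ish surface ----------------------------------------
    def fit(self, X, y=None):
        df = X
        for col in self.PROTECTED:
            if col in df.columns and df[col].isna().any():
                raise ValueError(f"missing values in protected field {col!r}")
        cand = list(self.covariates) if self.covariates is not None else [
            c for c in df.columns if c not in self.PROTECTED
        ]
        incomplete = [c for c in cand if df[c].isna().any()]
        for v in incomplete:
            if df[v].isna().all():
                raise ValueError(f"covariate {v!r} is missing for all patients")
        self.incomplete_ = incomplete
        # predictors: all candidate covariates that are numeric/boolean
        # or low-cardinality categorical
        preds = []
        for c in cand:
            if df[c].dtype.kind in "bif" or df[c].nunique(dropna=True) <= 10:
                preds.append(c)
        self.predictors_ = preds
        return self

    def transform(self, X):
        df = X
        if not self.incomplete_:
            return [df.copy() for _ in range(self.n_imputations)]
        out = []
        for i in range(self.n_imputations):
            rng = np.random.default_rng((int(self.random_state) + i) % (2**31))
            comp = self._impute_one(df, self.incomplete_, self.predictors_, rng)
            for v in self.incomplete_:
                if df[v].dropna().nunique() <= 2 and set(df[v].dropna().unique()) <= {0.0, 1.0}:
                    comp[v] = comp[v].astype(float)
            out.append(comp)
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def impute_missing(patients, n_imputations=1, max_iter=10, seed=0, **kwargs):
    """Thin functional wrapper over :class:`ChainedEquationsImputer`."""
    imp = ChainedEquationsImputer(
        n_imputations=n_imputations, max_iter=max_iter, random_state=seed, **kwargs
    )
    return imp.fit_transform(patients)
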