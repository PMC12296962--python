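"""Results assembly: unadjusted contrasts, the pipeline driver, subgroups.

``run_analysis`` strings the whole pipeline together — imputation,
eligibility, grace-period arm assignment, person-month expansion,
stabilized IPTW x IPCW weighting, weighted pooled logistic estimation —
for every (estimand x outcome) combination, producing a results table
in the familiar comparative-effectiveness layout (events, incidence
rates, unadjusted and adjusted RD/HR) plus the attrition report, risk
curves and weight diagnostics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import apply_eligibility, assign_treatment_arm, default_rules, impute_missing
from .config import AnalysisConfig
from .outcome import (
    EffectEstimate,
    PooledLogisticHazard,
    risk_difference,
    standardized_risk_curves,
)
from .persontime import (
    apply_estimand_censoring,
    detect_discontinuation,
    expand_person_months,
)
from .weights import (
    CensoringWeightModel,
    TreatmentWeightModel,
    combine_and_truncate,
    stabilized_ipcw,
    weighted_smd,
)

__all__ = [
    "incidence_rate",
    "unadjusted_rd_wald",
    "unadjusted_hr",
    "run_analysis",
    "run_subgroups",
    "render_results",
]

DAYS_PER_MONTH = 30
DAYS_PER_YEAR = 365.25
SUPPRESS_BELOW = 11


def incidence_rate(n_events: int, person_months: float) -> float:
    """Events per 1000 person-years from person-months of follow-up."""
    if person_months <= 0:
        raise ValueError("person_months must be positive")
    person_years = person_months * DAYS_PER_MONTH / DAYS_PER_YEAR
    return 1000.0 * n_events / person_years


def unadjusted_rd_wald(e1: int, n1: int, e0: int, n0: int):
    """Unadjusted risk difference with Wald 95% CI, in percentage points.

    ``rd = 100 * (e1/n1 - e0/n0)``; the CI uses the binomial Wald
    standard error.  Values are rounded to two decimals, matching the
    precision of a published results table.
    """
    for e, n in ((e1, n1), (e0, n0)):
        if n < 1:
            raise ValueError("denominators must be >= 1")
        if not (0 <= e <= n):
            raise ValueError("event counts must satisfy 0 <= e <= n")
    p1, p0 = e1 / n1, e0 / n0
    rd = 100.0 * (p1 - p0)
    se = 100.0 * np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
    z = stats.norm.ppf(0.975)
    return round(rd, 2), (round(rd - z * se, 2), round(rd + z * se, 2))


def unadjusted_hr(pm: pd.DataFrame, time_form: str = "indicator"):
    """Pooled logistic HR with arm + time only, all weights 1."""
    model = PooledLogisticHazard(time_form=time_form).fit(pm)
    return model.hazard_ratio()


def _arm_summaries(pm: pd.DataFrame, cohort: pd.DataFrame):
    events, person_years, rates, denom = {}, {}, {}, {}
    for arm in ("A", "B"):
        rows = pm[pm["arm"] == arm]
        e = int(rows["event"].sum())
        months = int(len(rows))
        events[arm] = e
        person_years[arm] = months * DAYS_PER_MONTH / DAYS_PER_YEAR
        rates[arm] = incidence_rate(e, months) if months else float("nan")
        denom[arm] = int((cohort["arm"] == arm).sum())
    return events, person_years, rates, denom


def _analyze_one(
    cohort,
    events_table,
    fills,
    tv,
    outcome,
    estimand,
    cfg: AnalysisConfig,
    deviations,
):
    """Weights + model + effect measures for one estimand x outcome."""
    pm = expand_person_months(
        cohort, events_table, fills, horizon_months=cfg.horizon_months,
        outcome=outcome, tv=tv,
    )
    pm = apply_estimand_censoring(pm, deviations, estimand)

    # --- weights
    tw = TreatmentWeightModel(covariates=tuple(cfg.baseline_covariates)).fit(cohort)
    iptw_pm = tw.transform(pm)
    causes = ["ltfu"] + (["deviation"] if estimand == "PP" else [])
    cens_models = [
        CensoringWeightModel(
            cause=c,
            baseline_covariates=tuple(cfg.baseline_covariates),
            tv_covariates=tuple(cfg.tv_covariates),
        ).fit(pm)
        for c in causes
    ]
    ipcw = stabilized_ipcw(cens_models, pm)
    pct = 95 if "truncate95" in cfg.sensitivity else cfg.truncation_percentile
    wset = combine_and_truncate(iptw_pm, ipcw, percentile=pct)

    # --- models
    model_covs = tuple(cfg.baseline_covariates)
    if estimand == "PP":
        model_covs = model_covs + tuple(cfg.tv_covariates)
    time_form = "spline" if cfg.horizon_months > 12 else "indicator"
    adj = PooledLogisticHazard(time_form=time_form, covariates=model_covs).fit(
        pm, sample_weight=wset
    )
    hr, hr_ci = adj.hazard_ratio()
    ev, py, rates, denom = _arm_summaries(pm, cohort)

    flagged = bool(getattr(adj, "unidentifiable_", False))
    if flagged:
        rd, rd_ci = float("nan"), (float("nan"), float("nan"))
        curves = None
        u_hr, u_ci = float("nan"), (float("nan"), float("nan"))
    else:
        base_w = tw.transform(cohort)
        # standardization holds time-varying covariates at month-0 values
        std_cohort = cohort
        tv_in_model = [c for c in model_covs if c not in cohort.columns]
        if tv_in_model:
            m0 = pm.loc[pm["month_t"] == 0, ["patient_id", *tv_in_model]]
            std_cohort = cohort.merge(m0, on="patient_id", how="left").fillna(
                {c: 0 for c in tv_in_model}
            )
        curves = standardized_risk_curves(adj, std_cohort, weights=base_w,
                                          horizon=cfg.horizon_months)
        rd, rd_ci = risk_difference(curves, cfg.horizon_months)
        u_hr, u_ci = unadjusted_hr(pm, time_form=time_form)
    urd, urd_ci = unadjusted_rd_wald(ev["A"], denom["A"], ev["B"], denom["B"])

    est = EffectEstimate(
        estimand=estimand, outcome=outcome, hr=hr, hr_ci=hr_ci,
        rd_horizon=rd, rd_ci=rd_ci, n_events=ev, person_years=py,
        incidence_rate=rates, flagged=flagged,
    )
    row = est.to_row()
    row.update(
        {
            "n_A": denom["A"],
            "n_B": denom["B"],
            "unadj_rd_pct": urd,
            "unadj_rd_lo": urd_ci[0],
            "unadj_rd_hi": urd_ci[1],
            "unadj_hr": u_hr,
            "unadj_hr_lo": u_ci[0],
            "unadj_hr_hi": u_ci[1],
        }
    )
    diagnostics = wset.diagnostics()
    diagnostics.insert(0, "outcome", outcome)
    diagnostics.insert(0, "estimand", estimand)
    balance = (
        weighted_smd(cohort, tw.transform(cohort), cfg.baseline_covariates)
        if cfg.baseline_covariates
        else pd.Series(dtype=float)
    )
    return row, curves, diagnostics, balance


def _prepare_cohort(baseline, fills, events, cfg: AnalysisConfig, outcome=None):
    """Impute, assign arm, apply eligibility for one outcome's analysis."""
    grace = 6 if "grace6" in cfg.sensitivity else cfg.grace_period_months
    threshold = "all" if "all_scores" in cfg.sensitivity else cfg.score_threshold

    completed = impute_missing(baseline, n_imputations=cfg.n_imputations,
                               seed=cfg.seed)[0]
    assigned = assign_treatment_arm(completed, fills, grace, keep_unassigned=True)
    rules = default_rules(score_threshold=threshold, outcome=outcome)
    cohort, report = apply_eligibility(assigned, fills, events, rules)
    if "drop_metastatic" in cfg.sensitivity:
        cohort = cohort[cohort["cancer_stage"] != "distant"].reset_index(drop=True)
    if "drop_thrombocytopenia" in cfg.sensitivity and "thrombocytopenia" in cohort:
        cohort = cohort[~cohort["thrombocytopenia"].astype(bool)].reset_index(drop=True)
    return cohort, report, grace


def run_analysis(config: AnalysisConfig, data):
    """Run the full pipeline; returns a dict of result artifacts.

    ``data`` is a directory containing the four input tables or a
    :class:`~emtrial.simulate.SyntheticCohort`.  Output keys:
    ``results`` (one row per estimand x outcome), ``curves`` (dict),
    ``attrition`` (per outcome), ``weight_diagnostics``, ``balance``.
    """
    from .simulate import SyntheticCohort

    if not isinstance(data, SyntheticCohort):
        data = SyntheticCohort.read(data)
    baseline, fills, events, tv = data

    if "horizon36" in config.sensitivity and config.horizon_months != 36:
        import copy

        config = copy.deepcopy(config)
        config.horizon_months = 36

    rows, curves, diags, attrition, balance = [], {}, [], {}, {}
    for outcome in config.outcomes:
        cohort, report, grace = _prepare_cohort(baseline, fills, events, config,
                                                outcome=outcome)
        attrition[outcome] = report
        if not len(cohort):
            continue
        assigned_cls = cohort.set_index("patient_id")["arm"]
        deviations = detect_discontinuation(fills, assigned=assigned_cls)
        for estimand in config.estimands:
            row, cv, dg, bal = _analyze_one(
                cohort, events, fills, tv, outcome, estimand, config, deviations
            )
            rows.append(row)
            if cv is not None:
                curves[(estimand, outcome)] = cv
            diags.append(dg)
            balance[(estimand, outcome)] = bal
    results = pd.DataFrame(rows)
    return {
        "results": results,
        "curves": curves,
        "attrition": attrition,
        "weight_diagnostics": pd.concat(diags, ignore_index=True) if diags else pd.DataFrame(),
        "balance": balance,
    }


def run_subgroups(config: AnalysisConfig, data, axes=None):
    """Re-run the full weighted analysis within each subgroup stratum.

    Weights are re-estimated per stratum.  Strata where an arm has zero
    events come back with ``flagged=True`` rather than an estimate.
    """
    from .simulate import SyntheticCohort

    axes = tuple(axes if axes is not None else config.subgroup_axes)
    allowed = {"cancer_type", "cancer_status", "cancer_stage", "tumor_grade"}
    for ax in axes:
        if ax not in allowed:
            raise ValueError(f"unknown subgroup axis {ax!r}")
    if not isinstance(data, SyntheticCohort):
        data = SyntheticCohort.read(data)
    baseline = data.baseline
    out = []
    for axis in axes:
        for level in sorted(baseline[axis].dropna().unique()):
            sub = data._replace(
                baseline=baseline[baseline[axis] == level].reset_index(drop=True)
            )
            res = run_analysis(config, sub)["results"]
            res.insert(0, "stratum", str(level))
            res.insert(0, "axis", axis)
            out.append(res)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


def render_results(results: pd.DataFrame, suppress_small_cells=False) -> str:
    """Human-readable results table; optionally masks cells < 11 events.

    Suppression affects only this rendering, never the stored frame.
    """
    lines = []
    for _, r in results.iterrows():
        for arm in ("A", "B"):
            e = r[f"events_{arm}"]
            shown = "-" if (suppress_small_cells and e < SUPPRESS_BELOW) else f"{int(e)}"
            rate = r[f"rate_{arm}"]
            rate_s = "-" if (suppress_small_cells and e < SUPPRESS_BELOW) else f"{rate:.2f}"
            lines.append(
                f"{r.estimand:3s} {r.outcome:<24s} arm {arm}: events {shown:>6s} "
                f"rate {rate_s:>8s}/1000py"
            )
        hr_s = "flagged" if r.flagged else f"{r.hr:.2f} ({r.hr_lo:.2f}, {r.hr_hi:.2f})"
        lines.append(
            f"{r.estimand:3s} {r.outcome:<24s} adjusted HR {hr_s}; "
            f"RD {r.rd_pct:.2f}% unadjusted RD {r.unadj_rd_pct:.2f}% "
            f"({r.unadj_rd_lo:.2f}, {r.unadj_rd_hi:.2f})"
        )
    return "\n".join(lines)
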