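"""Person-month expansion and follow-up / deviation / censoring rules.

Follow-up months are half-open 30-day bins from each patient's
treatment start: month ``k`` covers days ``[start + 30k, start +
30(k+1))``.  A patient's record sequence runs from month 0 to the
earliest of outcome event, death, loss to follow-up, or the
administrative horizon; the terminal record carries exactly one flag.
Ties within a day are resolved event > death > ltfu > admin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "expand_person_months",
    "detect_discontinuation",
    "apply_estimand_censoring",
]

DAYS_PER_MONTH = 30

TV_SCORE_COLS = ("cha2ds2_vasc_t", "has_bled_t")
FLAG_COLS = ("event", "censor_admin", "censor_death", "censor_ltfu", "censor_deviation")


def expand_person_months(
    cohort: pd.DataFrame,
    events: pd.DataFrame,
    fills: pd.DataFrame | None = None,
    horizon_months: int = 12,
    outcome: str = "event",
    tv: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Expand an analysis cohort into one row per patient-month.

    Parameters
    ----------
    cohort : baseline table with ``arm`` and ``treatment_start_day``
        assigned; all its columns are carried onto the person-month rows
        so downstream models can use baseline covariates directly.
    events : long table ``(patient_id, event_type, day)`` holding the
        outcome occurrences plus ``death`` / ``ltfu`` records.
    fills : unused here (deviation handling lives in
        :func:`detect_discontinuation`); accepted for pipeline symmetry.
    horizon_months : administrative horizon (12 default, 36 sensitivity).
    outcome : which ``event_type`` is the outcome of this analysis.
    tv : optional long table ``(patient_id, month_t, <covariates...>)``
        merged onto the person-months (forward-filled within patient).
    """
    if horizon_months < 1:
        raise ValueError("horizon_months must be >= 1")
    if not set(cohort["arm"].unique()) <= {"A", "B"}:
        raise ValueError("cohort must have arm assigned (A/B) before expansion")

    base = cohort.reset_index(drop=True)
    n = len(base)
    start = base["treatment_start_day"].to_numpy(int)
    pid = base["patient_id"].to_numpy()

    def _day_of(kind):
        ev = events[events["event_type"] == kind]
        ev = ev.sort_values("day").drop_duplicates("patient_id")
        s = base[["patient_id"]].merge(ev[["patient_id", "day"]], on="patient_id", how="left")
        return s["day"].to_numpy(float)

    event_day = _day_of(outcome)
    death_day = _day_of("death")
    ltfu_day = _day_of("ltfu")
    if np.any(event_day < start):
        bad = pid[np.nan_to_num(event_day, nan=np.inf) < start][:5]
        raise ValueError(
            f"outcome {outcome!r} occurs before treatment start for patients "
            f"{list(bad)}; exclude them upstream (outcome_free rule)"
        )

    admin_day = start + horizon_months * DAYS_PER_MONTH  # exclusive end

    # candidate (day, priority); smaller priority wins a same-day tie
    days = np.stack(
        [
            np.nan_to_num(event_day, nan=np.inf),
            np.nan_to_num(death_day, nan=np.inf),
            np.nan_to_num(ltfu_day, nan=np.inf),
            admin_day.astype(float),
        ]
    )
    # clip candidates beyond the horizon
    days = np.where(days >= admin_day, np.inf, days)
    days[3] = admin_day
    winner = np.argmin(days + np.arange(4)[:, None] * 1e-9, axis=0)
    term_day = days[winner, np.arange(n)]
    term_month = np.where(
        winner == 3, horizon_months - 1, ((term_day - start) // DAYS_PER_MONTH).astype(int)
    ).astype(int)

    counts = term_month + 1
    row_pid = np.repeat(np.arange(n), counts)
    flat = np.arange(counts.sum())
    month = flat - np.repeat(np.cumsum(counts) - counts, counts)

    pm = base.iloc[row_pid].reset_index(drop=True)
    pm["month_t"] = month
    is_term = month == np.repeat(term_month, counts)
    w = np.repeat(winner, counts)
    pm["event"] = is_term & (w == 0)
    pm["censor_death"] = is_term & (w == 1)
    pm["censor_ltfu"] = is_term & (w == 2)
    pm["censor_admin"] = is_term & (w == 3)
    pm["censor_deviation"] = False
    pm["on_initial_treatment"] = True

    if tv is not None:
        tv_cols = [c for c in tv.columns if c not in ("patient_id", "month_t")]
        pm = pm.merge(tv, on=["patient_id", "month_t"], how="left")
        pm[tv_cols] = pm.groupby("patient_id")[tv_cols].ffill().fillna(0)
    if "cha2ds2_vasc" in pm.columns:
        pm["cha2ds2_vasc_t"] = pm["cha2ds2_vasc"]
    if "has_bled" in pm.columns:
        pm["has_bled_t"] = pm["has_bled"]
    return pm


def detect_discontinuation(
    fills: pd.DataFrame,
    gap_days: int = 30,
    assigned: pd.Series | dict | None = None,
    deviation_at: str = "coverage_end",
    follow_up_end: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """First treatment-deviation day per patient from the fill history.

    Same-class fills extend a coverage interval (overlapping supplies
    stockpile additively).  A gap of ``gap_days`` or more between
    coverage end and the next same-class fill is a discontinuation,
    dated at coverage end (``deviation_at='coverage_end'``, default) or
    at gap completion (``'gap_complete'``).  Any fill of the other class
    is a switch, dated at that fill's day; the deviation day is the
    earlier of the two.  Pre-index fills (day < 0) are ignored.

    Parameters
    ----------
    assigned : optional patient_id -> class mapping; default is the
        class of each patient's first post-index fill.
    follow_up_end : optional patient_id -> day mapping; when given, a
        chain that simply ends only counts as discontinuation if the gap
        completes before follow-up end.

    Returns
    -------
    DataFrame ``(patient_id, deviation_day, kind)`` with one row per
    deviating patient; ``kind`` is ``"discontinuation"`` or ``"switch"``.
    """
    if (fills["days_supply"] <= 0).any():
        raise ValueError("days_supply must be positive")
    if deviation_at not in ("coverage_end", "gap_complete"):
        raise ValueError("deviation_at must be 'coverage_end' or 'gap_complete'")
    if isinstance(assigned, pd.Series):
        assigned = assigned.to_dict()
    if isinstance(follow_up_end, pd.Series):
        follow_up_end = follow_up_end.to_dict()

    post = fills[fills["day"] >= 0].sort_values(["patient_id", "day"], kind="mergesort")
    rows = []
    for patient, grp in post.groupby("patient_id", sort=False):
        day = grp["day"].to_numpy(int)
        supply = grp["days_supply"].to_numpy(int)
        cls = grp["drug_class"].to_numpy()
        own = assigned.get(patient, cls[0]) if assigned else cls[0]

        switch_days = day[cls != own]
        switch_day = int(switch_days.min()) if len(switch_days) else None

        cov_end = None
        disc_day = None
        for d, s, c in zip(day, supply, cls):
            if c != own:
                continue
            if cov_end is None:
                cov_end = d + s
            elif d < cov_end:
                cov_end += s  # stockpiled overlap carries forward
            elif d - cov_end >= gap_days:
                disc_day = cov_end
                break
            else:
                cov_end = d + s
        else:
            # chain ended without an interior gap
            if cov_end is not None:
                if follow_up_end is None:
                    disc_day = cov_end
                else:
                    end = follow_up_end.get(patient)
                    if end is not None and end - cov_end >= gap_days:
                        disc_day = cov_end
        if disc_day is not None and deviation_at == "gap_complete":
            disc_day += gap_days

        cands = []
        if disc_day is not None:
            cands.append((disc_day, "discontinuation"))
        if switch_day is not None:
            cands.append((switch_day, "switch"))
        if cands:
            dev_day, kind = min(cands)
            rows.append({"patient_id": patient, "deviation_day": int(dev_day), "kind": kind})
    return pd.DataFrame(rows, columns=["patient_id", "deviation_day", "kind"])


def apply_estimand_censoring(
    pm: pd.DataFrame, deviations: pd.DataFrame | None, estimand: str
) -> pd.DataFrame:
    """Apply estimand-specific artificial censoring.

    ITT leaves the table unchanged.  PP removes records after each
    patient's deviation month and marks the new terminal record with
    ``censor_deviation`` — unless that month already carries an event,
    death, or loss to follow-up, which take precedence.
    """
    estimand = str(estimand).upper()
    if estimand not in ("ITT", "PP"):
        raise ValueError(f"unknown estimand {estimand!r}; use 'ITT' or 'PP'")
    out = pm.copy()
    if estimand == "ITT" or deviations is None or not len(deviations):
        return out

    dev = deviations.set_index("patient_id")["deviation_day"]
    dev_day = out["patient_id"].map(dev)
    dev_month = np.floor(
        (dev_day - out["treatment_start_day"]) / DAYS_PER_MONTH
    )
    dev_month = np.maximum(dev_month, 0)  # deviation inside grace censors month 0
    dev_month = dev_month.fillna(np.inf)

    out = out[out["month_t"] <= dev_month].copy()
    dev_month = dev_month.loc[out.index]
    at_dev = (out["month_t"] == dev_month).to_numpy()
    keep_flag = (out["event"] | out["censor_death"] | out["censor_ltfu"]).to_numpy()
    mark = at_dev & ~keep_flag
    out.loc[mark, "censor_deviation"] = True
    out.loc[mark, "censor_admin"] = False
    out.loc[out["month_t"].to_numpy() >= np.asarray(dev_month), "on_initial_treatment"] = False
    return out.reset_index(drop=True)
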