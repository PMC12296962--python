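"""Synthetic claims-cohort generator with known ground truth.

The generator emulates the structure of a two-arm new-user
anticoagulant cohort drawn from linked cancer-registry/claims data:
patients indexed at an atrial-fibrillation diagnosis initiate one of two
drug classes within a grace period, refill in 30-day supplies with
stochastic discontinuation and switching, and are followed monthly for a
rare outcome until event, death, loss to follow-up, or an
administrative horizon.  Baseline confounders drive both arm choice and
outcome hazard; time-varying covariates drive deviation and loss to
follow-up (and, optionally, the outcome — the informative-censoring
scenario).

Time convention: day 0 is each patient's index diagnosis; month ``k``
of follow-up covers days ``[start + 30k, start + 30(k+1))`` where
``start`` is the first qualifying fill day.

Randomness: every random field is drawn from its own counter-derived
stream keyed by ``(seed, field name, month)``; patient ``i`` always
takes position ``i`` of the stream, so enlarging ``n_patients`` never
reshuffles earlier patients.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import SimulationConfig
from .risk_scores import scores_from_frame

__all__ = [
    "SyntheticCohort",
    "TruthRecord",
    "generate_cohort",
    "compute_true_marginal_hr",
]

DAYS_PER_MONTH = 30

#: baseline fields that are not confounders but feed eligibility rules
FLAG_FIELDS = (
    "continuous_enrollment",
    "contraindication",
    "recent_stroke_14d",
    "recent_bleed_30d",
    "renal_failure_esrd",
)


class SyntheticCohort(NamedTuple):
    """The four tables a generated cohort consists of."""

    baseline: pd.DataFrame
    fills: pd.DataFrame
    events: pd.DataFrame
    tv: pd.DataFrame

    def write(self, out_dir, fmt: str = "csv") -> None:
        """Write all four tables to ``out_dir`` as CSV or Parquet."""
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self._asdict().items():
            if fmt == "csv":
                df.to_csv(out / f"{name}.csv", index=False)
            elif fmt == "parquet":
                df.to_parquet(out / f"{name}.parquet", index=False)
            else:
                raise ValueError(f"unknown format {fmt!r}")

    @classmethod
    def read(cls, in_dir) -> "SyntheticCohort":
        import pathlib

        src = pathlib.Path(in_dir)
        frames = {}
        for name in cls._fields:
            pq, csv = src / f"{name}.parquet", src / f"{name}.csv"
            if pq.exists():
                frames[name] = pd.read_parquet(pq)
            elif csv.exists():
                frames[name] = pd.read_csv(csv)
            else:
                raise FileNotFoundError(f"missing table {name!r} in {src}")
        return cls(**frames)


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth effect summary from the randomized oracle."""

    true_log_hr: float
    true_marginal_hr: float
    oracle_n: int
    oracle_seed: int

    def __post_init__(self):
        if not self.true_marginal_hr > 0:
            raise ValueError("true_marginal_hr must be positive")


# ----------------------------------------------------------------- RNG


def _stream(seed: int, name: str, month: int = -1) -> np.random.Generator:
    key = [int(seed) % (2**31), zlib.crc32(name.encode()), (month + 1) % (2**31)]
    return np.random.default_rng(np.random.SeedSequence(key))


def _u(seed, name, n, month=-1):
    return _stream(seed, name, month).random(n)


# ------------------------------------------------------- core pieces


def _draw_baseline(cfg: SimulationConfig) -> pd.DataFrame:
    n, seed = cfg.n_patients, cfg.seed
    df = pd.DataFrame({"patient_id": np.arange(n, dtype=np.int64), "index_day": 0})

    # age: 66 + truncated-exponential tail (mean ~9y, capped at 95)
    u = _u(seed, "age", n)
    tail = -9.0 * np.log1p(-u * (1 - np.exp(-29 / 9.0)))
    df["age_at_index"] = np.floor(66 + tail).astype(int)

    u = _u(seed, "cancer_type", n)
    df["cancer_type"] = np.select(
        [u < 0.45, u < 0.70], ["breast", "lung"], default="prostate"
    )
    u = _u(seed, "sex", n)
    p_female = np.select(
        [df["cancer_type"] == "breast", df["cancer_type"] == "lung"], [0.99, 0.45], 0.0
    )
    df["sex"] = np.where(u < p_female, "female", "male")
    df["cancer_status"] = np.where(_u(seed, "cancer_status", n) < 0.4, "active", "history")
    u = _u(seed, "cancer_stage", n)
    df["cancer_stage"] = np.select([u < 0.60, u < 0.85], ["local", "regional"], "distant")
    u = _u(seed, "tumor_grade", n)
    df["tumor_grade"] = np.select([u < 0.30, u < 0.75], ["I", "II"], "III")
    df["months_since_cancer_dx"] = np.round(
        -24.0 * np.log1p(-_u(seed, "months_since_dx", n)), 2
    )

    for spec in cfg.confounder_spec:
        df[spec.name] = _u(seed, f"conf:{spec.name}", n) < spec.prevalence

    # eligibility flags (consumed as precomputed booleans by the rules)
    df["continuous_enrollment"] = _u(seed, "flag:enroll", n) < 0.97
    df["contraindication"] = _u(seed, "flag:contra", n) < 0.02
    df["recent_stroke_14d"] = _u(seed, "flag:stroke14", n) < 0.01
    df["recent_bleed_30d"] = _u(seed, "flag:bleed30", n) < 0.01
    df["renal_failure_esrd"] = _u(seed, "flag:esrd", n) < 0.01

    # scenario configs may omit score components; absent flags count 0
    from .risk_scores import CHA2DS2_VASC_COMPONENTS, HAS_BLED_COMPONENTS

    for col in {*CHA2DS2_VASC_COMPONENTS, *HAS_BLED_COMPONENTS, "uncontrolled_htn"}:
        if col not in df.columns:
            df[col] = False
    chads, hb = scores_from_frame(df)
    df["cha2ds2_vasc"] = chads
    df["has_bled"] = hb
    return df


def _assign_arm(cfg: SimulationConfig, baseline: pd.DataFrame) -> np.ndarray:
    """True arm indicator (1 = arm A) under the configured channeling."""
    n, seed = cfg.n_patients, cfg.seed
    # intercept centred at the expected covariate contribution so the
    # marginal share stays near the target regardless of channeling
    intercept = logit(cfg.treatment_marginal_share) - sum(
        spec.beta_treatment * spec.prevalence for spec in cfg.confounder_spec
    )
    eta = np.full(n, intercept)
    for spec in cfg.confounder_spec:
        if spec.beta_treatment:
            eta = eta + spec.beta_treatment * baseline[spec.name].to_numpy(float)
    return (_u(seed, "arm", n) < expit(eta)).astype(int)


def _draw_tv(cfg: SimulationConfig, horizon: int) -> dict:
    """name -> (n, horizon) 0/1 matrix following each Markov chain."""
    n, seed = cfg.n_patients, cfg.seed
    out = {}
    for spec in cfg.tv_covariate_spec:
        Z = np.zeros((n, horizon), dtype=np.int8)
        Z[:, 0] = _u(seed, f"tv0:{spec.name}", n) < spec.stationary_prevalence
        for t in range(1, horizon):
            u = _u(seed, f"tv:{spec.name}", n, month=t)
            on = Z[:, t - 1] == 1
            Z[:, t] = np.where(on, u >= spec.p_off, u < spec.p_on)
        out[spec.name] = Z
    return out


def _draw_event_months(cfg, arm, baseline, tv, horizon, outcome, odds, log_hr):
    """First-occurrence month per patient for one outcome (inf if none)."""
    n, seed = cfg.n_patients, cfg.seed
    eta = np.log(odds) + log_hr * arm.astype(float)
    for spec in cfg.confounder_spec:
        if spec.beta_outcome:
            eta = eta + spec.beta_outcome * baseline[spec.name].to_numpy(float)
    first = np.full(n, np.inf)
    for t in range(horizon):
        eta_t = eta.copy()
        for spec in cfg.tv_covariate_spec:
            if spec.beta_outcome:
                eta_t += spec.beta_outcome * tv[spec.name][:, t]
        hit = _u(seed, f"event:{outcome}", n, month=t) < expit(eta_t)
        first = np.where(np.isinf(first) & hit, t, first)
    return first


def _first_month(seed, name, n, horizon, p_logit_fn):
    """Generic first month a monthly Bernoulli process fires (inf if never)."""
    first = np.full(n, np.inf)
    for t in range(horizon):
        p = p_logit_fn(t)
        hit = _u(seed, name, n, month=t) < p
        first = np.where(np.isinf(first) & hit, t, first)
    return first


# ------------------------------------------------------------ public


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a synthetic claims cohort.

    Returns a :class:`SyntheticCohort` of four tables:

    * ``baseline`` — one row per patient: demographics, cancer
      characteristics, confounder flags, eligibility flags, risk scores.
    * ``fills`` — dated prescription fills (``patient_id, day,
      drug_class, days_supply``); day is relative to the index
      diagnosis and may be negative for baseline (washout-violating)
      use.
    * ``events`` — dated first occurrences per outcome plus at most one
      of death / loss to follow-up per patient
      (``patient_id, event_type, day``).
    * ``tv`` — patient x month time-varying covariate values for the
      full administrative horizon.
    """
    if not isinstance(config, SimulationConfig):
        config = SimulationConfig(**config)
    cfg = config
    n, seed, H = cfg.n_patients, cfg.seed, cfg.admin_horizon_months

    baseline = _draw_baseline(cfg)
    arm = _assign_arm(cfg, baseline)
    start_day = np.floor(
        _u(seed, "start_day", n) * DAYS_PER_MONTH * cfg.grace_period_months
    ).astype(int)
    tv = _draw_tv(cfg, H)

    # --- deviation: discontinuation (tv-modulated) and switching
    p_disc = {a: cfg.monthly_discontinuation_prob[a] for a in "AB"}
    p_switch = {a: cfg.monthly_switch_prob[a] for a in "AB"}
    arm_lbl = np.where(arm == 1, "A", "B")
    # deviation cannot begin in month 0: the qualifying first fill's
    # 30-day supply always covers it
    disc_first = np.full(n, np.inf)
    switch_first = np.full(n, np.inf)
    for t in range(1, H):
        eta = np.where(
            arm == 1,
            logit(p_disc["A"]) if p_disc["A"] > 0 else -np.inf,
            logit(p_disc["B"]) if p_disc["B"] > 0 else -np.inf,
        )
        for spec in cfg.tv_covariate_spec:
            if spec.beta_deviation or spec.beta_deviation_armB:
                eta = eta + (
                    spec.beta_deviation + spec.beta_deviation_armB * (arm == 0)
                ) * tv[spec.name][:, t]
        hit = _u(seed, "disc", n, month=t) < expit(eta)
        disc_first = np.where(np.isinf(disc_first) & hit, t, disc_first)
        p_sw = np.where(arm == 1, p_switch["A"], p_switch["B"])
        hit = _u(seed, "switch", n, month=t) < p_sw
        switch_first = np.where(np.isinf(switch_first) & hit, t, switch_first)
    deviation_month = np.minimum(disc_first, switch_first)
    is_switch = switch_first <= disc_first

    # --- loss to follow-up (tv-modulated) and death
    def ltfu_logit(t):
        if cfg.monthly_ltfu_prob <= 0:
            return np.zeros(n)
        eta = np.full(n, logit(cfg.monthly_ltfu_prob))
        for spec in cfg.tv_covariate_spec:
            if spec.beta_ltfu or spec.beta_ltfu_armB:
                eta = eta + (
                    spec.beta_ltfu + spec.beta_ltfu_armB * (arm == 0)
                ) * tv[spec.name][:, t]
        return expit(eta)

    ltfu_first = _first_month(seed, "ltfu", n, H, ltfu_logit)
    death_first = _first_month(
        seed, "death", n, H, lambda t: np.full(n, cfg.monthly_death_prob)
    )

    # censoring month: earliest of death / ltfu (death wins ties)
    cens_month = np.minimum(death_first, ltfu_first)
    cens_is_death = death_first <= ltfu_first

    # --- events table
    ev_frames = []
    day_in_month = {}
    for outcome, (odds, log_hr) in cfg.outcomes().items():
        first = _draw_event_months(cfg, arm, baseline, tv, H, outcome, odds, log_hr)
        offs = np.floor(_u(seed, f"eday:{outcome}", n) * DAYS_PER_MONTH).astype(int)
        keep = np.isfinite(first) & (first <= cens_month)
        # only the first occurrence per outcome is recorded: a
        # pre-initiation event supersedes any later one
        pre = np.zeros(n, dtype=bool)
        if cfg.pre_start_event_prob > 0:
            pre = (_u(seed, f"preev:{outcome}", n) < cfg.pre_start_event_prob) & (
                start_day > 0
            )
            keep &= ~pre
        idx = np.where(keep)[0]
        ev_frames.append(
            pd.DataFrame(
                {
                    "patient_id": idx,
                    "event_type": outcome,
                    "day": start_day[idx]
                    + (first[idx].astype(int)) * DAYS_PER_MONTH
                    + offs[idx],
                }
            )
        )
        day_in_month[outcome] = offs
        # rare pre-initiation events (excluded later by eligibility)
        if cfg.pre_start_event_prob > 0:
            pidx = np.where(pre)[0]
            if len(pidx):
                pre_day = np.floor(
                    _u(seed, f"preevday:{outcome}", n)[pidx] * start_day[pidx]
                ).astype(int)
                ev_frames.append(
                    pd.DataFrame(
                        {"patient_id": pidx, "event_type": outcome, "day": pre_day}
                    )
                )

    cens_offs = np.floor(_u(seed, "censday", n) * DAYS_PER_MONTH).astype(int)
    cidx = np.where(np.isfinite(cens_month))[0]
    ev_frames.append(
        pd.DataFrame(
            {
                "patient_id": cidx,
                "event_type": np.where(cens_is_death[cidx], "death", "ltfu"),
                "day": start_day[cidx]
                + cens_month[cidx].astype(int) * DAYS_PER_MONTH
                + cens_offs[cidx],
            }
        )
    )
    events = (
        pd.concat(ev_frames, ignore_index=True)
        .sort_values(["patient_id", "day", "event_type"], kind="mergesort")
        .reset_index(drop=True)
    )

    # --- fills: monthly 30-day supplies until deviation or follow-up end
    end_month = np.where(np.isfinite(cens_month), cens_month, H).astype(int)
    dev = np.where(np.isfinite(deviation_month), deviation_month, H).astype(int)
    # fills cover months [0, last); the initial fill always exists
    last_assigned = np.maximum(np.minimum(dev, end_month), 1)

    def _ragged(first_k, last_k):
        """(pid, k) pairs for per-patient month ranges [first_k, last_k)."""
        counts = np.maximum(last_k - first_k, 0)
        pid = np.repeat(np.arange(n), counts)
        flat = np.arange(counts.sum())
        offs = np.repeat(np.cumsum(counts) - counts, counts)
        return pid, flat - offs + np.repeat(first_k, counts)

    parts = []
    pid, k = _ragged(np.zeros(n, dtype=int), last_assigned)
    parts.append(
        pd.DataFrame(
            {
                "patient_id": pid,
                "day": start_day[pid] + k * DAYS_PER_MONTH,
                "drug_class": arm_lbl[pid],
                "days_supply": 30,
            }
        )
    )
    sw = is_switch & (dev < end_month)
    pid, k = _ragged(np.where(sw, dev, 0), np.where(sw, end_month, 0))
    other = np.where(arm_lbl == "A", "B", "A")
    parts.append(
        pd.DataFrame(
            {
                "patient_id": pid,
                "day": start_day[pid] + k * DAYS_PER_MONTH,
                "drug_class": other[pid],
                "days_supply": 30,
            }
        )
    )
    if cfg.baseline_oac_prob > 0:
        prior = np.where(_u(seed, "prior_oac", n) < cfg.baseline_oac_prob)[0]
        pday = -np.floor(30 + _u(seed, "prior_oac_day", n) * 330).astype(int)
        pcls = np.where(_u(seed, "prior_oac_class", n) < 0.5, "A", "B")
        parts.append(
            pd.DataFrame(
                {
                    "patient_id": prior,
                    "day": pday[prior],
                    "drug_class": pcls[prior],
                    "days_supply": 30,
                }
            )
        )
    fills = pd.concat(parts, ignore_index=True)
    fills = fills.sort_values(["patient_id", "day"], kind="mergesort").reset_index(
        drop=True
    )

    # baseline snapshot of month-0 time-varying states (feeds the
    # thrombocytopenia-exclusion sensitivity analysis)
    for name, Z in tv.items():
        if name.endswith("_t"):
            baseline[name[:-2]] = Z[:, 0].astype(bool)

    # --- tv long table (full horizon for every patient)
    tv_df = pd.DataFrame(
        {
            "patient_id": np.repeat(np.arange(n), H),
            "month_t": np.tile(np.arange(H), n),
        }
    )
    for name, Z in tv.items():
        tv_df[name] = Z.reshape(-1)

    # --- missingness (MCAR per covariate; scores stay observed)
    maskable = [c.name for c in cfg.confounder_spec] + ["months_since_cancer_dx"]
    for col in maskable:
        p = cfg.missingness_for(col)
        if p > 0:
            miss = _u(seed, f"miss:{col}", n) < p
            baseline[col] = baseline[col].astype(float)
            baseline.loc[miss, col] = np.nan

    return SyntheticCohort(baseline, fills, events, tv_df)


def compute_true_marginal_hr(
    config: SimulationConfig, oracle_n: int, oracle_seed: int
) -> TruthRecord:
    """Ground-truth marginal hazard ratio by randomized mega-simulation.

    Re-simulates the outcome process with treatment randomized 1:1
    (confounder effects on treatment zeroed), no deviation and no
    censoring other than the administrative horizon, then contrasts the
    two arms' discrete-time hazards with a Mantel-Haenszel common odds
    ratio over month strata — a closed-form estimator independent of the
    estimation pipeline.
    """
    if oracle_n < 2:
        raise ValueError("oracle_n must be >= 2")
    cfg = config.replace(
        n_patients=int(oracle_n),
        seed=int(oracle_seed),
        treatment_marginal_share=0.5,
        confounder_spec=tuple(
            c.__class__(c.name, c.prevalence, 0.0, c.beta_outcome)
            for c in config.confounder_spec
        ),
        monthly_ltfu_prob=0.0,
        monthly_death_prob=0.0,
        monthly_discontinuation_prob=0.0,
        monthly_switch_prob=0.0,
        missingness_prob=0.0,
        baseline_oac_prob=0.0,
        pre_start_event_prob=0.0,
    )
    n, H = cfg.n_patients, cfg.admin_horizon_months
    baseline = _draw_baseline(cfg)
    arm = _assign_arm(cfg, baseline)
    tv = _draw_tv(cfg, H)
    odds, log_hr = cfg.outcomes()[cfg.outcome_name]
    first = _draw_event_months(cfg, arm, baseline, tv, H, cfg.outcome_name, odds, log_hr)

    num = den = 0.0
    for t in range(H):
        at_risk = first >= t
        a1 = at_risk & (arm == 1)
        a0 = at_risk & (arm == 0)
        d1 = float(np.sum(a1 & (first == t)))
        d0 = float(np.sum(a0 & (first == t)))
        n1, n0 = float(a1.sum()), float(a0.sum())
        N = n1 + n0
        if N == 0:
            continue
        num += d1 * (n0 - d0) / N
        den += d0 * (n1 - d1) / N
    if den == 0 or num == 0:
        raise ValueError("oracle simulation produced no events in one arm")
    return TruthRecord(
        true_log_hr=float(config.true_log_hr),
        true_marginal_hr=num / den,
        oracle_n=int(oracle_n),
        oracle_seed=int(oracle_seed),
    )
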