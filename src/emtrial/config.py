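"""Configuration objects for the synthetic-cohort generator and the analysis.

All configs are plain dataclasses with eager validation (invalid values
raise ``ValueError`` naming the offending parameter) and YAML round-trip
helpers, so a study is fully described by a text file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ConfounderSpec",
    "TVCovariateSpec",
    "SimulationConfig",
    "AnalysisConfig",
    "DEFAULT_CONFOUNDERS",
    "DEFAULT_TV_COVARIATES",
]


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {p!r}")


@dataclass(frozen=True)
class ConfounderSpec:
    """A binary baseline confounder.

    Parameters
    ----------
    name : column name in the baseline table.
    prevalence : Bernoulli probability in [0, 1].
    beta_treatment : log-odds effect on receiving arm A.
    beta_outcome : log-odds effect on the monthly event hazard.
    """

    name: str
    prevalence: float
    beta_treatment: float = 0.0
    beta_outcome: float = 0.0

    def __post_init__(self):
        _check_prob(f"confounder {self.name!r} prevalence", self.prevalence)


@dataclass(frozen=True)
class TVCovariateSpec:
    """A binary time-varying covariate following a two-state Markov chain.

    ``p_on`` is the monthly off->on transition probability, ``p_off`` the
    on->off probability; the chain starts at its stationary distribution.
    Effects are log-odds shifts on the monthly hazards of treatment
    deviation (discontinuation), loss to follow-up, and — to allow
    informative-censoring scenarios — the outcome itself.  The
    ``*_armB`` fields are additional shifts applying only in the
    comparator arm; a nonzero value makes censoring selective for the
    arm contrast (the covariate depletes one arm faster), which is what
    turns mere censoring into bias the IPCW machinery must remove.
    """

    name: str
    p_on: float
    p_off: float
    beta_deviation: float = 0.0
    beta_ltfu: float = 0.0
    beta_outcome: float = 0.0
    beta_ltfu_armB: float = 0.0
    beta_deviation_armB: float = 0.0

    def __post_init__(self):
        _check_prob(f"tv covariate {self.name!r} p_on", self.p_on)
        _check_prob(f"tv covariate {self.name!r} p_off", self.p_off)

    @property
    def stationary_prevalence(self) -> float:
        denom = self.p_on + self.p_off
        return self.p_on / denom if denom > 0 else 0.0


# Default baseline confounders: the CHA2DS2-VASc / HAS-BLED component
# flags plus a medication-history flag, with modest channeling toward the
# comparator arm (beta_treatment < 0 mimics sicker patients receiving
# warfarin) and plausible outcome effects.
DEFAULT_CONFOUNDERS: tuple[ConfounderSpec, ...] = (
    ConfounderSpec("chf", 0.25, -0.3, 0.3),
    ConfounderSpec("hypertension", 0.70, -0.1, 0.2),
    ConfounderSpec("diabetes", 0.30, -0.2, 0.2),
    ConfounderSpec("stroke_tia_history", 0.10, -0.3, 0.5),
    ConfounderSpec("vascular_disease", 0.20, -0.2, 0.3),
    ConfounderSpec("uncontrolled_htn", 0.10, -0.1, 0.1),
    ConfounderSpec("renal_disease", 0.12, -0.4, 0.3),
    ConfounderSpec("liver_disease", 0.04, -0.2, 0.2),
    ConfounderSpec("bleeding_history", 0.08, -0.3, 0.4),
    ConfounderSpec("labile_inr", 0.05, 0.2, 0.1),
    ConfounderSpec("antiplatelet_or_nsaid", 0.30, -0.1, 0.2),
    ConfounderSpec("alcohol_use", 0.05, 0.0, 0.1),
)

DEFAULT_TV_COVARIATES: tuple[TVCovariateSpec, ...] = (
    TVCovariateSpec("thrombocytopenia_t", 0.02, 0.30, 0.3, 0.2, 0.2),
    TVCovariateSpec("akd_t", 0.015, 0.40, 0.2, 0.3, 0.3),
    TVCovariateSpec("radiation_t", 0.03, 0.50, 0.1, 0.1, 0.0),
    TVCovariateSpec("surgery_t", 0.02, 0.80, 0.2, 0.1, 0.0),
    TVCovariateSpec("interacting_drug_t", 0.05, 0.30, 0.2, 0.0, 0.1),
)


def _per_arm(value, name: str) -> dict:
    """Normalise a scalar or {'A':..,'B':..} mapping to a per-arm dict."""
    if isinstance(value, dict):
        out = {str(k): float(v) for k, v in value.items()}
        if set(out) != {"A", "B"}:
            raise ValueError(f"{name} mapping must have keys 'A' and 'B'")
    else:
        out = {"A": float(value), "B": float(value)}
    for arm, p in out.items():
        _check_prob(f"{name}[{arm}]", p)
    return out


@dataclass
class SimulationConfig:
    """Full description of a synthetic claims cohort.

    The generator draws a two-arm new-user cohort: binary baseline
    confounders drive both arm choice and the monthly event odds; binary
    time-varying covariates drive treatment deviation and loss to
    follow-up (and optionally the outcome, enabling informative
    censoring).  ``true_log_hr`` is the conditional log hazard (odds)
    ratio of arm A vs arm B per month; ``baseline_event_odds`` the
    monthly event odds for an arm-B patient with all covariates at zero.
    """

    n_patients: int = 1000
    seed: int = 0
    true_log_hr: float = 0.0
    baseline_event_odds: float = 0.003
    confounder_spec: Sequence[ConfounderSpec] = DEFAULT_CONFOUNDERS
    tv_covariate_spec: Sequence[TVCovariateSpec] = DEFAULT_TV_COVARIATES
    monthly_discontinuation_prob: object = field(
        default_factory=lambda: {"A": 0.03, "B": 0.05}
    )
    monthly_switch_prob: object = field(default_factory=lambda: {"A": 0.005, "B": 0.01})
    monthly_ltfu_prob: float = 0.01
    monthly_death_prob: float = 0.01
    grace_period_months: int = 3
    admin_horizon_months: int = 12
    missingness_prob: object = 0.0
    treatment_marginal_share: float = 0.75  # target P(arm A); DOAC-era fill mix
    outcome_name: str = "event"
    extra_outcomes: dict = field(default_factory=dict)  # name -> (odds, log_hr)
    baseline_oac_prob: float = 0.03  # washout-violating pre-index fill
    pre_start_event_prob: float = 0.01  # outcome event between index and initiation

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0.0 < self.baseline_event_odds < 1.0):
            raise ValueError("baseline_event_odds must be in (0, 1)")
        if self.grace_period_months < 1:
            raise ValueError("grace_period_months must be >= 1")
        if self.admin_horizon_months < 1:
            raise ValueError("admin_horizon_months must be >= 1")
        if self.grace_period_months > self.admin_horizon_months:
            raise ValueError("grace_period_months must be <= admin_horizon_months")
        self.confounder_spec = tuple(
            c if isinstance(c, ConfounderSpec) else ConfounderSpec(*c)
            for c in self.confounder_spec
        )
        self.tv_covariate_spec = tuple(
            c if isinstance(c, TVCovariateSpec) else TVCovariateSpec(*c)
            for c in self.tv_covariate_spec
        )
        self.monthly_discontinuation_prob = _per_arm(
            self.monthly_discontinuation_prob, "monthly_discontinuation_prob"
        )
        self.monthly_switch_prob = _per_arm(self.monthly_switch_prob, "monthly_switch_prob")
        _check_prob("monthly_ltfu_prob", self.monthly_ltfu_prob)
        _check_prob("monthly_death_prob", self.monthly_death_prob)
        _check_prob("treatment_marginal_share", self.treatment_marginal_share)
        _check_prob("baseline_oac_prob", self.baseline_oac_prob)
        _check_prob("pre_start_event_prob", self.pre_start_event_prob)
        if isinstance(self.missingness_prob, dict):
            for k, v in self.missingness_prob.items():
                _check_prob(f"missingness_prob[{k}]", v)
        else:
            _check_prob("missingness_prob", float(self.missingness_prob))

    # -- convenience -------------------------------------------------
    def missingness_for(self, covariate: str) -> float:
        if isinstance(self.missingness_prob, dict):
            return float(self.missingness_prob.get(covariate, 0.0))
        return float(self.missingness_prob)

    def outcomes(self) -> dict:
        """Mapping outcome name -> (baseline odds, log HR)."""
        out = {self.outcome_name: (self.baseline_event_odds, self.true_log_hr)}
        for name, (odds, loghr) in self.extra_outcomes.items():
            out[str(name)] = (float(odds), float(loghr))
        return out

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    # -- YAML round-trip ---------------------------------------------
    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["confounder_spec"] = [list(asdict(c).values()) for c in self.confounder_spec]
        d["tv_covariate_spec"] = [list(asdict(c).values()) for c in self.tv_covariate_spec]
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SimulationConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            text = str(source)
            if "\n" in text or ":" in text:
                d = yaml.safe_load(text)
            else:
                with open(text) as fh:
                    d = yaml.safe_load(fh)
        d["confounder_spec"] = [ConfounderSpec(*c) for c in d.get("confounder_spec", [])]
        d["tv_covariate_spec"] = [TVCovariateSpec(*c) for c in d.get("tv_covariate_spec", [])]
        d["extra_outcomes"] = {
            k: tuple(v) for k, v in (d.get("extra_outcomes") or {}).items()
        }
        return cls(**d)


SENSITIVITY_SWITCHES = (
    "grace6",
    "all_scores",
    "horizon36",
    "drop_metastatic",
    "drop_thrombocytopenia",
    "truncate95",
)


@dataclass
class AnalysisConfig:
    """Settings for a full pipeline run (see ``reporting.run_analysis``)."""

    estimands: tuple = ("ITT", "PP")
    outcomes: tuple = ("event",)
    grace_period_months: int = 3
    horizon_months: int = 12
    score_threshold: int = 2
    truncation_percentile: object = 99
    subgroup_axes: tuple = ()
    sensitivity: tuple = ()
    suppress_small_cells: bool = False
    n_imputations: int = 1
    baseline_covariates: tuple = ()
    tv_covariates: tuple = ()
    bootstrap_reps: int = 0
    seed: int = 0

    def __post_init__(self):
        self.estimands = tuple(str(e).upper() for e in self.estimands)
        if not self.estimands or not set(self.estimands) <= {"ITT", "PP"}:
            raise ValueError("estimands must be a non-empty subset of {'ITT','PP'}")
        self.outcomes = tuple(self.outcomes)
        if not self.outcomes:
            raise ValueError("at least one outcome required")
        for s in self.sensitivity:
            if s not in SENSITIVITY_SWITCHES:
                raise ValueError(f"unknown sensitivity switch {s!r}")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "AnalysisConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            text = str(source)
            if "\n" in text:
                d = yaml.safe_load(text)
            else:
                with open(text) as fh:
                    d = yaml.safe_load(fh)
        for key in ("estimands", "outcomes", "subgroup_axes", "sensitivity",
                    "baseline_covariates", "tv_covariates"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)
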