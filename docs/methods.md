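# Methods

## Design being emulated

The pipeline emulates a two-arm pragmatic trial in an observational
claims cohort: eligibility is assessed at an index diagnosis (day 0),
treatment is "assigned" by the first qualifying prescription fill
within a grace period (default 3 months, 6 in sensitivity analyses),
and follow-up runs from that fill to the earliest of outcome, death,
loss to follow-up, or an administrative horizon (default 12 months, 36
in sensitivity analyses). Aligning eligibility, assignment, and time
zero at the first fill avoids immortal-time and prevalent-user bias.
Two estimands are produced: the intention-to-treat analog (effect of
initiating, ignoring later deviation) and the per-protocol analog
(effect of sustaining, obtained by censoring at deviation and
reweighting).

## Time discretization

All dated records are integer days from the index diagnosis. Follow-up
month *k* is the half-open interval `[start + 30k, start + 30(k+1))`
days, where `start` is the first-fill day. The 30-day month matches the
30-day gap rule for discontinuation and makes a 12-month horizon 360
days. Consequence: an event on day `start + 30` falls in month 1, not
month 0.

## Treatment deviation

Supply chains extend a coverage interval; overlapping same-class fills
stockpile (supplies add). Discontinuation is declared when the next
same-class fill starts ≥ `gap_days` (default 30) after coverage ends,
or when the chain simply ends that far before follow-up end; a fill of
the other class at any time is a switch. The deviation is dated at
coverage end — the first uncovered day — by default; the alternative
reading (dated when the 30-day gap completes) is available via
`deviation_at="gap_complete"`. In the per-protocol analysis, records
from the deviation month onward are removed and the new terminal record
carries the deviation-censoring flag, except that an outcome event,
death, or loss to follow-up in that same month takes precedence.

## Weights

* **IPTW.** A main-effects logistic regression of arm membership on
  baseline covariates; the stabilized weight is `P(arm)/p̂` (arm A) or
  `(1−P(arm))/(1−p̂)` (arm B), constant over a patient's months.
  Fitted probabilities numerically at 0 or 1 raise rather than being
  clipped; an opt-in floor/ceiling (`prob_floor=(0.01, 0.99)`) exists
  but is off by default.
* **IPCW.** Cause-specific pooled logistic models of the monthly
  censoring hazard (loss to follow-up always; deviation additionally
  for per-protocol). The denominator uses a time term plus baseline
  and time-varying covariates; the stabilizing numerator uses the time
  term and baseline covariates only — structurally never the
  time-varying ones. The month-*k* weight is the within-patient
  cumulative product over months ≤ *k* of
  `(1 − numerator hazard)/(1 − denominator hazard)`. The default time
  term is linear + quadratic month rather than month indicators:
  censoring events are rare and months with zero events make
  categorical time quasi-separable. Categorical and spline time terms
  are available.
* **Truncation.** Total weights (IPTW × cumulative IPCW) are capped at
  the linear-interpolation empirical 99th percentile (95th in
  sensitivity; any value in (50, 100) via an explicit override),
  computed per estimand and outcome over all person-month rows.

## Outcome model

A weighted pooled logistic regression of the monthly event indicator on
arm, a time function (month indicators at horizon 12; B-spline df = 4
at horizon 36), and configured covariates, with rows weighted by the
total weight. "GEE with robust variance" is implemented as the
standard marginal-structural-model estimator: an independence-working
GLM with frequency weights and a patient-clustered sandwich
covariance. With monthly risks of order 10⁻³–10⁻², exp(arm
coefficient) approximates the hazard ratio; the package verifies this
against a day-resolution Cox partial-likelihood fit (lifelines) in its
acceptance suite and agrees within 2%.

Standardized risk curves follow the g-formula: every patient's monthly
hazard is predicted under both arm assignments, converted to cumulative
incidence `1 − Π(1 − ĥ)`, and averaged with stabilized baseline
weights. When the per-protocol model contains time-varying covariates
they are held at their month-0 values for standardization — a
simplification; the per-protocol risk curves are therefore conditional
cumulative incidences under the baseline covariate state, not a full
time-varying g-computation. The horizon risk difference is reported in
percentage points; its CI comes from a nonparametric bootstrap over
patients (weights and model refit per replicate) when requested, since
no closed-form CI is implied by the weighted standardization.

## Imputation

Fully conditional specification: each incomplete covariate is
regressed on all others, binary variables imputed by logistic draws,
continuous ones by predictive mean matching with 5 donor candidates
(imputed values therefore always equal observed values). Deterministic
given the seed. The main pipeline runs on a single imputed dataset by
default; Rubin's-rules pooling across imputations can be layered on the
returned list of completed tables.

## Risk scores

CHA₂DS₂-VASc: CHF 1, hypertension 1, age 65–74 1 / ≥75 2, diabetes 1,
prior stroke/TIA 2, vascular disease 1, female 1 (range 0–9).
HAS-BLED: one point each for uncontrolled hypertension, renal disease,
liver disease, stroke history, bleeding history, labile INR, age > 65,
antiplatelet/NSAID use, and alcohol use, capped at 9; drug and alcohol
use are scored as separate points, as in the original score's
"drugs/alcohol" axis. Labile INR is carried as a boolean flag (it is
not observable in claims; the synthetic generator draws it directly).

## Synthetic-data generator

The generator emulates the *structure* of a registry-linked claims
cohort, not its clinical content. Stated world (defaults):

* Binary baseline confounders = the risk-score component flags, with
  mild channeling of sicker patients toward the comparator arm
  (treatment log-odds −0.1 to −0.4) and outcome log-odds 0.1–0.5;
  marginal arm-A share 0.75 (a DOAC-era fill mix).
* Monthly event odds of order 10⁻³–10⁻² (`baseline_event_odds`,
  default 0.003); a single conditional log hazard ratio per outcome.
* Binary time-varying covariates follow two-state Markov chains started
  at their stationary distribution; they can shift the deviation, LTFU
  and outcome log-odds, with optional comparator-arm interactions (the
  mechanism that makes censoring selective for the arm contrast).
* Adherence: 30-day refills on schedule; monthly discontinuation odds
  3%/5% (A/B), switching 0.5%/1%; deviation starts at month 1 because
  the qualifying fill's supply always covers month 0.
* Censoring: monthly LTFU and death probabilities 1% each;
  administrative horizon 12 months. Death is a censoring mechanism,
  not an outcome — no death-cause IPCW is applied, matching a
  follow-up rule that censors at death and attributes IPCW to loss to
  follow-up only.
* Incidental realism: ~3% of patients have a washout-violating
  pre-index fill, ~1% a pre-initiation outcome event, ~1–3% carry each
  exclusion flag; covariates can be masked MCAR (default 0).

What the generator does **not** emulate: real code lists, seasonal or
calendar time, dose, competing risks beyond censoring-at-death,
measurement error in covariates, or correlation between confounders.
A green recovery test therefore establishes that the estimator chain
removes the *modeled* confounding/selection, not that any real-world
analysis is unconfounded.

Event hazards follow the **assigned** arm even after deviation, so the
per-protocol ground truth equals the intention-to-treat truth and
deviation bias is pure selection — exactly the thing deviation-cause
IPCW is supposed to remove, and the cleanest way to test it.

Randomness is drawn from counter-derived streams keyed by
`(seed, field, month)`, with patient *i* always at position *i*, so
enlarging `n_patients` never reshuffles earlier patients and identical
config + seed reproduces byte-identical tables.

## Ground-truth oracle

`compute_true_marginal_hr` re-simulates the outcome process with
treatment randomized 1:1, confounder→treatment effects zeroed, and no
censoring except the administrative horizon, then summarizes the
between-arm contrast with a Mantel–Haenszel common odds ratio over
month strata — closed form and fully independent of the estimation
pipeline. This is the *marginal* HR; with outcome-affecting covariates
it differs from the conditional `true_log_hr` by non-collapsibility,
which is why recovery tests target the oracle value rather than
`exp(true_log_hr)`.

## Numerical and design choices

* Same-day first fills of both classes are rejected as ambiguous by
  default; `same_day_tie="comparator"` breaks ties deterministically
  toward arm B.
* The outcome-free-history exclusion is applied per outcome (a prior
  GI bleed removes the patient from the GI-bleed analysis only); a
  global reading is available by passing the full outcome list to the
  rule.
* Terminal-event ties within a day resolve event > death > LTFU >
  administrative; deviation censoring yields to all of them within its
  month.
* Apparent separation (|log-odds| > 15 on a non-time term) raises with
  the offending covariate's name instead of returning garbage.
* Zero events in an arm flags the estimate (HR NaN, CI (0, ∞)) rather
  than crashing; degenerate censoring models (zero events of the
  cause) warn and return unit weights.
* Subgroup analyses re-estimate weights within each stratum (internal
  validity over efficiency).
* Person-years use 365.25-day years and 30-day months; incidence rates
  are per 1000 person-years.
* Display rounding is 2 decimals; machine-readable outputs keep full
  precision, and small-cell suppression (< 11 events) affects only the
  rendered report.

## Known limitations

* The stabilization identity (weighted arm share = unweighted share)
  is exact only for saturated propensity models; main-effects models
  satisfy it approximately.
* No doubly-robust estimation, no competing-risk estimands, no
  overlap/matching weights, and no E-value computation.
* The per-protocol standardized curves hold time-varying covariates at
  baseline (see above).
* Weight-model specifications are main-effects by default; interactions
  must be supplied explicitly as patsy terms (e.g. `"C(arm):flag_t"`).
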