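# emtrial

Target-trial emulation for longitudinal claims cohorts: a tested Python
pipeline for comparative-effectiveness studies of the kind run on linked
cancer-registry/Medicare data — for example, comparing stroke and
bleeding risk between direct oral anticoagulant (DOAC) and warfarin
initiators among patients with atrial fibrillation and cancer.

It is written for epidemiologists and biostatisticians who need the
full causal chain as reusable, testable components rather than a
one-off analysis script:

1. **New-user cohort construction** — ordered eligibility rules with an
   attrition report, grace-period treatment assignment (arm = drug
   class of the first fill within *g* months of the index diagnosis;
   follow-up clock starts at that fill), CHA₂DS₂-VASc / HAS-BLED score
   computation, and multiple imputation by chained equations (logistic
   draws for binary covariates, predictive mean matching for continuous
   ones).
2. **Person-time expansion** — patients become person-month records
   over half-open 30-day bins; follow-up ends at the earliest of
   outcome, death, loss to follow-up, or the administrative horizon.
   Treatment deviation (a ≥ 30-day gap after the last day of supply, or
   a switch to the other class) triggers artificial censoring in the
   per-protocol analysis.
3. **Stabilized weighting** — inverse-probability-of-treatment weights
   from a baseline propensity model and cause-specific
   inverse-probability-of-censoring weights from pooled logistic
   censoring-hazard models (time-varying covariates in the denominator
   only), multiplied and truncated at the 99th (or 95th) percentile.
4. **Outcome model** — weighted pooled logistic discrete-time hazard
   regression with patient-clustered robust variance; with rare monthly
   risks exp(arm coefficient) approximates the hazard ratio.
   Standardized (g-formula) cumulative-incidence curves give the
   horizon risk difference.
5. **Synthetic cohorts with known truth** — a claims-like generator
   with configurable confounding, adherence, and informative-censoring
   structure, plus a randomized mega-simulation oracle for the true
   marginal hazard ratio, so every stage has a parameter-recovery test.

## The model

For patient *i*, month *t*, the discrete-time hazard of the outcome is
modeled as

    logit P(Y_it = 1 | Y_i,t-1 = 0) = β₀t + β_A · A_i + γ'X_i

with `A_i` the treatment arm, `X_i` baseline covariates, and `β₀t` a
month-specific intercept. Rows are weighted by stabilized total weights

    W_it = SW^T_i × SW^C_it ,
    SW^T_i  = P(A_i) / P(A_i | X_i) ,
    SW^C_it = Π_{j≤t} P(uncens_j | X_i, j) / P(uncens_j | X_i, Z_ij, j)

where `Z_ij` are monthly time-varying covariates. exp(β_A) is the
reported hazard ratio (intention-to-treat, or per-protocol after
deviation censoring with a deviation-cause censoring weight added).

## Worked example

```python
import numpy as np
from emtrial import (SimulationConfig, AnalysisConfig, generate_cohort,
                     compute_true_marginal_hr, run_analysis, render_results)

sim = SimulationConfig(n_patients=20_000, seed=7,
                       true_log_hr=np.log(0.75), baseline_event_odds=0.006)
data = generate_cohort(sim)
truth = compute_true_marginal_hr(sim, oracle_n=200_000, oracle_seed=8)
print(f"oracle marginal HR: {truth.true_marginal_hr:.3f}")

cfg = AnalysisConfig(
    outcomes=("event",), estimands=("ITT", "PP"),
    baseline_covariates=("chf", "hypertension", "diabetes",
                         "stroke_tia_history", "vascular_disease",
                         "renal_disease", "bleeding_history"),
    tv_covariates=("thrombocytopenia_t", "akd_t"), seed=7,
)
arts = run_analysis(cfg, data)
print(render_results(arts["results"]))
```

prints

```
oracle marginal HR: 0.747
ITT event                    arm A: events   1082 rate   100.23/1000py
ITT event                    arm B: events    508 rate   138.88/1000py
ITT event                    adjusted HR 0.79 (0.71, 0.88); RD -2.37% unadjusted RD -3.11% (-4.17, -2.04)
PP  event                    arm A: events    940 rate   101.50/1000py
PP  event                    arm B: events    398 rate   139.90/1000py
PP  event                    adjusted HR 0.79 (0.70, 0.89); RD -2.43% unadjusted RD -1.71% (-2.68, -0.74)
```

The generator channels sicker patients toward the comparator arm, so
the unadjusted contrast overstates the benefit; the IPTW/IPCW-weighted
pooled logistic estimate (0.79, CI 0.71–0.88) recovers the randomized
oracle's marginal hazard ratio (0.747) within Monte-Carlo error. The
incidence rates are events per 1000 person-years; the RD is the
standardized 12-month risk difference in percentage points.
`arts["attrition"]` holds the eligibility flowchart, and
`arts["weight_diagnostics"]` / `arts["balance"]` the weight summaries
and weighted standardized mean differences.

A `typer` CLI wraps the same pipeline:

```bash
emtrial simulate --config sim.yaml --out data/
emtrial estimate --config study.yaml --in data/ --out results/ --estimand itt
emtrial report --results results/results.csv --suppress
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete seeded pipeline from scratch — synthetic-cohort
generation, cohort construction, weighting, and both estimands of the
weighted hazard model — and writes the summary JSON to `--out` with the
full results table next to it.

See `docs/methods.md` for the statistical methods, the generator's
assumptions, and known limitations.
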