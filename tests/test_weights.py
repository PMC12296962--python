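import numpy as np
import pandas as pd
import pytest

from emtrial.cohort import assign_treatment_arm
from emtrial.config import ConfounderSpec, SimulationConfig, TVCovariateSpec
from emtrial.persontime import expand_person_months
from emtrial.simulate import generate_cohort
from emtrial.weights import (
    CensoringWeightModel,
    TreatmentWeightModel,
    combine_and_truncate,
    stabilized_ipcw,
    weighted_smd,
)


def _two_stratum_cohort():
    """Saturated design: X=1 has 80 A / 20 B, X=0 has 40 A / 60 B."""
    rows = (
        [("A", 1)] * 80 + [("B", 1)] * 20 + [("A", 0)] * 40 + [("B", 0)] * 60
    )
    return pd.DataFrame(
        {"patient_id": range(200), "arm": [a for a, _ in rows], "x": [x for _, x in rows]}
    )


class TestTreatmentWeights:
    def test_intercept_only_weights_are_one(self, clean_world):
        cfg, data = clean_world
        cohort = assign_treatment_arm(data.baseline, data.fills, 3)
        w = TreatmentWeightModel().fit_transform(cohort)
        assert np.allclose(w, 1.0)

    def test_saturated_logit_equals_stratum_proportions(self):
        cohort = _two_stratum_cohort()
        m = TreatmentWeightModel(covariates=("x",)).fit(cohort)
        p = m.predict_proba(cohort)
        assert p[cohort["x"] == 1] == pytest.approx(0.8, abs=1e-8)
        assert p[cohort["x"] == 0] == pytest.approx(0.4, abs=1e-8)
        # arm A patient in the X=1 stratum: share 0.6 / p 0.8 = 0.75
        w = m.transform(cohort)
        assert w[0] == pytest.approx(0.75, abs=1e-8)

    def test_stabilization_preserves_marginal_share(self, default_world):
        """The weighted arm share equals the unweighted one — exactly for
        a saturated propensity model, approximately for main effects."""
        cohort = _two_stratum_cohort()
        w = TreatmentWeightModel(covariates=("x",)).fit_transform(cohort)
        a = (cohort["arm"] == "A").to_numpy()
        assert np.average(a, weights=w) == pytest.approx(a.mean(), abs=1e-10)

        cfg, data = default_world
        big = assign_treatment_arm(data.baseline, data.fills, 3)
        covs = ("chf", "hypertension", "diabetes", "renal_disease")
        w = TreatmentWeightModel(covariates=covs).fit_transform(big)
        a = (big["arm"] == "A").to_numpy()
        assert np.average(a, weights=w) == pytest.approx(a.mean(), abs=0.01)

    def test_coefficient_recovery(self):
        """Fitted propensity coefficients land within 3 SE of the
        generating log-odds at n = 20,000."""
        spec = (
            ConfounderSpec("x1", 0.4, -0.8, 0.0),
            ConfounderSpec("x2", 0.3, 0.6, 0.0),
        )
        cfg = SimulationConfig(
            n_patients=20_000, seed=5, confounder_spec=spec, tv_covariate_spec=(),
            missingness_prob=0.0, baseline_oac_prob=0.0, pre_start_event_prob=0.0,
        )
        data = generate_cohort(cfg)
        cohort = assign_treatment_arm(data.baseline, data.fills, 3)
        m = TreatmentWeightModel(covariates=("x1", "x2")).fit(cohort)
        for name, true_beta in (("x1", -0.8), ("x2", 0.6)):
            col = [c for c in m.coef_.index if name in c][0]
            assert abs(m.coef_[col] - true_beta) < 3 * m.se_[col]

    def test_single_arm_rejected(self):
        cohort = _two_stratum_cohort()
        with pytest.raises(ValueError, match="both arms"):
            TreatmentWeightModel().fit(cohort.assign(arm="A"))

    def test_separation_rejected_with_name(self):
        cohort = _two_stratum_cohort()
        cohort["leaky"] = (cohort["arm"] == "A").astype(float)
        with pytest.raises(ValueError, match="leaky"):
            TreatmentWeightModel(covariates=("leaky",)).fit(cohort)

    def test_positivity_violation_surfaced(self):
        cohort = _two_stratum_cohort()
        m = TreatmentWeightModel(covariates=("x",)).fit(cohort)
        extreme = cohort.assign(x=60.0)  # pushes fitted probability to ~1
        with pytest.raises(ValueError, match="positivity"):
            m.transform(extreme)

    def test_iptw_mean_near_one_and_balance(self, default_world):
        """Structural invariants: stabilized IPTW mean within 0.05 of 1
        and weighted SMDs below 0.1 at n >= 5000."""
        cfg, data = default_world
        cohort = assign_treatment_arm(data.baseline, data.fills, 3)
        covs = tuple(c.name for c in cfg.confounder_spec)
        m = TreatmentWeightModel(covariates=covs).fit(cohort)
        w = m.transform(cohort)
        assert abs(w.mean() - 1.0) < 0.05
        smd_raw = weighted_smd(cohort, np.ones(len(cohort)), covs)
        smd_w = weighted_smd(cohort, w, covs)
        assert smd_w.abs().max() < 0.1
        assert smd_w.abs().mean() <= smd_raw.abs().mean()


class _StubCensor:
    """predict_hazard stub so the cumulative arithmetic can be checked
    against literal values, independent of any model fit."""

    def __init__(self, num, den):
        self.num, self.den = num, den

    def predict_hazard(self, pm, which="den"):
        probs = self.den if which == "den" else self.num
        return np.asarray([probs[m] for m in pm["month_t"]])


class TestCensoringWeights:
    def _pm(self, months=3, n=2):
        rows = [
            {"patient_id": i, "month_t": t, "censor_ltfu": False}
            for i in range(n)
            for t in range(months)
        ]
        return pd.DataFrame(rows)

    def test_single_month_factor_arithmetic(self):
        pm = self._pm(months=1, n=1)
        w = stabilized_ipcw([_StubCensor({0: 0.05}, {0: 0.10})], pm)
        assert w[0] == pytest.approx(0.95 / 0.90)

    def test_cumulative_product_matches_bruteforce(self):
        num = {0: 0.02, 1: 0.03, 2: 0.01}
        den = {0: 0.05, 1: 0.02, 2: 0.08}
        pm = self._pm(months=3, n=2)
        w = stabilized_ipcw([_StubCensor(num, den)], pm)
        expected = []
        for _ in range(2):
            acc = 1.0
            for t in range(3):
                acc *= (1 - num[t]) / (1 - den[t])
                expected.append(acc)
        assert np.allclose(w, expected)

    def test_no_censoring_degenerates_to_unit_weights(self):
        pm = self._pm()
        with pytest.warns(UserWarning, match="no ltfu"):
            m = CensoringWeightModel(cause="ltfu").fit(pm)
        assert m.degenerate_
        assert np.allclose(m.predict_hazard(pm), 0.0)
        assert np.allclose(stabilized_ipcw(m, pm), 1.0)

    def test_positivity_rejected(self):
        pm = self._pm(months=1, n=1)
        with pytest.raises(ValueError, match="positivity"):
            stabilized_ipcw([_StubCensor({0: 0.0}, {0: 1.0})], pm)

    def test_numerator_excludes_time_varying_covariates(self):
        """Structural check: the stabilizing numerator design never
        contains the time-varying terms."""
        cfg = SimulationConfig(
            n_patients=3000, seed=2, baseline_event_odds=0.005,
            tv_covariate_spec=(TVCovariateSpec("flag_t", 0.1, 0.2, 0.0, 1.0, 0.0),),
            monthly_ltfu_prob=0.03, missingness_prob=0.0, baseline_oac_prob=0.0,
            pre_start_event_prob=0.0,
        )
        data = generate_cohort(cfg)
        cohort = assign_treatment_arm(data.baseline, data.fills, 3)
        pm = expand_person_months(cohort, data.events, tv=data.tv)
        m = CensoringWeightModel(
            cause="ltfu", baseline_covariates=("chf",), tv_covariates=("flag_t",)
        ).fit(pm)
        num_terms = m.num_result_.params.index
        den_terms = m.den_result_.params.index
        assert not any("flag_t" in t for t in num_terms)
        assert any("flag_t" in t for t in den_terms)

    def test_ltfu_coefficient_recovery(self):
        """LTFU hazard driven by a flag with log-odds 1.0: the pooled
        censoring model recovers it within 3 SE at n = 20,000."""
        cfg = SimulationConfig(
            n_patients=20_000, seed=8, baseline_event_odds=0.002,
            confounder_spec=(), monthly_death_prob=0.0,
            tv_covariate_spec=(TVCovariateSpec("flag_t", 0.1, 0.1, 0.0, 1.0, 0.0),),
            monthly_ltfu_prob=0.03, missingness_prob=0.0, baseline_oac_prob=0.0,
            pre_start_event_prob=0.0, monthly_discontinuation_prob=0.0,
            monthly_switch_prob=0.0,
        )
        data = generate_cohort(cfg)
        cohort = assign_treatment_arm(data.baseline, data.fills, 3)
        pm = expand_person_months(cohort, data.events, tv=data.tv)
        m = CensoringWeightModel(cause="ltfu", tv_covariates=("flag_t",)).fit(pm)
        coef = m.den_result_.params["flag_t"]
        se = m.den_result_.bse["flag_t"]
        assert abs(coef - 1.0) < 3 * se


class TestCombineAndTruncate:
    def test_all_ones_identity(self):
        ws = combine_and_truncate(np.ones(10), np.ones(10), percentile=99)
        assert np.allclose(ws.total, 1.0)
        assert ws.truncation_cap == pytest.approx(1.0)

    def test_cap_is_empirical_percentile(self):
        vec = np.r_[np.ones(99), 100.0]
        ws = combine_and_truncate(vec, np.ones(100), percentile=95)
        expected_cap = float(np.quantile(vec, 0.95, method="linear"))
        assert ws.truncation_cap == pytest.approx(expected_cap)
        assert ws.total.max() == pytest.approx(expected_cap)

    def test_truncation_shrinks_variance_and_nests(self):
        rng = np.random.default_rng(0)
        w = np.exp(rng.normal(size=2000))
        untrunc = combine_and_truncate(w, np.ones_like(w), percentile=None)
        t99 = combine_and_truncate(w, np.ones_like(w), percentile=99)
        t95 = combine_and_truncate(w, np.ones_like(w), percentile=95)
        assert t99.total.var() <= untrunc.total.var()
        assert t95.total.var() <= t99.total.var()
        assert t95.total.max() <= t99.total.max()

    def test_percentile_validation(self):
        with pytest.raises(ValueError, match="percentile"):
            combine_and_truncate(np.ones(5), np.ones(5), percentile=80)
        ws = combine_and_truncate(
            np.ones(5), np.ones(5), explicit_percentile=80
        )
        assert ws.truncation_cap == pytest.approx(1.0)
        with pytest.raises(ValueError, match="explicit_percentile"):
            combine_and_truncate(np.ones(5), np.ones(5), explicit_percentile=40)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError, match="finite and positive"):
            combine_and_truncate(np.array([1.0, 0.0]), np.ones(2))
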