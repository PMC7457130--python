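"""Survival layer: subcohort filter, KM/log-rank, Cox, risk scans."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from cnvland.array_io import ClinicalRecord, ValidationError
from cnvland.survival import (
    ConvergenceError,
    SurvivalRecord,
    combined_risk,
    cox_fit,
    cox_score_test,
    km_logrank,
    prognostic_subcohort,
    recurrence_scan,
)


def _patient(pid="P1", **overrides):
    base = dict(
        patient_id=pid, gender="female", age=50.0, history="primary",
        who_grade="I", subtype="fibrous", location="skull-base",
        bone_invasion=False, edema=False, multiple=False, diameter_cm=3.0,
        simpson="II", radiotherapy=False, followup_months=24.0,
        recurrence_event=False,
    )
    base.update(overrides)
    return ClinicalRecord(**base)


class TestPrognosticSubcohort:
    def test_simpson_iv_excluded(self):
        assert prognostic_subcohort([_patient(simpson="IV")]) == []

    def test_recurrent_history_excluded(self):
        assert prognostic_subcohort([_patient(history="recurrent")]) == []

    def test_radiotherapy_excluded(self):
        assert prognostic_subcohort([_patient(radiotherapy=True)]) == []

    def test_eligible_patient_retained(self):
        p = _patient(simpson="II")
        assert prognostic_subcohort([p]) == [p]


def _exp_group(rng, n, rate, censor=60.0, prefix="g"):
    t = rng.exponential(1 / rate, n)
    return [
        SurvivalRecord(f"{prefix}{i}", float(min(t[i], censor)), bool(t[i] <= censor))
        for i in range(n)
    ]


class TestKmLogrank:
    def test_identical_groups_chi2_zero(self):
        recs = [SurvivalRecord(f"a{i}", t, e) for i, (t, e) in
                enumerate([(5, True), (10, False), (15, True)])]
        recs2 = [SurvivalRecord(f"b{i}", r.time_months, r.event)
                 for i, r in enumerate(recs)]
        _, chi2, p = km_logrank({"A": recs, "B": recs2})
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_censored_group_curve_constant_one(self):
        censored = [SurvivalRecord(f"c{i}", 10.0 + i, False) for i in range(5)]
        events = [SurvivalRecord(f"e{i}", 5.0 + i, True) for i in range(5)]
        curves, _, _ = km_logrank({"cens": censored, "ev": events})
        assert np.all(curves["cens"]["survival"].to_numpy() == 1.0)

    def test_km_curve_monotone_from_one(self):
        rng = np.random.default_rng(2)
        curves, _, _ = km_logrank(
            {"A": _exp_group(rng, 80, 0.05), "B": _exp_group(rng, 80, 0.02)}
        )
        for df in curves.values():
            s = df["survival"].to_numpy()
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 1e-12)

    def test_true_hr_three_detected(self):
        rng = np.random.default_rng(3)
        g1 = _exp_group(rng, 500, 0.01, prefix="a")
        g2 = _exp_group(rng, 500, 0.03, prefix="b")
        _, _, p = km_logrank({"low": g1, "high": g2})
        assert p < 1e-6

    def test_no_events_rejected(self):
        a = [SurvivalRecord("a", 5.0, False)]
        b = [SurvivalRecord("b", 6.0, False)]
        with pytest.raises(ValidationError, match="undefined"):
            km_logrank({"A": a, "B": b})


class TestCoxFit:
    def _data(self, seed=0, n=300, log_hr=1.0, censor=60.0):
        rng = np.random.default_rng(seed)
        x = (rng.random(n) < 0.3).astype(float)
        t = rng.exponential(1 / (0.01 * np.exp(log_hr * x)))
        recs = [
            SurvivalRecord(f"P{i}", float(min(t[i], censor)), bool(t[i] <= censor))
            for i in range(n)
        ]
        X = pd.DataFrame({"x": x}, index=[f"P{i}" for i in range(n)])
        return recs, X, t

    def test_matches_lifelines_efron(self):
        recs, X, _ = self._data(seed=1)
        res = cox_fit(recs, X)[0]
        df = pd.DataFrame(
            {"T": [r.time_months for r in recs], "E": [r.event for r in recs],
             "x": X["x"].to_numpy()}
        )
        cph = CoxPHFitter().fit(df, "T", "E")
        assert res.coef == pytest.approx(cph.params_["x"], abs=1e-4)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)
        assert res.ci95_low <= res.hazard_ratio <= res.ci95_high

    def test_score_test_equals_logrank_on_tie_free_data(self):
        recs, X, t = self._data(seed=2, censor=np.inf)  # no censoring, no ties
        x = X["x"].to_numpy()
        groups = {
            "carrier": [r for r, xi in zip(recs, x) if xi == 1],
            "non": [r for r, xi in zip(recs, x) if xi == 0],
        }
        _, chi2, p_lr = km_logrank(groups)
        time = np.array([r.time_months for r in recs])
        event = np.array([r.event for r in recs])
        s_chi2, s_p = cox_score_test(x, time, event, ties="breslow")
        assert abs(p_lr - s_p) < 1e-6
        assert chi2 == pytest.approx(s_chi2, abs=1e-8)

    def test_breslow_close_to_efron_with_few_ties(self):
        recs, X, _ = self._data(seed=3)
        efron = cox_fit(recs, X, ties="efron")[0]
        breslow = cox_fit(recs, X, ties="breslow")[0]
        assert efron.coef == pytest.approx(breslow.coef, abs=0.05)

    def test_constant_covariate_rejected(self):
        recs, X, _ = self._data()
        X["x"] = 1.0
        with pytest.raises(ValidationError, match="constant"):
            cox_fit(recs, X)

    def test_no_events_rejected(self):
        recs = [SurvivalRecord("a", 5.0, False), SurvivalRecord("b", 6.0, False)]
        X = pd.DataFrame({"x": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="event"):
            cox_fit(recs, X)

    def test_complete_separation_flagged(self):
        # every event in carriers, all non-carriers censored early
        recs = (
            [SurvivalRecord(f"c{i}", float(i + 1), True) for i in range(10)]
            + [SurvivalRecord(f"n{i}", 100.0, False) for i in range(10)]
        )
        X = pd.DataFrame(
            {"x": [1.0] * 10 + [0.0] * 10},
            index=[r.patient_id for r in recs],
        )
        with pytest.raises(ConvergenceError, match="separation"):
            cox_fit(recs, X)

    def test_null_covariate_p_uniform(self):
        """Wald p under the null is uniform (KS over 200 replicates)."""
        from scipy import stats as sps

        ps = []
        for rep in range(200):
            rng = np.random.default_rng(9000 + rep)
            n = 120
            x = (rng.random(n) < 0.5).astype(float)
            t = rng.exponential(1 / 0.02, n)
            censor = 60.0
            recs = [
                SurvivalRecord(f"P{i}", float(min(t[i], censor)),
                               bool(t[i] <= censor))
                for i in range(n)
            ]
            X = pd.DataFrame({"x": x}, index=[f"P{i}" for i in range(n)])
            ps.append(cox_fit(recs, X)[0].p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestRecurrenceScan:
    def _cohort(self, seed=0, n=240, hr=6.0, freq=0.25):
        rng = np.random.default_rng(seed)
        carrier = rng.random(n) < freq
        h = 0.004 * np.where(carrier, hr, 1.0)
        t = rng.exponential(1 / h)
        censor = 60.0
        clinical, rows = [], []
        for i in range(n):
            clinical.append(
                _patient(
                    pid=f"P{i:03d}",
                    gender="male" if rng.random() < 0.3 else "female",
                    followup_months=round(float(min(t[i], censor)), 3),
                    recurrence_event=bool(t[i] <= censor),
                )
            )
            rows.append("loss" if carrier[i] else "none")
        cm = pd.DataFrame({"r1:loss": rows},
                          index=[f"P{i:03d}" for i in range(n)])
        return clinical, cm

    def test_planted_hazard_region_found_and_retained(self):
        found = 0
        n_rep = 10
        for rep in range(n_rep):
            clinical, cm = self._cohort(seed=rep)
            uni, multi = recurrence_scan(cm, clinical)
            uni_hit = ((uni["covariate"] == "r1:loss") & (uni["p"] <= 0.05)).any()
            multi_hit = multi.empty or (multi["covariate"] == "r1:loss").any()
            found += uni_hit and multi_hit
        assert found >= 0.9 * n_rep

    def test_no_events_rejected(self):
        clinical = [_patient(pid=f"P{i}", recurrence_event=False) for i in range(10)]
        cm = pd.DataFrame({"r1:loss": ["none"] * 10},
                          index=[f"P{i}" for i in range(10)])
        with pytest.raises(ValidationError, match="no recurrence events"):
            recurrence_scan(cm, clinical)


class TestCombinedRisk:
    def test_nobody_carries_single_stratum_no_test(self):
        clinical = [
            _patient(pid=f"P{i}", recurrence_event=(i == 0),
                     followup_months=10.0 + i)
            for i in range(6)
        ]
        flags = pd.DataFrame({"a": [0] * 6, "b": [0] * 6},
                             index=[f"P{i}" for i in range(6)])
        curves, chi2, p, per_cnv = combined_risk(clinical, flags)
        assert chi2 is None and p is None and per_cnv is None
        assert len(curves) == 1

    def test_additive_hazard_recovered(self):
        """Per-CNV ln-HR estimated within 20% of truth (additive on the
        log-hazard scale, n=400)."""
        rng = np.random.default_rng(77)
        n, true_hr = 400, 3.0
        c1 = rng.random(n) < 0.3
        c2 = rng.random(n) < 0.3
        count = c1.astype(int) + c2.astype(int)
        h = 0.004 * true_hr**count
        t = rng.exponential(1 / h)
        censor = 60.0
        clinical = [
            _patient(pid=f"P{i:03d}", followup_months=round(float(min(t[i], censor)), 3),
                     recurrence_event=bool(t[i] <= censor))
            for i in range(n)
        ]
        flags = pd.DataFrame({"a": c1.astype(int), "b": c2.astype(int)},
                             index=[f"P{i:03d}" for i in range(n)])
        curves, chi2, p, per_cnv = combined_risk(clinical, flags)
        assert p < 1e-4
        assert abs(np.log(per_cnv.hazard_ratio) - np.log(true_hr)) <= 0.2 * np.log(true_hr)
        # median survival ordering across strata: more CNVs -> earlier events
        medians = {}
        for label, df in curves.items():
            below = df[df["survival"] <= 0.5]
            medians[int(label)] = below["time"].iloc[0] if len(below) else np.inf
        assert medians[0] >= medians[1] >= medians[2]
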