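"""Survival harness: KM/log-rank behaviour, Cox recovery, cohort filters."""

import numpy as np
import pytest

from luadgrade import SurvivalRecord, cox_fit, km_logrank, subset


def make_records(rng, n, scale, group, endpoint="OS", censor_at=None, cohort=""):
    t = rng.exponential(scale, size=n)
    event = np.ones(n, dtype=int)
    if censor_at is not None:
        event = (t <= censor_at).astype(int)
        t = np.minimum(t, censor_at)
    return [
        SurvivalRecord(
            case_id=f"{group}_{i}", endpoint=endpoint, time=float(max(ti, 1e-3)),
            event=int(ei), pT=int(rng.integers(1, 5)), pN=int(rng.integers(0, 3)),
            age=float(rng.normal(65, 8)), stage=str(rng.choice(["I", "II", "III"])),
            cohort=cohort,
        )
        for i, (ti, ei) in enumerate(zip(t, event))
    ]


class TestRecordValidation:
    def test_invalid_fields_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord("c", "OS", -1.0, 1)
        with pytest.raises(ValueError):
            SurvivalRecord("c", "XX", 10.0, 1)
        with pytest.raises(ValueError):
            SurvivalRecord("c", "OS", 10.0, 2)
        with pytest.raises(ValueError):
            SurvivalRecord("c", "OS", 10.0, 1, pN=3)


class TestSubset:
    def test_filters_compose(self, rng):
        recs = make_records(rng, 50, 30, "a", cohort="A") + make_records(
            rng, 50, 30, "b", cohort="B"
        )
        stage1 = subset(recs, stage="I")
        assert all(r.stage == "I" for r in stage1)
        both = subset(recs, stage="I", pT=1)
        assert all(r.stage == "I" and r.pT == 1 for r in both)
        no_b = subset(recs, cohort_not_in={"B"})
        assert {r.cohort for r in no_b} == {"A"}
        only_b = subset(recs, cohort_in={"B"})
        assert len(only_b) + len(no_b) == 100

    def test_empty_result_warns(self, rng):
        recs = make_records(rng, 5, 30, "a")
        with pytest.warns(UserWarning):
            subset(recs, cohort_in={"missing"})


class TestKMLogrank:
    def test_curve_shape(self, rng):
        recs = make_records(rng, 80, 30, "g1") + make_records(rng, 80, 15, "g2")
        grades = {r.case_id: r.case_id.split("_")[0] for r in recs}
        km = km_logrank(recs, grades)
        for g, curve in km["curves"].items():
            s = curve["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert (np.diff(s) <= 1e-12).all()  # non-increasing step function

    def test_ordered_groups_separate(self, rng):
        # group B lives half as long as group A, no censoring
        recs = make_records(rng, 300, 40, "A") + make_records(rng, 300, 20, "B")
        grades = {r.case_id: r.case_id.split("_")[0] for r in recs}
        km = km_logrank(recs, grades)
        assert km["median_survival"]["A"] > km["median_survival"]["B"]
        assert km["logrank_p"] < 0.001
        assert km["df"] == 1

    def test_null_p_roughly_uniform(self):
        # identically generated groups: p should not pile up near 0
        ps = []
        for s in range(40):
            rng = np.random.default_rng(1000 + s)
            recs = make_records(rng, 60, 30, "A") + make_records(rng, 60, 30, "B")
            grades = {r.case_id: r.case_id.split("_")[0] for r in recs}
            ps.append(km_logrank(recs, grades)["logrank_p"])
        assert 0.2 < np.mean(ps) < 0.8
        assert np.mean(np.array(ps) < 0.05) <= 0.2

    def test_power_at_hazard_ratio_2(self):
        rejections = 0
        n_sim = 40
        for s in range(n_sim):
            rng = np.random.default_rng(2000 + s)
            recs = make_records(rng, 500, 40, "A") + make_records(rng, 500, 20, "B")
            grades = {r.case_id: r.case_id.split("_")[0] for r in recs}
            if km_logrank(recs, grades)["logrank_p"] < 0.05:
                rejections += 1
        assert rejections >= int(0.99 * n_sim)

    def test_zero_event_group_retained_with_warning(self, rng):
        recs = make_records(rng, 30, 30, "A")
        dead = make_records(rng, 30, 30, "B", censor_at=1e9)
        for r in recs:
            r.event = 0
        grades = {r.case_id: r.case_id.split("_")[0] for r in recs + dead}
        with pytest.warns(UserWarning, match="zero events"):
            km = km_logrank(recs + dead, grades)
        assert set(km["groups"]) == {"A", "B"}

    def test_single_group_rejected(self, rng):
        recs = make_records(rng, 20, 30, "A")
        with pytest.raises(ValueError):
            km_logrank(recs, {r.case_id: "A" for r in recs})


class TestCoxFit:
    def _simulate(self, rng, n, log_hr):
        group = rng.integers(0, 2, size=n)
        lam = 0.02 * np.exp(log_hr * group)
        recs, grades = [], {}
        for i, (gi, li) in enumerate(zip(group, lam)):
            t = float(rng.exponential(1 / li))
            recs.append(SurvivalRecord(f"c{i}", "OS", max(t, 1e-3), 1,
                                       pT=int(rng.integers(1, 5)),
                                       pN=int(rng.integers(0, 3)),
                                       age=float(rng.normal(65, 8))))
            grades[f"c{i}"] = "G2" if gi else "G1"
        return recs, grades

    def test_null_covers_one(self, rng):
        recs, grades = self._simulate(rng, 400, 0.0)
        fit = cox_fit(recs, grades)
        row = fit[fit["term"] == "grade_G2"].iloc[0]
        assert row["HR_low95"] <= 1.0 <= row["HR_high95"]

    def test_recovers_known_log_hr(self, rng):
        recs, grades = self._simulate(rng, 1000, 0.6)
        fit = cox_fit(recs, grades)
        row = fit[fit["term"] == "grade_G2"].iloc[0]
        assert row["coef"] == pytest.approx(0.6, abs=0.2)

    def test_noise_covariates_leave_grade_stable(self, rng):
        recs, grades = self._simulate(rng, 1000, 0.6)
        bare = cox_fit(recs, grades)
        full = cox_fit(recs, grades, covariates=("pT", "pN", "age"))
        c1 = bare[bare["term"] == "grade_G2"].iloc[0]
        c2 = full[full["term"] == "grade_G2"].iloc[0]
        assert abs(c1["coef"] - c2["coef"]) < 0.15
        assert full.attrs["n_used"] == 1000

    def test_pt_categorical_encoding(self, rng):
        recs, grades = self._simulate(rng, 300, 0.4)
        fit = cox_fit(recs, grades, covariates=("pT",), pT_categorical=True)
        assert {"pT_2", "pT_3", "pT_4"} <= set(fit["term"])

    def test_missing_covariates_complete_case(self, rng):
        recs, grades = self._simulate(rng, 200, 0.4)
        for r in recs[:50]:
            r.age = None
        fit = cox_fit(recs, grades, covariates=("age",))
        assert fit.attrs["n_used"] == 150
        assert fit.attrs["n_dropped_incomplete"] == 50
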