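"""New-user identification, eligibility attrition and covariate assembly."""

import numpy as np
import pandas as pd
import pytest

import claimstte as c
from conftest import ADMIN_END, STUDY_START, build_db, patient_rows

IDX = 30000


class TestFindInitiators:
    def test_same_day_ult_and_colchicine_is_candidate(self, spec):
        db = build_db(patient_rows(1, index=IDX, arm="colchicine"))
        cand = c.find_initiators(db, spec)
        assert len(cand) == 1
        row = cand.iloc[0]
        assert (row["index_day"], row["arm"]) == (IDX, "colchicine")

    def test_recent_washout_drug_disqualifies(self, spec):
        """Colchicine 60 days before ULT violates the 6-month washout."""
        p = patient_rows(1, index=IDX, arm="colchicine",
                         extra_rx=((IDX - 60, "colchicine", 30),))
        cand = c.find_initiators(build_db(p), spec)
        assert cand.empty

    def test_old_washout_drug_is_allowed(self, spec):
        p = patient_rows(1, index=IDX, arm="colchicine",
                         extra_rx=((IDX - 200, "NSAID", 30),))
        assert len(c.find_initiators(build_db(p), spec)) == 1

    def test_both_prophylaxis_classes_excluded(self, spec):
        p = patient_rows(1, index=IDX, arm="colchicine",
                         extra_rx=((IDX, "NSAID", 30),))
        assert c.find_initiators(build_db(p), spec).empty

    def test_pairing_window_bounds(self, spec):
        near = patient_rows(1, index=IDX, arm=None,
                            extra_rx=((IDX + spec.pairing_window_days, "NSAID", 30),))
        far = patient_rows(2, index=IDX, arm=None,
                           extra_rx=((IDX + spec.pairing_window_days + 1, "NSAID", 30),))
        cand = c.find_initiators(build_db(near, far), spec)
        assert cand["id"].tolist() == [1]


class TestEligibility:
    def test_attrition_attributes_first_failure(self, spec):
        """8 candidates: one fails each criterion, two pass -> attrition
        vector (1,1,1,1,1,1) and cohort size 2."""
        fixtures = [
            patient_rows(0, index=IDX),                                  # pass
            patient_rows(1, index=IDX, enroll_start=IDX - 100),          # enrollment
            patient_rows(2, index=IDX, age_years=65.9),                  # age
            patient_rows(3, index=IDX, qual_dx=False),                   # required dx
            patient_rows(4, index=IDX, encounter=False, qual_dx=True),   # no lookback use
            patient_rows(5, index=IDX,
                         extra_dx=(((IDX - 10), "CKD4-5/ESKD"),)),       # exclusion
            patient_rows(6, index=ADMIN_END + 100,
                         enroll_end=ADMIN_END + 300),                    # window
            patient_rows(7, index=IDX + 5),                              # pass
        ]
        # patient 4: qualifying dx exist but nothing in the lookback window
        db = build_db(*fixtures, admin_end=ADMIN_END)
        cand = c.find_initiators(db, spec)
        assert len(cand) == 8
        eligible, att = c.apply_eligibility(db, cand, spec)
        assert att["candidates"] == 8
        assert [att[k] for k in ("enrollment", "age", "required_dx",
                                 "encounter", "exclusion", "window")] == [1] * 6
        assert att["eligible"] == 2 == len(eligible)
        assert sorted(eligible["id"]) == [0, 7]

    def test_attrition_counts_sum(self, sim_study):
        _, _, _, att = sim_study
        parts = sum(att[k] for k in ("enrollment", "age", "required_dx",
                                     "encounter", "exclusion", "window"))
        assert att["candidates"] == att["eligible"] + parts


class TestCovariates:
    def _cohort(self, *patients, spec):
        db = build_db(*patients)
        cand = c.find_initiators(db, spec)
        eligible, _ = c.apply_eligibility(db, cand, spec)
        return db, c.assemble_covariates(db, eligible, spec)

    def test_lookback_medication_and_counts(self, spec):
        p = patient_rows(1, index=IDX, enroll_start=IDX - 600,
                         extra_rx=((IDX - 30, "steroid", 30),
                                   (IDX - 40, "antihypertensive_1", 30),
                                   (IDX - 40, "antihypertensive_2", 30)))
        db, cov = self._cohort(p, spec=spec)
        row = cov.iloc[0]
        assert row["prior_steroid"] == 1
        assert row["antihtn_count"] == 2
        assert row["enrol_blocks"] == 20          # 600 days / 30
        assert row["insulin"] == 0

    def test_zero_antihypertensives_category(self, spec):
        db, cov = self._cohort(patient_rows(1, index=IDX), spec=spec)
        assert cov.iloc[0]["antihtn_count"] == 0

    def test_outside_lookback_not_counted(self, spec):
        p = patient_rows(1, index=IDX,
                         extra_rx=((IDX - 300, "steroid", 30),),
                         outcome_events=((IDX - 300, "MACE"),))
        db, cov = self._cohort(p, spec=spec)
        assert cov.iloc[0]["prior_steroid"] == 0
        assert cov.iloc[0]["prior_mace"] == 0

    def test_missing_patient_is_integrity_error(self, spec):
        db = build_db(patient_rows(1, index=IDX))
        ghost = pd.DataFrame({"id": [99], "index_day": [IDX],
                              "arm": ["colchicine"], "febuxostat": [0]})
        with pytest.raises(Exception, match="absent"):
            c.assemble_covariates(db, ghost, spec)

    def test_no_covariate_uses_post_index_information(self, sim_study):
        """Shifting every post-index record far into the future leaves the
        baseline covariate vector unchanged."""
        _, db, cohort, _ = sim_study
        idx = cohort.set_index("id")["index_day"]
        import dataclasses
        shifted = dataclasses.replace(db)
        for name in ("diagnoses", "dispensings", "outcomes"):
            tab = getattr(db, name).copy()
            post = tab["day"] > tab["id"].map(idx).fillna(-1)
            tab.loc[post, "day"] += 100_000
            setattr(shifted, name, tab)
        spec = c.EligibilitySpec(study_start_day=db.study_start_day,
                                 admin_end_day=db.admin_end_day)
        base = cohort[["id", "index_day", "arm", "febuxostat"]]
        cov1 = c.assemble_covariates(db, base, spec)
        cov2 = c.assemble_covariates(shifted, base, spec)
        pd.testing.assert_frame_equal(cov1, cov2)

    def test_row_order_independence(self, sim_study):
        _, db, cohort, _ = sim_study
        import dataclasses
        rng = np.random.default_rng(0)
        shuffled = dataclasses.replace(db)
        for name in ("patients", "enrollment", "diagnoses", "dispensings",
                     "outcomes", "deaths"):
            tab = getattr(db, name)
            setattr(shuffled, name,
                    tab.sample(frac=1.0, random_state=rng.integers(2**31))
                    .reset_index(drop=True))
        cohort2, att2 = c.build_cohort(shuffled)
        a = cohort.sort_values("id").reset_index(drop=True)
        b = cohort2.sort_values("id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)


class TestAscertainment:
    def test_no_events_censored_at_horizon_or_admin_end(self, spec):
        db = build_db(patient_rows(1, index=IDX))
        cohort, _ = c.build_cohort(db, spec)
        row = cohort.iloc[0]
        assert row["admin_censor_day"] == min(IDX + 730, ADMIN_END)
        assert np.isnan(row["mace_day"]) and np.isnan(row["death_day"])

    def test_same_day_event_and_death_single_composite_event(self, spec):
        p = patient_rows(1, index=IDX, outcome_events=((IDX + 10, "MALE"),),
                         death=IDX + 10)
        cohort, _ = c.build_cohort(build_db(p), spec)
        from claimstte.survival_t1 import COMPOSITE, event_censor_times
        t, e = event_censor_times(cohort, COMPOSITE, 730)
        assert t[0] == 10 and e[0]

    def test_composite_takes_earliest_component(self, spec):
        p = patient_rows(1, index=IDX, outcome_events=((IDX + 100, "MACE"),),
                         death=IDX + 50)
        cohort, _ = c.build_cohort(build_db(p), spec)
        from claimstte.survival_t1 import COMPOSITE, event_censor_times
        t, e = event_censor_times(cohort, COMPOSITE, 730)
        assert t[0] == 50 and e[0]

    def test_invalid_horizon(self, spec):
        db = build_db(patient_rows(1, index=IDX))
        with pytest.raises(ValueError):
            c.build_cohort(db, spec, horizon_days=0)
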