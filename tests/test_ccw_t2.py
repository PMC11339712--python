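"""Cloning, protocol adjudication, censoring weights and the pooled model."""

import numpy as np
import pandas as pd
import pytest

import claimstte as c
from claimstte.ccw_t2 import (PooledLogisticModel, clone_and_discretize,
                              deviation_days, fit_censoring_models,
                              fit_outcome_model, long_term, short_term)
from claimstte.survival_t1 import COMPOSITE
from claimstte.synthetic_claims import HazardModel
from conftest import ADMIN_END, STUDY_START, build_db, patient_rows

IDX = 30000


def _aug_for(coverage_days, admin_end=ADMIN_END, grace=0, horizon=730, **kw):
    """One patient with colchicine dispensings covering [0, coverage_days)."""
    offsets = tuple(range(0, coverage_days, 30))
    p = patient_rows(1, index=IDX, arm="colchicine", proph_offsets=offsets, **kw)
    db = build_db(p, admin_end=admin_end)
    spec = c.EligibilitySpec(study_start_day=STUDY_START, admin_end_day=admin_end)
    cohort, _ = c.build_cohort(db, spec)
    assert len(cohort) == 1
    return c.attach_trajectories(cohort, db, grace_days=grace, horizon=horizon)


def _adjudicated(aug, horizon=720):
    pi = clone_and_discretize(aug, COMPOSITE, horizon=horizon)
    return c.adjudicate_protocol(pi, aug)


class TestCloning:
    def test_two_clones_per_patient(self, spec):
        patients = [patient_rows(i, index=IDX, arm="colchicine") for i in range(5)]
        db = build_db(*patients)
        cohort, _ = c.build_cohort(db, spec)
        aug = c.attach_trajectories(cohort, db)
        pi = clone_and_discretize(aug, COMPOSITE, horizon=720)
        assert (pi["k"] == 0).sum() == 2 * len(cohort)
        assert set(pi["arm"]) == {"long_term", "short_term"}

    def test_event_day_to_interval(self):
        aug = _aug_for(300, outcome_events=((IDX + 45, "MACE"),))
        pi = clone_and_discretize(aug, COMPOSITE, horizon=720)
        long = pi[pi.arm == "long_term"]
        assert long["k"].tolist() == [0, 1]
        assert long["event"].tolist() == [0, 1]

    def test_event_at_day_100_gives_four_intervals(self):
        aug = _aug_for(300, outcome_events=((IDX + 100, "MACE"),))
        pi = clone_and_discretize(aug, COMPOSITE, horizon=720)
        assert pi[pi.arm == "long_term"]["k"].tolist() == [0, 1, 2, 3]

    def test_censored_partial_interval_dropped(self):
        aug = _aug_for(300, enroll_end=IDX + 100)   # disenrolls at day 100
        pi = clone_and_discretize(aug, COMPOSITE, horizon=720)
        assert pi[pi.arm == "long_term"]["k"].tolist() == [0, 1, 2]

    def test_non_multiple_horizon_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            clone_and_discretize(_aug_for(300), COMPOSITE, horizon=100)


class TestAdjudication:
    """Hand-traced strategy rules at zero grace."""

    def test_stop_at_day_60_censors_both_clones_in_interval_2(self):
        aug = _aug_for(60)
        assert deviation_days(aug, long_term(0))[0] == 60
        assert deviation_days(aug, short_term(0))[0] == 60
        adj = _adjudicated(aug)
        for arm in ("long_term", "short_term"):
            part = adj[adj.arm == arm]
            assert part["k"].tolist() == [0, 1, 2]
            assert part["uncensored"].tolist() == [1, 1, 0]
            assert part["in_outcome"].tolist() == [True, True, False]

    def test_stop_at_day_90_boundary(self):
        """Coverage 0-89: the long clone deviates in interval 3; the short
        clone is fully compliant and is never censored."""
        aug = _aug_for(90)
        adj = _adjudicated(aug)
        long = adj[adj.arm == "long_term"]
        assert long["k"].tolist() == [0, 1, 2, 3]
        assert long["uncensored"].tolist() == [1, 1, 1, 0]
        short = adj[adj.arm == "short_term"]
        assert short["k"].tolist() == list(range(24))
        assert (short["uncensored"] == 1).all()

    def test_continuous_use_censors_short_clone_after_switch(self):
        """Coverage through end of follow-up (day 300): the long clone never
        deviates; the short clone is censored at the first coverage start
        at/after day 90."""
        aug = _aug_for(300, admin_end=IDX + 300)
        adj = _adjudicated(aug)
        long = adj[adj.arm == "long_term"]
        assert (long["uncensored"] == 1).all()
        assert long["k"].tolist() == list(range(10))   # admin end at day 300
        short = adj[adj.arm == "short_term"]
        assert short["k"].tolist() == [0, 1, 2, 3]
        assert short["uncensored"].tolist() == [1, 1, 1, 0]

    def test_never_starting_censors_at_interval_zero(self, spec):
        p = patient_rows(1, index=IDX, arm="NSAID")
        db = build_db(p)
        cohort, _ = c.build_cohort(db, spec)
        aug = c.attach_trajectories(cohort, db, grace_days=0)
        adj = _adjudicated(aug)
        assert adj["k"].tolist() == [0, 0]
        assert (adj["uncensored"] == 0).all()

    def test_event_on_deviation_day_counts(self):
        aug = _aug_for(60, outcome_events=((IDX + 60, "MACE"),))
        adj = _adjudicated(aug)
        long = adj[adj.arm == "long_term"]
        assert long["event"].tolist() == [0, 0, 1]
        assert (long["uncensored"] == 1).all()

    def test_event_after_deviation_dropped(self):
        aug = _aug_for(60, outcome_events=((IDX + 70, "MACE"),))
        adj = _adjudicated(aug)
        long = adj[adj.arm == "long_term"]
        assert long["event"].sum() == 0
        assert long["uncensored"].tolist() == [1, 1, 0]

    def test_grace_extends_compliance(self):
        """With a 30-day grace, a stop at day 60 deviates at day 90."""
        aug = _aug_for(60, grace=30)
        d = deviation_days(aug, long_term(30))
        assert d[0] == 90


class TestCensoringWeights:
    def test_cumulative_weight_closed_form(self):
        pi = pd.DataFrame({
            "arm": "long_term", "pid": 0, "k": [0, 1],
            "p_num": [0.9, 0.9], "p_den": [0.8, 0.8],
            "at_risk_dev": True, "uncensored": 1, "event": 0,
            "in_outcome": True, "weight": 1.0})
        out = c.compute_tv_weights(pi, truncation_percentile=100)
        assert out["weight"].tolist() == pytest.approx([1.125, 1.265625])

    def test_unit_ratios_give_unit_weights(self):
        pi = pd.DataFrame({
            "arm": "long_term", "pid": 0, "k": [0, 1, 2],
            "p_num": 1.0, "p_den": 1.0, "at_risk_dev": True,
            "uncensored": 1, "event": 0, "in_outcome": True, "weight": 1.0})
        out = c.compute_tv_weights(pi, 99)
        assert (out["weight"] == 1.0).all()

    def test_zero_probability_is_positivity_error(self):
        pi = pd.DataFrame({
            "arm": "long_term", "pid": 0, "k": [0], "p_num": [1.0],
            "p_den": [0.0], "at_risk_dev": True, "uncensored": 1,
            "event": 0, "in_outcome": True, "weight": 1.0})
        with pytest.raises(c.ccw_t2.PositivityError):
            c.compute_tv_weights(pi, 99)

    def test_no_deviations_all_probabilities_one(self):
        aug = _aug_for(90)
        adj = _adjudicated(aug)
        short = adj[adj.arm == "short_term"].copy()   # fully compliant
        out = fit_censoring_models(short, aug)
        assert (out["p_num"] == 1.0).all()
        assert (out["p_den"] == 1.0).all()

    def test_covariate_independent_deviation_gives_unit_ratios(self):
        """When discontinuation depends only on arm and time, numerator and
        denominator models agree and stabilized ratios are ~1."""
        cfg = c.default_config(3000, seed=55)
        cfg.treatment.coefficients = {}
        cfg.flare.prior_steroid_logit = 0.0
        cfg.flare.off_prophylaxis_logit = 0.0
        cfg.duration.steroid_logit = 0.0
        db = c.simulate_cohort(cfg)
        cohort, _ = c.build_cohort(db)
        aug = c.attach_trajectories(cohort, db)
        pi = clone_and_discretize(aug, COMPOSITE, horizon=720)
        pi = c.adjudicate_protocol(pi, aug)
        pi = fit_censoring_models(pi, aug)
        at_risk = pi[pi["at_risk_dev"]]
        ratio = at_risk["p_num"] / at_risk["p_den"]
        assert abs(ratio.mean() - 1.0) < 0.02
        assert np.quantile(np.abs(ratio - 1.0), 0.95) < 0.25

    def test_steroid_coefficient_recovers_dgp_sign(self):
        """In the generator, gout flares rebound once prophylaxis stops
        (off-prophylaxis steroid odds ratio > 1), so current steroid use
        marks person-time around discontinuation and its fitted
        remaining-uncensored coefficient must be negative."""
        cfg = c.default_config(5000, seed=99)
        cfg.flare.off_prophylaxis_logit = 2.0   # strengthen the flare rebound
        db = c.simulate_cohort(cfg)
        cohort, _ = c.build_cohort(db)
        aug = c.attach_trajectories(cohort, db)
        pi = clone_and_discretize(aug, COMPOSITE, horizon=720)
        pi = c.adjudicate_protocol(pi, aug)
        pi = fit_censoring_models(pi, aug)
        models = pi.attrs["censoring_models"]
        assert models["long_term"]["den"]["steroid"] < 0


class TestOutcomeModel:
    def test_null_constant_hazard_coefficients_near_zero(self):
        cfg = c.persistent_treatment_config(4000, seed=17)
        cfg.hazard = HazardModel(
            base_prob={"MACE": 0.006, "MALE": 0.002, "death": 0.005},
            coefficients={"MACE": {}, "MALE": {}, "death": {}},
            steroid_logit={"MACE": 0.0, "MALE": 0.0, "death": 0.0})
        db = c.simulate_cohort(cfg)
        cohort, _ = c.build_cohort(db)
        aug = c.attach_trajectories(cohort, db)
        pi = clone_and_discretize(aug, COMPOSITE, horizon=720)
        pi = c.adjudicate_protocol(pi, aug)     # unit weights
        model = fit_outcome_model(pi)
        z = np.abs(model.params[1:] / model.bse[1:])   # all but the intercept
        assert (z < 3).all(), dict(zip(model.columns[1:], z))

    def test_saturated_model_reproduces_empirical_hazards(self, spec):
        """With unit weights, the saturated-time fit equals interval
        event/at-risk ratios, and its risk curve equals the discretized
        Kaplan-Meier complement exactly."""
        rng = np.random.default_rng(3)
        patients = []
        for i in range(20):
            events = ()
            death = None
            if rng.random() < 0.4:
                events = ((IDX + int(rng.integers(10, 700)), "MACE"),)
            if rng.random() < 0.2:
                death = IDX + int(rng.integers(10, 700))
            patients.append(patient_rows(
                i, index=IDX, arm="colchicine",
                proph_offsets=tuple(range(0, 720, 30)),
                outcome_events=events, death=death))
        db = build_db(*patients)
        cohort, _ = c.build_cohort(db, spec)
        aug = c.attach_trajectories(cohort, db)
        pi = clone_and_discretize(aug, COMPOSITE, horizon=720)  # no deviation
        model = fit_outcome_model(pi, saturated_time=True)
        curves = c.predict_risk_curves(model, 720)

        # independent loop-based discrete-time estimate per arm
        t, e = c.survival_t1.event_censor_times(cohort, COMPOSITE, 720)
        surv = 1.0
        expect = []
        for k in range(24):
            at_risk = ((t >= 30 * (k + 1)) | (e & (t >= 30 * k))).sum()
            d = (e & (t >= 30 * k) & (t < 30 * (k + 1))).sum()
            h = d / at_risk if at_risk else 0.0
            surv *= 1.0 - h
            expect.append(1.0 - surv)
        for arm in ("long_term", "short_term"):
            got = [curves[arm].risk_at(30 * (k + 1)) for k in range(24)]
            assert got == pytest.approx(expect, abs=1e-12)

    def test_predicted_risk_closed_form_and_monotone(self):
        model = PooledLogisticModel(
            params=np.array([np.log(0.01 / 0.99), 0.0, 0.0, 0.0, 0.0, 0.0]),
            columns=["const", "arm", "k", "k2", "k3", "arm_k"])
        curves = c.predict_risk_curves(model, 720)
        assert curves["long_term"].risk_at(720) == pytest.approx(1 - 0.99**24)
        for cv in curves.values():
            assert (np.diff(cv.risks) >= -1e-15).all()

    def test_all_zero_hazards_zero_risk(self):
        model = PooledLogisticModel(
            params=np.array([-50.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
            columns=["const", "arm", "k", "k2", "k3", "arm_k"])
        curves = c.predict_risk_curves(model, 720)
        assert curves["long_term"].risk_at(720) == pytest.approx(0.0, abs=1e-12)
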