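"""Schedules, eligibility, participation, the LDCT gate and the pathway."""

import math

import numpy as np
import pytest

from lungscreen.natural_history import DiseaseCourse
from lungscreen.params import ParticipationParams
from lungscreen.params import TestCharacteristics as LdctCharacteristics
from lungscreen.population import IndividualProfile
from lungscreen.screening import (FALSE_NEGATIVE, FALSE_POSITIVE, TRUE_NEGATIVE,
                                  TRUE_POSITIVE, StrategySpec, apply_ldct,
                                  build_schedule, check_eligibility,
                                  full_strategy_grid, run_screening_pathway,
                                  sample_participation)


def _profile(age=60.0, risk=5.0, seed=1, pid=0):
    p = IndividualProfile(id=pid, sex="male", entry_age=age,
                          smoking_category="current", master_seed=seed)
    p.risk_percent = risk
    return p


def _course(onset, entries, presentation=math.inf, stage=None):
    arr = np.full(7, math.inf)
    arr[:len(entries)] = entries
    return DiseaseCourse(onset_age=onset, stage_entry_age=arr,
                         presentation_age=presentation, presentation_stage=stage)


class TestSchedules:
    def test_triple_screen_offsets(self):
        assert build_schedule("T", 62.0) == [0.0, 1.0, 2.0]

    def test_single_screen(self):
        assert build_schedule("S", 79.0) == [0.0]

    def test_biennial_at_79_only_entry_screen(self):
        assert build_schedule("B", 79.0) == [0.0]

    def test_annual_at_77_three_screens(self):
        assert build_schedule("A", 77.0) == [0.0, 1.0, 2.0]

    def test_annual_cap_strictly_before_80(self):
        times = build_schedule("A", 55.0)
        assert times[0] == 0.0 and len(times) == 25 and 55.0 + times[-1] < 80.0

    def test_triple_not_age_capped(self):
        assert build_schedule("T", 80.0) == [0.0, 1.0, 2.0]

    def test_grid_has_48_strategies(self):
        grid = full_strategy_grid()
        assert len(grid) == 48
        assert len({s.name for s in grid}) == 48


class TestEligibility:
    def test_age_below_window(self):
        spec = StrategySpec("S", 60, 75, 3.0)
        assert not check_eligibility(_profile(age=59.0), spec)

    def test_risk_threshold_boundary_inclusive(self):
        spec = StrategySpec("S", 55, 80, 3.0)
        assert check_eligibility(_profile(risk=3.0), spec)
        assert not check_eligibility(_profile(risk=2.999), spec)

    def test_upper_age_bound_inclusive(self):
        spec = StrategySpec("S", 60, 75, 3.0)
        assert check_eligibility(_profile(age=75.4), spec)
        assert not check_eligibility(_profile(age=76.0), spec)


class TestParticipation:
    def test_joint_joining_probability(self):
        """Responds x joins ~ 0.307 * 0.465 = 0.1428 over many draws."""
        p = ParticipationParams(p_response=0.307, p_join_given_eligible=0.465)
        rng = np.random.default_rng(5)
        u = rng.random((100_000, 2))
        joins = sum(sample_participation(_profile(), p, u=(a, b))["joins"]
                    for a, b in u)
        assert joins / 100_000 == pytest.approx(0.307 * 0.465, abs=0.004)

    def test_zero_response_nobody_joins(self):
        p = ParticipationParams(p_response=0.0, p_join_given_eligible=1.0)
        assert not sample_participation(_profile(), p, u=(0.0, 0.0))["joins"]

    def test_certain_participation(self):
        p = ParticipationParams(p_response=1.0, p_join_given_eligible=1.0)
        assert sample_participation(_profile(), p, u=(0.999, 0.999))["joins"]


class TestLdctGate:
    def test_empirical_rates(self):
        test = LdctCharacteristics(sensitivity=0.709, specificity=0.624)
        u = np.random.default_rng(3).random(100_000)
        tp = np.mean([apply_ldct(True, test, x) == TRUE_POSITIVE for x in u])
        fp = np.mean([apply_ldct(False, test, x) == FALSE_POSITIVE for x in u])
        assert tp == pytest.approx(0.709, abs=0.005)
        assert fp == pytest.approx(1 - 0.624, abs=0.005)

    def test_stage_independent_by_construction(self):
        """The gate sees only the occult indicator, never the stage."""
        test = LdctCharacteristics(sensitivity=0.709, specificity=0.624)
        assert apply_ldct(True, test, 0.5) == apply_ldct(True, test, 0.5)
        assert apply_ldct(True, test, 0.70) == TRUE_POSITIVE
        assert apply_ldct(True, test, 0.71) == FALSE_NEGATIVE


class TestPathway:
    TEST = LdctCharacteristics(sensitivity=0.709, specificity=0.624)

    def test_presentation_before_first_screen_is_clinical(self):
        prof = _profile(age=60.0)
        course = _course(59.0, [59.0], presentation=60.3, stage=0)
        events, dx = run_screening_pathway(prof, course, [1.0, 2.0], self.TEST,
                                           [0.0, 0.0], oc_death_time=30.0)
        assert events == []
        assert dx.mode == "clinical" and dx.time == pytest.approx(0.3)

    def test_fn_then_tp_hand_traced(self):
        """Occult at screens 1-2; forced uniforms give FN then TP: diagnosis
        at screen 2 in the stage occupied then."""
        prof = _profile(age=60.0)
        course = _course(59.5, [59.5, 61.2])  # enters stage IB at age 61.2
        events, dx = run_screening_pathway(prof, course, [0.0, 2.0], self.TEST,
                                           [0.99, 0.01], oc_death_time=30.0)
        assert [e.result for e in events] == [FALSE_NEGATIVE, TRUE_POSITIVE]
        assert dx.mode == "screen_detected" and dx.time == 2.0 and dx.stage == 1

    def test_disease_free_all_screens_no_diagnosis(self):
        prof = _profile()
        events, dx = run_screening_pathway(prof, None, [0.0, 1.0, 2.0], self.TEST,
                                           [0.9, 0.1, 0.9], oc_death_time=30.0)
        assert dx is None
        assert [e.result for e in events] == [FALSE_POSITIVE, TRUE_NEGATIVE, FALSE_POSITIVE]

    def test_interval_cancer_between_screens(self):
        prof = _profile(age=60.0)
        course = _course(60.5, [60.5], presentation=61.5, stage=0)
        events, dx = run_screening_pathway(prof, course, [0.0, 2.0], self.TEST,
                                           [0.9, 0.9], oc_death_time=30.0)
        assert dx.mode == "interval" and dx.time == pytest.approx(1.5)

    def test_presentation_after_last_screen_is_clinical(self):
        prof = _profile(age=60.0)
        course = _course(64.0, [64.0], presentation=65.0, stage=0)
        events, dx = run_screening_pathway(prof, course, [0.0, 1.0], self.TEST,
                                           [0.9, 0.9], oc_death_time=30.0)
        assert dx.mode == "clinical"

    def test_screens_stop_at_other_cause_death(self):
        prof = _profile(age=60.0)
        events, dx = run_screening_pathway(prof, None, [0.0, 1.0, 2.0], self.TEST,
                                           [0.9, 0.9, 0.9], oc_death_time=1.5)
        assert len(events) == 2 and dx is None


class TestPopulationProperties:
    def test_screen_detection_brings_stage_forward(self, small_pool, fixture_params):
        """Screen-detected stage <= the same person's counterfactual clinical
        presentation stage, pathwise."""
        from lungscreen.engine import run_strategy

        res_pool = small_pool
        spec = StrategySpec("A", 55, 80, 3.0)
        from lungscreen.engine import run_strategy  # noqa: F811
        from lungscreen.screening import build_schedule as bs

        params = fixture_params
        checked = 0
        for person in res_pool.people:
            course = person.course
            if course is None or course.presentation_stage is None:
                continue
            schedule = bs("A", person.profile.entry_age)
            events, dx = run_screening_pathway(person.profile, course, schedule,
                                               params.test, person.screen_uniforms,
                                               person.oc_death_time)
            if dx is not None and dx.mode == "screen_detected":
                assert dx.stage <= course.presentation_stage
                checked += 1
        assert checked > 10

    def test_screening_diagnoses_superset_of_control(self, small_pool, fixture_params):
        """Everyone diagnosed without screening is also diagnosed (no later)
        under screening on the same CRN draws: over-diagnosis is nonnegative."""
        for person in small_pool.people:
            dx_c = person.control_outcome.diagnosis
            if dx_c is None:
                continue
            schedule = build_schedule("B", person.profile.entry_age)
            _, dx_s = run_screening_pathway(person.profile, person.course, schedule,
                                            fixture_params.test, person.screen_uniforms,
                                            person.oc_death_time)
            assert dx_s is not None
            assert dx_s.time <= dx_c.time
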