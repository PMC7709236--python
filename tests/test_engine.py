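"""Strategy engine: aggregation, frontier, secondary outcomes, optimisation."""

import math

import numpy as np
import pytest

from lungscreen.engine import (StrategyResult, build_pool, compute_frontier,
                               net_monetary_benefit, odds_ratio_2x2,
                               optimise_population, run_strategy, secondary_outcomes)
from lungscreen.screening import NO_SCREENING, StrategySpec
from lungscreen.survival import PersonOutcome

S_55_80_3 = StrategySpec("S", 55, 80, 3.0)


class TestRunStrategy:
    def test_no_screening_null_effects(self, small_pool):
        res = run_strategy(small_pool, NO_SCREENING)
        assert res.screens_per_participant == 0.0
        assert res.fp_per_participant == 0.0
        assert res.rr_diagnosis == pytest.approx(1.0)
        assert res.inc_cost_invited == 0.0 and res.inc_qaly_invited == 0.0

    def test_single_screen_design_one_screen_per_participant(self, small_pool):
        """Design S: survivors to the entry screen attend exactly one LDCT."""
        res = run_strategy(small_pool, S_55_80_3)
        assert res.n_participants > 0
        assert res.screens_per_participant == pytest.approx(1.0)

    def test_determinism_bit_identical(self, fixture_params):
        a = run_strategy(build_pool(fixture_params, seed=3, n=800), S_55_80_3)
        b = run_strategy(build_pool(fixture_params, seed=3, n=800), S_55_80_3)
        assert a.to_dict() == b.to_dict()

    def test_empty_participant_metrics_undefined_not_nan(self, fixture_params):
        pool = build_pool(fixture_params, seed=4, n=50)
        spec = StrategySpec("S", 55, 80, 1e9)  # nobody passes the risk filter
        res = run_strategy(pool, spec)
        assert res.n_invited == 0
        assert res.screens_per_participant is None
        assert not math.isnan(res.inc_cost_invited)

    def test_mixture_identity(self, small_pool):
        """Invited-population mean = participation-weighted mixture of
        participant and non-participant means (exact algebra)."""
        res = run_strategy(small_pool, S_55_80_3)
        n, k = res.n_invited, res.n_participants
        mixture = (k * res.mean_cost_participants_arm +
                   (n - k) * res.mean_cost_nonparticipants_arm) / n
        assert mixture == pytest.approx(res.mean_cost_invited, rel=1e-12)
        mixture_q = (k * res.mean_qaly_participants_arm +
                     (n - k) * res.mean_qaly_nonparticipants_arm) / n
        assert mixture_q == pytest.approx(res.mean_qaly_invited, rel=1e-12)

    def test_cost_decomposition_exact(self, small_pool):
        """The population total decomposes exactly into the four categories."""
        res = run_strategy(small_pool, S_55_80_3)
        total = res.mean_cost_invited * res.n_invited
        assert sum(res.cost_categories.values()) == pytest.approx(total, rel=1e-9)

    def test_pathwise_clamp_over_pool(self, small_pool):
        """Lung-cancer deaths per 100k participants under screening never
        exceed the control arm's (population corollary of the clamp)."""
        for design in ("S", "T", "B", "A"):
            res = run_strategy(small_pool, StrategySpec(design, 55, 80, 3.0))
            assert res.lc_deaths_per_100k <= res.lc_deaths_per_100k_control

    def test_rr_diagnosis_at_least_one(self, small_pool):
        res = run_strategy(small_pool, StrategySpec("A", 55, 80, 3.0))
        assert res.rr_diagnosis >= 1.0


class TestSecondaryOutcomes:
    def test_odds_ratio_hand_calculation(self):
        assert odds_ratio_2x2(20, 10, 10, 20) == pytest.approx(4.0)

    def test_zero_cell_haldane_correction(self):
        assert odds_ratio_2x2(5, 0, 3, 7) == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    def test_identical_arms_null_metrics(self):
        from lungscreen.population import IndividualProfile
        from lungscreen.screening import DiagnosisRecord

        outs = []
        profs = []
        for i in range(40):
            dx = DiagnosisRecord(time=1.0, stage=i % 7, mode="clinical") if i % 3 == 0 \
                else None
            cause = "lung_cancer" if dx is not None and i % 6 == 0 else "other"
            outs.append(PersonOutcome(arm="x", diagnosis=dx, death_time=10.0,
                                      death_cause=cause))
            profs.append(IndividualProfile(id=i, sex="male", entry_age=60.0,
                                           smoking_category="current", master_seed=0))
        sec = secondary_outcomes(outs, outs, profs)
        assert sec["or_early_diagnosis"] == pytest.approx(1.0)
        assert sec["rr_diagnosis"] == pytest.approx(1.0)
        assert sec["mortality_reduction"] == pytest.approx(0.0)

    def test_all_lc_deaths_averted(self):
        from lungscreen.population import IndividualProfile
        from lungscreen.screening import DiagnosisRecord

        dx = DiagnosisRecord(time=1.0, stage=0, mode="screen_detected")
        dxc = DiagnosisRecord(time=2.0, stage=6, mode="clinical")
        prof = IndividualProfile(id=0, sex="male", entry_age=60.0,
                                 smoking_category="current", master_seed=0)
        out_s = [PersonOutcome(arm="screening", diagnosis=dx, death_time=30.0,
                               death_cause="other")]
        out_c = [PersonOutcome(arm="control", diagnosis=dxc, death_time=5.0,
                               death_cause="lung_cancer")]
        sec = secondary_outcomes(out_s, out_c, [prof])
        assert sec["mortality_reduction"] == pytest.approx(1.0)


def _result(name, dq, dc):
    return StrategyResult(strategy=name, n_pool=1, n_invited=1, n_participants=1,
                          inc_qaly_invited=dq, inc_cost_invited=dc)


class TestFrontier:
    COMPARATOR = _result("no-screening", 0.0, 0.0)

    def test_icer_division_oracle(self):
        """(dC, dQ) = (23, 0.00082) vs comparator -> ICER 28,049."""
        entries = compute_frontier([self.COMPARATOR, _result("s1", 0.00082, 23.0)])
        assert entries[0].icer_vs_none == pytest.approx(23.0 / 0.00082)
        assert entries[0].icer_vs_none == pytest.approx(28_048.78, abs=0.01)

    def test_dominated_strategy_excluded(self):
        entries = compute_frontier([self.COMPARATOR,
                                    _result("good", 0.002, 30.0),
                                    _result("bad", 0.001, 40.0)])  # costlier, fewer QALYs
        assert [e.strategy for e in entries] == ["good"]

    def test_extended_dominance_removes_middle_collinear(self):
        """Middle point above the chord between its neighbours is never the
        NMB winner at any threshold (brute-force sweep agrees)."""
        results = [self.COMPARATOR,
                   _result("a", 0.001, 10.0),
                   _result("b", 0.002, 40.0),   # extendedly dominated
                   _result("c", 0.003, 50.0)]
        entries = compute_frontier(results)
        assert [e.strategy for e in entries] == ["a", "c"]
        # oracle: NMB sweep over thresholds never selects "b"
        winners = set()
        for wtp in np.linspace(0, 100_000, 2001):
            winners.add(max(results, key=lambda r: wtp * r.inc_qaly_invited
                            - r.inc_cost_invited).strategy)
        assert "b" not in winners
        assert winners <= {"no-screening", "a", "c"}

    def test_icers_vs_previous_strictly_increasing(self):
        rng = np.random.default_rng(5)
        results = [self.COMPARATOR] + [
            _result(f"s{i}", float(rng.uniform(0, 0.01)), float(rng.uniform(0, 500)))
            for i in range(30)]
        entries = compute_frontier(results)
        icers = [e.icer_vs_previous for e in entries]
        assert all(a < b for a, b in zip(icers, icers[1:]))

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            compute_frontier([self.COMPARATOR, _result("x", 1, 1), _result("x", 2, 2)])

    def test_comparator_required(self):
        with pytest.raises(ValueError, match="comparator"):
            compute_frontier([_result("x", 1, 1)])


class TestOptimisation:
    def test_wtp_zero_no_screening_optimal(self, small_pool):
        spec, icer, nmb = optimise_population(small_pool, "S", [(55, 80)], [3.0], wtp=0.0)
        assert spec == NO_SCREENING and nmb == 0.0

    def test_single_cell_grid(self, small_pool):
        spec, icer, nmb = optimise_population(small_pool, "S", [(60, 75)], [3.0],
                                              wtp=1e9)
        assert spec.name == "S-60-75-3%"

    def test_nmb_matches_brute_force_recomputation(self, small_pool):
        """NMB of each grid cell equals wtp*dQ - dC recomputed from the
        per-person means independently."""
        wtp = 20_000.0
        for lo, hi in [(55, 80), (60, 75)]:
            spec = StrategySpec("S", lo, hi, 3.0)
            res = run_strategy(small_pool, spec)
            assert net_monetary_benefit(res, wtp) == pytest.approx(
                wtp * res.inc_qaly_invited - res.inc_cost_invited)

    def test_empty_grid_rejected(self, small_pool):
        with pytest.raises(ValueError):
            optimise_population(small_pool, "S", [], [3.0], wtp=0.0)


class TestExports:
    def test_paired_outcome_table_schema(self, small_pool):
        from lungscreen.engine import paired_outcome_table

        df = paired_outcome_table(small_pool, StrategySpec("S", 55, 80, 3.0))
        assert len(df) == 2 * small_pool.n
        assert set(df.arm) == {"screening", "control"}
        assert {"id", "dx_mode", "dx_stage", "death_time", "cause",
                "lead_time", "overdiagnosed"} <= set(df.columns)
        # control rows are never flagged as over-diagnosed
        assert not df[df.arm == "control"].overdiagnosed.any()

    def test_course_event_log_flat_records(self, small_pool):
        from lungscreen.natural_history import course_event_log

        person = next(p for p in small_pool.people
                      if p.course is not None and p.course.presentation_stage is not None)
        log = course_event_log(person.profile.id, person.course)
        assert log[0]["event"] == "stage_entry" and log[0]["stage"] == "IA"
        assert log[-1]["event"] == "presentation"
        assert course_event_log(0, None) == []
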