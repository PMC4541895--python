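import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gaitmon.acquisition import normalize
from gaitmon.fuzzy import (
    DEFAULT_MEMBERSHIP_PARAMS,
    DEFAULT_RULEBASE,
    PERRY_PERCENTAGES,
    FuzzyRule,
    GaitPhase,
    MembershipParams,
    PhaseEvent,
    active_phases,
    demarcate_phases,
    evaluate_stream,
    infer_phase_memberships,
    membership_high,
    membership_low,
    minimum_tnorm,
    phase_duration_differences,
    reference_phase_duration,
    rule_activation,
    segment_cycles,
)
from gaitmon.synthetic import GaitSimParams, sensor_profile, simulate_walk_forward


class TestMembershipFunctions:
    def test_inflection_point_is_half(self):
        for s in (1.0, 15.0, 50.0):
            p = MembershipParams(slope=s)
            assert membership_low(0.5, p) == pytest.approx(0.5)
            assert membership_high(0.5, p) == pytest.approx(0.5)

    def test_low_grade_at_zero_slope_15(self):
        expected = 1.0 / (1.0 + math.exp(-7.5))
        assert membership_low(0.0, MembershipParams(slope=15.0)) == pytest.approx(
            expected, abs=1e-12
        )
        # symmetry: high grade at x=1 equals low grade at x=0
        assert membership_high(1.0, MembershipParams(slope=15.0)) == pytest.approx(
            expected, abs=1e-12
        )

    @given(st.floats(0.0, 1.0), st.floats(0.5, 100.0))
    def test_complement_sums_to_one(self, x, s):
        p = MembershipParams(slope=s)
        assert membership_low(x, p) + membership_high(x, p) == pytest.approx(
            1.0, abs=1e-12
        )

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_low_grade_strictly_decreasing(self, a, b):
        p = MembershipParams(slope=15.0)
        if a < b:
            assert membership_low(a, p) > membership_low(b, p)

    def test_rejects_input_outside_unit_interval(self):
        with pytest.raises(ValueError):
            membership_low(1.2)
        with pytest.raises(ValueError):
            membership_low(-0.1)

    def test_rejects_invalid_params(self):
        with pytest.raises(ValueError):
            MembershipParams(slope=-1.0)
        with pytest.raises(ValueError):
            MembershipParams(inflection=1.5)


class TestRuleInference:
    def test_terminal_stance_worked_example(self):
        # heel-low 0.95, 5th-high 0.90, 1st-high 1.00 -> min = 0.90
        rule = next(r for r in DEFAULT_RULEBASE if r.phase is GaitPhase.TSt)
        grade = rule_activation(
            rule, {"fsr_heel": 0.95}, {"fsr_5th": 0.90, "fsr_1st": 1.00}
        )
        assert grade == pytest.approx(0.90)

    def test_all_sensors_unloaded_activates_swing(self):
        grades = infer_phase_memberships(
            {ch: 0.0 for ch in ("fsr_heel", "fsr_5th", "fsr_1st", "fsr_toe")}
        )
        assert grades[GaitPhase.Sw] == pytest.approx(1 / (1 + math.exp(-7.5)), abs=1e-5)
        for phase in (GaitPhase.LR, GaitPhase.MSt, GaitPhase.TSt, GaitPhase.PSw):
            # complement of the swing grade: 1/(1+e^{7.5}) ~ 5.5e-4
            assert grades[phase] <= 1.0 - grades[GaitPhase.Sw] + 1e-12

    def test_midstance_ignores_dont_care_channels(self):
        base = {"fsr_heel": 0.9, "fsr_5th": 0.8, "fsr_1st": 0.2, "fsr_toe": 0.1}
        varied = dict(base, fsr_1st=0.9, fsr_toe=0.7)
        g1 = infer_phase_memberships(base)[GaitPhase.MSt]
        g2 = infer_phase_memberships(varied)[GaitPhase.MSt]
        assert g1 == pytest.approx(g2)

    @given(
        st.fixed_dictionaries(
            {ch: st.floats(0.0, 1.0) for ch in ("fsr_heel", "fsr_5th", "fsr_1st", "fsr_toe")}
        )
    )
    def test_min_tnorm_bound_and_range(self, fsrs):
        grades = infer_phase_memberships(fsrs)
        low = {ch: membership_low(x, DEFAULT_MEMBERSHIP_PARAMS[ch]) for ch, x in fsrs.items()}
        for rule in DEFAULT_RULEBASE:
            g = grades[rule.phase]
            assert 0.0 <= g <= 1.0
            for ch, level in rule.antecedents.items():
                antecedent = low[ch] if level == "low" else 1.0 - low[ch]
                assert g <= antecedent + 1e-12

    @pytest.mark.parametrize("rule", DEFAULT_RULEBASE, ids=lambda r: r.phase.name)
    def test_ideal_pattern_grade_near_one(self, rule):
        ideal = {ch: 0.0 for ch in ("fsr_heel", "fsr_5th", "fsr_1st", "fsr_toe")}
        for ch, level in rule.antecedents.items():
            ideal[ch] = 1.0 if level == "high" else 0.0
        assert infer_phase_memberships(ideal)[rule.phase] >= 0.999

    def test_empty_rule_is_configuration_error(self):
        with pytest.raises(ValueError):
            FuzzyRule(GaitPhase.LR, {})
        with pytest.raises(ValueError):
            minimum_tnorm([])


class TestDemarcation:
    def test_constant_midstance_pattern_yields_single_event(self):
        n = 50
        grades = np.tile([0.01, 0.98, 0.02, 0.01, 0.01], (n, 1))
        events = demarcate_phases(np.arange(n) / 50.0, grades, side="left")
        assert len(events) == 1
        assert events[0].phase is GaitPhase.MSt
        assert events[0].duration_ms == pytest.approx(n / 50.0 * 1000.0)

    def test_exact_tie_retains_previous_phase(self):
        grades = np.array(
            [
                [0.9, 0.1, 0.1, 0.1, 0.1],  # LR active
                [0.9, 0.9, 0.1, 0.1, 0.1],  # tie LR/MSt -> stay LR
                [0.1, 0.9, 0.1, 0.1, 0.1],  # MSt wins
            ]
        )
        assert list(active_phases(grades)) == [1, 1, 2]

    def test_clean_walk_events_cycle_in_canonical_order(self):
        walk = simulate_walk_forward(GaitSimParams(noise_sd=0.0, seed=4), n_cycles=6)
        normalized = normalize(walk.frame, sensor_profile())
        ts, grades = evaluate_stream(normalized, "left")
        events = demarcate_phases(ts, grades, side="left")
        order = [ev.phase for ev in events]
        canonical = [GaitPhase.LR, GaitPhase.MSt, GaitPhase.TSt, GaitPhase.PSw, GaitPhase.Sw]
        start = canonical.index(order[0])
        for i, phase in enumerate(order):
            assert phase is canonical[(start + i) % 5]

    def test_rejects_empty_stream(self):
        with pytest.raises(ValueError):
            demarcate_phases(np.array([]), np.empty((0, 5)))


class TestReferenceCycle:
    def test_percentages_are_the_canonical_partition(self):
        assert {p.name: v for p, v in PERRY_PERCENTAGES.items()} == {
            "LR": 10.0, "MSt": 20.0, "TSt": 20.0, "PSw": 10.0, "Sw": 40.0,
        }

    @pytest.mark.parametrize(
        "pct,cycle,expected", [(10, 1000, 100), (40, 1200, 480), (20, 850, 170)]
    )
    def test_phase_duration_arithmetic(self, pct, cycle, expected):
        assert reference_phase_duration(pct, cycle) == pytest.approx(expected)

    @given(st.floats(100.0, 5000.0))
    def test_phase_durations_sum_to_cycle_time(self, cycle_ms):
        total = sum(
            reference_phase_duration(pct, cycle_ms)
            for pct in PERRY_PERCENTAGES.values()
        )
        assert total == pytest.approx(cycle_ms)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            reference_phase_duration(-1, 1000)
        with pytest.raises(ValueError):
            reference_phase_duration(10, 0)


def _events_from_durations(durations_ms, t0=0.0):
    """Build one cycle of events (LR..Sw) from per-phase durations in ms."""
    events, t = [], t0
    for phase, dur in zip(GaitPhase, durations_ms):
        events.append(PhaseEvent(phase, t, t + dur / 1000.0))
        t += dur / 1000.0
    return events, t


class TestPhaseDurationDifferences:
    def test_reference_durations_give_zero_differences(self):
        events, _ = _events_from_durations([100, 200, 200, 100, 400])
        diffs = phase_duration_differences(events)
        for phase in GaitPhase:
            assert diffs[phase] == pytest.approx(0.0, abs=1e-9)

    def test_overestimated_loading_response_is_positive(self):
        # 1000 ms cycle, LR measured 110 ms instead of 100 -> +10
        events, _ = _events_from_durations([110, 200, 200, 100, 390])
        diffs = phase_duration_differences(events)
        assert diffs[GaitPhase.LR] == pytest.approx(10.0)

    def test_matches_per_cycle_recomputation_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(3):
            all_events, per_cycle, t = [], [], 0.0
            n_cycles = rng.integers(2, 6)
            for _ in range(n_cycles):
                durs = rng.uniform(50, 500, 5)
                events, t = _events_from_durations(durs, t)
                all_events.extend(events)
                per_cycle.append(durs)
            got = phase_duration_differences(all_events)
            # independent spreadsheet-style recomputation
            for i, phase in enumerate(GaitPhase):
                expected = np.mean(
                    [
                        durs[i] - PERRY_PERCENTAGES[phase] / 100.0 * durs.sum()
                        for durs in per_cycle
                    ]
                )
                assert got[phase] == pytest.approx(expected, abs=1e-9)

    def test_incomplete_cycles_are_excluded(self):
        events, t = _events_from_durations([100, 200, 200, 100, 400])
        # trailing partial cycle: LR then MSt only
        events.append(PhaseEvent(GaitPhase.LR, t, t + 0.1))
        events.append(PhaseEvent(GaitPhase.MSt, t + 0.1, t + 0.3))
        diffs = phase_duration_differences(events)
        assert diffs[GaitPhase.LR] == pytest.approx(0.0, abs=1e-9)
        assert len(segment_cycles(events)) == 1

    def test_no_complete_cycle_raises(self):
        events = [PhaseEvent(GaitPhase.MSt, 0.0, 1.0)]
        with pytest.raises(ValueError):
            phase_duration_differences(events)
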