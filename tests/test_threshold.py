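"""Bisection threshold search against closed-form predicates."""

import numpy as np
import pytest

from fesim.fiber import StimulusWaveform, build_fiber
from fesim.threshold import (
    NonMonotoneActivationError,
    activation_monotonicity_check,
    find_threshold,
)


def step_predicate(true_threshold):
    return lambda amp: amp >= true_threshold


class TestBisection:
    def test_known_threshold_within_10uA_in_16_bisections(self):
        res = find_threshold(None, None, StimulusWaveform(),
                             predicate=step_predicate(123.456))
        assert res.threshold_mA == pytest.approx(123.456, abs=0.01)
        assert res.n_bisections <= 16
        lo, hi = res.bracket_mA
        assert hi - lo <= 0.01

    @pytest.mark.parametrize("true_thr", [5.01, 57.3, 499.9])
    def test_bracket_brackets_the_truth(self, true_thr):
        res = find_threshold(None, None, StimulusWaveform(),
                             predicate=step_predicate(true_thr))
        lo, hi = res.bracket_mA
        assert lo <= true_thr <= hi + 1e-12
        assert hi - lo <= 0.01

    def test_never_activated_flags_out_of_range_high(self):
        res = find_threshold(None, None, StimulusWaveform(),
                             predicate=lambda amp: False)
        assert res.out_of_range == "high"
        assert res.threshold_mA is None

    def test_active_at_5mA_extends_bracket_down_once(self):
        res = find_threshold(None, None, StimulusWaveform(),
                             predicate=step_predicate(2.5))
        assert res.out_of_range is None
        assert res.threshold_mA == pytest.approx(2.5, abs=0.01)

    def test_active_below_extended_bracket_flags_low(self):
        res = find_threshold(None, None, StimulusWaveform(),
                             predicate=step_predicate(0.05))
        assert res.out_of_range == "low"
        assert res.threshold_mA is None

    def test_reported_value_is_bracket_midpoint(self):
        res = find_threshold(None, None, StimulusWaveform(),
                             predicate=step_predicate(123.456))
        lo, hi = res.bracket_mA
        assert res.threshold_mA == pytest.approx((lo + hi) / 2.0, rel=1e-15)

    def test_bit_for_bit_reproducible(self, cm1_profile_12um, waveform):
        fiber, profile = cm1_profile_12um
        r1 = find_threshold(profile, fiber, waveform)
        r2 = find_threshold(profile, fiber, waveform)
        assert r1.threshold_mA == r2.threshold_mA
        assert r1.bracket_mA == r2.bracket_mA


class TestMonotonicityCheck:
    def test_monotone_pattern_ok(self):
        flags = activation_monotonicity_check(
            None, None, StimulusWaveform(), [10, 20, 30, 40],
            predicate=step_predicate(25))
        assert flags == [False, False, True, True]

    def test_non_monotone_raises_diagnostic(self):
        table = {10: False, 20: True, 30: False}
        with pytest.raises(NonMonotoneActivationError):
            activation_monotonicity_check(
                None, None, StimulusWaveform(), [10, 20, 30],
                predicate=lambda a: table[a])

    def test_single_amplitude_trivially_monotone(self):
        flags = activation_monotonicity_check(
            None, None, StimulusWaveform(), [50], predicate=step_predicate(25))
        assert flags == [True]

    def test_unsorted_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            activation_monotonicity_check(
                None, None, StimulusWaveform(), [30, 10],
                predicate=step_predicate(25))


class TestStrengthDurationAndRecruitment:
    """Physiological orderings on a realistic lead-field profile."""

    def test_strength_duration_monotone(self, cm1_profile_12um):
        # the fast nodal membrane makes the strength-duration curve nearly
        # flat beyond ~0.3 ms; a 0.1 uA bracket resolves the strict ordering
        fiber, profile = cm1_profile_12um
        thresholds = [
            find_threshold(profile, fiber,
                           StimulusWaveform(pulse_width_ms=w,
                                            total_duration_ms=w + 1.5),
                           tol_mA=1e-4).threshold_mA
            for w in (0.1, 0.5, 1.0)
        ]
        assert thresholds[0] > thresholds[1] > thresholds[2]

    def test_recruitment_order_large_fibres_first(
            self, cm1, cm1_electrodes, cm1_solution, waveform):
        from fesim.fiber import node_positions_m
        import fesim as f
        thr = {}
        for diam in (8.0, 12.0, 16.0):
            fib = build_fiber(diam)
            pl = f.FiberPlacement("anterior", 5.0, diam)
            nodes = node_positions_m(cm1, pl, cm1_electrodes, fib)
            profile = cm1_solution.sample_fiber_profile(nodes)
            thr[diam] = find_threshold(profile, fib, waveform).threshold_mA
        assert thr[16.0] < thr[12.0] < thr[8.0]
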