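"""Myelinated-fibre cable model: geometry rules, CRRSS kinetics, detection."""

import numpy as np
import pytest

from fesim.fiber import (
    ACTIVATION_THRESHOLD_MV,
    SimulationTrace,
    StimulusWaveform,
    build_fiber,
    crrss_rates,
    crrss_steady_state,
    detect_activation,
    simulate_response,
)


class TestBuildFiber:
    @pytest.mark.parametrize("diameter, internode_mm, nodes", [
        (12.0, 1.2, 53),
        (8.0, 0.8, 79),
        (16.0, 1.6, 39),
    ])
    def test_node_count_rule(self, diameter, internode_mm, nodes):
        fib = build_fiber(diameter, 63.0)
        assert fib.internode_length_mm == pytest.approx(internode_mm)
        assert fib.node_count == nodes
        assert fib.node_count % 2 == 1
        assert (fib.node_count - 1) * fib.internode_length_mm <= 63.0 + 1e-9

    def test_axon_diameter_ratio(self):
        assert build_fiber(12.0).axon_diameter_um == pytest.approx(8.4)

    def test_too_short_cable_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            build_fiber(16.0, 10.0)


class TestCRRSSKinetics:
    V = np.arange(-50.0, 151.0, 1.0)

    def test_rates_positive_and_finite(self):
        for rate in crrss_rates(self.V):
            assert np.all(np.isfinite(rate)) and np.all(rate > 0)

    def test_m_inf_monotone_increasing(self):
        m_inf, _ = crrss_steady_state(self.V)
        assert np.all(np.diff(m_inf) > 0)

    def test_h_inf_monotone_decreasing(self):
        _, h_inf = crrss_steady_state(self.V)
        assert np.all(np.diff(h_inf) < 0)

    def test_rest_is_equilibrium_after_leak_calibration(self):
        fib = build_fiber(12.0)
        m0, h0 = crrss_steady_state(0.0)
        g_na = fib.g_na_mS_cm2 * m0 * m0 * h0
        i_total = g_na * (0.0 - fib.e_na_mV) + fib.g_leak_mS_cm2 * (0.0 - fib.e_leak_mV)
        # residual nodal current at rest, expressed as dV/dt in mV/ms
        dvdt = -i_total / (fib.c_node_uF_cm2)
        assert abs(dvdt) < 1e-6


class TestSimulation:
    @pytest.mark.parametrize("diameter", [8.0, 12.0, 16.0])
    def test_resting_stability_10ms(self, diameter):
        fib = build_fiber(diameter)
        wf = StimulusWaveform(amplitude_mA=0.0, total_duration_ms=10.0)
        trace = simulate_response(fib, np.zeros(fib.node_count), wf)
        assert np.max(np.abs(trace.V_mV)) < 0.1

    def test_uniform_extracellular_profile_does_not_depolarize(self):
        fib = build_fiber(12.0)
        wf = StimulusWaveform(amplitude_mA=100.0)
        trace = simulate_response(fib, np.full(fib.node_count, -3.0), wf)
        assert np.max(np.abs(trace.V_mV)) < 0.1
        assert not trace.activated

    def test_profile_length_mismatch_rejected(self):
        fib = build_fiber(12.0)
        with pytest.raises(ValueError, match="node count"):
            simulate_response(fib, np.zeros(10), StimulusWaveform())

    def test_suprathreshold_propagates_with_increasing_latency(
            self, cm1_profile_12um, waveform):
        from fesim.threshold import find_threshold
        fiber, profile = cm1_profile_12um
        res = find_threshold(profile, fiber, waveform)
        trace = simulate_response(
            fiber, profile, waveform.with_amplitude(2.0 * res.threshold_mA))
        assert trace.activated
        first = trace.first_crossing_ms
        centre = int(np.nanargmin(first))
        # crossing times increase monotonically moving away from onset
        right = first[centre:]
        left = first[centre::-1]
        for arm in (right, left):
            arm = arm[np.isfinite(arm)]
            assert len(arm) >= 6
            assert np.all(np.diff(arm) >= 0)

    def test_anodic_polarity_flips_drive_sign(self, cm1_profile_12um):
        fiber, profile = cm1_profile_12um
        wf_c = StimulusWaveform(amplitude_mA=10.0, polarity="cathodic")
        wf_a = StimulusWaveform(amplitude_mA=10.0, polarity="anodic")
        tc = simulate_response(fiber, profile, wf_c)
        ta = simulate_response(fiber, profile, wf_a)
        k = 25  # early in the pulse, response is approximately linear
        centre = fiber.node_count // 2
        assert np.sign(tc.V_mV[k, centre]) == -np.sign(ta.V_mV[k, centre])


class TestPassiveInternodeVariant:
    def test_resting_stability_with_internode_compartments(self):
        fib = build_fiber(12.0, passive_internodes=True)
        wf = StimulusWaveform(amplitude_mA=0.0, total_duration_ms=5.0)
        trace = simulate_response(fib, np.zeros(fib.node_count), wf)
        assert np.max(np.abs(trace.V_mV)) < 0.1

    def test_activation_close_to_insulating_myelin_default(
            self, cm1_profile_12um, waveform):
        from fesim.threshold import find_threshold
        fiber, profile = cm1_profile_12um
        thr_default = find_threshold(profile, fiber, waveform).threshold_mA
        fib_passive = build_fiber(12.0, passive_internodes=True)
        thr_passive = find_threshold(profile, fib_passive, waveform).threshold_mA
        # a leaky but nearly insulating myelin barely changes the threshold
        assert thr_passive == pytest.approx(thr_default, rel=0.10)


def _trace_from_V(V_mV, dt_ms=0.002, pulse_width_ms=0.5):
    n_t = V_mV.shape[0]
    return SimulationTrace(
        times_ms=np.arange(n_t) * dt_ms, V_mV=V_mV,
        pulse_width_ms=pulse_width_ms, internode_length_mm=1.2,
    )


class TestDetectActivation:
    def test_just_below_threshold_not_activated(self):
        V = np.zeros((400, 53))
        V[300, :] = 79.9
        assert not detect_activation(_trace_from_V(V))

    def test_local_crossing_under_cathode_only_is_not_propagation(self):
        V = np.zeros((400, 53))
        V[250:300, 26] = 120.0  # only the node under the cathode
        trace = _trace_from_V(V)
        assert not detect_activation(trace)
        assert trace.activation_node is None

    def test_crossing_at_both_ends_counts_as_propagation(self):
        V = np.zeros((400, 53))
        V[250, 26] = 100.0  # end-of-pulse peak at the centre
        V[350, 0] = ACTIVATION_THRESHOLD_MV + 5
        V[340, 52] = ACTIVATION_THRESHOLD_MV + 5
        trace = _trace_from_V(V)
        assert detect_activation(trace)
        assert trace.activation_node == 52  # earliest far crossing
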