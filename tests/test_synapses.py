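"""Two-state synapse kinetics: exact decay, normalization, linearity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbgt import synapses as syn


def free_decay_peak(params, n_events=1, t_end=None, dt=0.01):
    """Max of (h - m) after simultaneous events at t = 0."""
    state = syn.SynapseState()
    state = syn.on_presynaptic_spike(state, params, n_events)
    t_end = t_end or 8 * params.tau_off
    peak = -np.inf
    for _ in range(int(t_end / dt)):
        state = syn.advance_synapse(state, params, dt)
        peak = max(peak, state.h - state.m)
    return peak


class TestKinetics:
    def test_exact_exponential_decay(self):
        p = syn.SynapseParams(syn.SynapseKind.AMPA, tau_on=1.0,
                              tau_off=10.0, e_syn=0.0)
        s = syn.SynapseState(m=1.0, h=1.0)
        s1 = syn.advance_synapse(s, p, 1.0)
        assert s1.m == pytest.approx(math.exp(-1.0), rel=1e-12)
        s2 = syn.advance_synapse(s, p, 10.0)
        assert s2.h == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_zero_state_is_fixed_point(self):
        s = syn.advance_synapse(syn.SynapseState(), syn.AMPA, 5.0)
        assert s.m == 0.0 and s.h == 0.0

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            syn.advance_synapse(syn.SynapseState(), syn.AMPA, 0.0)

    def test_tau_ordering_enforced(self):
        with pytest.raises(ValueError):
            syn.SynapseParams(syn.SynapseKind.GABA, tau_on=5.0,
                              tau_off=1.0, e_syn=-80.0)


class TestEventNormalization:
    @pytest.mark.parametrize("params", [syn.AMPA, syn.NMDA, syn.GABA])
    def test_unitary_event_peaks_at_one(self, params):
        # the analytic peak time is t* = ln(off/on)*on*off/(off-on)
        peak = free_decay_peak(params, 1, dt=0.002)
        assert peak == pytest.approx(1.0, abs=1e-5)

    def test_two_simultaneous_events_peak_at_two(self):
        assert free_decay_peak(syn.GABA, 2, dt=0.002) == pytest.approx(
            2.0, abs=2e-5)

    def test_no_event_leaves_state_unchanged(self):
        s = syn.SynapseState(m=0.3, h=0.7)
        s2 = syn.on_presynaptic_spike(s, syn.AMPA, 0)
        assert (s2.m, s2.h) == (0.3, 0.7)


class TestCurrents:
    def test_zero_gates_give_zero_current(self):
        assert syn.synapse_current(syn.SynapseState(), syn.AMPA, -55.0) == 0

    def test_equal_gates_give_zero_current(self):
        s = syn.SynapseState(m=0.4, h=0.4)
        assert syn.synapse_current(s, syn.NMDA, 10.0) == 0

    def test_gaba_current_vanishes_at_reversal(self):
        s = syn.SynapseState(m=0.1, h=0.6)
        assert syn.synapse_current(s, syn.GABA, -80.0) == 0

    def test_current_signs(self):
        s = syn.SynapseState(m=0.1, h=0.6)  # open conductance
        # AMPA inward (negative) below 0 mV; GABA outward above -80
        assert syn.synapse_current(s, syn.AMPA, -60.0) < 0
        assert syn.synapse_current(s, syn.GABA, -60.0) > 0

    def test_weighted_current(self):
        assert syn.weighted_current(0.0, -3.0) == 0.0
        assert syn.weighted_current(1.0, -3.0) == -3.0
        assert syn.weighted_current(2.0, -3.0) == -6.0
        with pytest.raises(ValueError):
            syn.weighted_current(-1.0, 1.0)


class TestLinearity:
    """Response to an event train equals the sum of single-event
    responses (superposition), and decays to zero without events."""

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(times=st.lists(st.integers(min_value=0, max_value=400),
                          min_size=1, max_size=8, unique=True))
    def test_superposition_over_event_trains(self, times):
        p = syn.GABA
        dt = 0.5
        n_steps = 1000
        times = sorted(times)

        def trajectory(event_steps):
            s = syn.SynapseState()
            out = np.empty(n_steps)
            for k in range(n_steps):
                if k in event_steps:
                    s = syn.on_presynaptic_spike(s, p)
                s = syn.advance_synapse(s, p, dt)
                out[k] = s.h - s.m
            return out

        combined = trajectory(set(times))
        summed = sum(trajectory({t}) for t in times)
        assert np.allclose(combined, summed, atol=1e-12)

    def test_conductance_decays_to_zero_without_events(self):
        s = syn.on_presynaptic_spike(syn.SynapseState(), syn.NMDA)
        g_prev = None
        # past the rise peak the conductance is monotone decreasing
        for k in range(400):
            s = syn.advance_synapse(s, syn.NMDA, 2.0)
            g = s.h - s.m
            if k > 10 and g_prev is not None:
                assert g <= g_prev + 1e-15
            g_prev = g
        assert g_prev < 1e-3
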