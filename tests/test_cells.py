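"""Single-compartment cell dynamics: fixed points, phenotypes, bounds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbgt import cells
from conftest import count_spikes, integrate_rhs, pack_cell


class TestFixedPoints:
    def test_th_leak_reversal_with_steady_gates_is_stationary(self):
        p = cells.THParams(i_app=0.0)
        # solve for the true rest (near the leak reversal) by finding
        # the zero of the steady-state current, then check dv/dt = 0
        from scipy.optimize import brentq

        def iss(v):
            s = cells.th_steady_state(v, p)
            return cells.th_rhs(s, 0.0, p).v
        v_rest = brentq(iss, -90.0, -50.0)
        s = cells.th_steady_state(v_rest, p)
        d = cells.th_rhs(s, 0.0, p)
        assert abs(d.v) < 1e-9
        assert abs(d.gates["h"]) < 1e-12
        assert abs(d.gates["r"]) < 1e-12

    def test_stn_gate_derivatives_vanish_at_steady_state(self):
        p = cells.STNParams()
        s = cells.stn_steady_state(-55.0, p)
        d = cells.stn_rhs(s, 0.0, p)
        for g, dg in d.gates.items():
            assert abs(dg) < 1e-12, g

    def test_gpi_rhs_is_pure(self):
        p = cells.GPParams()
        s = cells.gp_steady_state(-60.0, p)
        d1 = cells.gpi_rhs(s, {"d1": 0.3, "stn": -0.2}, p)
        d2 = cells.gpi_rhs(s, {"d1": 0.3, "stn": -0.2}, p)
        assert d1.v == d2.v
        assert d1.gates == d2.gates

    def test_da_fixed_point_of_full_system_is_stationary(self):
        # at a voltage where the net current vanishes with gates and
        # calcium at their steady values, dv/dt must be ~0
        from scipy.optimize import brentq
        p = cells.DAParams(g_leak_na=0.05)  # weak drive: stable rest exists

        def iss(v):
            s = cells.da_steady_state(v, p)
            s.ca = _ca_ss(v, s, p)
            return cells.da_rhs(s, 0.0, p).v

        def _ca_ss(v, s, p):
            ca = 0.0
            for _ in range(200):
                cur = cells.da_currents(v, *(s.gates[k] for k in
                                             cells.DA_GATES), ca, p)
                i_ca = cur[4] + cur[5] + cur[6]
                ca_new = max(-i_ca / p.k_ca, 0.0)
                if abs(ca_new - ca) < 1e-12:
                    break
                ca = ca_new
            return ca
        v_rest = brentq(iss, -80.0, -40.0)
        assert abs(iss(v_rest)) < 1e-9

    def test_non_finite_state_raises(self):
        p = cells.THParams()
        s = cells.CellState(float("nan"), {"h": 0.5, "r": 0.1})
        with pytest.raises(cells.InvalidStateError):
            cells.th_rhs(s, 0.0, p)


class TestPhenotypes:
    """Discharge phenotypes of each cell type, via reference integration."""

    def test_th_silent_at_rest_and_spikes_under_step(self):
        p = cells.THParams(i_app=0.0)
        f, y0, _ = pack_cell("th", p)
        t, y = integrate_rhs(f, y0, 2000.0)
        assert len(count_spikes(t, y[0])) == 0
        p2 = cells.THParams(i_app=1.2)
        f, y0, _ = pack_cell("th", p2)
        t, y = integrate_rhs(f, y0, 500.0)
        assert len(count_spikes(t, y[0])) >= 1

    def test_stn_spontaneous_low_rate_and_driven_faster(self):
        p = cells.STNParams()
        f, y0, _ = pack_cell("stn", p)
        t, y = integrate_rhs(f, y0, 2000.0)
        n_spont = len(count_spikes(t, y[0]))
        assert 1 <= n_spont <= 60  # (0, 30] Hz over 2 s
        f, y0, _ = pack_cell("stn", p, i_ext=10.0)
        t, y = integrate_rhs(f, y0, 2000.0)
        assert len(count_spikes(t, y[0])) > n_spont

    def test_gpe_silent_at_rest_fires_with_excitation(self):
        p = cells.GPParams(i_app=0.0)
        f, y0, _ = pack_cell("gpe", p)
        t, y = integrate_rhs(f, y0, 2000.0)
        assert len(count_spikes(t, y[0])) == 0
        f, y0, _ = pack_cell("gpe", p, i_ext=2.0)
        t, y = integrate_rhs(f, y0, 2000.0)
        assert len(count_spikes(t, y[0])) > 0

    def test_gpi_inhibitory_input_cannot_elicit_spikes(self):
        p = cells.GPParams(i_app=0.0)
        f, y0, _ = pack_cell("gpi", p, i_ext=-1.5)  # hyperpolarizing
        t, y = integrate_rhs(f, y0, 2000.0)
        assert len(count_spikes(t, y[0])) == 0

    def test_py_spike_frequency_adaptation(self):
        p = cells.PYParams(i_app=0.0)
        f, y0, _ = pack_cell("py", p)
        t, y = integrate_rhs(f, y0, 1000.0)
        assert len(count_spikes(t, y[0])) == 0  # silent at rest
        f, y0, _ = pack_cell("py", p, i_ext=0.75)
        t, y = integrate_rhs(f, y0, 2000.0)
        sp = count_spikes(t, y[0])
        isis = np.diff(sp)
        assert len(isis) >= 3
        # successive ISIs non-decreasing (up to solver wiggle)
        assert np.all(np.diff(isis) >= -2.0)

    def test_py_adaptation_current_removes_late_spikes(self):
        late = {}
        for g_m in (0.075, 0.0):
            p = cells.PYParams(i_app=0.0, g_m=g_m)
            f, y0, _ = pack_cell("py", p)
            t, y = integrate_rhs(f, y0, 2000.0)
            sp = count_spikes(t, y[0]) if g_m == 0 else None
            f, y0, _ = pack_cell("py", p, i_ext=0.75)
            t, y = integrate_rhs(f, y0, 2000.0)
            sp = count_spikes(t, y[0])
            late[g_m] = np.sum(sp > 1000.0)
        assert late[0.075] <= late[0.0]

    def test_da_tonic_pacemaking(self):
        p = cells.DAParams()
        f, y0, _ = pack_cell("da", p)
        t, y = integrate_rhs(f, y0, 4000.0)
        sp = count_spikes(t, y[0])
        sp = sp[sp > 1000.0]
        assert len(sp) >= 5
        isis = np.diff(sp)
        assert isis.std() / isis.mean() < 0.5  # regular tonic firing


class TestGateBounds:
    """Gating variables stay in [0, 1] under extreme square pulses."""

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(amp=st.floats(min_value=-50.0, max_value=50.0),
           t_on=st.floats(min_value=10.0, max_value=200.0))
    def test_gates_bounded_under_square_pulse(self, amp, t_on):
        from cbgt.engine import run_single_cell
        pulse = lambda t: amp if t >= t_on else 0.0
        for cell in ("th", "stn", "gpe", "py", "da"):
            _, tr, _ = run_single_cell(cell, 400.0, dt=0.05, i_ext=pulse)
            assert np.all(np.isfinite(tr))

    def test_gate_arrays_bounded_in_reference_integration(self):
        p = cells.STNParams()
        f, y0, names = pack_cell("stn", p, i_ext=20.0)
        t, y = integrate_rhs(f, y0, 1000.0)
        gates = y[1:1 + len(names)]
        assert gates.min() >= -1e-9
        assert gates.max() <= 1.0 + 1e-9
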