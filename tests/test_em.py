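"""Electromagnetically driven cortical neuron: flux coupling and modes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbgt import cells, em_cortex as em


class TestMemconductance:
    def test_value_at_zero_flux(self):
        assert em.memconductance(0.0, 0.4, 0.01) == pytest.approx(0.4)

    def test_direct_evaluation(self):
        assert em.memconductance(1.0, 0.4, 0.01) == pytest.approx(0.43)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(phi=st.floats(min_value=-50.0, max_value=50.0))
    def test_even_function(self, phi):
        assert em.memconductance(phi, 0.4, 0.01) == \
            em.memconductance(-phi, 0.4, 0.01)

    def test_positive_constants_required(self):
        with pytest.raises(ValueError):
            em.EMParams(alpha=-0.1)


class TestReduction:
    def test_zero_field_zero_coupling_matches_plain_pyramidal(self):
        """With a_e = 0 and k = 0 the EM trajectory coincides with the
        plain pyramidal cell integrated by the same engine."""
        from cbgt.engine import run_single_cell
        p_cell = cells.PYParams(i_app=0.9)
        params = em.EMParams(a_e=0.0, k=0.0, i_app=0.0, cell=p_cell)
        tr_em = em.run_em(params, duration=1000.0)
        _, tr_py, _ = run_single_cell("py", 1000.0, params=p_cell)
        assert np.max(np.abs(tr_em - tr_py[1:])) < 1e-6

    def test_ac_derivative_term_at_t_zero(self):
        # at t = 0 the capacitive AC drive equals -A_e * omega * Cm
        p = em.EMParams(a_e=1.5, omega=4.0)
        s = cells.py_steady_state(-70.3, p.cell)
        st0 = em.EMState(v=s.v, gates=dict(s.gates), phi=0.0)
        d_on = em.em_rhs(st0, p, 0.0)
        d_off = em.em_rhs(st0, em.EMParams(a_e=0.0, omega=4.0,
                                           k=p.k, cell=p.cell), 0.0)
        assert (d_on.v - d_off.v) * p.cell.cm == pytest.approx(
            -p.a_e * p.omega * p.cell.cm, rel=1e-9)

    def test_flux_remains_bounded(self):
        p = em.EMParams(a_e=2.0, omega=6.31, i_app=5.0)
        cell = p.cell
        from cbgt._kernels import step_py_em
        s0 = cells.py_steady_state(-70.3, cell)
        v = np.array([s0.v])
        phi = np.array([0.0])
        g = {k: np.array([s0.gates[k]]) for k in cells.PY_GATES}
        zero = np.zeros(1)
        phis = []
        for s in range(200000):  # 5 s
            step_py_em(v, g["m"], g["h"], g["n"], g["p"], g["q"], g["r"],
                       phi, zero, zero, zero, s * 0.025, 0.025,
                       cell.cm, cell.g_leak, cell.e_leak, cell.g_na,
                       cell.e_na, cell.g_kd, cell.e_k, cell.g_m,
                       cell.tau_max, cell.g_lca, cell.e_ca, cell.v_t,
                       p.i_app, p.k, p.k1, p.k2, p.alpha, p.beta,
                       p.a_e, p.omega, p.t_scale)
            phis.append(phi[0])
        phis = np.asarray(phis)
        # linear stable flux equation: |phi| <= k1/k2 * max|v|
        assert np.max(np.abs(phis)) <= p.k1 / p.k2 * 200.0


class TestClassification:
    def test_trace_too_short_errors(self):
        with pytest.raises(ValueError):
            em.classify_mode(np.zeros(1000), 0.025)

    def test_quiescent_and_smpo_split(self):
        n = int(12000 / 0.025)
        flat = np.full(n, -70.0)
        assert em.classify_mode(flat, 0.025) == "quiescent"
        t = np.arange(n) * 0.025
        wob = -70.0 + 3.0 * np.sin(2 * np.pi * t / 1000.0)
        assert em.classify_mode(wob, 0.025) == "smpo"

    def test_synthetic_period1_and_bursting(self):
        dt = 0.025
        n = int(12000 / dt)
        t = np.arange(n) * dt
        tr = np.full(n, -70.0)
        for t0 in np.arange(100.0, 11900.0, 500.0):  # regular single spikes
            tr += 90.0 * np.exp(-0.5 * ((t - t0) / 1.0) ** 2)
        assert em.classify_mode(tr, dt) == "spiking_period1"
        tr2 = np.full(n, -70.0)
        for t0 in np.arange(100.0, 11000.0, 1000.0):  # triplets
            for k in range(3):
                tr2 += 90.0 * np.exp(-0.5 * ((t - t0 - 20 * k) / 1.0) ** 2)
        assert em.classify_mode(tr2, dt) == "bursting_period_n"

    def test_sweep_single_point(self):
        df = em.sweep([em.EMParams(a_e=0.0, k=0.0)], duration=12500.0)
        assert len(df) == 1
        assert df.iloc[0]["mode"] == "quiescent"

    def test_sweep_empty_grid_errors(self):
        with pytest.raises(ValueError):
            em.sweep([])
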