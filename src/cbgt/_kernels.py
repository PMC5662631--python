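"""Compiled fixed-step integration kernels.

One step kernel per cell family, numba-jitted.  Gating variables use
exponential-Euler updates (exact for frozen rates over one step);
membrane potentials use a conductance-linearized implicit update,
which for the multi-compartment MSN becomes a backward-Euler solve of
the coupled cable system by Hines elimination on the tree (compartments
are ordered parent-before-child).

These kernels are the engine's hot path; the numpy ``*_rhs`` functions
in :mod:`cbgt.cells` and :mod:`cbgt.msn` define the same dynamics and
the test suite checks the two against each other and against adaptive
reference integrations.

All kernels advance state arrays in place by one step of ``dt`` (ms).
Synaptic input enters as summed conductance ``g_syn`` (mS/cm^2) and
conductance-weighted reversal ``ge_syn`` so it participates in the
implicit update; injected current ``i_ext`` (uA/cm^2) enters
explicitly.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

F = "float64"


@njit(cache=True, fastmath=False)
def _sig(v, theta, k):
    return 1.0 / (1.0 + math.exp(-(v - theta) / k))


@njit(cache=True, fastmath=False)
def _gate_exp(x, x_inf, tau, dt):
    return x_inf + (x - x_inf) * math.exp(-dt / tau)


# ---------------------------------------------------------------------------
# TH
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def step_th(v, h, r, g_syn, ge_syn, i_ext, dt,
            cm, g_l, e_l, g_na, e_na, g_k, e_k, g_t, e_t, i_app):
    n = v.shape[0]
    for i in range(n):
        vi = v[i]
        h_inf = _sig(vi, -41.0, -4.0)
        a_h = 0.128 * math.exp(-(vi + 46.0) / 18.0)
        b_h = 4.0 / (1.0 + math.exp(-(vi + 23.0) / 5.0))
        tau_h = 1.0 / (a_h + b_h)
        r_inf = _sig(vi, -84.0, -4.0)
        tau_r = 0.15 * (28.0 + math.exp(-(vi + 25.0) / 10.5))
        h[i] = _gate_exp(h[i], h_inf, tau_h, dt)
        r[i] = _gate_exp(r[i], r_inf, tau_r, dt)

        g_na_eff = g_na * _sig(vi, -37.0, 7.0) ** 3 * h[i]
        g_k_eff = g_k * (0.75 * (1.0 - h[i])) ** 4
        g_t_eff = g_t * _sig(vi, -60.0, 6.2) ** 2 * r[i]
        g_tot = g_l + g_na_eff + g_k_eff + g_t_eff + g_syn[i]
        ge_tot = (g_l * e_l + g_na_eff * e_na + g_k_eff * e_k
                  + g_t_eff * e_t + ge_syn[i])
        a = cm / dt
        v[i] = (a * vi + ge_tot + i_ext[i] + i_app) / (a + g_tot)


# ---------------------------------------------------------------------------
# STN
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def step_stn(v, h, n_g, r, ca, g_syn, ge_syn, i_ext, dt,
             cm, g_l, e_l, g_na, e_na, g_k, e_k, g_t, g_ca, e_ca,
             g_ahp, k1, k_ca, eps, phi_h, phi_n, phi_r, i_app):
    n = v.shape[0]
    b_off = _sig(0.0, 0.4, 0.1)
    for i in range(n):
        vi = v[i]
        h_inf = _sig(vi, -39.0, -3.1)
        tau_h = 1.0 + 500.0 / (1.0 + math.exp((vi + 57.0) / 3.0))
        n_inf = _sig(vi, -32.0, 8.0)
        tau_n = 1.0 + 100.0 / (1.0 + math.exp((vi + 80.0) / 26.0))
        r_inf = _sig(vi, -67.0, -2.0)
        tau_r = 40.0 + 17.5 / (1.0 + math.exp((vi - 68.0) / 2.2))
        h[i] = _gate_exp(h[i], h_inf, tau_h / phi_h, dt)
        n_g[i] = _gate_exp(n_g[i], n_inf, tau_n / phi_n, dt)
        r[i] = _gate_exp(r[i], r_inf, tau_r / phi_r, dt)

        b = _sig(r[i], 0.4, 0.1) - b_off
        g_na_eff = g_na * _sig(vi, -30.0, 15.0) ** 3 * h[i]
        g_k_eff = g_k * n_g[i] ** 4
        g_t_eff = g_t * _sig(vi, -63.0, 7.8) ** 3 * b * b
        g_ca_eff = g_ca * _sig(vi, -39.0, 8.0) ** 2
        g_ahp_eff = g_ahp * ca[i] / (ca[i] + k1)
        g_tot = (g_l + g_na_eff + g_k_eff + g_t_eff + g_ca_eff
                 + g_ahp_eff + g_syn[i])
        ge_tot = (g_l * e_l + g_na_eff * e_na + g_k_eff * e_k
                  + g_t_eff * e_ca + g_ca_eff * e_ca + g_ahp_eff * e_k
                  + ge_syn[i])
        a = cm / dt
        v_new = (a * vi + ge_tot + i_ext[i] + i_app) / (a + g_tot)
        i_ca_cur = g_ca_eff * (v_new - e_ca)
        i_t_cur = g_t_eff * (v_new - e_ca)
        ca[i] = ca[i] + dt * eps * (-i_ca_cur - i_t_cur - k_ca * ca[i])
        if ca[i] < 0.0:
            ca[i] = 0.0
        v[i] = v_new


# ---------------------------------------------------------------------------
# GPe / GPi (shared pallidal dynamics)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def step_gp(v, h, n_g, r, ca, g_syn, ge_syn, i_ext, dt,
            cm, g_l, e_l, g_na, e_na, g_k, e_k, g_t, g_ca, e_ca,
            g_ahp, k1, k_ca, eps, phi_h, phi_n, phi_r, i_app):
    n = v.shape[0]
    for i in range(n):
        vi = v[i]
        h_inf = _sig(vi, -58.0, -12.0)
        n_inf = _sig(vi, -50.0, 14.0)
        tau_hn = 0.05 + 0.27 / (1.0 + math.exp((vi + 40.0) / 12.0))
        r_inf = _sig(vi, -70.0, -2.0)
        h[i] = _gate_exp(h[i], h_inf, tau_hn / phi_h, dt)
        n_g[i] = _gate_exp(n_g[i], n_inf, tau_hn / phi_n, dt)
        r[i] = _gate_exp(r[i], r_inf, 30.0 / phi_r, dt)

        g_na_eff = g_na * _sig(vi, -37.0, 10.0) ** 3 * h[i]
        g_k_eff = g_k * n_g[i] ** 4
        g_t_eff = g_t * _sig(vi, -57.0, 2.0) ** 3 * r[i]
        g_ca_eff = g_ca * _sig(vi, -35.0, 2.0) ** 2
        g_ahp_eff = g_ahp * ca[i] / (ca[i] + k1)
        g_tot = (g_l + g_na_eff + g_k_eff + g_t_eff + g_ca_eff
                 + g_ahp_eff + g_syn[i])
        ge_tot = (g_l * e_l + g_na_eff * e_na + g_k_eff * e_k
                  + g_t_eff * e_ca + g_ca_eff * e_ca + g_ahp_eff * e_k
                  + ge_syn[i])
        a = cm / dt
        v_new = (a * vi + ge_tot + i_ext[i] + i_app) / (a + g_tot)
        i_ca_cur = g_ca_eff * (v_new - e_ca)
        i_t_cur = g_t_eff * (v_new - e_ca)
        ca[i] = ca[i] + dt * eps * (-i_ca_cur - i_t_cur - k_ca * ca[i])
        if ca[i] < 0.0:
            ca[i] = 0.0
        v[i] = v_new


# ---------------------------------------------------------------------------
# PY (and the electromagnetically driven variant)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def _vtrap(x, y):
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / (2.0 * y))
    return x / (math.exp(x / y) - 1.0)


@njit(cache=True, fastmath=False)
def step_py(v, m, h, n_g, p, q, r, g_syn, ge_syn, i_ext, dt,
            cm, g_leak, e_leak, g_na, e_na, g_kd, e_k, g_m, tau_max,
            g_lca, e_ca, v_t, i_app):
    n = v.shape[0]
    for i in range(n):
        vi = v[i]
        a_m = 0.32 * _vtrap(-(vi - v_t - 13.0), 4.0)
        b_m = 0.28 * _vtrap(vi - v_t - 40.0, 5.0)
        a_h = 0.128 * math.exp(-(vi - v_t - 17.0) / 18.0)
        b_h = 4.0 / (1.0 + math.exp(-(vi - v_t - 40.0) / 5.0))
        a_n = 0.032 * _vtrap(-(vi - v_t - 15.0), 5.0)
        b_n = 0.5 * math.exp(-(vi - v_t - 10.0) / 40.0)
        p_inf = 1.0 / (1.0 + math.exp(-(vi + 35.0) / 10.0))
        tau_p = tau_max / (3.3 * math.exp((vi + 35.0) / 20.0)
                           + math.exp(-(vi + 35.0) / 20.0))
        a_q = 0.055 * _vtrap(-27.0 - vi, 3.8)
        b_q = 0.94 * math.exp((-75.0 - vi) / 17.0)
        a_r = 0.000457 * math.exp((-13.0 - vi) / 50.0)
        b_r = 0.0065 / (math.exp((-15.0 - vi) / 28.0) + 1.0)

        m[i] = _gate_exp(m[i], a_m / (a_m + b_m), 1.0 / (a_m + b_m), dt)
        h[i] = _gate_exp(h[i], a_h / (a_h + b_h), 1.0 / (a_h + b_h), dt)
        n_g[i] = _gate_exp(n_g[i], a_n / (a_n + b_n), 1.0 / (a_n + b_n), dt)
        p[i] = _gate_exp(p[i], p_inf, tau_p, dt)
        q[i] = _gate_exp(q[i], a_q / (a_q + b_q), 1.0 / (a_q + b_q), dt)
        r[i] = _gate_exp(r[i], a_r / (a_r + b_r), 1.0 / (a_r + b_r), dt)

        g_na_eff = g_na * m[i] ** 3 * h[i]
        g_kd_eff = g_kd * n_g[i] ** 4
        g_m_eff = g_m * p[i]
        g_lca_eff = g_lca * q[i] ** 2 * r[i]
        g_tot = g_leak + g_na_eff + g_kd_eff + g_m_eff + g_lca_eff + g_syn[i]
        ge_tot = (g_leak * e_leak + g_na_eff * e_na + g_kd_eff * e_k
                  + g_m_eff * e_k + g_lca_eff * e_ca + ge_syn[i])
        a = cm / dt
        v[i] = (a * vi + ge_tot + i_ext[i] + i_app) / (a + g_tot)


@njit(cache=True, fastmath=False)
def step_py_em(v, m, h, n_g, p, q, r, phi, g_syn, ge_syn, i_ext, t, dt,
               cm, g_leak, e_leak, g_na, e_na, g_kd, e_k, g_m, tau_max,
               g_lca, e_ca, v_t, i_app,
               k, k1, k2, alpha, beta, a_e, omega, t_scale):
    """Pyramidal step with electromagnetic induction.

    The AC field shifts every channel's driving potential by
    ``V_e = A_e sin(omega * t * t_scale)``, adds the capacitive drive
    ``-A_e * omega * Cm * cos(omega * t * t_scale)`` and the memristive
    feedback ``k * rho(phi) * (v + V_e)`` with ``rho = alpha + 3 beta
    phi^2``; the flux obeys ``phi' = k1 v - k2 phi`` on the slow
    (scaled) time axis.
    """
    n = v.shape[0]
    ts = t * t_scale
    v_e = a_e * math.sin(omega * ts)
    i_ac = -a_e * omega * cm * math.cos(omega * ts)
    for i in range(n):
        vi = v[i] + v_e  # channels see the shifted potential
        a_m = 0.32 * _vtrap(-(vi - v_t - 13.0), 4.0)
        b_m = 0.28 * _vtrap(vi - v_t - 40.0, 5.0)
        a_h = 0.128 * math.exp(-(vi - v_t - 17.0) / 18.0)
        b_h = 4.0 / (1.0 + math.exp(-(vi - v_t - 40.0) / 5.0))
        a_n = 0.032 * _vtrap(-(vi - v_t - 15.0), 5.0)
        b_n = 0.5 * math.exp(-(vi - v_t - 10.0) / 40.0)
        p_inf = 1.0 / (1.0 + math.exp(-(vi + 35.0) / 10.0))
        tau_p = tau_max / (3.3 * math.exp((vi + 35.0) / 20.0)
                           + math.exp(-(vi + 35.0) / 20.0))
        a_q = 0.055 * _vtrap(-27.0 - vi, 3.8)
        b_q = 0.94 * math.exp((-75.0 - vi) / 17.0)
        a_r = 0.000457 * math.exp((-13.0 - vi) / 50.0)
        b_r = 0.0065 / (math.exp((-15.0 - vi) / 28.0) + 1.0)

        m[i] = _gate_exp(m[i], a_m / (a_m + b_m), 1.0 / (a_m + b_m), dt)
        h[i] = _gate_exp(h[i], a_h / (a_h + b_h), 1.0 / (a_h + b_h), dt)
        n_g[i] = _gate_exp(n_g[i], a_n / (a_n + b_n), 1.0 / (a_n + b_n), dt)
        p[i] = _gate_exp(p[i], p_inf, tau_p, dt)
        q[i] = _gate_exp(q[i], a_q / (a_q + b_q), 1.0 / (a_q + b_q), dt)
        r[i] = _gate_exp(r[i], a_r / (a_r + b_r), 1.0 / (a_r + b_r), dt)

        g_na_eff = g_na * m[i] ** 3 * h[i]
        g_kd_eff = g_kd * n_g[i] ** 4
        g_m_eff = g_m * p[i]
        g_lca_eff = g_lca * q[i] ** 2 * r[i]
        rho = alpha + 3.0 * beta * phi[i] * phi[i]
        # channel currents evaluated at v + V_e: treat the shift as an
        # extra drive so the implicit update stays in conductance form
        g_chan = g_na_eff + g_kd_eff + g_m_eff + g_lca_eff + g_leak
        ge_chan = (g_leak * e_leak + g_na_eff * e_na + g_kd_eff * e_k
                   + g_m_eff * e_k + g_lca_eff * e_ca)
        # feedback current k*rho*(v+V_e) enters with + sign
        g_tot = g_chan + g_syn[i] - k * rho
        ge_tot = (ge_chan - g_chan * v_e + ge_syn[i] + k * rho * v_e)
        a = cm / dt
        v[i] = (a * v[i] + ge_tot + i_ext[i] + i_ac + i_app) / (a + g_tot)
        phi[i] = phi[i] + dt * t_scale * (k1 * v[i] - k2 * phi[i])


# ---------------------------------------------------------------------------
# DA
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def step_da(v, m, h, n_g, a_g, b_g, ht, ca, g_syn, ge_syn, i_ext, dt,
            cm, g_na, e_na, g_kdr, e_k, g_a, g_sk, k_sk,
            g_ca_t, g_ca_n, g_ca_l, vh_l, k_l, e_ca,
            i_pump_na, i_pump_ca, k_pump,
            g_leak_na, g_leak_k, g_leak_ca, eps_ca, k_ca, i_app):
    n = v.shape[0]
    for i in range(n):
        vi = v[i]
        m_inf = _sig(vi, -30.0, 15.0)
        h_inf = _sig(vi, -39.0, -3.1)
        tau_h = 1.0 + 500.0 / (1.0 + math.exp((vi + 57.0) / 3.0))
        n_inf = _sig(vi, -32.0, 8.0)
        tau_n = 1.0 + 100.0 / (1.0 + math.exp((vi + 80.0) / 26.0))
        a_inf = _sig(vi, -42.0, 13.0)
        b_inf = _sig(vi, -63.0, -8.0)
        ht_inf = _sig(vi, -70.0, -5.0)
        m[i] = _gate_exp(m[i], m_inf, 0.1, dt)
        h[i] = _gate_exp(h[i], h_inf, tau_h, dt)
        n_g[i] = _gate_exp(n_g[i], n_inf, tau_n, dt)
        a_g[i] = _gate_exp(a_g[i], a_inf, 1.0, dt)
        b_g[i] = _gate_exp(b_g[i], b_inf, 50.0, dt)
        ht[i] = _gate_exp(ht[i], ht_inf, 25.0, dt)

        g_na_eff = g_na * m[i] ** 3 * h[i]
        g_kdr_eff = g_kdr * n_g[i] ** 3
        g_a_eff = g_a * a_g[i] * b_g[i]
        g_sk_eff = g_sk * ca[i] / (ca[i] + k_sk)
        g_t_eff = g_ca_t * _sig(vi, -52.0, 6.0) ** 2 * ht[i]
        g_n_eff = g_ca_n * _sig(vi, -25.0, 6.0) ** 2
        g_l_eff = g_ca_l * _sig(vi, vh_l, k_l) ** 2
        i_pumps = i_pump_na + i_pump_ca * ca[i] / (ca[i] + k_pump)
        g_tot = (g_na_eff + g_kdr_eff + g_a_eff + g_sk_eff + g_t_eff
                 + g_n_eff + g_l_eff + g_leak_na + g_leak_k + g_leak_ca
                 + g_syn[i])
        ge_tot = (g_na_eff * e_na + g_kdr_eff * e_k + g_a_eff * e_k
                  + g_sk_eff * e_k
                  + (g_t_eff + g_n_eff + g_l_eff) * e_ca
                  + g_leak_na * e_na + g_leak_k * e_k + g_leak_ca * e_ca
                  + ge_syn[i])
        a = cm / dt
        v_new = (a * vi + ge_tot - i_pumps + i_ext[i] + i_app) / (a + g_tot)
        i_ca_tot = (g_t_eff + g_n_eff + g_l_eff) * (v_new - e_ca)
        ca[i] = ca[i] + dt * eps_ca * (-i_ca_tot - k_ca * ca[i])
        if ca[i] < 0.0:
            ca[i] = 0.0
        v[i] = v_new


# ---------------------------------------------------------------------------
# MSN (multi-compartment, Hines backward-Euler cable solve)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def step_msn(v, act, inact, ca, parent, g_ax_den_self, g_ax_den_parent,
             g_chan, e_chan, vh_act, k_act, n_act, dec_act,
             inact_of, vh_in, k_in, dec_in, frac_in,
             gate_kind, kd_ca, feeds_ca,
             g_syn, ge_syn, i_ext, dt,
             cm, g_leak, e_leak, e_k, alpha_ca, tau_ca,
             diag, rhs, upper):
    """One backward-Euler step of all MSN compartments.

    act: (n_ch, n) activation gates; inact: (n_in, n); gate_kind: 0
    plain, 1 BK (voltage and calcium), 2 SK (calcium only).
    g_ax_den_self[i]: axial conductance density of the edge to the
    parent, referred to compartment i's area; g_ax_den_parent[i]: same
    edge referred to the parent's area.  diag/rhs/upper are n-sized
    scratch arrays.
    """
    n_ch = g_chan.shape[0]
    n = v.shape[0]
    dec_ca = math.exp(-dt / tau_ca)
    for i in range(n):
        vi = v[i]
        g_tot = g_leak + g_syn[i]
        ge_tot = g_leak * e_leak + ge_syn[i]
        i_ca_tot = 0.0
        for c in range(n_ch):
            x_inf = _sig(vi, vh_act[c], k_act[c])
            x = x_inf + (act[c, i] - x_inf) * dec_act[c]
            act[c, i] = x
            ii = inact_of[c]
            open_f = x ** n_act[c]
            if ii >= 0:
                h_inf = _sig(vi, vh_in[ii], k_in[ii])
                hh = h_inf + (inact[ii, i] - h_inf) * dec_in[ii]
                inact[ii, i] = hh
                open_f *= (1.0 - frac_in[ii]) + frac_in[ii] * hh
            if gate_kind[c] == 1:  # BK
                open_f *= ca[i] / (ca[i] + kd_ca[c])
            elif gate_kind[c] == 2:  # SK
                open_f = ca[i] * ca[i] / (ca[i] * ca[i]
                                          + kd_ca[c] * kd_ca[c])
            g_eff = g_chan[c, i] * open_f
            g_tot += g_eff
            ge_tot += g_eff * e_chan[c]
            if feeds_ca[c] == 1:
                i_ca_tot += g_eff * (vi - e_chan[c])
        a = cm / dt
        diag[i] = a + g_tot
        rhs[i] = a * vi + ge_tot + i_ext[i]
        upper[i] = 0.0
        if parent[i] >= 0:
            diag[i] += g_ax_den_self[i]
            upper[i] = -g_ax_den_self[i]
            diag[parent[i]] += g_ax_den_parent[i]
        # calcium pool relaxes toward the level set by the current influx
        ca_inf = -alpha_ca * tau_ca * i_ca_tot
        if ca_inf < 0.0:
            ca_inf = 0.0
        ca[i] = ca_inf + (ca[i] - ca_inf) * dec_ca

    # Hines elimination: children (higher index) into parents
    for i in range(n - 1, 0, -1):
        p = parent[i]
        if p >= 0:
            lower = -g_ax_den_parent[i]
            factor = lower / diag[i]
            diag[p] -= factor * upper[i]
            rhs[p] -= factor * rhs[i]
    v[0] = rhs[0] / diag[0]
    for i in range(1, n):
        p = parent[i]
        if p >= 0:
            v[i] = (rhs[i] - upper[i] * v[p]) / diag[i]
        else:
            v[i] = rhs[i] / diag[i]


# ---------------------------------------------------------------------------
# synapse state decay (all two-state synapses concatenated)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def decay_synapses(m, h, dec_on, dec_off):
    for i in range(m.shape[0]):
        m[i] *= dec_on[i]
        h[i] *= dec_off[i]
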