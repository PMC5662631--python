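"""Single-compartment current-balance models for the six network cell types.

Each cell type (TH, STN, GPe, GPi, PY, DA) is a conductance-based
Hodgkin-Huxley model written as a current balance on one compartment::

    Cm dv/dt = -sum(I_ion) - I_syn + I_app

with all currents in uA/cm^2, conductances in mS/cm^2, capacitance in
uF/cm^2, time in ms and voltage in mV.  Synaptic currents are computed
outward-positive (``I = g * s * (V - E)``) and subtracted.

The thalamic (TH) and pallidal (GPe/GPi) cells follow the Rubin-Terman
basal-ganglia formulation, the subthalamic (STN) cell the Terman et al.
formulation, and the cortical pyramidal (PY) cell the Pospischil et al.
regular-spiking neuron with an M-type adaptation current and a
high-threshold calcium current.  The dopaminergic (DA) cell is a
soma-only model carrying the twelve named currents of its multi-
compartment ancestor (fast Na, A-type, delayed-rectifier and SK
potassium, Na/Ca pumps, T/N/L calcium, and three ionic leaks),
calibrated to the tonic pacemaking phenotype of nigral DA neurons.

Functions named ``*_rhs`` return time derivatives of a :class:`CellState`
and are the definitional dynamics; the fixed-step network engine uses
compiled kernels that are tested against these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "InvalidStateError",
    "CellState",
    "THParams",
    "STNParams",
    "GPParams",
    "PYParams",
    "DAParams",
    "th_rhs",
    "stn_rhs",
    "gpe_rhs",
    "gpi_rhs",
    "py_rhs",
    "da_rhs",
    "th_steady_state",
    "stn_steady_state",
    "gp_steady_state",
    "py_steady_state",
    "da_steady_state",
]


class InvalidStateError(ValueError):
    """Raised when a cell state contains non-finite values."""


def _sig(v, theta, k):
    """Boltzmann sigmoid 1 / (1 + exp(-(v - theta)/k)).

    Negative ``k`` yields a monotonically decreasing (inactivation) curve.
    """
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - theta) / k))


@dataclass
class CellState:
    """Membrane potential, gating variables and calcium for one cell.

    ``gates`` maps gate names to values in [0, 1]; ``ca`` is the pooled
    intracellular calcium (model units) for cell types with
    calcium-dependent currents, else 0.
    """

    v: float
    gates: dict[str, float] = field(default_factory=dict)
    ca: float = 0.0

    def check(self) -> None:
        vals = [self.v, self.ca, *self.gates.values()]
        if not np.all(np.isfinite(vals)):
            raise InvalidStateError(f"non-finite cell state: {self}")

    def derivative(self, dv, dgates, dca=0.0) -> "CellState":
        return CellState(v=dv, gates=dict(dgates), ca=dca)


# ---------------------------------------------------------------------------
# TH: thalamocortical relay cell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class THParams:
    cm: float = 1.0
    g_l: float = 0.05
    e_l: float = -70.0
    g_na: float = 3.0
    e_na: float = 50.0
    g_k: float = 5.0
    e_k: float = -75.0
    g_t: float = 5.0
    e_t: float = 0.0
    i_app: float = 0.0


TH_GATES = ("h", "r")


def _th_rates(v):
    h_inf = _sig(v, -41.0, -4.0)
    a_h = 0.128 * np.exp(-(v + 46.0) / 18.0)
    b_h = 4.0 / (1.0 + np.exp(-(v + 23.0) / 5.0))
    tau_h = 1.0 / (a_h + b_h)
    r_inf = _sig(v, -84.0, -4.0)
    tau_r = 0.15 * (28.0 + np.exp(-(v + 25.0) / 10.5))
    return h_inf, tau_h, r_inf, tau_r


def th_currents(v, h, r, p: THParams):
    i_l = p.g_l * (v - p.e_l)
    i_na = p.g_na * _sig(v, -37.0, 7.0) ** 3 * h * (v - p.e_na)
    i_k = p.g_k * (0.75 * (1.0 - h)) ** 4 * (v - p.e_k)
    i_t = p.g_t * _sig(v, -60.0, 6.2) ** 2 * r * (v - p.e_t)
    return i_l, i_na, i_k, i_t


def th_rhs(state: CellState, i_syn: float, params: THParams) -> CellState:
    """Thalamic relay cell: leak, Na, K, T-type Ca, GPi inhibition, bias.

    ``i_syn`` is the (outward-positive) inhibitory current from GPi.
    Without synaptic input and bias the cell sits at a stable rest and
    does not discharge spontaneously; phasic release from inhibition can
    trigger rebound bursts through the T current.
    """
    state.check()
    v, h, r = state.v, state.gates["h"], state.gates["r"]
    i_l, i_na, i_k, i_t = th_currents(v, h, r, params)
    dv = (-i_l - i_na - i_k - i_t - i_syn + params.i_app) / params.cm
    h_inf, tau_h, r_inf, tau_r = _th_rates(v)
    return state.derivative(dv, {"h": (h_inf - h) / tau_h,
                                 "r": (r_inf - r) / tau_r})


def th_steady_state(v: float, params: THParams | None = None) -> CellState:
    h_inf, _, r_inf, _ = _th_rates(v)
    return CellState(v=float(v), gates={"h": float(h_inf), "r": float(r_inf)})


# ---------------------------------------------------------------------------
# STN: subthalamic nucleus cell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class STNParams:
    cm: float = 1.0
    g_l: float = 2.25
    e_l: float = -60.0
    g_na: float = 37.5
    e_na: float = 55.0
    g_k: float = 45.0
    e_k: float = -80.0
    g_t: float = 0.5
    g_ca: float = 0.5
    e_ca: float = 140.0
    g_ahp: float = 9.0
    k1: float = 15.0
    k_ca: float = 22.5
    eps: float = 5e-5
    phi_h: float = 0.75
    phi_n: float = 0.75
    phi_r: float = 0.2
    i_app: float = 0.0


STN_GATES = ("h", "n", "r")


def _stn_rates(v):
    h_inf = _sig(v, -39.0, -3.1)
    tau_h = 1.0 + 500.0 / (1.0 + np.exp((v + 57.0) / 3.0))
    n_inf = _sig(v, -32.0, 8.0)
    tau_n = 1.0 + 100.0 / (1.0 + np.exp((v + 80.0) / 26.0))
    r_inf = _sig(v, -67.0, -2.0)
    tau_r = 40.0 + 17.5 / (1.0 + np.exp((v - 68.0) / 2.2))
    return h_inf, tau_h, n_inf, tau_n, r_inf, tau_r


def _stn_b(r):
    # T-current availability as a function of the slow gate r
    return _sig(r, 0.4, 0.1) - _sig(0.0, 0.4, 0.1)


def stn_currents(v, h, n, r, ca, p: STNParams):
    i_l = p.g_l * (v - p.e_l)
    i_na = p.g_na * _sig(v, -30.0, 15.0) ** 3 * h * (v - p.e_na)
    i_k = p.g_k * n ** 4 * (v - p.e_k)
    i_t = p.g_t * _sig(v, -63.0, 7.8) ** 3 * _stn_b(r) ** 2 * (v - p.e_ca)
    i_ca = p.g_ca * _sig(v, -39.0, 8.0) ** 2 * (v - p.e_ca)
    i_ahp = p.g_ahp * (v - p.e_k) * ca / (ca + p.k1)
    return i_l, i_na, i_k, i_t, i_ca, i_ahp


def stn_rhs(state: CellState, i_syn: float, params: STNParams) -> CellState:
    """STN cell: leak, Na, K, T, Ca, AHP; tonic at low rate when isolated.

    ``i_syn`` carries the summed GPe (inhibitory) and cortical
    (excitatory) synaptic currents, outward-positive.
    """
    state.check()
    v = state.v
    h, n, r = (state.gates[k] for k in STN_GATES)
    ca = state.ca
    i_l, i_na, i_k, i_t, i_ca, i_ahp = stn_currents(v, h, n, r, ca, params)
    dv = (-i_l - i_na - i_k - i_t - i_ca - i_ahp - i_syn
          + params.i_app) / params.cm
    h_inf, tau_h, n_inf, tau_n, r_inf, tau_r = _stn_rates(v)
    dca = params.eps * (-i_ca - i_t - params.k_ca * ca)
    return state.derivative(
        dv,
        {"h": params.phi_h * (h_inf - h) / tau_h,
         "n": params.phi_n * (n_inf - n) / tau_n,
         "r": params.phi_r * (r_inf - r) / tau_r},
        dca,
    )


def stn_steady_state(v: float, params: STNParams | None = None) -> CellState:
    h_inf, _, n_inf, _, r_inf, _ = _stn_rates(v)
    return CellState(v=float(v),
                     gates={"h": float(h_inf), "n": float(n_inf),
                            "r": float(r_inf)},
                     ca=0.05)


# ---------------------------------------------------------------------------
# GPe / GPi: pallidal cells (shared dynamics, different synaptic inputs)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPParams:
    cm: float = 1.0
    g_l: float = 0.1
    e_l: float = -65.0
    g_na: float = 120.0
    e_na: float = 55.0
    g_k: float = 30.0
    e_k: float = -80.0
    g_t: float = 0.5
    g_ca: float = 0.15
    e_ca: float = 120.0
    g_ahp: float = 30.0
    k1: float = 30.0
    k_ca: float = 15.0
    eps: float = 1e-4
    phi_h: float = 0.05
    phi_n: float = 0.05
    phi_r: float = 1.0
    i_app: float = 0.0


GP_GATES = ("h", "n", "r")


def _gp_rates(v):
    h_inf = _sig(v, -58.0, -12.0)
    n_inf = _sig(v, -50.0, 14.0)
    tau_h = 0.05 + 0.27 / (1.0 + np.exp((v + 40.0) / 12.0))
    tau_n = 0.05 + 0.27 / (1.0 + np.exp((v + 40.0) / 12.0))
    r_inf = _sig(v, -70.0, -2.0)
    tau_r = 30.0
    return h_inf, tau_h, n_inf, tau_n, r_inf, tau_r


def gp_currents(v, h, n, r, ca, p: GPParams):
    i_l = p.g_l * (v - p.e_l)
    i_na = p.g_na * _sig(v, -37.0, 10.0) ** 3 * h * (v - p.e_na)
    i_k = p.g_k * n ** 4 * (v - p.e_k)
    i_t = p.g_t * _sig(v, -57.0, 2.0) ** 3 * r * (v - p.e_ca)
    i_ca = p.g_ca * _sig(v, -35.0, 2.0) ** 2 * (v - p.e_ca)
    i_ahp = p.g_ahp * (v - p.e_k) * ca / (ca + p.k1)
    return i_l, i_na, i_k, i_t, i_ca, i_ahp


def _gp_rhs(state: CellState, i_syn_total: float, i_app: float,
            params: GPParams) -> CellState:
    state.check()
    v = state.v
    h, n, r = (state.gates[k] for k in GP_GATES)
    ca = state.ca
    i_l, i_na, i_k, i_t, i_ca, i_ahp = gp_currents(v, h, n, r, ca, params)
    dv = (-i_l - i_na - i_k - i_t - i_ca - i_ahp - i_syn_total
          + i_app) / params.cm
    h_inf, tau_h, n_inf, tau_n, r_inf, tau_r = _gp_rates(v)
    dca = params.eps * (-i_ca - i_t - params.k_ca * ca)
    return state.derivative(
        dv,
        {"h": params.phi_h * (h_inf - h) / tau_h,
         "n": params.phi_n * (n_inf - n) / tau_n,
         "r": params.phi_r * (r_inf - r) / tau_r},
        dca,
    )


def gpe_rhs(state: CellState, i_syn: Mapping[str, float],
            params: GPParams) -> CellState:
    """GPe cell.  ``i_syn`` holds 'd2' (striatal inhibition), 'gpe'
    (lateral inhibition) and 'stn' (excitation) currents separately,
    each outward-positive; the constant bias ``i_app`` stands in for
    unmodelled afferents.  With zero input and zero bias the cell is
    silent."""
    total = i_syn.get("d2", 0.0) + i_syn.get("gpe", 0.0) + i_syn.get("stn", 0.0)
    return _gp_rhs(state, total, params.i_app, params)


def gpi_rhs(state: CellState, i_syn: Mapping[str, float],
            params: GPParams) -> CellState:
    """GPi cell: inputs 'd1', 'gpe', 'gpi', 'stn'; bias enters with +."""
    total = (i_syn.get("d1", 0.0) + i_syn.get("gpe", 0.0)
             + i_syn.get("gpi", 0.0) + i_syn.get("stn", 0.0))
    return _gp_rhs(state, total, params.i_app, params)


def gp_steady_state(v: float, params: GPParams | None = None) -> CellState:
    h_inf, _, n_inf, _, r_inf, _ = _gp_rates(v)
    return CellState(v=float(v),
                     gates={"h": float(h_inf), "n": float(n_inf),
                            "r": float(r_inf)},
                     ca=0.01)


# ---------------------------------------------------------------------------
# PY: cortical regular-spiking pyramidal cell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PYParams:
    cm: float = 1.0
    g_leak: float = 0.0205
    e_leak: float = -70.3
    g_na: float = 56.0
    e_na: float = 50.0
    g_kd: float = 6.0
    e_k: float = -90.0
    g_m: float = 0.075
    tau_max: float = 608.0
    g_lca: float = 0.05
    e_ca: float = 120.0
    v_t: float = -56.2
    i_app: float = 0.0


PY_GATES = ("m", "h", "n", "p", "q", "r")


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x / y) < 1e-6, y * (1.0 - x / (2.0 * y)),
                   x / np.expm1(np.clip(x / y, -50.0, 50.0)))
    return out


def py_rates(v, p: PYParams | None = None):
    """Traub-style alpha/beta rates for m, h, n plus M-current p and
    high-threshold Ca q, r kinetics."""
    vt = (p.v_t if p is not None else -56.2)
    a_m = 0.32 * _vtrap(-(v - vt - 13.0), 4.0)
    b_m = 0.28 * _vtrap(v - vt - 40.0, 5.0)
    a_h = 0.128 * np.exp(np.clip(-(v - vt - 17.0) / 18.0, -50.0, 50.0))
    b_h = 4.0 / (1.0 + np.exp(-(v - vt - 40.0) / 5.0))
    a_n = 0.032 * _vtrap(-(v - vt - 15.0), 5.0)
    b_n = 0.5 * np.exp(np.clip(-(v - vt - 10.0) / 40.0, -50.0, 50.0))
    p_inf = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    tau_max = p.tau_max if p is not None else 608.0
    tau_p = tau_max / (3.3 * np.exp((v + 35.0) / 20.0)
                       + np.exp(-(v + 35.0) / 20.0))
    a_q = 0.055 * _vtrap(-27.0 - v, 3.8)
    b_q = 0.94 * np.exp(np.clip((-75.0 - v) / 17.0, -50.0, 50.0))
    a_r = 0.000457 * np.exp(np.clip((-13.0 - v) / 50.0, -50.0, 50.0))
    b_r = 0.0065 / (np.exp((-15.0 - v) / 28.0) + 1.0)
    return (a_m, b_m, a_h, b_h, a_n, b_n, p_inf, tau_p, a_q, b_q, a_r, b_r)


def py_currents(v, m, h, n, pg, q, r, p: PYParams):
    i_leak = p.g_leak * (v - p.e_leak)
    i_na = p.g_na * m ** 3 * h * (v - p.e_na)
    i_kd = p.g_kd * n ** 4 * (v - p.e_k)
    i_m = p.g_m * pg * (v - p.e_k)
    i_lca = p.g_lca * q ** 2 * r * (v - p.e_ca)
    return i_leak, i_na, i_kd, i_m, i_lca


def py_rhs(state: CellState, i_syn: float, i_ext: float,
           params: PYParams) -> CellState:
    """Pyramidal cell: leak, Na, Kd, M (adaptation), high-threshold Ca,
    thalamic feedback (in ``i_syn``) and external stimulus ``i_ext``."""
    state.check()
    v = state.v
    m, h, n, pg, q, r = (state.gates[k] for k in PY_GATES)
    i_leak, i_na, i_kd, i_m, i_lca = py_currents(v, m, h, n, pg, q, r, params)
    dv = (-i_leak - i_na - i_kd - i_m - i_lca - i_syn + i_ext
          + params.i_app) / params.cm
    (a_m, b_m, a_h, b_h, a_n, b_n,
     p_inf, tau_p, a_q, b_q, a_r, b_r) = py_rates(v, params)
    return state.derivative(
        dv,
        {"m": a_m * (1 - m) - b_m * m,
         "h": a_h * (1 - h) - b_h * h,
         "n": a_n * (1 - n) - b_n * n,
         "p": (p_inf - pg) / tau_p,
         "q": a_q * (1 - q) - b_q * q,
         "r": a_r * (1 - r) - b_r * r},
    )


def py_steady_state(v: float, params: PYParams | None = None) -> CellState:
    (a_m, b_m, a_h, b_h, a_n, b_n,
     p_inf, _, a_q, b_q, a_r, b_r) = py_rates(v, params)
    g = {"m": a_m / (a_m + b_m), "h": a_h / (a_h + b_h),
         "n": a_n / (a_n + b_n), "p": p_inf,
         "q": a_q / (a_q + b_q), "r": a_r / (a_r + b_r)}
    return CellState(v=float(v), gates={k: float(x) for k, x in g.items()})


# ---------------------------------------------------------------------------
# DA: dopaminergic cell (soma only)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DAParams:
    """Soma-only dopaminergic pacemaker.

    Carries fast Na, A-type, delayed-rectifier and SK potassium, T/N/L
    calcium, Na and Ca pump currents and three ionic leaks.  The three
    leaks jointly set an effective rest above spike threshold so the
    isolated cell pacemakes tonically at a low rate, with the
    calcium-gated SK current pacing the interspike interval -- the
    classic phenotype of nigral DA neurons.
    """

    cm: float = 1.0
    g_na: float = 37.5
    e_na: float = 55.0
    g_kdr: float = 45.0
    e_k: float = -80.0
    g_a: float = 1.0
    g_sk: float = 40.0
    k_sk: float = 15.0
    g_ca_t: float = 0.3
    g_ca_n: float = 0.3
    g_ca_l: float = 0.3
    v_half_ca_l: float = -39.0
    k_ca_l: float = 8.0
    e_ca: float = 140.0
    i_pump_na: float = 0.05
    i_pump_ca: float = 0.1
    k_pump: float = 15.0
    g_leak_na: float = 0.24
    g_leak_k: float = 1.2
    g_leak_ca: float = 0.02
    eps_ca: float = 5e-5
    k_ca: float = 22.5
    i_app: float = 0.0


DA_GATES = ("m", "h", "n", "a", "b", "ht")


def _da_rates(v):
    m_inf = _sig(v, -30.0, 15.0)
    tau_m = 0.1
    h_inf = _sig(v, -39.0, -3.1)
    tau_h = 1.0 + 500.0 / (1.0 + np.exp((v + 57.0) / 3.0))
    n_inf = _sig(v, -32.0, 8.0)
    tau_n = 1.0 + 100.0 / (1.0 + np.exp((v + 80.0) / 26.0))
    a_inf = _sig(v, -42.0, 13.0)
    tau_a = 1.0
    b_inf = _sig(v, -63.0, -8.0)
    tau_b = 50.0
    ht_inf = _sig(v, -70.0, -5.0)
    tau_ht = 25.0
    return (m_inf, tau_m, h_inf, tau_h, n_inf, tau_n,
            a_inf, tau_a, b_inf, tau_b, ht_inf, tau_ht)


def da_currents(v, m, h, n, a, b, ht, ca, p: DAParams):
    i_na = p.g_na * m ** 3 * h * (v - p.e_na)
    i_kdr = p.g_kdr * n ** 4 * (v - p.e_k)
    i_a = p.g_a * a * b * (v - p.e_k)
    i_sk = p.g_sk * (ca / (ca + p.k_sk)) * (v - p.e_k)
    i_ca_t = p.g_ca_t * _sig(v, -52.0, 6.0) ** 2 * ht * (v - p.e_ca)
    i_ca_n = p.g_ca_n * _sig(v, -25.0, 6.0) ** 2 * (v - p.e_ca)
    i_ca_l = p.g_ca_l * _sig(v, p.v_half_ca_l, p.k_ca_l) ** 2 * (v - p.e_ca)
    i_pump_na = p.i_pump_na
    i_pump_ca = p.i_pump_ca * ca / (ca + p.k_pump)
    i_leak_na = p.g_leak_na * (v - p.e_na)
    i_leak_k = p.g_leak_k * (v - p.e_k)
    i_leak_ca = p.g_leak_ca * (v - p.e_ca)
    return (i_na, i_kdr, i_a, i_sk, i_ca_t, i_ca_n, i_ca_l,
            i_pump_na, i_pump_ca, i_leak_na, i_leak_k, i_leak_ca)


def da_rhs(state: CellState, i_ext: float, params: DAParams) -> CellState:
    """Dopaminergic soma: twelve currents, tonic pacemaking by default."""
    state.check()
    v = state.v
    m, h, n, a, b, ht = (state.gates[k] for k in DA_GATES)
    ca = state.ca
    cur = da_currents(v, m, h, n, a, b, ht, ca, params)
    dv = (-sum(cur) + i_ext + params.i_app) / params.cm
    (m_inf, tau_m, h_inf, tau_h, n_inf, tau_n,
     a_inf, tau_a, b_inf, tau_b, ht_inf, tau_ht) = _da_rates(v)
    i_ca_tot = cur[4] + cur[5] + cur[6]
    dca = params.eps_ca * (-i_ca_tot - params.k_ca * ca)
    return state.derivative(
        dv,
        {"m": (m_inf - m) / tau_m, "h": (h_inf - h) / tau_h,
         "n": (n_inf - n) / tau_n, "a": (a_inf - a) / tau_a,
         "b": (b_inf - b) / tau_b, "ht": (ht_inf - ht) / tau_ht},
        dca,
    )


def da_steady_state(v: float, params: DAParams | None = None) -> CellState:
    (m_inf, _, h_inf, _, n_inf, _, a_inf, _, b_inf, _, ht_inf, _) = _da_rates(v)
    return CellState(
        v=float(v),
        gates={"m": float(m_inf), "h": float(h_inf), "n": float(n_inf),
               "a": float(a_inf), "b": float(b_inf), "ht": float(ht_inf)},
        ca=0.05,
    )
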