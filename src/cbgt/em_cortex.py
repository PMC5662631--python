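"""Cortical neuron under electromagnetic induction (memristive drive).

The pyramidal cell of :mod:`cbgt.cells` is augmented with a magnetic
flux variable ``phi`` and an AC electric field.  Every channel current
is evaluated at the shifted potential ``v + V_e`` with
``V_e = A_e sin(omega t)``; the field also contributes the capacitive
drive ``-A_e omega Cm cos(omega t)`` to the voltage balance, and the
flux feeds back through the memconductance
``rho(phi) = alpha + 3 beta phi^2`` as the current
``k rho(phi) (v + V_e)``.  The flux itself relaxes as
``phi' = k1 v - k2 phi``.

Time units: the membrane equations run in ms.  The field frequency
``omega`` is interpreted in rad/s, i.e. the trigonometric argument and
the flux equation evolve on a slow axis ``t_scale`` (= 1e-3) times the
integration time; this is the only reading under which the printed
drive amplitudes produce the catalogued discharge-mode ladder
(subthreshold oscillation -> single spiking -> multi-spike bursting as
A_e grows).  The EM analysis cell uses a larger leak conductance than
the in-network pyramidal cell (0.25 vs 0.0205 mS/cm^2), calibrated so
that ladder appears at the catalogued (A_e, omega) values.

Discharge-mode classification is heuristic, from spike times and ISI
statistics after a discarded transient: quiescent, SMPO (subthreshold
membrane potential oscillation), period-1 spiking, period-n bursting,
mixed-mode, chaotic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cells
from ._kernels import step_py_em

__all__ = [
    "EMParams",
    "EMState",
    "memconductance",
    "em_rhs",
    "run_em",
    "classify_mode",
    "spikes_per_burst_of",
    "sweep",
    "EM_CELL",
]

#: Cell parameters for standalone EM-mode analysis: pyramidal kinetics
#: with the field-coupling leak (see module docstring).
EM_CELL = replace(cells.PYParams(), g_leak=0.25)


@dataclass(frozen=True)
class EMParams:
    """Flux-coupling and AC-field parameters.

    k, k1, k2: interaction coefficients between membrane potential and
    flux; alpha, beta (> 0): memconductance constants; a_e: field
    amplitude; omega: field angular frequency (rad/s); i_app: constant
    forcing current (uA/cm^2); t_scale: slow-time factor applied to the
    trig argument and flux equation (1e-3 for omega in rad/s with the
    membrane in ms).
    """

    k: float = 0.001
    k1: float = 0.1
    k2: float = 1.0
    alpha: float = 0.4
    beta: float = 0.01
    a_e: float = 0.0
    omega: float = 6.27
    i_app: float = 0.0
    t_scale: float = 1e-3
    cell: cells.PYParams = field(default_factory=lambda: EM_CELL)

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


@dataclass
class EMState:
    """Membrane potential, the six pyramidal gates, and magnetic flux."""

    v: float
    gates: dict[str, float]
    phi: float = 0.0


def memconductance(phi: float, alpha: float, beta: float) -> float:
    """Flux-controlled memconductance rho(phi) = alpha + 3 beta phi^2."""
    return alpha + 3.0 * beta * np.asarray(phi, dtype=float) ** 2


def em_rhs(state: EMState, params: EMParams, t: float) -> EMState:
    """Time derivative of the electromagnetically driven cortical cell.

    With ``a_e = 0`` this reduces to the plain pyramidal dynamics plus
    the flux feedback; with ``k = 0`` as well, it is exactly
    :func:`cbgt.cells.py_rhs`.
    """
    p = params.cell
    ts = t * params.t_scale
    v_e = params.a_e * np.sin(params.omega * ts)
    i_ac = -params.a_e * params.omega * p.cm * np.cos(params.omega * ts)
    rho = memconductance(state.phi, params.alpha, params.beta)
    v_sh = state.v + v_e
    shifted = cells.CellState(v=v_sh, gates=dict(state.gates))
    base = cells.py_rhs(shifted, 0.0, 0.0, replace(p, i_app=0.0))
    dv = (base.v * p.cm + i_ac + params.i_app + p.i_app
          + params.k * rho * v_sh) / p.cm
    dphi = params.t_scale * (params.k1 * state.v - params.k2 * state.phi)
    out = EMState(v=dv, gates=base.gates, phi=dphi)
    return out


def run_em(params: EMParams, duration: float = 12000.0, dt: float = 0.025,
           v0: float = -70.3) -> np.ndarray:
    """Fixed-step trace of the EM cell (mV, one sample per step)."""
    p = params.cell
    s0 = cells.py_steady_state(v0, p)
    v = np.array([s0.v])
    phi = np.array([0.0])
    g = {k_: np.array([s0.gates[k_]]) for k_ in cells.PY_GATES}
    zero = np.zeros(1)
    nsteps = int(round(duration / dt))
    rec = np.empty(nsteps)
    for s in range(nsteps):
        step_py_em(v, g["m"], g["h"], g["n"], g["p"], g["q"], g["r"], phi,
                   zero, zero, zero, s * dt, dt,
                   p.cm, p.g_leak, p.e_leak, p.g_na, p.e_na, p.g_kd,
                   p.e_k, p.g_m, p.tau_max, p.g_lca, p.e_ca, p.v_t,
                   params.i_app + p.i_app, params.k, params.k1,
                   params.k2, params.alpha, params.beta, params.a_e,
                   params.omega, params.t_scale)
        rec[s] = v[0]
    return rec


def _detect_spikes(trace: np.ndarray, dt: float, threshold: float = -20.0,
                   refractory: float = 2.0) -> np.ndarray:
    up = np.where((trace[1:] >= threshold) & (trace[:-1] < threshold))[0]
    times = up * dt
    keep: list[float] = []
    last = -np.inf
    for t in times:
        if t - last >= refractory:
            keep.append(t)
            last = t
    return np.asarray(keep)


def _burst_sizes(spike_times: np.ndarray, gap: float) -> list[int]:
    if len(spike_times) == 0:
        return []
    groups = np.split(spike_times,
                      np.where(np.diff(spike_times) > gap)[0] + 1)
    return [len(g) for g in groups]


def classify_mode(trace: np.ndarray, dt: float,
                  transient: float = 2000.0,
                  smpo_p2p: float = 2.0,
                  burst_gap: float = 100.0) -> str:
    """Label a discharge mode from a voltage trace.

    Requires >= 10 s of trace after the discarded transient.  Returns
    one of 'quiescent', 'smpo', 'spiking_period1', 'bursting_period_n',
    'mixed_mode', 'chaotic'.
    """
    n_skip = int(round(transient / dt))
    kept = trace[n_skip:]
    if len(kept) * dt < 10000.0:
        raise ValueError("trace too short: need >= 10 s after transient")
    spikes = _detect_spikes(kept, dt)
    if len(spikes) < 2:
        p2p = float(kept.max() - kept.min())
        return "smpo" if p2p >= smpo_p2p else "quiescent"
    isis = np.diff(spikes)
    cv = isis.std() / isis.mean()
    if cv < 0.05 or isis.max() <= burst_gap:
        return "spiking_period1"
    sizes = _burst_sizes(spikes, burst_gap)
    if len(sizes) < 2:
        return "spiking_period1"
    inner = sizes[1:-1] if len(sizes) > 3 else sizes
    if len(set(inner)) == 1:
        return ("spiking_period1" if inner[0] == 1
                else "bursting_period_n")
    if len(set(inner)) == 2 and len(inner) >= 4:
        # alternating burst sizes -> mixed mode
        a, b = sorted(set(inner))
        pattern = [s for s in inner]
        alternating = all(pattern[i] != pattern[i + 1]
                          for i in range(len(pattern) - 1))
        if alternating:
            return "mixed_mode"
    # irregular: dispersion of the ISI return map
    if len(isis) >= 8:
        ret = np.abs(np.diff(isis))
        if np.median(ret) / isis.mean() > 0.05:
            return "chaotic"
    return "mixed_mode"


def spikes_per_burst_of(trace: np.ndarray, dt: float,
                        transient: float = 2000.0,
                        burst_gap: float = 100.0) -> float:
    """Mean spikes per burst after the transient (0 if silent)."""
    n_skip = int(round(transient / dt))
    spikes = _detect_spikes(trace[n_skip:], dt)
    sizes = _burst_sizes(spikes, burst_gap)
    return float(np.mean(sizes)) if sizes else 0.0


def sweep(param_grid, duration: float = 12000.0, dt: float = 0.025,
          transient: float = 2000.0) -> pd.DataFrame:
    """Classify the discharge mode on a grid of EMParams.

    ``param_grid`` is an iterable of :class:`EMParams`.  Returns a
    DataFrame with columns a_e, omega, i_app, mode, mfr, spikes_per_burst.
    """
    grid = list(param_grid)
    if not grid:
        raise ValueError("parameter grid is empty")
    rows = []
    for p in grid:
        tr = run_em(p, duration=duration, dt=dt)
        mode = classify_mode(tr, dt, transient=transient)
        n_skip = int(round(transient / dt))
        spikes = _detect_spikes(tr[n_skip:], dt)
        window_s = (len(tr) - n_skip) * dt / 1000.0
        rows.append(dict(a_e=p.a_e, omega=p.omega, i_app=p.i_app,
                         mode=mode, mfr=len(spikes) / window_s,
                         spikes_per_burst=spikes_per_burst_of(
                             tr, dt, transient=transient)))
    return pd.DataFrame(rows)
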