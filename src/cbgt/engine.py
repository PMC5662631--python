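"""Fixed-step network integration, stimuli, spike detection, recording.

The engine advances all cell, synapse and flux states on a common grid
(default dt = 0.025 ms).  Gating variables use exponential-Euler
updates; membrane potentials a conductance-linearized implicit update
(backward-Euler Hines solve over the MSN trees).  Synaptic events are
aligned to the step grid; per (edge-class, postsynaptic target) the
two-state synapse variables are aggregated, which is exact because the
kinetics are linear in the event train.

Runs are bit-reproducible for a fixed configuration and platform: the
only randomness is in network construction (seeded); integration is
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import cells, msn as msn_mod
from ._kernels import (step_th, step_stn, step_gp, step_py, step_da,
                       step_msn)
from .network import Network, EDGE_KIND
from .synapses import AMPA, GABA, NMDA, event_normalization

__all__ = [
    "SimulationSpec",
    "Recording",
    "EngineCellParams",
    "make_waveform",
    "detect_spikes",
    "integrate",
    "NumericalBlowupError",
    "SPIKE_THRESHOLD",
    "SPIKE_REFRACTORY",
]

SPIKE_THRESHOLD = -20.0  # mV, upward crossing
SPIKE_REFRACTORY = 2.0  # ms lockout

#: synapse-class kinetics: kind -> (tau_on, tau_off, E, g_max)
SYN_CLASSES: dict[str, tuple[float, float, float, float]] = {
    "AMPA": (AMPA.tau_on, AMPA.tau_off, 0.0, 0.15),
    "NMDA": (NMDA.tau_on, NMDA.tau_off, 0.0, 0.03),
    "GABA": (GABA.tau_on, GABA.tau_off, -80.0, 0.3),
    "DA_exc": (NMDA.tau_on, NMDA.tau_off, 0.0, 0.1),
    "DA_inh": (NMDA.tau_on, NMDA.tau_off, -80.0, 0.1),
}

#: conductance (mS/cm^2, on the site compartment) of one cortical or
#: dopaminergic contact on an MSN spine site
MSN_SITE_G = {"AMPA": 0.25, "NMDA": 0.02, "DA_exc": 0.08, "DA_inh": 0.07}


class NumericalBlowupError(RuntimeError):
    """|v| exceeded 200 mV during integration."""


@dataclass(frozen=True)
class EngineCellParams:
    """Per-population cell parameters with in-network bias currents."""

    th: cells.THParams = field(
        default_factory=lambda: cells.THParams(i_app=0.25))
    stn: cells.STNParams = field(default_factory=cells.STNParams)
    gpe: cells.GPParams = field(
        default_factory=lambda: cells.GPParams(i_app=1.2))
    gpi: cells.GPParams = field(
        default_factory=lambda: cells.GPParams(i_app=1.2))
    py: cells.PYParams = field(
        default_factory=lambda: cells.PYParams(i_app=1.2))
    da: cells.DAParams = field(default_factory=cells.DAParams)
    msn: msn_mod.MSNParams = field(default_factory=msn_mod.MSNParams)


@dataclass(frozen=True)
class SimulationSpec:
    """Duration (ms), step (ms), stimuli and probes for one run.

    ``stimuli``: list of (population name, waveform dict) pairs; the
    waveform dict is passed to :func:`make_waveform`.  ``record``:
    probes (population, cell index); 'msn' probes address ('d1'/'d2',
    cell index) somata.
    """

    duration: float = 2000.0
    dt: float = 0.025
    seed: int = 0
    stimuli: tuple = ()
    record: tuple = (("th", 0),)
    cell_params: EngineCellParams = field(default_factory=EngineCellParams)

    def __post_init__(self):
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("require dt > 0 and duration >= dt")


@dataclass
class Recording:
    """Probe traces (mV) and spike times (ms) from one run."""

    times: np.ndarray
    dt: float
    traces: dict
    spikes: dict

    def spike_times(self, pop: str, idx: int = 0) -> np.ndarray:
        return np.asarray(self.spikes.get((pop, idx), ()))

    def trace(self, pop: str, idx: int = 0) -> np.ndarray:
        return self.traces[(pop, idx)]

    def write_spikes(self, path) -> None:
        """Plain-text spike file: one line per spike (cell id, time ms)."""
        with open(path, "w") as fh:
            for (pop, idx), times in sorted(self.spikes.items()):
                for t in times:
                    fh.write(f"{pop}[{idx}] {t:.3f}\n")

    def to_hdf5(self, path) -> None:
        """Dump probe traces (and times) to an HDF5 file (needs h5py)."""
        import h5py
        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.attrs["dt"] = self.dt
            grp = fh.create_group("traces")
            for (pop, idx), tr in self.traces.items():
                grp.create_dataset(f"{pop}_{idx}", data=tr)


def make_waveform(kind: str, params: dict) -> Callable[[float], float]:
    """Stimulus waveform factory.

    kinds: 'constant' (value); 'sine' (amplitude, freq_hz or
    omega rad/ms, phase).  Sine is A*sin(omega*t), zero at t = 0.
    """
    if kind == "constant":
        c = float(params.get("value", 0.0))
        return lambda t: c
    if kind == "sine":
        a = float(params.get("amplitude", 0.0))
        if "omega" in params:
            om = float(params["omega"])
        else:
            om = 2.0 * math.pi * float(params.get("freq_hz", 1.0)) * 1e-3
        ph = float(params.get("phase", 0.0))
        return lambda t: a * math.sin(om * t + ph)
    raise ValueError(f"unknown waveform kind: {kind!r}")


def detect_spikes(trace: np.ndarray, dt: float,
                  threshold: float = SPIKE_THRESHOLD,
                  refractory: float = SPIKE_REFRACTORY) -> np.ndarray:
    """Upward threshold crossings separated by >= refractory (ms)."""
    trace = np.asarray(trace)
    up = np.where((trace[1:] >= threshold) & (trace[:-1] < threshold))[0]
    out: list[float] = []
    last = -np.inf
    for i in up:
        t = (i + 1) * dt
        if t - last >= refractory:
            out.append(t)
            last = t
    return np.asarray(out)


# ---------------------------------------------------------------------------
# internal simulation state containers
# ---------------------------------------------------------------------------

class _SynGroup:
    """Aggregated two-state synapses of one edge class."""

    def __init__(self, edge_class: str, n_pre: int, n_post: int,
                 edges, dt: float, g_scale: float = 1.0):
        kind = EDGE_KIND[edge_class]
        tau_on, tau_off, e_syn, g_max = SYN_CLASSES[kind]
        self.edge_class = edge_class
        self.e_syn = e_syn
        self.g_max = g_max * g_scale
        self.m = np.zeros(n_post)
        self.h = np.zeros(n_post)
        self.dec_on = math.exp(-dt / tau_on)
        self.dec_off = math.exp(-dt / tau_off)
        norm = event_normalization(tau_on, tau_off)
        self.w = np.zeros((n_post, n_pre))
        for e in edges:
            self.w[e.post, e.pre] += e.weight * norm

    def conductance(self):
        return self.g_max * (self.h - self.m)

    def step(self, pre_spikes: np.ndarray):
        self.m *= self.dec_on
        self.h *= self.dec_off
        if pre_spikes.any():
            inc = self.w @ pre_spikes
            self.m += inc
            self.h += inc


class _SitesGroup:
    """Synapse states on MSN spine sites (one value per active site)."""

    def __init__(self, kind: str, n_sites: int, weight: float, dt: float):
        tau_on, tau_off, e_syn, _ = SYN_CLASSES[kind]
        self.e_syn = e_syn
        self.g_max = MSN_SITE_G[kind]
        self.m = np.zeros(n_sites)
        self.h = np.zeros(n_sites)
        self.dec_on = math.exp(-dt / tau_on)
        self.dec_off = math.exp(-dt / tau_off)
        self.amp = weight * event_normalization(tau_on, tau_off)

    def conductance(self):
        return self.g_max * (self.h - self.m)

    def step(self, n_events: int):
        self.m *= self.dec_on
        self.h *= self.dec_off
        if n_events:
            self.m += self.amp * n_events
            self.h += self.amp * n_events


class _MSNCell:
    """Kernel arrays and site synapses for one multi-compartment MSN."""

    def __init__(self, morph, params, weights, dt: float):
        self.morph = morph
        self.params = params
        self.ka = msn_mod.pack_kernel_arrays(morph, params, dt)
        state = msn_mod.msn_steady_state(morph, -85.0, params)
        self.v, self.act, self.inact, self.ca = msn_mod.pack_state(
            morph, state, params)
        n = len(self.v)
        self.n = n
        self.g_syn = np.zeros(n)
        self.ge_syn = np.zeros(n)
        self.i_ext = np.zeros(n)
        self.scratch = (np.zeros(n), np.zeros(n), np.zeros(n))
        pos = {int(cid): k for k, cid in enumerate(self.ka["ids"])}
        rt = morph.receptor_type.lower()
        self.glut_idx = np.array([pos[s] for s in morph.glut_synapse_sites],
                                 dtype=int)
        active_da = [s for s in morph.da_synapse_sites
                     if s not in set(morph.lost_da_sites)]
        self.da_idx = np.array([pos[s] for s in active_da], dtype=int)
        w_ampa = weights[f"py_{rt}_ampa"]
        w_nmda = weights[f"py_{rt}_nmda"]
        w_da = weights[f"da_{rt}"]
        self.ampa = _SitesGroup("AMPA", len(self.glut_idx), w_ampa, dt)
        self.nmda = _SitesGroup("NMDA", len(self.glut_idx), w_nmda, dt)
        da_kind = "DA_exc" if rt == "d1" else "DA_inh"
        self.da = _SitesGroup(da_kind, len(self.da_idx), w_da, dt)


def integrate(network: Network, spec: SimulationSpec) -> Recording:
    """Run the full network for ``spec.duration`` ms.

    Returns probe voltage traces and per-cell spike times.  Raises
    :class:`NumericalBlowupError` naming the population if any membrane
    potential leaves [-200, 200] mV.
    """
    cfg = network.config
    dt = spec.dt
    cp = spec.cell_params
    nsteps = int(round(spec.duration / dt))
    weights = cfg.weights

    # --- population states -------------------------------------------------
    pops: dict[str, dict] = {}

    def init_pop(name, n, steady, gates, v0, ca0=0.0):
        st = steady(v0)
        d = {"size": n, "v": np.full(n, st.v),
             "ca": np.full(n, ca0 if st.ca == 0 else st.ca)}
        for g in gates:
            d[g] = np.full(n, st.gates[g])
        d["g_syn"] = np.zeros(n)
        d["ge_syn"] = np.zeros(n)
        d["i_ext"] = np.zeros(n)
        d["v_prev"] = d["v"].copy()
        d["refr"] = np.zeros(n)
        d["spiked"] = np.zeros(n)
        pops[name] = d
        return d

    init_pop("th", cfg.n_th, cells.th_steady_state, cells.TH_GATES, -66.0)
    init_pop("stn", cfg.n_stn, cells.stn_steady_state, cells.STN_GATES, -62.0)
    init_pop("gpe", cfg.n_gpe, cells.gp_steady_state, cells.GP_GATES, -65.0)
    init_pop("gpi", cfg.n_gpi, cells.gp_steady_state, cells.GP_GATES, -65.0)
    init_pop("py", cfg.n_py, cells.py_steady_state, cells.PY_GATES, -70.3)
    init_pop("da", cfg.n_da, cells.da_steady_state, cells.DA_GATES, -60.0)

    # slight deterministic desynchronization of initial potentials
    rng = np.random.default_rng(cfg.seed + 9001)
    for name in ("th", "stn", "gpe", "gpi", "py", "da"):
        pops[name]["v"] += rng.uniform(-3.0, 3.0, size=pops[name]["size"])

    d1_cells = [_MSNCell(m, cp.msn, weights, dt) for m in network.d1_cells]
    d2_cells = [_MSNCell(m, cp.msn, weights, dt) for m in network.d2_cells]
    msn_cells = {"d1": d1_cells, "d2": d2_cells}
    for mc_list in msn_cells.values():
        for j, mc in enumerate(mc_list):
            mc.v += rng.uniform(-2.0, 2.0)
            mc.refr = 0.0
            mc.v_prev = mc.v[0]
            mc.spiked = 0.0

    # --- synapse groups between point populations --------------------------
    by_class: dict[str, list] = {}
    for e in network.wiring.edges:
        by_class.setdefault(e.edge_class, []).append(e)
    groups: dict[str, _SynGroup] = {}
    active_da = set(network.active_da_cells())
    for cls, edges in by_class.items():
        pre_pop, post_pop = edges[0].pre_pop, edges[0].post_pop
        if post_pop in ("d1", "d2"):
            continue  # handled at MSN site level
        n_pre = cfg.size(pre_pop)
        n_post = cfg.size(post_pop)
        groups[cls] = _SynGroup(cls, n_pre, n_post, edges, dt)
        groups[cls].pre_pop = pre_pop
        groups[cls].post_pop = post_pop

    # --- stimuli ------------------------------------------------------------
    stim_fns: dict[str, list] = {}
    for pop_name, wf in spec.stimuli:
        stim_fns.setdefault(pop_name, []).append(
            make_waveform(wf["kind"], wf))

    # --- recording ----------------------------------------------------------
    probes = list(spec.record)
    traces = {p: np.empty(nsteps + 1) for p in probes}
    spikes: dict = {}
    for name in ("th", "stn", "gpe", "gpi", "py", "da"):
        for i in range(pops[name]["size"]):
            spikes[(name, i)] = []
    for rt, mc_list in msn_cells.items():
        for i in range(len(mc_list)):
            spikes[(rt, i)] = []

    def probe_value(p):
        pop_name, idx = p
        if pop_name in ("d1", "d2"):
            return msn_cells[pop_name][idx].v[0]
        return pops[pop_name]["v"][idx]

    for p in probes:
        traces[p][0] = probe_value(p)

    n_da_active = len(active_da)

    def detect(pop):
        d = pops[pop]
        sp = (d["refr"] <= 0) & (d["v"] >= SPIKE_THRESHOLD) \
            & (d["v_prev"] < SPIKE_THRESHOLD)
        d["spiked"] = sp.astype(float)
        d["refr"] -= dt
        d["refr"][sp] = SPIKE_REFRACTORY
        d["v_prev"][:] = d["v"]
        return sp

    check_every = int(round(50.0 / dt))  # blow-up check cadence

    for step in range(1, nsteps + 1):
        t = (step - 1) * dt

        # synaptic conductances onto point populations
        for name in ("th", "stn", "gpe", "gpi", "py", "da"):
            d = pops[name]
            d["g_syn"][:] = 0.0
            d["ge_syn"][:] = 0.0
            d["i_ext"][:] = 0.0
            for fn in stim_fns.get(name, ()):
                d["i_ext"] += fn(t)
        for g in groups.values():
            cond = g.conductance()
            d = pops[g.post_pop]
            d["g_syn"] += cond
            d["ge_syn"] += cond * g.e_syn

        # MSN site conductances
        for rt, mc_list in msn_cells.items():
            for mc in mc_list:
                mc.g_syn[:] = 0.0
                mc.ge_syn[:] = 0.0
                for grp, idx in ((mc.ampa, mc.glut_idx),
                                 (mc.nmda, mc.glut_idx),
                                 (mc.da, mc.da_idx)):
                    if len(idx) == 0:
                        continue
                    cond = grp.conductance()
                    np.add.at(mc.g_syn, idx, cond)
                    np.add.at(mc.ge_syn, idx, cond * grp.e_syn)
                for fn in stim_fns.get(rt, ()):
                    mc.i_ext[0] = fn(t)

        # advance membranes
        p = cp.th
        d = pops["th"]
        step_th(d["v"], d["h"], d["r"], d["g_syn"], d["ge_syn"], d["i_ext"],
                dt, p.cm, p.g_l, p.e_l, p.g_na, p.e_na, p.g_k, p.e_k,
                p.g_t, p.e_t, p.i_app)
        p = cp.stn
        d = pops["stn"]
        step_stn(d["v"], d["h"], d["n"], d["r"], d["ca"], d["g_syn"],
                 d["ge_syn"], d["i_ext"], dt, p.cm, p.g_l, p.e_l, p.g_na,
                 p.e_na, p.g_k, p.e_k, p.g_t, p.g_ca, p.e_ca, p.g_ahp,
                 p.k1, p.k_ca, p.eps, p.phi_h, p.phi_n, p.phi_r, p.i_app)
        for gp_name, gp_par in (("gpe", cp.gpe), ("gpi", cp.gpi)):
            p = gp_par
            d = pops[gp_name]
            step_gp(d["v"], d["h"], d["n"], d["r"], d["ca"], d["g_syn"],
                    d["ge_syn"], d["i_ext"], dt, p.cm, p.g_l, p.e_l,
                    p.g_na, p.e_na, p.g_k, p.e_k, p.g_t, p.g_ca, p.e_ca,
                    p.g_ahp, p.k1, p.k_ca, p.eps, p.phi_h, p.phi_n,
                    p.phi_r, p.i_app)
        p = cp.py
        d = pops["py"]
        step_py(d["v"], d["m"], d["h"], d["n"], d["p"], d["q"], d["r"],
                d["g_syn"], d["ge_syn"], d["i_ext"], dt, p.cm, p.g_leak,
                p.e_leak, p.g_na, p.e_na, p.g_kd, p.e_k, p.g_m, p.tau_max,
                p.g_lca, p.e_ca, p.v_t, p.i_app)
        p = cp.da
        d = pops["da"]
        step_da(d["v"], d["m"], d["h"], d["n"], d["a"], d["b"], d["ht"],
                d["ca"], d["g_syn"], d["ge_syn"], d["i_ext"], dt, p.cm,
                p.g_na, p.e_na, p.g_kdr, p.e_k, p.g_a, p.g_sk, p.k_sk,
                p.g_ca_t, p.g_ca_n, p.g_ca_l, p.v_half_ca_l, p.k_ca_l,
                p.e_ca, p.i_pump_na, p.i_pump_ca, p.k_pump, p.g_leak_na,
                p.g_leak_k, p.g_leak_ca, p.eps_ca, p.k_ca, p.i_app)
        mp = cp.msn
        for rt, mc_list in msn_cells.items():
            for mc in mc_list:
                ka = mc.ka
                step_msn(mc.v, mc.act, mc.inact, mc.ca, ka["parent"],
                         ka["g_ax_den_self"], ka["g_ax_den_parent"],
                         ka["g_chan"], ka["e_chan"], ka["vh_act"],
                         ka["k_act"], ka["n_act"], ka["dec_act"],
                         ka["inact_of"], ka["vh_in"], ka["k_in"],
                         ka["dec_in"], ka["frac_in"], ka["gate_kind"],
                         ka["kd_ca"], ka["feeds_ca"], mc.g_syn, mc.ge_syn,
                         mc.i_ext, dt, mp.cm, mp.g_leak, mp.e_leak,
                         mp.e_k, mp.alpha_ca, mp.tau_ca, *mc.scratch)

        # spike detection
        pre_spikes: dict[str, np.ndarray] = {}
        for name in ("th", "stn", "gpe", "gpi", "py", "da"):
            sp = detect(name)
            pre_spikes[name] = pops[name]["spiked"]
            if sp.any():
                tt = t + dt
                for i in np.where(sp)[0]:
                    spikes[(name, int(i))].append(tt)
        for rt, mc_list in msn_cells.items():
            vec = np.zeros(len(mc_list))
            for j, mc in enumerate(mc_list):
                mc.refr -= dt
                if (mc.refr <= 0 and mc.v[0] >= SPIKE_THRESHOLD
                        and mc.v_prev < SPIKE_THRESHOLD):
                    vec[j] = 1.0
                    mc.refr = SPIKE_REFRACTORY
                    spikes[(rt, j)].append(t + dt)
                mc.v_prev = mc.v[0]
            pre_spikes[rt] = vec

        # DA spikes from surviving cells only
        da_sp = pre_spikes["da"].copy()
        for i in network.removed_da:
            da_sp[i] = 0.0
        n_da_events = int(da_sp.sum())
        n_py_events = int(pre_spikes["py"].sum())

        # synapse updates
        for g in groups.values():
            src = pre_spikes[g.pre_pop]
            if g.pre_pop == "da":
                src = da_sp
            g.step(src)
        for rt, mc_list in msn_cells.items():
            for mc in mc_list:
                mc.ampa.step(n_py_events)
                mc.nmda.step(n_py_events)
                mc.da.step(n_da_events)

        # record
        for pr in probes:
            traces[pr][step] = probe_value(pr)

        if step % check_every == 0:
            for name in ("th", "stn", "gpe", "gpi", "py", "da"):
                if np.any(np.abs(pops[name]["v"]) > 200.0):
                    raise NumericalBlowupError(
                        f"membrane potential blow-up in population "
                        f"'{name}' at t = {t:.2f} ms")
            for rt, mc_list in msn_cells.items():
                for j, mc in enumerate(mc_list):
                    if np.any(np.abs(mc.v) > 200.0):
                        raise NumericalBlowupError(
                            f"membrane potential blow-up in {rt}[{j}] "
                            f"at t = {t:.2f} ms")

    times = np.arange(nsteps + 1) * dt
    spikes = {k: np.asarray(v) for k, v in spikes.items()}
    return Recording(times=times, dt=dt, traces=traces, spikes=spikes)


def run_single_cell(cell_type: str, duration: float, dt: float = 0.025,
                    params=None, i_ext=None, v0: float | None = None,
                    record: bool = True):
    """Integrate one isolated cell with the fixed-step kernels.

    ``cell_type``: 'th' | 'stn' | 'gpe' | 'gpi' | 'py' | 'da'.
    ``i_ext``: constant (uA/cm^2) or callable of t (ms).  Returns
    (times, v_trace, spike_times).  The same kernels drive the full
    network, so this is the engine's reference path for single-cell
    checks.
    """
    cp = EngineCellParams()
    defaults = {"th": (cp.th, cells.th_steady_state, cells.TH_GATES, -66.0),
                "stn": (cp.stn, cells.stn_steady_state, cells.STN_GATES,
                        -62.0),
                "gpe": (cp.gpe, cells.gp_steady_state, cells.GP_GATES,
                        -65.0),
                "gpi": (cp.gpi, cells.gp_steady_state, cells.GP_GATES,
                        -65.0),
                "py": (cp.py, cells.py_steady_state, cells.PY_GATES, -70.3),
                "da": (cp.da, cells.da_steady_state, cells.DA_GATES, -60.0)}
    if cell_type not in defaults:
        raise ValueError(f"unknown cell type {cell_type!r}")
    default_p, steady, gates, v_init = defaults[cell_type]
    p = params if params is not None else default_p
    v0 = v_init if v0 is None else v0
    st = steady(v0, p)
    v = np.array([st.v])
    arrs = {g: np.array([st.gates[g]]) for g in gates}
    ca = np.array([st.ca])
    g_syn = np.zeros(1)
    ge_syn = np.zeros(1)
    ext = np.zeros(1)
    if i_ext is None:
        fn = lambda t: 0.0
    elif callable(i_ext):
        fn = i_ext
    else:
        fn = lambda t, c=float(i_ext): c
    nsteps = int(round(duration / dt))
    trace = np.empty(nsteps + 1) if record else None
    if record:
        trace[0] = v[0]
    for s in range(nsteps):
        t = s * dt
        ext[0] = fn(t)
        if cell_type == "th":
            step_th(v, arrs["h"], arrs["r"], g_syn, ge_syn, ext, dt,
                    p.cm, p.g_l, p.e_l, p.g_na, p.e_na, p.g_k, p.e_k,
                    p.g_t, p.e_t, p.i_app)
        elif cell_type == "stn":
            step_stn(v, arrs["h"], arrs["n"], arrs["r"], ca, g_syn,
                     ge_syn, ext, dt, p.cm, p.g_l, p.e_l, p.g_na, p.e_na,
                     p.g_k, p.e_k, p.g_t, p.g_ca, p.e_ca, p.g_ahp, p.k1,
                     p.k_ca, p.eps, p.phi_h, p.phi_n, p.phi_r, p.i_app)
        elif cell_type in ("gpe", "gpi"):
            step_gp(v, arrs["h"], arrs["n"], arrs["r"], ca, g_syn,
                    ge_syn, ext, dt, p.cm, p.g_l, p.e_l, p.g_na, p.e_na,
                    p.g_k, p.e_k, p.g_t, p.g_ca, p.e_ca, p.g_ahp, p.k1,
                    p.k_ca, p.eps, p.phi_h, p.phi_n, p.phi_r, p.i_app)
        elif cell_type == "py":
            step_py(v, arrs["m"], arrs["h"], arrs["n"], arrs["p"],
                    arrs["q"], arrs["r"], g_syn, ge_syn, ext, dt, p.cm,
                    p.g_leak, p.e_leak, p.g_na, p.e_na, p.g_kd, p.e_k,
                    p.g_m, p.tau_max, p.g_lca, p.e_ca, p.v_t, p.i_app)
        else:
            step_da(v, arrs["m"], arrs["h"], arrs["n"], arrs["a"],
                    arrs["b"], arrs["ht"], ca, g_syn, ge_syn, ext, dt,
                    p.cm, p.g_na, p.e_na, p.g_kdr, p.e_k, p.g_a, p.g_sk,
                    p.k_sk, p.g_ca_t, p.g_ca_n, p.g_ca_l, p.v_half_ca_l,
                    p.k_ca_l, p.e_ca, p.i_pump_na, p.i_pump_ca, p.k_pump,
                    p.g_leak_na, p.g_leak_k, p.g_leak_ca, p.eps_ca,
                    p.k_ca, p.i_app)
        if record:
            trace[s + 1] = v[0]
    times = np.arange(nsteps + 1) * dt
    spikes = detect_spikes(trace, dt) if record else np.array([])
    return times, trace, spikes


def run_msn_cell(morph, i_soma, duration: float, dt: float = 0.025,
                 params=None, v0: float = -85.0):
    """Integrate one isolated MSN under somatic current injection.

    ``i_soma``: constant current density (uA/cm^2 of somatic membrane)
    or callable of t.  Returns (times, soma trace, spike times).
    """
    p = params if params is not None else msn_mod.MSNParams()
    ka = msn_mod.pack_kernel_arrays(morph, p, dt)
    state = msn_mod.msn_steady_state(morph, v0, p)
    v, act, inact, ca = msn_mod.pack_state(morph, state, p)
    n = len(v)
    g_syn = np.zeros(n)
    ge_syn = np.zeros(n)
    i_ext = np.zeros(n)
    scratch = (np.zeros(n), np.zeros(n), np.zeros(n))
    fn = i_soma if callable(i_soma) else (lambda t, c=float(i_soma): c)
    nsteps = int(round(duration / dt))
    trace = np.empty(nsteps + 1)
    trace[0] = v[0]
    for s in range(nsteps):
        i_ext[0] = fn(s * dt)
        step_msn(v, act, inact, ca, ka["parent"], ka["g_ax_den_self"],
                 ka["g_ax_den_parent"], ka["g_chan"], ka["e_chan"],
                 ka["vh_act"], ka["k_act"], ka["n_act"], ka["dec_act"],
                 ka["inact_of"], ka["vh_in"], ka["k_in"], ka["dec_in"],
                 ka["frac_in"], ka["gate_kind"], ka["kd_ca"],
                 ka["feeds_ca"], g_syn, ge_syn, i_ext, dt, p.cm,
                 p.g_leak, p.e_leak, p.e_k, p.alpha_ca, p.tau_ca,
                 *scratch)
        trace[s + 1] = v[0]
    times = np.arange(nsteps + 1) * dt
    return times, trace, detect_spikes(trace, dt)
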