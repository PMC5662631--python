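"""File formats and fixtures: SWC morphology, YAML configs, synthetic traces.

SWC export lays the stylized MSN out deterministically in 3D (trunks
radiate from the soma in the xy-plane) and encodes the dendrite level
in the SWC type column (1 soma, 5 primary, 6 secondary, 7
subordinate).  Re-import preserves compartment count, parentage,
diameters and level labels exactly; the finer 58-section partition is
not representable in SWC, so sections are reconstructed as maximal
unbranched same-level runs.

The synthetic trace generator produces voltage-like traces with
Gaussian response bumps of prescribed relative heights over a baseline
-- the ground-truth fixture for testing peak classification and the
error index without running the network.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import msn as msn_mod
from .engine import SimulationSpec
from .network import LesionSpec, NetworkConfig

__all__ = [
    "SyntheticTraceSpec",
    "generate_trace",
    "write_swc",
    "read_swc",
    "SWCParseError",
    "load_config",
    "save_config",
]

_LEVEL_TO_SWC = {msn_mod.Level.SOMA: 1, msn_mod.Level.PRIMARY: 5,
                 msn_mod.Level.SECONDARY: 6, msn_mod.Level.SUBORDINATE: 7}
_SWC_TO_LEVEL = {v: k for k, v in _LEVEL_TO_SWC.items()}


# ---------------------------------------------------------------------------
# synthetic traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Peaks of given relative heights at given times over a baseline.

    Heights are relative to a reference maximum of 1.0; peak times in
    ms, strictly increasing.  ``n_windows`` fixes the trace duration to
    ``n_windows * window`` ms so that lost-peak counting is exact.
    """

    peak_heights: tuple = ()
    peak_times: tuple = ()
    baseline: float = 0.0
    noise_sd: float = 0.0
    dt: float = 0.1
    window: float = 100.0
    n_windows: int | None = None
    peak_width: float = 4.0

    def __post_init__(self):
        if len(self.peak_heights) != len(self.peak_times):
            raise ValueError("heights and times must align")
        if any(h < 0 for h in self.peak_heights):
            raise ValueError("peak heights must be >= 0")
        t = np.asarray(self.peak_times)
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("peak times must be strictly increasing")


def generate_trace(spec: SyntheticTraceSpec, seed: int = 0) -> np.ndarray:
    """Deterministic synthetic voltage trace from a spec."""
    n_win = spec.n_windows
    if n_win is None:
        last = (max(spec.peak_times) if spec.peak_times else 0.0)
        n_win = max(int(np.ceil((last + spec.dt) / spec.window)), 1)
    t = np.arange(0.0, n_win * spec.window, spec.dt)
    v = np.full(t.shape, float(spec.baseline))
    for height, tc in zip(spec.peak_heights, spec.peak_times):
        v += height * np.exp(-0.5 * ((t - tc) / spec.peak_width) ** 2)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=t.shape)
    return v


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

class SWCParseError(ValueError):
    """Malformed SWC input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _layout(morph: msn_mod.MSNMorphology) -> dict[int, np.ndarray]:
    """Deterministic 3D coordinates: trunks radiate in the xy-plane."""
    by_id = {c.id: c for c in morph.compartments}
    children: dict[int | None, list[int]] = {}
    for c in morph.compartments:
        children.setdefault(c.parent, []).append(c.id)
    coords = {morph.soma_id: np.zeros(3)}
    trunks = sorted(children.get(morph.soma_id, []))
    for k, root in enumerate(trunks):
        theta = 2.0 * math.pi * k / max(len(trunks), 1)
        direction = np.array([math.cos(theta), math.sin(theta), 0.0])
        stack = [(root, direction, 1)]
        while stack:
            cid, d, depth = stack.pop()
            c = by_id[cid]
            coords[cid] = coords[c.parent] + d * c.length
            kids = sorted(children.get(cid, []))
            for j, kid in enumerate(kids):
                if len(kids) == 1:
                    nd = d
                else:
                    # split branches by +/- 20 degrees around the z axis
                    ang = math.radians(20.0) * (1 if j % 2 == 0 else -1)
                    ca_, sa = math.cos(ang), math.sin(ang)
                    nd = np.array([d[0] * ca_ - d[1] * sa,
                                   d[0] * sa + d[1] * ca_, d[2]])
                stack.append((kid, nd, depth + 1))
    return coords


def write_swc(morph: msn_mod.MSNMorphology, path) -> None:
    """Write the morphology as SWC (one sample line per compartment)."""
    coords = _layout(morph)
    lines = ["# cbgt medium spiny neuron morphology",
             "# columns: id type x y z radius parent",
             "# type: 1 soma, 5 primary, 6 secondary, 7 subordinate"]
    for c in sorted(morph.compartments, key=lambda c: c.id):
        x, y, z = coords[c.id]
        parent = -1 if c.parent is None else c.parent + 1
        lines.append(
            f"{c.id + 1} {_LEVEL_TO_SWC[c.level]} "
            f"{x:.3f} {y:.3f} {z:.3f} {c.diameter / 2:.4f} {parent}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path) -> msn_mod.MSNMorphology:
    """Parse an SWC file back into a morphology.

    Raises :class:`SWCParseError` (with line number) on malformed rows,
    unknown types, or orphan nodes.  Sections are rebuilt as maximal
    unbranched same-level runs.
    """
    text = Path(path).read_text() if not isinstance(path, io.StringIO) \
        else path.getvalue()
    rows: dict[int, tuple] = {}
    order: list[int] = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCParseError("expected 7 columns", ln)
        try:
            sid = int(parts[0])
            stype = int(parts[1])
            xyz = tuple(float(p) for p in parts[2:5])
            radius = float(parts[5])
            parent = int(parts[6])
        except ValueError as exc:
            raise SWCParseError(str(exc), ln) from None
        if stype not in _SWC_TO_LEVEL:
            raise SWCParseError(f"unknown type {stype}", ln)
        if sid in rows:
            raise SWCParseError(f"duplicate id {sid}", ln)
        rows[sid] = (stype, xyz, radius, parent, ln)
        order.append(sid)

    comps: list[msn_mod.Compartment] = []
    for sid in order:
        stype, xyz, radius, parent, ln = rows[sid]
        if parent != -1 and parent not in rows:
            raise SWCParseError(f"orphan node {sid}: parent {parent} "
                                "not defined", ln)
        level = _SWC_TO_LEVEL[stype]
        if parent == -1:
            length = 2.0 * radius
        else:
            pxyz = np.asarray(rows[parent][1])
            length = float(np.linalg.norm(np.asarray(xyz) - pxyz))
        comps.append(msn_mod.Compartment(
            id=sid - 1, parent=None if parent == -1 else parent - 1,
            level=level, section=-1, length=length, diameter=2.0 * radius))

    # rebuild sections as unbranched same-level runs
    children: dict[int | None, list[int]] = {}
    by_id = {c.id: c for c in comps}
    for c in comps:
        children.setdefault(c.parent, []).append(c.id)
    sections: dict[int, msn_mod.Level] = {}
    section_parent: dict[int, int] = {}
    next_sec = 0
    for c in comps:
        if c.level is msn_mod.Level.SOMA:
            continue
        par = by_id[c.parent] if c.parent is not None else None
        new_run = (par is None or par.level is not c.level
                   or len(children.get(par.id, [])) > 1)
        if new_run:
            sec = next_sec
            next_sec += 1
            sections[sec] = c.level
            section_parent[sec] = par.section if par is not None else -1
        else:
            sec = par.section
        c.section = sec
    for c in comps:
        if c.parent is not None:
            c.coupling_conductance_to_parent = msn_mod._axial_g(
                c, by_id[c.parent])

    subs = [c.id for c in comps if c.level is msn_mod.Level.SUBORDINATE]
    m = msn_mod.MSNMorphology(
        receptor_type="D1", compartments=comps, sections=sections,
        section_parent=section_parent, glut_synapse_sites=list(subs),
        da_synapse_sites=list(subs))
    if not m.is_tree():
        raise SWCParseError("compartment graph is not a tree", 0)
    return m


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_NETWORK_KEYS = {"n_py", "n_d1", "n_d2", "n_da", "n_stn", "n_gpe",
                 "n_gpi", "n_th", "weights", "seed",
                 "dopamine_depletion", "lesion"}
_LESION_KEYS = {"ns", "nd", "spine_order"}
_SIM_KEYS = {"duration", "dt", "seed", "stimuli", "record"}


def load_config(path) -> tuple[NetworkConfig, SimulationSpec]:
    """Load and validate a YAML run configuration.

    Two top-level documents sections: ``network`` and ``simulation``;
    unknown keys are rejected with the offending field named; omitted
    keys take the documented defaults (dt = 0.025 ms etc.).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - {"network", "simulation"}
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    net_raw = dict(raw.get("network") or {})
    sim_raw = dict(raw.get("simulation") or {})
    bad = set(net_raw) - _NETWORK_KEYS
    if bad:
        raise ValueError(f"unknown network keys: {sorted(bad)}")
    bad = set(sim_raw) - _SIM_KEYS
    if bad:
        raise ValueError(f"unknown simulation keys: {sorted(bad)}")
    lesion_raw = dict(net_raw.pop("lesion", {}) or {})
    bad = set(lesion_raw) - _LESION_KEYS
    if bad:
        raise ValueError(f"unknown lesion keys: {sorted(bad)}")
    net_raw["lesion"] = LesionSpec(**lesion_raw)
    if "stimuli" in sim_raw:
        sim_raw["stimuli"] = tuple(
            (s["population"], {k: v for k, v in s.items()
                               if k != "population"})
            for s in sim_raw["stimuli"])
    if "record" in sim_raw:
        sim_raw["record"] = tuple((p["population"], int(p.get("index", 0)))
                                  for p in sim_raw["record"])
    cfg = NetworkConfig(**net_raw)
    spec = SimulationSpec(**sim_raw)
    return cfg, spec


def save_config(cfg: NetworkConfig, spec: SimulationSpec, path) -> None:
    """Write a configuration back to YAML (stable key order)."""
    doc = {
        "network": {
            "n_py": cfg.n_py, "n_d1": cfg.n_d1, "n_d2": cfg.n_d2,
            "n_da": cfg.n_da, "n_stn": cfg.n_stn, "n_gpe": cfg.n_gpe,
            "n_gpi": cfg.n_gpi, "n_th": cfg.n_th,
            "weights": dict(sorted(cfg.weights.items())),
            "seed": cfg.seed,
            "dopamine_depletion": cfg.dopamine_depletion,
            "lesion": {"ns": cfg.lesion.ns, "nd": cfg.lesion.nd,
                       "spine_order": cfg.lesion.spine_order},
        },
        "simulation": {
            "duration": spec.duration, "dt": spec.dt, "seed": spec.seed,
            "stimuli": [dict(population=pop, **wf)
                        for pop, wf in spec.stimuli],
            "record": [dict(population=pop, index=idx)
                       for pop, idx in spec.record],
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


# ---------------------------------------------------------------------------
# cell-parameter record
# ---------------------------------------------------------------------------

def params_record() -> dict:
    """Nested dict of every adopted cell/channel/synapse parameter.

    This is what ships as ``data/default_params.yaml`` -- the versioned
    record of the model's defaults.
    """
    from dataclasses import asdict
    from .engine import MSN_SITE_G, SYN_CLASSES, EngineCellParams
    from .network import DEFAULT_WEIGHTS
    ecp = EngineCellParams()
    rec = {
        "cells": {
            "th": asdict(ecp.th), "stn": asdict(ecp.stn),
            "gpe": asdict(ecp.gpe), "gpi": asdict(ecp.gpi),
            "py": asdict(ecp.py), "da": asdict(ecp.da),
        },
        "msn": {
            "membrane": {k: v for k, v in asdict(ecp.msn).items()
                         if k != "channels"},
            "channels": [asdict(ch) for ch in ecp.msn.channels],
        },
        "synapse_classes": {k: dict(tau_on=v[0], tau_off=v[1],
                                    e_syn=v[2], g_max=v[3])
                            for k, v in SYN_CLASSES.items()},
        "msn_site_conductances": dict(MSN_SITE_G),
        "connection_weights": dict(sorted(DEFAULT_WEIGHTS.items())),
    }
    return rec


def dump_default_params(path) -> None:
    """Write the adopted parameter defaults to YAML (stable order)."""
    Path(path).write_text(yaml.safe_dump(params_record(), sort_keys=True))


def load_cell_params(path):
    """Load a cell-parameter file into an :class:`EngineCellParams`.

    The file uses the ``cells``/``msn`` layout of
    :func:`params_record`; unknown fields are rejected.
    """
    from . import cells as cells_mod
    from .engine import EngineCellParams
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cls_map = dict(th=cells_mod.THParams, stn=cells_mod.STNParams,
                   gpe=cells_mod.GPParams, gpi=cells_mod.GPParams,
                   py=cells_mod.PYParams, da=cells_mod.DAParams)
    kwargs = {}
    for name, cls in cls_map.items():
        entry = dict((raw.get("cells") or {}).get(name) or {})
        valid = {f.name for f in __import__("dataclasses").fields(cls)}
        bad = set(entry) - valid
        if bad:
            raise ValueError(f"unknown {name} parameter(s): {sorted(bad)}")
        kwargs[name] = cls(**entry)
    msn_raw = raw.get("msn") or {}
    membrane = dict(msn_raw.get("membrane") or {})
    channels = msn_raw.get("channels")
    if channels is not None:
        membrane["channels"] = tuple(msn_mod.MSNChannel(**ch)
                                     for ch in channels)
    kwargs["msn"] = msn_mod.MSNParams(**membrane)
    return EngineCellParams(**kwargs)


def run_metadata(cfg: NetworkConfig, spec: SimulationSpec) -> dict:
    """Run-provenance record: config hash, seed, package version."""
    import hashlib
    from . import __version__
    import io as _io
    import tempfile

    buf_path = Path(tempfile.mkstemp(suffix=".yaml")[1])
    try:
        save_config(cfg, spec, buf_path)
        digest = hashlib.sha256(buf_path.read_bytes()).hexdigest()
    finally:
        buf_path.unlink(missing_ok=True)
    return {"config_sha256": digest, "seed": cfg.seed,
            "duration_ms": spec.duration, "dt_ms": spec.dt,
            "cbgt_version": __version__}


def save_run_metadata(cfg: NetworkConfig, spec: SimulationSpec,
                      path) -> None:
    import json
    Path(path).write_text(json.dumps(run_metadata(cfg, spec),
                                     indent=2, sort_keys=True) + "\n")
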