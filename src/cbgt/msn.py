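"""Multi-compartment medium spiny neuron: morphology, channels, lesions.

The MSN is a stylized 121-compartment tree: a soma bearing 8 primary
trunks that branch into secondary and subordinate dendrites, for 58
dendritic sections in total of which 32 (all the secondary and
subordinate ones) are the lesionable, spine-bearing pool.  Spines are
not modelled as explicit compartments; instead 32 glutamatergic
(cortical) and 32 dopaminergic synapse sites sit on the subordinate
compartments, one of each per subordinate compartment, and spine loss
is modelled by deactivating glutamatergic sites.

Compartments are coupled by a discretized cable model: the interchange
current into compartment i is ``sum_j (V_j - V_i) / R_ij`` over tree
neighbours j, with R_ij the axial resistance between compartment
centres computed from level-specific geometry and cytoplasmic
resistivity.

Somatic membrane carries 14 intrinsic channel families (NaF, NaP, KAf,
KAs, KIR, KRP, BK, SK, CaL1.2, CaL1.3, CaN, CaQ, CaR, CaT) plus leak;
dendrites carry the same set minus KRP.  Kinetics use Boltzmann
steady-states with fixed time constants and a pooled intracellular
calcium per compartment driving the SK and BK currents.  Calcium
currents are ohmic with a fixed reversal (a deliberate simplification
of GHK flux).

Two lesion operators act on the morphology:

``remove_spines``
    deactivates glutamatergic sites (spine loss, fraction Ns/32);
    under ``type1_first`` ordering, sites whose paired dopaminergic
    site was already lost to dopamine depletion go first.

``degrade_dendrites``
    detaches secondary/subordinate sections from their parents,
    deleting the detached subtree (degeneration, fraction Nd/32).
    Sections are peeled from the distal end so any Nd in 0..32 is
    exact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Level",
    "Compartment",
    "LesionRecord",
    "MSNMorphology",
    "MSNChannel",
    "MSNParams",
    "MSNState",
    "CHANNELS",
    "build_morphology",
    "cable_coupling_current",
    "msn_rhs",
    "msn_soma_rhs",
    "msn_steady_state",
    "remove_spines",
    "degrade_dendrites",
    "N_COMPARTMENTS",
    "N_DENDRITE_SECTIONS",
    "N_REMOVABLE_SECTIONS",
    "N_SYNAPSE_SITES",
]

N_COMPARTMENTS = 121
N_DENDRITE_SECTIONS = 58
N_REMOVABLE_SECTIONS = 32
N_SYNAPSE_SITES = 32


class Level(enum.Enum):
    SOMA = "soma"
    PRIMARY = "primary"
    SECONDARY = "secondary"
    SUBORDINATE = "subordinate"


#: Compartment geometry per level: (length um, diameter um).  The soma is
#: a 16 um sphere treated as an equivalent cylinder.
GEOMETRY = {
    Level.SOMA: (16.0, 16.0),
    Level.PRIMARY: (10.0, 2.25),
    Level.SECONDARY: (12.0, 1.10),
    Level.SUBORDINATE: (15.0, 0.72),
}

#: Cytoplasmic resistivity, ohm * cm.
RA = 100.0


@dataclass
class Compartment:
    """One electrical compartment of the MSN tree."""

    id: int
    parent: int | None
    level: Level
    section: int  # dendrite section index; -1 for the soma
    length: float  # um
    diameter: float  # um
    coupling_conductance_to_parent: float = 0.0  # uS; 0 for the soma

    @property
    def area_cm2(self) -> float:
        return np.pi * self.diameter * self.length * 1e-8


@dataclass
class LesionRecord:
    """Bookkeeping for applied lesions.

    ns spines (glutamatergic sites) removed out of 32; nd dendrite
    sections removed out of the 32 secondary+subordinate sections.
    """

    ns: int = 0
    nd: int = 0
    spine_order: str = "type1_first"
    removed_spine_sites: list[int] = field(default_factory=list)
    removed_sections: list[int] = field(default_factory=list)

    @property
    def spine_loss_fraction(self) -> float:
        return self.ns / N_SYNAPSE_SITES

    @property
    def dendrite_loss_fraction(self) -> float:
        return self.nd / N_REMOVABLE_SECTIONS


@dataclass
class MSNMorphology:
    """Compartment tree plus synapse-site bookkeeping.

    ``compartments`` holds only attached compartments (121 when intact);
    ``glut_synapse_sites`` / ``da_synapse_sites`` list the *active*
    sites' compartment ids.  ``lost_da_sites`` marks dopaminergic sites
    silenced by dopamine depletion (these define the type-1 spine
    positions).
    """

    receptor_type: str  # "D1" or "D2"
    compartments: list[Compartment]
    sections: dict[int, Level]  # section id -> level
    section_parent: dict[int, int]  # section id -> parent section (-1: soma)
    glut_synapse_sites: list[int]
    da_synapse_sites: list[int]
    lost_da_sites: list[int] = field(default_factory=list)
    lesion: LesionRecord = field(default_factory=LesionRecord)

    # -- derived helpers -------------------------------------------------
    def compartment(self, cid: int) -> Compartment:
        return self._by_id()[cid]

    def _by_id(self) -> dict[int, Compartment]:
        return {c.id: c for c in self.compartments}

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    @property
    def soma_id(self) -> int:
        (sid,) = [c.id for c in self.compartments if c.level is Level.SOMA]
        return sid

    def children(self, cid: int) -> list[int]:
        return [c.id for c in self.compartments if c.parent == cid]

    def section_ids(self, level: Level | None = None) -> list[int]:
        if level is None:
            return sorted(self.sections)
        return sorted(s for s, lv in self.sections.items() if lv is level)

    def attached_section_ids(self) -> set[int]:
        return {c.section for c in self.compartments if c.section >= 0}

    def is_tree(self) -> bool:
        """Connected and acyclic, rooted at the soma."""
        ids = {c.id for c in self.compartments}
        seen = set()
        for c in self.compartments:
            cur, path = c.id, set()
            by_id = self._by_id()
            while cur is not None:
                if cur in path:
                    return False
                path.add(cur)
                if cur in seen:
                    break
                seen.add(cur)
                parent = by_id[cur].parent
                if parent is not None and parent not in ids:
                    return False
                cur = parent
        return True

    def index_arrays(self):
        """(ids, parent_index, level codes, areas cm^2, g_axial uS).

        Compartments are ordered so a parent precedes its children
        (required by the Hines solver); index -1 marks the root.
        """
        order = sorted(self.compartments, key=lambda c: c.id)
        pos = {c.id: i for i, c in enumerate(order)}
        ids = np.array([c.id for c in order])
        parent = np.array([pos[c.parent] if c.parent is not None else -1
                           for c in order])
        if not np.all(parent < np.arange(len(order))):
            raise ValueError("compartment ids are not topologically sorted")
        levels = np.array([list(Level).index(c.level) for c in order])
        areas = np.array([c.area_cm2 for c in order])
        g_ax = np.array([c.coupling_conductance_to_parent for c in order])
        return ids, parent, levels, areas, g_ax


def _axial_g(child: Compartment, parent: Compartment) -> float:
    """Axial (coupling) conductance between compartment centres, uS."""
    def half_r(c: Compartment) -> float:
        radius_cm = c.diameter / 2 * 1e-4
        cross = np.pi * radius_cm ** 2
        return RA * (c.length / 2 * 1e-4) / cross  # ohm
    r_total = half_r(child) + half_r(parent)
    return 1e6 / r_total


def build_morphology(receptor_type: str = "D1", seed: int = 0) -> MSNMorphology:
    """Construct the intact 121-compartment MSN tree.

    Eight primary trunks leave the soma (two of four sections, six of
    three: 26 primary sections); each trunk tip splits into two
    secondary sections, each continuing into one subordinate section
    (16 + 16 = 32 removable sections; 58 sections in all).  Subordinate
    sections carry two compartments each; every subordinate compartment
    bears one glutamatergic and one dopaminergic synapse site (32 of
    each).  The tree is deterministic; ``seed`` fixes the order in which
    lesion operators sample sites and sections.
    """
    if receptor_type not in ("D1", "D2"):
        raise ValueError("receptor_type must be 'D1' or 'D2'")
    comps: list[Compartment] = []
    sections: dict[int, Level] = {}
    section_parent: dict[int, int] = {}
    soma = Compartment(0, None, Level.SOMA, -1, *GEOMETRY[Level.SOMA])
    comps.append(soma)
    next_id = 1
    next_sec = 0

    def add_section(level: Level, parent_comp: int, parent_sec: int,
                    n_comp: int) -> tuple[int, int]:
        nonlocal next_id, next_sec
        sec = next_sec
        next_sec += 1
        sections[sec] = level
        section_parent[sec] = parent_sec
        length, diam = GEOMETRY[level]
        last = parent_comp
        for _ in range(n_comp):
            c = Compartment(next_id, last, level, sec, length, diam)
            comps.append(c)
            last = next_id
            next_id += 1
        return sec, last

    for trunk in range(8):
        n_primary_sections = 4 if trunk < 2 else 3
        parent_comp, parent_sec = 0, -1
        for k in range(n_primary_sections):
            # four of the 26 primary sections carry three compartments so
            # the totals come out at 56 primary compartments
            n_comp = 3 if (trunk >= 4 and k == 0) else 2
            parent_sec, parent_comp = add_section(
                Level.PRIMARY, parent_comp, parent_sec, n_comp)
        for _branch in range(2):
            sec2, tip2 = add_section(Level.SECONDARY, parent_comp,
                                     parent_sec, 2)
            add_section(Level.SUBORDINATE, tip2, sec2, 2)

    # axial coupling
    by_id = {c.id: c for c in comps}
    for c in comps:
        if c.parent is not None:
            c.coupling_conductance_to_parent = _axial_g(c, by_id[c.parent])

    sub_comp_ids = [c.id for c in comps if c.level is Level.SUBORDINATE]
    assert len(comps) == N_COMPARTMENTS
    assert len(sections) == N_DENDRITE_SECTIONS
    assert len(sub_comp_ids) == N_SYNAPSE_SITES

    return MSNMorphology(
        receptor_type=receptor_type,
        compartments=comps,
        sections=sections,
        section_parent=section_parent,
        glut_synapse_sites=list(sub_comp_ids),
        da_synapse_sites=list(sub_comp_ids),
    )


def cable_coupling_current(morph: MSNMorphology, v: np.ndarray,
                           cid: int) -> float:
    """Compartment-interchange current density into compartment ``cid``.

    ``v`` holds membrane potentials indexed like
    ``morph.index_arrays()`` order.  Returns
    ``sum_j (V_j - V_i)/R_ij`` mapped to uA/cm^2 of the compartment's
    membrane; antisymmetric across each edge in absolute (nA) terms.
    """
    ids, parent, _, areas, g_ax = morph.index_arrays()
    pos = {int(i): k for k, i in enumerate(ids)}
    if cid not in pos:
        raise ValueError(f"compartment {cid} is not attached")
    i = pos[cid]
    total_na = 0.0
    if parent[i] >= 0:
        total_na += g_ax[i] * (v[parent[i]] - v[i])  # uS * mV = nA
    for j in range(len(ids)):
        if parent[j] == i:
            total_na += g_ax[j] * (v[j] - v[i])
    return total_na * 1e-3 / areas[i]  # uA / cm^2


# ---------------------------------------------------------------------------
# Channels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MSNChannel:
    """One intrinsic channel family with Boltzmann kinetics.

    Activation gate: x_inf = sig((v - vh)/k), power ``n_act``, constant
    time constant tau_act (ms).  Optional inactivation gate with
    ``frac_inact`` the inactivating fraction (1 = full inactivation).
    ``ca_gated`` channels multiply the conductance by a calcium factor:
    ca/(ca + kd) for BK (also voltage gated) and ca^2/(ca^2 + kd^2) for
    SK (purely calcium gated).
    """

    name: str
    ion: str  # 'na' | 'k' | 'ca'
    g_soma: float
    g_dend: float
    vh_act: float
    k_act: float
    tau_act: float
    n_act: int = 1
    vh_inact: float | None = None
    k_inact: float | None = None
    tau_inact: float = 1.0
    frac_inact: float = 1.0
    ca_gated: bool = False
    kd_ca: float = 1.0
    feeds_ca: bool = False


def _boltz(v, vh, k):
    return 1.0 / (1.0 + np.exp(-(v - vh) / k))


#: The 14 channel families.  Conductances in mS/cm^2; dendrites carry the
#: same set minus KRP (g_dend = 0).
CHANNELS: tuple[MSNChannel, ...] = (
    MSNChannel("NaF", "na", 300.0, 30.0, -28.0, 9.7, 0.1, n_act=3,
               vh_inact=-55.0, k_inact=-10.7, tau_inact=2.0),
    MSNChannel("NaP", "na", 0.04, 0.015, -52.6, 4.6, 3.0),
    MSNChannel("KAf", "k", 6.0, 3.0, -10.0, 17.7, 1.0,
               vh_inact=-75.6, k_inact=-10.0, tau_inact=25.0),
    MSNChannel("KAs", "k", 0.3, 0.15, -27.0, 16.0, 10.0,
               vh_inact=-33.5, k_inact=-21.5, tau_inact=1000.0,
               frac_inact=0.8),
    MSNChannel("KIR", "k", 0.15, 0.15, -82.0, -13.0, 1.0),
    MSNChannel("KRP", "k", 0.3, 0.0, -13.4, 12.1, 30.0,
               vh_inact=-55.0, k_inact=-19.0, tau_inact=3000.0,
               frac_inact=0.7),
    MSNChannel("BK", "k", 2.0, 1.0, -20.0, 10.0, 1.0,
               ca_gated=True, kd_ca=2.0),
    MSNChannel("SK", "k", 0.5, 0.25, 0.0, 1.0, 1.0,
               ca_gated=True, kd_ca=0.35),
    MSNChannel("CaL12", "ca", 0.3, 0.15, -8.9, 6.7, 1.0, n_act=2,
               feeds_ca=True),
    MSNChannel("CaL13", "ca", 0.2, 0.1, -33.0, 6.7, 3.0, n_act=2,
               feeds_ca=True),
    MSNChannel("CaN", "ca", 0.3, 0.1, -8.7, 7.4, 1.0, n_act=2,
               vh_inact=-74.8, k_inact=-6.5, tau_inact=70.0,
               frac_inact=0.2, feeds_ca=True),
    MSNChannel("CaQ", "ca", 0.3, 0.1, -9.0, 6.6, 1.5, n_act=2,
               feeds_ca=True),
    MSNChannel("CaR", "ca", 0.3, 0.1, -10.3, 6.6, 1.7, n_act=3,
               vh_inact=-33.3, k_inact=-17.0, tau_inact=30.0,
               feeds_ca=True),
    MSNChannel("CaT", "ca", 0.1, 0.15, -51.7, 6.2, 2.0, n_act=3,
               vh_inact=-80.0, k_inact=-6.4, tau_inact=15.0,
               feeds_ca=True),
)


@dataclass(frozen=True)
class MSNParams:
    """Membrane constants and calcium-pool parameters."""

    cm: float = 1.0
    e_na: float = 50.0
    e_k: float = -90.0
    e_ca: float = 130.0
    g_leak: float = 0.0075
    e_leak: float = -75.0
    alpha_ca: float = 0.02  # uM per (uA/cm^2 * ms)
    tau_ca: float = 20.0  # ms
    channels: tuple[MSNChannel, ...] = CHANNELS

    def e_rev(self, ch: MSNChannel) -> float:
        return {"na": self.e_na, "k": self.e_k, "ca": self.e_ca}[ch.ion]


@dataclass
class MSNState:
    """Per-compartment state arrays, ordered like ``index_arrays()``."""

    v: np.ndarray
    act: dict[str, np.ndarray]
    inact: dict[str, np.ndarray]
    ca: np.ndarray


def msn_steady_state(morph: MSNMorphology, v0: float = -85.0,
                     params: MSNParams | None = None) -> MSNState:
    params = params or MSNParams()
    n = morph.n_compartments
    v = np.full(n, float(v0))
    act, inact = {}, {}
    for ch in params.channels:
        act[ch.name] = np.full(n, float(_boltz(v0, ch.vh_act, ch.k_act)))
        if ch.vh_inact is not None:
            inact[ch.name] = np.full(
                n, float(_boltz(v0, ch.vh_inact, ch.k_inact)))
    return MSNState(v=v, act=act, inact=inact, ca=np.full(n, 0.01))


def _channel_open(ch: MSNChannel, state: MSNState):
    x = state.act[ch.name] ** ch.n_act
    if ch.vh_inact is not None:
        h = state.inact[ch.name]
        x = x * ((1.0 - ch.frac_inact) + ch.frac_inact * h)
    if ch.ca_gated:
        if ch.name == "SK":
            x = state.ca ** 2 / (state.ca ** 2 + ch.kd_ca ** 2)
        else:
            x = x * state.ca / (state.ca + ch.kd_ca)
    return x


def msn_rhs(morph: MSNMorphology, state: MSNState,
            params: MSNParams | None = None,
            i_syn: np.ndarray | float = 0.0,
            i_ext: np.ndarray | float = 0.0) -> MSNState:
    """Time derivative of the full compartment state.

    ``i_syn`` (outward-positive) and ``i_ext`` (inward-positive) are
    per-compartment current densities (uA/cm^2), scalar or arrays.
    Returns an :class:`MSNState` of derivatives.
    """
    params = params or MSNParams()
    ids, parent, levels, areas, g_ax = morph.index_arrays()
    v = state.v
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite MSN state")
    n = len(v)
    is_soma = levels == 0

    i_ion = params.g_leak * (v - params.e_leak)
    i_ca_total = np.zeros(n)
    for ch in params.channels:
        g = np.where(is_soma, ch.g_soma, ch.g_dend)
        cur = g * _channel_open(ch, state) * (v - params.e_rev(ch))
        i_ion = i_ion + cur
        if ch.feeds_ca:
            i_ca_total += cur

    # cable interchange currents (uS * mV = nA -> uA/cm^2)
    i_couple_na = np.zeros(n)
    has_parent = parent >= 0
    delta = np.where(has_parent, v[parent] - v, 0.0) * g_ax
    i_couple_na += delta
    np.add.at(i_couple_na, parent[has_parent], -delta[has_parent])
    i_couple = i_couple_na * 1e-3 / areas

    dv = (-i_ion + i_couple - i_syn + i_ext) / params.cm
    dact, dinact = {}, {}
    for ch in params.channels:
        x_inf = _boltz(v, ch.vh_act, ch.k_act)
        dact[ch.name] = (x_inf - state.act[ch.name]) / ch.tau_act
        if ch.vh_inact is not None:
            h_inf = _boltz(v, ch.vh_inact, ch.k_inact)
            dinact[ch.name] = (h_inf - state.inact[ch.name]) / ch.tau_inact
    dca = -params.alpha_ca * i_ca_total - state.ca / params.tau_ca
    return MSNState(v=dv, act=dact, inact=dinact, ca=dca)


def msn_soma_rhs(morph: MSNMorphology, state: MSNState,
                 params: MSNParams | None = None,
                 i_syn: np.ndarray | float = 0.0,
                 i_ext: np.ndarray | float = 0.0) -> float:
    """dv/dt of the soma (14 channels + interchange + synaptic terms)."""
    d = msn_rhs(morph, state, params, i_syn, i_ext)
    ids, _, levels, _, _ = morph.index_arrays()
    return float(d.v[levels == 0][0])


# ---------------------------------------------------------------------------
# Lesion operators
# ---------------------------------------------------------------------------

def mark_lost_da_sites(morph: MSNMorphology, fraction: float,
                       seed: int = 0) -> MSNMorphology:
    """Silence a fraction of dopaminergic synapse sites (depletion).

    ceil(32 * fraction) sites are chosen uniformly; their glutamatergic
    partners on the same compartment become the type-1 spine positions.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n_lost = int(np.ceil(N_SYNAPSE_SITES * fraction))
    rng = np.random.default_rng(seed)
    lost = sorted(rng.choice(morph.da_synapse_sites, size=n_lost,
                             replace=False).tolist()) if n_lost else []
    return replace(morph, lost_da_sites=list(lost))


def remove_spines(morph: MSNMorphology, ns: int,
                  order: str = "type1_first", seed: int = 0) -> MSNMorphology:
    """Remove ``ns`` glutamatergic synapse sites (spine loss).

    ``type1_first`` removes sites whose paired dopaminergic site was
    already lost (type-1) before intact-pair sites (type-2); ``random``
    ignores the pairing.  Topology is unchanged.
    """
    if not 0 <= ns <= N_SYNAPSE_SITES:
        raise ValueError(f"ns must lie in 0..{N_SYNAPSE_SITES}")
    if order not in ("type1_first", "random"):
        raise ValueError("order must be 'type1_first' or 'random'")
    active = [s for s in morph.glut_synapse_sites]
    if ns == 0:
        return morph
    rng = np.random.default_rng(seed)
    if order == "type1_first":
        type1 = [s for s in active if s in set(morph.lost_da_sites)]
        type2 = [s for s in active if s not in set(morph.lost_da_sites)]
        rng.shuffle(type1)
        rng.shuffle(type2)
        ordered = type1 + type2
    else:
        ordered = list(active)
        rng.shuffle(ordered)
    removed = ordered[:ns]
    remaining = [s for s in active if s not in set(removed)]
    rec = replace(morph.lesion, ns=morph.lesion.ns + ns,
                  spine_order=order,
                  removed_spine_sites=sorted(
                      morph.lesion.removed_spine_sites + removed))
    return replace(morph, glut_synapse_sites=remaining, lesion=rec)


def _removable_now(morph: MSNMorphology, attached: set[int]) -> list[int]:
    """Sections removable next under distal-first peeling."""
    out = []
    children: dict[int, list[int]] = {}
    for s, p in morph.section_parent.items():
        children.setdefault(p, []).append(s)
    for s in attached:
        lv = morph.sections[s]
        if lv not in (Level.SECONDARY, Level.SUBORDINATE):
            continue
        kids = [k for k in children.get(s, []) if k in attached]
        if not kids:
            out.append(s)
    return sorted(out)


def degrade_dendrites(morph: MSNMorphology, nd: int, seed: int = 0,
                      sections: Sequence[int] | None = None) -> MSNMorphology:
    """Detach ``nd`` secondary/subordinate dendrite sections.

    Sections are peeled distal-first (a subordinate section before its
    secondary parent), sampling uniformly among currently removable
    sections, so exactly ``nd`` of the 32-section pool are removed and
    the remaining graph stays a soma-rooted tree.  An explicit
    ``sections`` list (each with its subtree) overrides the sampling.
    """
    if not 0 <= nd <= N_REMOVABLE_SECTIONS:
        raise ValueError(f"nd must lie in 0..{N_REMOVABLE_SECTIONS}")
    attached = set(morph.attached_section_ids())
    rng = np.random.default_rng(seed)
    removed: list[int] = []
    if sections is not None:
        # explicit targets: detach each with its subtree
        children: dict[int, list[int]] = {}
        for s, p in morph.section_parent.items():
            children.setdefault(p, []).append(s)
        stack = list(sections)
        while stack:
            s = stack.pop()
            if s in attached:
                attached.discard(s)
                removed.append(s)
                stack.extend(children.get(s, []))
    else:
        for _ in range(nd):
            pool = _removable_now(morph, attached)
            if not pool:
                break
            pick = int(rng.choice(pool))
            attached.discard(pick)
            removed.append(pick)

    keep_comps = [c for c in morph.compartments
                  if c.section < 0 or c.section in attached]
    keep_ids = {c.id for c in keep_comps}
    glut = [s for s in morph.glut_synapse_sites if s in keep_ids]
    da = [s for s in morph.da_synapse_sites if s in keep_ids]
    lost_da = [s for s in morph.lost_da_sites if s in keep_ids]
    n_removed = len([s for s in removed
                     if morph.sections[s] in (Level.SECONDARY,
                                              Level.SUBORDINATE)])
    rec = replace(morph.lesion, nd=morph.lesion.nd + n_removed,
                  removed_sections=sorted(morph.lesion.removed_sections
                                          + removed))
    return replace(morph, compartments=keep_comps,
                   glut_synapse_sites=glut, da_synapse_sites=da,
                   lost_da_sites=lost_da, lesion=rec)


def pack_kernel_arrays(morph: MSNMorphology, params: MSNParams, dt: float):
    """Flatten morphology + channel parameters into kernel arrays.

    Returns a dict consumed by :func:`cbgt._kernels.step_msn`; gate
    decay factors are precomputed for the step size ``dt``.
    """
    ids, parent, levels, areas, g_ax = morph.index_arrays()
    n = len(ids)
    is_soma = levels == 0
    chans = params.channels
    n_ch = len(chans)
    g_chan = np.zeros((n_ch, n))
    e_chan = np.zeros(n_ch)
    vh_act = np.zeros(n_ch)
    k_act = np.zeros(n_ch)
    n_act = np.zeros(n_ch, dtype=np.int64)
    dec_act = np.zeros(n_ch)
    inact_of = np.full(n_ch, -1, dtype=np.int64)
    vh_in, k_in, dec_in, frac_in = [], [], [], []
    gate_kind = np.zeros(n_ch, dtype=np.int64)
    kd_ca = np.ones(n_ch)
    feeds_ca = np.zeros(n_ch, dtype=np.int64)
    for c, ch in enumerate(chans):
        g_chan[c] = np.where(is_soma, ch.g_soma, ch.g_dend)
        e_chan[c] = params.e_rev(ch)
        vh_act[c], k_act[c] = ch.vh_act, ch.k_act
        n_act[c] = ch.n_act
        dec_act[c] = np.exp(-dt / ch.tau_act)
        if ch.vh_inact is not None:
            inact_of[c] = len(vh_in)
            vh_in.append(ch.vh_inact)
            k_in.append(ch.k_inact)
            dec_in.append(np.exp(-dt / ch.tau_inact))
            frac_in.append(ch.frac_inact)
        if ch.ca_gated:
            gate_kind[c] = 2 if ch.name == "SK" else 1
            kd_ca[c] = ch.kd_ca
        feeds_ca[c] = 1 if ch.feeds_ca else 0
    g_ax_den_self = np.zeros(n)
    g_ax_den_parent = np.zeros(n)
    has_parent = parent >= 0
    g_ax_den_self[has_parent] = (g_ax[has_parent] * 1e-3
                                 / areas[has_parent])
    g_ax_den_parent[has_parent] = (g_ax[has_parent] * 1e-3
                                   / areas[parent[has_parent]])
    return dict(
        ids=ids, parent=parent, levels=levels, areas=areas,
        g_ax_den_self=g_ax_den_self, g_ax_den_parent=g_ax_den_parent,
        g_chan=g_chan, e_chan=e_chan, vh_act=vh_act, k_act=k_act,
        n_act=n_act, dec_act=dec_act, inact_of=inact_of,
        vh_in=np.array(vh_in), k_in=np.array(k_in),
        dec_in=np.array(dec_in), frac_in=np.array(frac_in),
        gate_kind=gate_kind, kd_ca=kd_ca, feeds_ca=feeds_ca,
    )


def pack_state(morph: MSNMorphology, state: MSNState, params: MSNParams):
    """MSNState -> (v, act 2-D, inact 2-D, ca) kernel arrays."""
    chans = params.channels
    act = np.stack([state.act[ch.name] for ch in chans])
    inact_list = [state.inact[ch.name] for ch in chans
                  if ch.vh_inact is not None]
    inact = (np.stack(inact_list) if inact_list
             else np.zeros((0, len(state.v))))
    return state.v.copy(), act, inact, state.ca.copy()
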