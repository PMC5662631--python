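"""Population construction, connectivity, dopamine depletion, lesions.

The circuit contains eight populations: cortical pyramidal cells (PY),
direct- and indirect-pathway medium spiny neurons (D1, D2, one detailed
multi-compartment cell each by default), dopaminergic neurons (DA), and
the subthalamic nucleus (STN), external/internal pallidum (GPe, GPi)
and thalamus (TH) populations.

Connectivity contract (per postsynaptic neuron):

* D1 and D2 receive input from every PY (glutamatergic, on the 32
  spine sites) and from every DA (excitatory on D1, inhibitory on D2);
* each STN receives excitatory input from 3 randomly chosen PY and
  inhibitory input from its 2 ring-neighbouring GPe;
* each GPe receives inhibition from its 2 neighbouring GPe and from D2,
  and excitation from 2 neighbouring STN;
* each GPi receives inhibition from D1, from 2 randomly chosen GPe and
  from 1 neighbouring GPi, and excitation from 2 neighbouring STN;
* each TH receives inhibition from 3 GPi;
* exactly 6 randomly chosen PY receive excitatory thalamic feedback.

Dopamine depletion removes ceil(fraction * n_da) DA neurons (their
output synapses fall silent) and marks the matching fraction of
dopaminergic synapse sites on each MSN as lost, which defines the
type-1 spine positions.  Depletion beyond 50% defines the parkinsonian
(PD) state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from . import msn as msn_mod

__all__ = [
    "LesionSpec",
    "NetworkConfig",
    "Edge",
    "Wiring",
    "Network",
    "DEFAULT_WEIGHTS",
    "build_network",
    "build",
    "apply_dopamine_depletion",
    "count_in_degrees",
]

POPULATIONS = ("py", "d1", "d2", "da", "stn", "gpe", "gpi", "th")

#: Synaptic connection weights g_{alpha->beta} per edge class
#: (dimensionless multipliers on the class conductance).
DEFAULT_WEIGHTS: dict[str, float] = {
    "py_d1_ampa": 1.0,
    "py_d1_nmda": 0.4,
    "py_d2_ampa": 1.0,
    "py_d2_nmda": 0.4,
    "da_d1": 1.0,
    "da_d2": 1.0,
    "py_stn": 0.35,
    "gpe_stn": 0.9,
    "d2_gpe": 10.0,
    "gpe_gpe": 0.25,
    "stn_gpe": 0.5,
    "d1_gpi": 10.0,
    "gpe_gpi": 0.35,
    "gpi_gpi": 0.2,
    "stn_gpi": 0.6,
    "gpi_th": 0.8,
    "th_py": 0.3,
}

#: synapse kind per edge class (AMPA / NMDA / GABA / DA_exc / DA_inh)
EDGE_KIND: dict[str, str] = {
    "py_d1_ampa": "AMPA", "py_d1_nmda": "NMDA",
    "py_d2_ampa": "AMPA", "py_d2_nmda": "NMDA",
    "da_d1": "DA_exc", "da_d2": "DA_inh",
    "py_stn": "AMPA", "gpe_stn": "GABA",
    "d2_gpe": "GABA", "gpe_gpe": "GABA", "stn_gpe": "AMPA",
    "d1_gpi": "GABA", "gpe_gpi": "GABA", "gpi_gpi": "GABA",
    "stn_gpi": "AMPA", "gpi_th": "GABA", "th_py": "AMPA",
}


@dataclass(frozen=True)
class LesionSpec:
    """Morphological lesion applied to every MSN."""

    ns: int = 0  # spines removed, 0..32
    nd: int = 0  # dendrite sections removed, 0..32
    spine_order: str = "type1_first"

    def __post_init__(self):
        if not 0 <= self.ns <= msn_mod.N_SYNAPSE_SITES:
            raise ValueError("ns out of range")
        if not 0 <= self.nd <= msn_mod.N_REMOVABLE_SECTIONS:
            raise ValueError("nd out of range")


@dataclass(frozen=True)
class NetworkConfig:
    """Population sizes, weights, seed, depletion and lesion settings."""

    n_py: int = 10
    n_d1: int = 1
    n_d2: int = 1
    n_da: int = 8
    n_stn: int = 10
    n_gpe: int = 10
    n_gpi: int = 10
    n_th: int = 10
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    seed: int = 0
    dopamine_depletion: float = 0.0
    lesion: LesionSpec = field(default_factory=LesionSpec)

    def __post_init__(self):
        for name in POPULATIONS:
            if getattr(self, f"n_{name}") < 1:
                raise ValueError(f"population {name} must have >= 1 neuron")
        if not 0.0 <= self.dopamine_depletion <= 1.0:
            raise ValueError("dopamine_depletion must lie in [0, 1]")
        unknown = set(self.weights) - set(DEFAULT_WEIGHTS)
        if unknown:
            raise ValueError(f"unknown weight keys: {sorted(unknown)}")

    def size(self, pop: str) -> int:
        return getattr(self, f"n_{pop}")


@dataclass(frozen=True)
class Edge:
    """One synaptic connection pre -> post."""

    pre_pop: str
    pre: int
    post_pop: str
    post: int
    edge_class: str
    weight: float

    @property
    def kind(self) -> str:
        return EDGE_KIND[self.edge_class]


@dataclass
class Wiring:
    """Edge list plus the PY indices receiving thalamic feedback."""

    edges: list[Edge]
    th_fed_py: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(pre_pop=e.pre_pop, pre=e.pre, post_pop=e.post_pop,
                  post=e.post, edge_class=e.edge_class, kind=e.kind,
                  weight=e.weight) for e in self.edges])


def build_network(config: NetworkConfig) -> Wiring:
    """Wire the circuit per the connectivity contract (seeded)."""
    rng = np.random.default_rng(config.seed)
    w = {**DEFAULT_WEIGHTS, **config.weights}
    edges: list[Edge] = []

    def add(pre_pop, pre, post_pop, post, edge_class):
        edges.append(Edge(pre_pop, int(pre), post_pop, int(post),
                          edge_class, w[edge_class]))

    def require(pop, need, rule):
        if config.size(pop) < need:
            raise ValueError(
                f"population {pop} too small for rule '{rule}' "
                f"(need >= {need}, have {config.size(pop)})")

    # cortex and dopamine onto the MSNs: all-to-one
    for d_pop, n_d in (("d1", config.n_d1), ("d2", config.n_d2)):
        for post in range(n_d):
            for pre in range(config.n_py):
                add("py", pre, d_pop, post, f"py_{d_pop}_ampa")
                add("py", pre, d_pop, post, f"py_{d_pop}_nmda")
            for pre in range(config.n_da):
                add("da", pre, d_pop, post, f"da_{d_pop}")

    # STN <- 3 random PY, 2 neighbouring GPe
    require("py", 3, "stn<-3 py")
    require("gpe", 2, "stn<-2 gpe")
    for post in range(config.n_stn):
        for pre in rng.choice(config.n_py, size=3, replace=False):
            add("py", pre, "stn", post, "py_stn")
        for pre in ((post - 1) % config.n_gpe, (post + 1) % config.n_gpe):
            add("gpe", pre, "stn", post, "gpe_stn")

    # GPe <- 2 neighbouring GPe, all D2, 2 neighbouring STN
    require("gpe", 3, "gpe ring")
    for post in range(config.n_gpe):
        for pre in ((post - 1) % config.n_gpe, (post + 1) % config.n_gpe):
            add("gpe", pre, "gpe", post, "gpe_gpe")
        for pre in range(config.n_d2):
            add("d2", pre, "gpe", post, "d2_gpe")
        for pre in ((post - 1) % config.n_stn, (post + 1) % config.n_stn):
            add("stn", pre, "gpe", post, "stn_gpe")

    # GPi <- all D1, 2 random GPe, 2 neighbouring STN, 1 neighbouring GPi
    require("gpe", 2, "gpi<-2 gpe")
    require("gpi", 2, "gpi ring")
    for post in range(config.n_gpi):
        for pre in range(config.n_d1):
            add("d1", pre, "gpi", post, "d1_gpi")
        for pre in rng.choice(config.n_gpe, size=2, replace=False):
            add("gpe", pre, "gpi", post, "gpe_gpi")
        for pre in ((post - 1) % config.n_stn, (post + 1) % config.n_stn):
            add("stn", pre, "gpi", post, "stn_gpi")
        add("gpi", (post + 1) % config.n_gpi, "gpi", post, "gpi_gpi")

    # TH <- 3 GPi
    require("gpi", 3, "th<-3 gpi")
    for post in range(config.n_th):
        for pre in rng.choice(config.n_gpi, size=3, replace=False):
            add("gpi", pre, "th", post, "gpi_th")

    # 6 randomly selected PY <- TH feedback
    require("py", 6, "6 py<-th")
    fed = sorted(int(i) for i in rng.choice(config.n_py, size=6,
                                            replace=False))
    for j, post in enumerate(fed):
        add("th", j % config.n_th, "py", post, "th_py")

    return Wiring(edges=edges, th_fed_py=fed)


def count_in_degrees(wiring: Wiring) -> pd.DataFrame:
    """In-degree per (post_pop, post, pre_pop); empty wiring -> empty."""
    df = wiring.to_frame()
    if df.empty:
        return pd.DataFrame(columns=["post_pop", "post", "pre_pop", "count"])
    out = (df.groupby(["post_pop", "post", "pre_pop"])
             .size().rename("count").reset_index())
    return out


@dataclass
class Network:
    """A wired, possibly depleted and lesioned, network instance."""

    config: NetworkConfig
    wiring: Wiring
    d1_cells: list[msn_mod.MSNMorphology]
    d2_cells: list[msn_mod.MSNMorphology]
    removed_da: list[int] = field(default_factory=list)

    @property
    def dopamine_depletion(self) -> float:
        return self.config.dopamine_depletion

    @property
    def is_pd(self) -> bool:
        """Parkinsonian iff more than half the DA neurons are removed."""
        return self.config.dopamine_depletion > 0.5

    def active_da_cells(self) -> list[int]:
        return [i for i in range(self.config.n_da)
                if i not in set(self.removed_da)]


def apply_dopamine_depletion(network: Network, fraction: float,
                             seed: int | None = None) -> Network:
    """Remove ceil(fraction * n_da) DA neurons and mark lost DA sites.

    Removed neurons' synapses onto D1/D2 are silenced permanently; the
    matching fraction of DA sites on every MSN is marked lost (type-1
    spine positions for subsequent spine-loss lesions).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    cfg = network.config
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed + 101)
    n_remove = math.ceil(fraction * cfg.n_da)
    removed = (sorted(int(i) for i in
                      rng.choice(cfg.n_da, size=n_remove, replace=False))
               if n_remove else [])
    d1 = [msn_mod.mark_lost_da_sites(m, fraction, seed + 7 + i)
          for i, m in enumerate(network.d1_cells)]
    d2 = [msn_mod.mark_lost_da_sites(m, fraction, seed + 37 + i)
          for i, m in enumerate(network.d2_cells)]
    new_cfg = replace(cfg, dopamine_depletion=fraction)
    return Network(config=new_cfg, wiring=network.wiring,
                   d1_cells=d1, d2_cells=d2, removed_da=removed)


def _apply_lesion(m: msn_mod.MSNMorphology, lesion: LesionSpec,
                  seed: int) -> msn_mod.MSNMorphology:
    if lesion.nd:
        m = msn_mod.degrade_dendrites(m, lesion.nd, seed=seed + 1)
    if lesion.ns:
        m = msn_mod.remove_spines(m, lesion.ns, lesion.spine_order,
                                  seed=seed + 2)
    return m


def build(config: NetworkConfig) -> Network:
    """Build wiring and MSN cells, then apply depletion and lesions.

    Order matters: dopamine depletion is applied before spine removal so
    that type-1 ordering sees the lost dopaminergic sites.
    """
    wiring = build_network(config)
    d1 = [msn_mod.build_morphology("D1", seed=config.seed + i)
          for i in range(config.n_d1)]
    d2 = [msn_mod.build_morphology("D2", seed=config.seed + 50 + i)
          for i in range(config.n_d2)]
    net = Network(config=replace(config, dopamine_depletion=0.0),
                  wiring=wiring, d1_cells=d1, d2_cells=d2)
    if config.dopamine_depletion > 0:
        net = apply_dopamine_depletion(net, config.dopamine_depletion,
                                       config.seed)
    lesion = config.lesion
    if lesion.ns or lesion.nd:
        net = Network(
            config=net.config, wiring=net.wiring,
            d1_cells=[_apply_lesion(m, lesion, config.seed + 211 + i)
                      for i, m in enumerate(net.d1_cells)],
            d2_cells=[_apply_lesion(m, lesion, config.seed + 311 + i)
                      for i, m in enumerate(net.d2_cells)],
            removed_da=net.removed_da)
    net.config = replace(net.config, lesion=lesion,
                         dopamine_depletion=config.dopamine_depletion)
    return net
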