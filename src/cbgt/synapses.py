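"""Two-state (dual-exponential) synapses and weighted synaptic currents.

AMPA, NMDA and GABA-A conductances follow an Exp2Syn-style two-state
scheme: two auxiliary variables relax exponentially toward zero,

    m' = -m / tau_on        h' = -h / tau_off,

and the synaptic current is ``I = g_max * (h - m) * (V - E_syn)``.
A presynaptic spike increments both states by a factor chosen so that a
unitary event drives the conductance gate ``(h - m)`` to a peak of
exactly 1; responses to event trains superpose linearly.  Edge weights
scale the current per connection (``I_ab = g_ab * I_syn``).

Rise/decay constants: AMPA and NMDA from hippocampal mossy-fiber
voltage-clamp data, GABA-A from neocortical paired recordings.  The
NMDA conductance is purely kinetic (no magnesium-block voltage
dependence), matching the printed model.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SynapseKind",
    "SynapseParams",
    "SynapseState",
    "AMPA",
    "NMDA",
    "GABA",
    "synapse_current",
    "advance_synapse",
    "on_presynaptic_spike",
    "event_normalization",
    "weighted_current",
]


class SynapseKind(enum.Enum):
    AMPA = "AMPA"
    NMDA = "NMDA"
    GABA = "GABA"


@dataclass(frozen=True)
class SynapseParams:
    """Kinetic and conductance parameters for one synapse class.

    tau_on/tau_off in ms (rise < decay), e_syn in mV, g_max in mS/cm^2
    of postsynaptic membrane.
    """

    kind: SynapseKind
    tau_on: float
    tau_off: float
    e_syn: float
    g_max: float = 1.0

    def __post_init__(self):
        if not (self.tau_off > self.tau_on > 0.0):
            raise ValueError(
                f"require tau_off > tau_on > 0, got "
                f"tau_on={self.tau_on}, tau_off={self.tau_off}")

    def with_gmax(self, g_max: float) -> "SynapseParams":
        return replace(self, g_max=g_max)


#: Default synapse classes.  AMPA/NMDA reverse at 0 mV, GABA-A at -80 mV.
AMPA = SynapseParams(SynapseKind.AMPA, tau_on=0.5, tau_off=2.5, e_syn=0.0)
NMDA = SynapseParams(SynapseKind.NMDA, tau_on=2.3, tau_off=95.0, e_syn=0.0)
GABA = SynapseParams(SynapseKind.GABA, tau_on=0.5, tau_off=6.4, e_syn=-80.0)


@dataclass
class SynapseState:
    """Rise (m) and decay (h) state variables; both >= 0, decay to 0."""

    m: float = 0.0
    h: float = 0.0


def synapse_current(state: SynapseState, params: SynapseParams,
                    v_post: float) -> float:
    """Instantaneous synaptic current g_max * (h - m) * (V - E_syn)."""
    return params.g_max * (state.h - state.m) * (v_post - params.e_syn)


def advance_synapse(state: SynapseState, params: SynapseParams,
                    dt: float) -> SynapseState:
    """Advance by dt using the exact exponential solution."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return SynapseState(m=state.m * math.exp(-dt / params.tau_on),
                        h=state.h * math.exp(-dt / params.tau_off))


def event_normalization(tau_on: float, tau_off: float) -> float:
    """Increment applied to m and h per unitary event.

    Chosen so the free decay after a single event has max_t (h - m) = 1:
    the peak occurs at t* = ln(tau_off/tau_on) * tau_on*tau_off /
    (tau_off - tau_on).
    """
    t_peak = (math.log(tau_off / tau_on)
              * tau_on * tau_off / (tau_off - tau_on))
    peak = math.exp(-t_peak / tau_off) - math.exp(-t_peak / tau_on)
    return 1.0 / peak


def on_presynaptic_spike(state: SynapseState, params: SynapseParams,
                         n_events: int = 1) -> SynapseState:
    """Register n simultaneous presynaptic spikes (linear summation)."""
    if n_events == 0:
        return SynapseState(state.m, state.h)
    inc = n_events * event_normalization(params.tau_on, params.tau_off)
    return SynapseState(m=state.m + inc, h=state.h + inc)


def weighted_current(g_edge: float, i_syn) -> float:
    """Connection-weighted current I_ab = g_ab * I_syn (g_ab >= 0)."""
    if np.any(np.asarray(g_edge) < 0):
        raise ValueError("connection weight must be non-negative")
    return g_edge * i_syn
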