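# Methods

`cbgt` simulates a cortico–basal-ganglia–thalamic loop built around a
detailed medium spiny neuron (MSN), to study how striatal morphological
lesions — dendritic spine loss and dendrite-tree degeneration — and
cortical drive modulate thalamic relay fidelity under dopamine
depletion.  This note documents the models, the parameter provenance,
the numerical scheme, and what the synthetic test conditions do and do
not show.

## Circuit

Eight populations: cortical pyramidal cells (PY), direct- and
indirect-pathway medium spiny neurons (D1, D2), dopaminergic neurons
(DA), subthalamic nucleus (STN), external and internal pallidum (GPe,
GPi), and thalamus (TH).  Default sizes are 10 PY/STN/GPe/GPi/TH, 8 DA
and one detailed MSN per pathway; the singular D1/D2 follows the
lesion analyses, which manipulate a single reconstructed cell, and
keeps the multi-compartment cost tractable.  All sizes are
configurable.

Connectivity (per postsynaptic cell): D1/D2 receive all-to-one input
from every PY (AMPA+NMDA on spine sites) and every DA (excitatory on
D1, inhibitory on D2 — the modulatory action of dopamine reduced to
its net pathway signs); STN ← 3 random PY + 2 ring-neighbouring GPe;
GPe ← 2 neighbouring GPe + D2 + 2 neighbouring STN; GPi ← D1 + 2
random GPe + 2 neighbouring STN + 1 neighbouring GPi; TH ← 3 GPi; and
exactly 6 randomly chosen PY receive thalamic feedback.  "Neighbouring"
uses ring topology with wrap-around, the convention of the
subthalamopallidal network models this circuit descends from.  The
GPe→STN and D2→GPe projections are GABAergic (E = −80 mV): the
current-balance equations and the circuit description treat them as
inhibition, and we follow that over two contradictory prose mentions
of "excitatory" input.

## Single-compartment cells

All cells are conductance-based Hodgkin–Huxley models in standard
units (mV, ms, µA/cm², mS/cm², µF/cm²).  TH, GPe and GPi follow the
Rubin–Terman formulation, STN the Terman et al. subthalamopallidal
model, and PY the Pospischil et al. regular-spiking cortical neuron
(leak, Na, Kd, M-type adaptation, high-threshold Ca).  The DA cell is
a soma-only model carrying the twelve currents of its multi-compartment
ancestor — fast Na, A-type, delayed-rectifier and SK potassium, T/N/L
calcium, Na and Ca pumps, three ionic leaks.  Its kinetics are this
package's own composition of standard Hodgkin–Huxley forms, calibrated
**once** to the defining phenotype of nigral DA neurons: regular tonic pacemaking
(default ≈ 7.5 Hz, ISI CV ≈ 0.01), with the three leaks setting an
effective rest above spike threshold and the calcium-gated SK current
pacing the interspike interval.

Rest-state contracts (all verified by the test suite): TH, GPe and GPi
are silent at zero input and zero bias; STN fires tonically at ~3 Hz
when isolated and accelerates under cortical drive; PY is silent at
rest and shows spike-frequency adaptation under a step (the M
current); DA pacemakes tonically.  In-network bias currents
(I_app = 0.25 TH, 1.2 GPe/GPi, 1.2 PY µA/cm²) stand in for afferents
outside the model, as in the source models.

## The medium spiny neuron

The MSN is a stylized 121-compartment tree: one soma, 8 primary trunks
(two of four chained primary sections, six of three — 26 primary
sections), each trunk tip splitting into 2 secondary sections, each
continuing into one distal subordinate section.  That yields 58
dendritic sections, of which the 32 secondary+subordinate sections are
the lesionable pool, and 32 subordinate compartments each bearing one
glutamatergic and one dopaminergic synapse site (spines are sites, not
compartments).  The printed counts (121 compartments, 58 dendrites, 8
soma-attached trunks, 32 removable dendrites, 32+32 synapse sites) are
the testable contract; the exact branching pattern within those counts
is this package's choice, since only a schematic is available, and the
mapping of sections onto compartments (2 per section, 3 in four trunk
roots) is likewise documented here rather than inferred.  Geometry per
level (length × diameter, µm): soma 16 × 16, primary 10 × 2.25,
secondary 12 × 1.10, subordinate 15 × 0.72, axial resistivity
100 Ω·cm.

Somatic membrane carries 14 channel families (NaF, NaP, KAf, KAs,
KIR, KRP, BK, SK, CaL1.2, CaL1.3, CaN, CaQ, CaR, CaT) plus leak;
dendrites carry the same set minus KRP.  Kinetics are Boltzmann
steady-states with fixed time constants; calcium channels are ohmic
with a fixed 130 mV reversal (a deliberate simplification of GHK
flux); a pooled calcium per compartment (decay τ = 20 ms) gates SK and
BK.  The conductance set is the package's own, calibrated once to the
MSN phenotype: a
hyperpolarized KIR-dominated rest (≈ −89 mV), an input resistance of
order 10² MΩ, rheobase ≈ 0.2 nA of somatic current, and regular firing
that accelerates with input — and then frozen.  The F–I curve runs
≈ 8–15 Hz over 30–80 µA/cm² of somatic drive.

**Lesion operators.**  *Spine loss* deactivates `ns` of the 32
glutamatergic sites (fraction Ns/32).  Under dopamine depletion a
matching fraction of dopaminergic sites is marked lost; spines whose
paired dopaminergic site is lost (type-1) are removed first, then
intact-pair (type-2) sites — each glutamatergic site is paired 1:1
with the dopaminergic site on its own compartment, the simplest
pairing consistent with spines preferring to fall where the dopamine
binding site has gone.  *Dendrite degeneration* detaches `nd` of the
32 secondary/subordinate sections (fraction Nd/32) at the parent
junction and deletes the subtree, peeling distal-first (a subordinate
section before its secondary parent) so every `nd` in 0..32 is exact
and the remainder stays a soma-rooted tree.  Removing dendrites
removes membrane load, so the soma fires faster under the same
stimulus — the tests pin this monotone trend over nd ∈ {0,8,16,24,32}
— while equal-sized distal and proximal lesions change the rate by
less than the across-seed spread.

## Synapses

AMPA, NMDA and GABA-A use an Exp2Syn-style two-state scheme: m and h
decay exponentially (τ_on, τ_off), the conductance gate is (h − m),
and the current is ḡ(h − m)(V − E).  Events increment both states by
the dual-exponential peak normalization so a unitary event peaks at
exactly 1, and responses superpose linearly (which is why per-target
aggregation in the engine is exact).  Time constants: AMPA 0.5/2.5 ms,
NMDA 2.3/95 ms (no magnesium-block voltage dependence — the printed
model has none), GABA-A 0.5/6.4 ms; reversals 0/0/−80 mV.  Dopamine
synapses reuse the slow (NMDA-like) kinetics with E = 0 on D1 and
−80 mV on D2.  Connection weights are a config-level table
(`cbgt.network.DEFAULT_WEIGHTS`, recorded with every other adopted
value in `src/cbgt/data/default_params.yaml`); they were tuned once so
that the healthy network reproduces the qualitative operating point
(cortex ≈ 15 Hz, pallidum ≈ 15–20 Hz, TH relaying at ≈ 10 Hz in
rebound bursts, D1 active and D2 nearly silent under dopamine) and the
depletion contrast described below, and are not adjusted per
experiment.

## Dopamine depletion and the parkinsonian state

Depletion of fraction f removes ⌈f·n_da⌉ DA neurons (uniformly at the
seed); their synapses fall silent and ⌈32f⌉ dopaminergic sites per MSN
are marked lost.  f > 0.5 defines the PD state.  The emergent chain —
D1 loses its dopamine boost (direct-pathway inhibition of GPi
weakens), D2 is released from dopamine inhibition (GPe more
suppressed, GPi less inhibited) — raises GPi output and degrades
thalamic relay: TH mean rate falls below the healthy band and the
error index rises.  At 10% depletion the TH rate stays inside the
healthy band; the transition to significant reduction falls between
10% and 25% in this implementation (the exact location of that
threshold depends on the synaptic weight table, for which this package
ships its own calibrated defaults).

## Error index

Response events in a TH voltage trace are classified against a
*healthy reference*: the response amplitude and rhythm period measured
in a zero-depletion calibration run of the same seed (a per-trace
maximum would make the normal class tautologically non-empty).  Events
≥ 90% of the reference amplitude are normal, 10–90% incomplete, and
expected-response windows (tiles of the healthy period) with no event
above the 10% detection floor are lost.  EI = incomplete / normal;
with no normal peaks EI is reported as undefined, never as a number.
The 10% floor doubles as the event-detection cutoff.  Baselines are
the 20th percentile of the trace; burst grouping uses a 50 ms ISI gap.
All thresholds are exposed as arguments.

## Electromagnetically driven cortical neuron

The pyramidal cell is augmented with a magnetic flux φ and an AC
field: every channel current is evaluated at v + V_e with
V_e = A_e·sin(ωt), the field adds the capacitive drive
−A_e·ω·C_m·cos(ωt), and the flux feeds back through the
memconductance ρ(φ) = α + 3βφ² as k·ρ(φ)(v + V_e), with
φ′ = k_1·v − k_2·φ.  Defaults k = 0.001, k_1 = 0.1, k_2 = 1, α = 0.4,
β = 0.01.

Two readings of the printed equations were examined.  With ω taken as
rad/ms the drive is a ~1 kHz ripple of < 1 mV and no catalogued mode
transition occurs at any amplitude; with the literal pyramidal leak
(0.0205 mS/cm²) and ω as rad/s the drive produces ±250 mV unphysical
excursions.  The adopted model therefore runs the field and flux on a
slow axis (ω in rad/s, t_scale = 10⁻³ from ms) and uses a larger
field-coupling leak for the standalone EM cell (0.25 mS/cm², other
parameters unchanged), calibrated once so the catalogued
amplitude ladder appears at the catalogued values: A_e = 0.4 →
subthreshold membrane potential oscillation (SMPO, ~20 mV
peak-to-peak), 0.8 → one spike per forcing period, 2.0 → multi-spike
bursting per period; and spikes-per-burst grow monotonically with the
DC forcing current at A_e = 1.2, ω = 6.28.  One catalogued point does
not reproduce under this calibration: at A_e = 0, I_app = 3 the cell
is quiescent rather than period-1 spiking (the DC rheobase at this
leak is ≈ 5 µA/cm²), although the more-spiking-with-amplitude trend of
that scan holds.  Mode classification is heuristic — spike detection
at −20 mV with 2 ms lockout, SMPO when spikeless peak-to-peak ≥ 2 mV,
period-1 when the ISI CV < 0.05, bursts grouped by a 100 ms gap,
chaos flagged by ISI return-map dispersion — with a 2 s transient
discarded and ≥ 10 s of trace required.

The in-network cortical stimulation experiments use a plain additive
somatic current I_stim = A·sin(2πft) on every PY cell, per the
stimulation protocol's own formula; the flux model is the standalone
analysis.

## Numerics

Fixed step dt = 0.025 ms throughout.  Gating variables use
exponential-Euler updates (exact for rates frozen over one step).
Membrane potentials use a conductance-linearized implicit update —
every current is in g·(V − E) form, so
v⁺ = (C/dt·v + Σg·E + I)/(C/dt + Σg) — rather than forward/midpoint
stepping: forward Euler is unstable at this dt for the pallidal
gNa = 120 mS/cm² and for the axial coupling densities of thin distal
MSN compartments (hundreds of mS/cm²).  For the MSN the coupled cable
system is solved each step by backward-Euler Hines elimination on the
tree (compartments ordered parent-before-child).  Synaptic events are
aligned to the step grid; per-class, per-target synapse states are
aggregated (exact, by linearity).  Hot kernels are numba-jitted; the
plain-numpy `*_rhs` functions are the definitional dynamics, and the
test suite holds the two paths together (sup-norm < 1 mV over 500 ms
against an adaptive LSODA reference on subthreshold protocols, where a
sup-norm is meaningful; spiking protocols are compared by spike
count).  Halving dt changes subthreshold traces by < 0.5 mV.
Integration is deterministic; all randomness (wiring, lesion targets,
initial-condition jitter) is seeded.  A membrane potential outside
±200 mV raises a diagnostic naming the cell.

## Problem sizes

The headline protocols are ten 16-s trials per condition.  The test
suite and the acceptance script run scaled-down versions — 2-s trials,
3 seeds, with metrics computed after a 500 ms transient — chosen as
the smallest sizes at which the depletion contrast (EI ordering, TH
rate bands) is stable across seeds.  The CLI runs the full-size
protocols.

## What the synthetic conditions do not show

The generator-side fixtures (synthetic peak trains for the EI metric,
isolated-cell protocols, scaled-down network trials) validate the
machinery, orderings and trends, not exact magnitudes: the synaptic
weight table and several cell parameter sets are this package's own
calibrated defaults, so EI curves and sweep intervals are qualitative,
and headline numbers (the exact depletion threshold for thalamic
slowing, the spine-loss window that restores relay) shift under
different weight tables.  Conduction delays, short-term plasticity,
receptor desensitization, stochastic channel noise, GHK calcium flux
and explicit spine compartments are out of scope by design.
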