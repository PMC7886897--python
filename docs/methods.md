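# Methods

This note documents the models implemented in `stellate`, their
assumptions, the calibration choices that were genuinely open, and what
the test suite does and does not establish.

## The stellate-cell model

Cerebellar stellate cells (SCs) are small inhibitory interneurons of the
outer molecular layer. The model is a conductance-based compartmental
neuron with five electrotonic compartment classes — soma, proximal
dendrite, distal dendrite, axon initial segment (AIS) and axon — carved
out of a detailed morphology at a dendritic diameter cut-off of 0.6 µm.
Passive properties follow the experimental constraints: axial
resistivity 110 Ω·cm everywhere, membrane capacitance 1.5 µF/cm² on
dendrites and 1.0 µF/cm² elsewhere, an ohmic leak of 3·10⁻⁵ S/cm² with
E_leak = −48 mV, and fixed reversal potentials E_Na = 60, E_K = −84,
E_Ca = 137.5, E_h = −34 mV (no Nernst updating; Ca currents use the
ohmic driving force implied by the fixed Ca reversal, not GHK).

### Electrotonic reduction

The simulated cell uses a ten-compartment reduction of the morphology:
soma (cylinder matched to the ~42 µm² somatic surface), one proximal
equivalent cylinder (40 × 1.8 µm), three distal equivalent compartments
in series (60 × 1.5 µm), three thin *synaptic branchlets* (90 × 0.25 µm,
one per distal compartment), the 28-µm AIS and a compact axonal
compartment. Equivalent-cylinder diameters exceed the anatomical 0.6-µm
cut-off — class labels, not reduced diameters, carry the
proximal/distal distinction — and the total reduced membrane (~1430 µm²)
sits below the raw anatomical area: part of the arbor is
electrotonically remote, and the measured input resistance and the
depth of hyperpolarizing excursions (with the fixed leak, the −16 pA
floor is E_leak − 16 pA/g_leak) pin down the *effective* load the soma
sees. The branchlets represent the
sub-0.6-µm terminal branches that host parallel-fiber (PF) synapses in
the real cell: their few hundred MΩ of series resistance reproduces the
local saturation that keeps physiologically large synaptic conductances
from overwhelming a ~0.75 GΩ neuron. Without them the reduced cell
depolarization-blocks under a 3-synapse PF burst, which the real cell
demonstrably does not.

### Channels

Fourteen mechanisms populate the model: Nav1.1, Nav1.6, Kv3.4, Kv4.3,
Kv1.1, Kir2.3, Kv7, KCa1.1 (BK), KCa2.2 (SK), Cav2.1 (P/Q), Cav3.2 and
Cav3.3 (T-type), HCN1 and leak. Their kinetics are expressed in a
uniform Hodgkin–Huxley parameterization (Boltzmann steady states,
bell-shaped time constants; a Ca-Hill gate for SK and a Ca-shifted
Boltzmann for BK). The kinetic constants are this package's own fits in
the spirit of the cerebellar modelling literature for each isoform; the
published multi-state Markov schemes are not reproduced verbatim. All
constants are plain data on the specs and are stated at 32 °C, the
simulation temperature; running at another temperature applies Q10 = 3
to every time constant.

Functionally, the division of labour is: a persistent Nav1.6 window
current plus the depolarized leak reversal and the T-type window drive
pacemaking; Kv3.4 (with slowed subthreshold deactivation) and BK
repolarize the spike and carry the trough low enough to re-prime Na;
HCN1 produces the hyperpolarizing sag and contributes to rebound; its
gate is deliberately steep and slow (half-activation −68 mV, slope
4 mV, τ up to ~850 ms) so that it is nearly unrecruited during
pacemaking, activates over hundreds of milliseconds during a
hyperpolarizing step (letting the step reach its passive floor before
the sag develops), and is largely saturated below −75 mV (so a brief
voltage-clamp pulse from −70 mV measures mostly driving-force, not
fresh conductance — which is what reconciles a ~10-mV sag with a
~0.8 GΩ input resistance); Cav3.2/3.3
de-inactivate during hyperpolarization and drive rebound bursting;
Kv4.3 (A-type) delays the rebound first spike; SK and Ca-fed BK set
adaptation and the post-burst AHP; Kir2.3 adds inward rectification.
These attributions are asserted as knockout-directionality tests.

Each compartment carries a single sub-membrane calcium shell (0.2 µm
deep). Parvalbumin-like buffering is folded into a constant buffering
capacity ratio κ = 60 that scales influx, and free Ca relaxes to 50 nM
with τ = 20 ms. This is the minimal pool that couples Cav influx to
BK/SK; it does not model buffer saturation or diffusion.

### Conductance optimization

The 36 free parameters are the maximum conductance densities of the
(channel × compartment-class) layout — 12 somatic, 8 proximal, 7
distal, 5 AIS and 4 axonal slots; the leak is fixed. The layout itself
is a declared assumption (the experimental localization is known only
graphically): Na and fast rectifiers concentrate in soma/AIS/axon,
A-type/Ca/KCa extend into dendrites, HCN1 is somatodendritic.

Optimization is an Indicator-Based Evolutionary Algorithm (IBEA,
additive ε-indicator, κ = 0.05) over log-conductance space with uniform
crossover and multiplicative Gaussian mutation; NSGA-II selection is
available as an option. Objectives are SEM-normalized absolute errors
of twelve features measured from the standard battery (2-s steps at 0,
+4, +16, −16 pA): spontaneous rate 24.2 ± 2.1 Hz, step rates placed on
the 2.13 Hz/pA frequency–current line (32.7 ± 2.5 and 58.3 ± 3.5 Hz,
since per-step rates are not tabulated), spike half-width 1.0 ± 0.2 ms,
spike amplitude 37.3 ± 5.2 mV, sag 10.3 ± 2.0 mV, rebound first-spike
delay 17.2 ± 2.3 ms and first ISI 20.1 ± 1.0 ms, plus the 100-Hz PF
burst increase 154.5 ± 40.5 % and the 0.75 ± 0.06 GΩ input resistance.
Folding the two synaptic/passive constraints into the fitness is this
package's choice: models in the source study were optimized on somatic
steps alone but retained only when they also matched synaptic
responsiveness; at desk scale a single objective vector is the cleaner
equivalent. The full-scale preset is 100 × 50; the desk preset (default)
refines 20 × 10 in bounds centred on the stored reference set
(`SC_REFERENCE_GENOME`), which is the hall-of-fame product of this
package's own longer runs.

### Numerics

The cable equation is integrated with the theta method (Crank–Nicolson
by default, backward Euler as a flag) at a fixed 0.025-ms step; gates
use exact exponential integration against their (steady state, τ) at
the current voltage, calcium pools relax exactly toward their influx
fixed point, and the tree-structured linear system is solved directly
(Hines elimination), so cost is linear in compartment count. The inner
loop is numba-compiled. Voltage clamp is ideal (the clamped node is
pinned by a penalty term; the recorded clamp current is the sum of
membrane and axial currents there). Spike detection for event streams
is an upward crossing of −20 mV with a 1-ms refractory; the
second-derivative threshold estimate is a measurement, not the
detector. Network spikes propagate to target synapses with a 1-ms
delay. The pacemaking limit cycle shows a weak period-2 ISI alternation
(±1 ms) whose phase is step-size sensitive; convergence under dt
halving therefore holds for early spike times and mean rate rather than
for every late spike time.

## Synapses

Presynaptic dynamics follow the Tsodyks–Markram resource/utilization
recursion, in the variant that applies the facilitation increment
before computing release, so the first pulse from rest releases exactly
p. Parameters are the recorded sets: PF→SC AMPA p = 0.15, τ_R = 35.1 ms,
τ_F = 10.8 ms, 2300 pS, E = 0 mV; PF→SC NMDA (NR2B-like) p = 0.15,
τ_R = 8 ms, τ_F = 5 ms, 10000 pS, E = −3.7 mV; SC GABA_A p = 0.42,
τ_R = 38.7 ms, τ_F = 0 (purely depressing), 1600 pS, E = −65 mV.
"Facilitation off" multiplies τ_F by 10; "depression off" sets τ_R = 0.

Receptor conductances are event-triggered waveforms: instantaneous rise
with single-exponential decay for AMPA (1.8 ms) and GABA_A (11 ms), and
a normalized rise/decay difference of exponentials for NMDA
(rise 10 ms, decay 220 ms) with sigmoidal Mg block. Three NMDA choices
deserve explanation, since the underlying multi-state scheme is not
reproduced here:

* the published per-synapse maximum (10000 pS) is treated as the
  channel-level ceiling of that scheme, whose peak open probability is
  well below one; the two-state reduction carries peak_open = 0.07;
* release increments scale with the unoccupied receptor fraction
  (occupancy saturation), which caps the slow NMDA build-up during
  trains — the physical behaviour of a receptor pool that cannot exceed
  all-channels-open;
* the Mg voltage sensitivity is 0.045/mV (shallower than the classic
  0.062), consistent with the weaker block of NR2B-containing receptors.

peak_open, the NMDA decay and the branchlet dimensions were calibrated
once, jointly, so that (i) the 20-pulse EPSC gain curve of the SC under
−70 mV clamp is sigmoidal with half-maximal frequency near 50 Hz, the
study's stated synaptic signature, and (ii) the free-membrane burst
drive keeps the cell firing throughout a 100-Hz train (no
depolarization block) in the range of the observed ~150 % rate
increase. These two constraints pull in opposite directions — the clamp
envelope wants a large slow conductance, the free membrane a small one
— and the calibration sits at their intersection. Gain here is the maximum
absolute clamp-current response during the train divided by the first
EPSC; per-pulse amplitudes (peak minus the mean of the preceding 1 ms)
are used for train-shape comparisons. The half-frequency comes from a
4-parameter logistic fit in log frequency (multi-start, preferring
midpoints inside the sampled range, since mildly non-monotone curves
otherwise destabilize the fit).

## The microcircuit and the Purkinje-cell stand-in

The circuit wires PF inputs to one (optionally two) SCs and a Purkinje
cell (PC): 100 PF→PC synapses on branch II, 3 PF→SC synapses per SC,
25–300 SC→PC GABA synapses restricted to branches I–II (branch III
never receives inhibition), and optionally 32 SC→SC synapses (one-way,
second SC onto the first, per the source wiring; a reciprocal mode is a
config choice away). Placement is seeded-random over the permitted
compartments.

The PC is an explicit stand-in, not a reproduction of any published
detailed model: a six-compartment pacemaker (~35 Hz) using the same
channel library, with branch I/II/III dendritic classes in centrifugal
order (trunk 200 × 6 µm, two spiny branch-II sections 160 × 2 µm, tuft
250 × 2.5 µm). Its Ca-activated K densities are kept low so the cell's
gain is ~0.12 Hz/pA — with the stronger BK/SK brake first tried, the
stand-in was rate-clamped and could not express burst responses at all.
Its PF synapse (p = 0.05, τ_R = 80 ms, τ_F = 200 ms, 5500 pS, 0.8-ms
decay with occupancy saturation) is calibrated so its EPSC gain
half-frequency lands near 10 Hz — the property that matters for
filtering, since the SC's ~50 Hz versus the PC's ~10 Hz is what
converts feed-forward inhibition into low-pass filtering of PC
responses. SC→PC inhibition keeps the recorded presynaptic parameters
but uses an 18-ms receptor decay (postsynaptic kinetics belong to the
target cell and PC GABA-A receptors are slower than the SC's
α1-dominated ones). PC burst gain is normalized to the same
condition's 4-Hz response. Response-onset latency uses 10-ms PSTH bins
over trials whose train onset is jittered against the pacemaking phase;
onset is the first pair of consecutive bins exceeding the pre-stimulus
baseline by two baseline standard deviations. The SC's own burst delay
uses the half-rise latency instead (first bin halfway between baseline
and peak rate): the SC response ramps up as facilitation builds, and a
single phase-advanced pacemaker spike in the first bins would otherwise
masquerade as an instant response. The canonical 40-ms PSTH bin is too
coarse to resolve a ~50-ms latency, so both latency measures use 10-ms
bins over onset-jittered trials.

## The synthetic morphology generator

The generator emulates the printed morphometric summary of the
reconstructed cells: soma surface 42.4 ± 9.3 µm², total dendritic
length 845.2 ± 121.2 µm, ~11 proximal and ~63.5 distal segments, 3–4
dendritic trees, a 28.0 ± 6.7 µm AIS continuing into a 577.9 ± 225.0 µm
branched axon. It builds the branching topology first (every expansion
adds two daughters), then assigns diameters by centrifugal rank so the
proximal/distal counts are met exactly at the 0.6-µm cut-off, then
lengths (jittered equal shares rescaled to the sampled total), then 3D
positions (trees radiate in the sagittal plane; orientation carries no
physiology). What it does *not* emulate: realistic tortuosity, 3D space
filling, diameter noise within segments, or the four specific
reconstructed cells — so tests passing on generated cells show the
pipeline works on cells with the right summary statistics, not that any
particular biological reconstruction is reproduced.

## Problem sizes and tolerances

Default experiment sizes used throughout the package: 2-s steps for
electroresponsiveness, 10 s for spontaneous-rate estimates, 3–5 s for
PF-burst runs, 8–10 trials for PSTH latencies, and three input
frequencies per condition for circuit filtering summaries; the
desk-scale optimization preset refines 14–20 individuals for 6–10
generations around the reference set. These sizes give
SEM-of-measurement well inside the experimental SEM bands they are
compared against. Acceptance-style checks use the experimental
mean ± 2·SEM bands; exact numerical identities (TM fixed point, RC and
cable closed forms, kernel-vs-reference equivalence) are asserted at
1e−9.

## Known limitations

* Channel kinetics are package-authored HH fits, not the original
  Markov schemes; absolute conductance densities are therefore not
  comparable to the source models, only the emergent physiology is.
* The PC stand-in reproduces pacemaking, burst-pause and synaptic gain
  qualitatively; its absolute firing rates and morphology are not
  Purkinje-realistic.
* Ca handling is a single shell per compartment with a constant buffer
  ratio; no radial diffusion, buffer saturation, or ER handling.
* The ISI alternans noted above means spike-by-spike reproducibility
  across step sizes degrades over multi-second runs even though rates
  and all reported statistics converge.
* The reduced model's per-synapse burst efficacy is higher than the
  recorded one: three PF synapses raise the firing rate by ~200 %
  rather than ~155 %, and the burst band is already reached with two
  synapses under a band-entry reading of the calibration. Relatedly,
  the burst's PSTH half-rise sits near 20 ms rather than ~50 ms: the
  very first PF volleys phase-advance the pacemaker, where the full
  60-segment arbor of the source cells attenuates unitary volleys more
  strongly. Both are structural limits of the ten-compartment
  reduction, not of the synapse model.
* Voltage clamp is ideal; series-resistance artefacts of real
  recordings are intentionally out of scope.
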