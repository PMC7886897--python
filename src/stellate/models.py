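"""Stellate-cell model construction.

The detailed morphology is reduced to a ten-compartment electrical
backbone covering the five electrotonic classes: soma, one proximal
dendritic equivalent cylinder, three distal dendritic compartments in
series, three thin synaptic branchlets carrying the excitatory PF
synapses (standing in for the sub-cut-off terminal branches of the
full arbor), the axon initial segment, and one axonal compartment.
Because parallel dendritic trees are merged, equivalent diameters
exceed the anatomical 0.6-um cut-off -- the class labels, not the
reduced diameters, carry the proximal/distal distinction -- and the
total membrane is the *effective* electrotonic load rather than the
raw anatomical area (see docs/methods.md).

The 36 free maximum conductances (channel x compartment-class slots)
form the optimization genome.  ``SC_REFERENCE_GENOME`` is the
hall-of-fame parameter set produced by the package's own evolutionary
optimization against the experimental feature targets; optimizations
seed their bounds around it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .channels import CONDUCTANCE_SLOTS, CalciumPool, G_LEAK_DEFAULT
from .morphology import Morphology, MorphometricTargets, generate_sc_morphology, morphometrics
from .protocols import StepProtocol, TrainProtocol, train_times
from .solver import CompartmentalModel, Simulation, TraceSet, DT_DEFAULT
from .synapses import PF_SC_AMPA, PF_SC_NMDA, SC_GABAA, SynapseType

__all__ = [
    "ReductionGeometry",
    "SCCell",
    "build_sc_cell",
    "genome_to_conductances",
    "SC_REFERENCE_GENOME",
    "FEATURE_TARGETS",
    "run_step",
    "run_train",
]


@dataclass(frozen=True)
class ReductionGeometry:
    """(length, diameter) of each reduced compartment, um."""

    soma: tuple[float, float] = (3.67, 3.67)
    proximal: tuple[float, float] = (40.0, 1.8)
    distal: tuple[float, float] = (60.0, 1.5)  # each of three in series
    branchlet: tuple[float, float] = (90.0, 0.25)  # thin PF-synapse carrier
    ais: tuple[float, float] = (28.0, 0.6)
    axon: tuple[float, float] = (80.0, 0.6)

    #: fraction of the anatomical dendritic membrane carried by the
    #: reduced cylinders.  Part of the arbor is electrotonically remote
    #: and contributes little to the somatic load; matching the measured
    #: input resistance and hyperpolarization depth requires an
    #: effective area below the raw anatomical total.
    DENDRITIC_LOAD_FRACTION = 0.78

    @staticmethod
    def from_morphology(morph: Morphology) -> "ReductionGeometry":
        """Equivalent cylinders from a morphology's per-class membrane
        area, scaled by the electrotonic load fraction."""
        mm = morphometrics(morph)
        d_soma = math.sqrt(mm["soma_surface_um2"] / math.pi)
        # split dendritic area by segment-count proportions
        n_p = max(mm["proximal_segment_count"], 1)
        n_d = max(mm["distal_segment_count"], 1)
        area_d = sum(s.surface() for s in morph.by_label("dendrite"))
        area_d *= ReductionGeometry.DENDRITIC_LOAD_FRACTION
        frac_p = n_p / (n_p + n_d) * 1.6  # proximal segments are thicker
        frac_p = min(frac_p, 0.5)
        a_prox = area_d * frac_p
        a_dist = area_d - a_prox
        l_prox = 40.0
        l_dist = 60.0
        ais_l = max(mm["ais_length_um"], 5.0)
        return ReductionGeometry(
            soma=(d_soma, d_soma),
            proximal=(l_prox, a_prox / (math.pi * l_prox)),
            distal=(l_dist, (a_dist / 3.0) / (math.pi * l_dist)),
            ais=(ais_l, 0.6),
        )


def genome_to_conductances(genome: Sequence[float]) -> dict[tuple[str, str], float]:
    """Map the 36-vector genome onto the (class, channel) slots."""
    if len(genome) != len(CONDUCTANCE_SLOTS):
        raise ValueError(f"genome must have {len(CONDUCTANCE_SLOTS)} entries")
    if any(g < 0 for g in genome):
        raise ValueError("conductances must be non-negative")
    return dict(zip(CONDUCTANCE_SLOTS, (float(g) for g in genome)))


#: reference optimized conductance set (S/cm^2), ordered as
#: channels.CONDUCTANCE_SLOTS.  Produced by the package's IBEA run
#: against FEATURE_TARGETS; optimizations use it to centre their bounds.
SC_REFERENCE_GENOME: tuple[float, ...] = (
    # soma: Nav1.1 Nav1.6 Kv3.4 Kv4.3 Kv1.1 Kir2.3 Kv7 KCa1.1 KCa2.2 Cav2.1 Cav3.2 HCN1
    0.163879, 0.0418586, 0.0659594, 0.00372961, 0.00295163, 2.70383e-05, 0.000307139, 0.0165358, 0.000278509, 0.00334507, 0.00131753, 0.00188198,
    # proximal dendrite: Kv4.3 Kv1.1 KCa1.1 KCa2.2 Cav2.1 Cav3.2 Cav3.3 HCN1
    0.00704915, 0.0011909, 0.00407746, 8.63167e-05, 0.000356447, 0.000960467, 0.000211482, 0.000108336,
    # distal dendrite: Kv4.3 Kv1.1 KCa1.1 KCa2.2 Cav2.1 Cav3.2 Cav3.3
    0.000192477, 7.2141e-05, 0.00365509, 7.99516e-05, 0.000137854, 0.000440436, 8.67368e-05,
    # AIS: Nav1.6 Kv3.4 Kv1.1 Kv7 Cav2.1
    0.20016, 0.119576, 0.00240012, 0.000335477, 8.97473e-05,
    # axon: Nav1.6 Kv3.4 Kv1.1 KCa1.1
    0.0182424, 0.034241, 0.0015015, 0.00420413,
)

_CLASS_OF_COMP = {
    "soma": "soma",
    "prox": "proximal_dendrite",
    "dist1": "distal_dendrite",
    "dist2": "distal_dendrite",
    "dist3": "distal_dendrite",
    "ais": "ais",
    "axon": "axon",
}


@dataclass
class SCCell:
    """A runnable stellate cell: reduced model + synapse placement."""

    model: CompartmentalModel
    geometry: ReductionGeometry
    genome: tuple[float, ...]
    leak: float = G_LEAK_DEFAULT

    @property
    def soma(self) -> int:
        return self.model.index("soma")

    @property
    def distal_indices(self) -> list[int]:
        return [self.model.index(n) for n in ("dist1", "dist2", "dist3")]

    @property
    def pf_target_indices(self) -> list[int]:
        """Thin distal branchlets carrying the excitatory PF synapses."""
        return [self.model.index(n) for n in ("syn1", "syn2", "syn3")]

    @property
    def dendrite_indices(self) -> list[int]:
        return [self.model.index(n) for n in ("prox", "dist1", "dist2", "dist3")]


def build_sc_cell(
    genome: Optional[Sequence[float]] = None,
    geometry: Optional[ReductionGeometry] = None,
    morph: Optional[Morphology] = None,
    leak: float = G_LEAK_DEFAULT,
) -> SCCell:
    """Assemble a stellate cell from a conductance genome and a reduced
    geometry (either given directly or derived from a morphology)."""
    if geometry is None:
        geometry = (
            ReductionGeometry.from_morphology(morph) if morph is not None else ReductionGeometry()
        )
    genome = tuple(genome) if genome is not None else SC_REFERENCE_GENOME
    gmap = genome_to_conductances(genome)

    m = CompartmentalModel()

    def conds(cls: str) -> dict[str, float]:
        out = {"leak": leak}
        for (c, ch), val in gmap.items():
            if c == cls and val > 0:
                out[ch] = val
        return out

    pool = CalciumPool()
    soma = m.add("soma", "soma", *geometry.soma, conductances=conds("soma"), ca_pool=pool)
    prox = m.add(
        "prox",
        "proximal_dendrite",
        *geometry.proximal,
        parent=soma,
        conductances=conds("proximal_dendrite"),
        ca_pool=CalciumPool(),
    )
    prev = prox
    dist = []
    for k in range(3):
        prev = m.add(
            f"dist{k + 1}",
            "distal_dendrite",
            *geometry.distal,
            parent=prev,
            conductances=conds("distal_dendrite"),
            ca_pool=CalciumPool(),
        )
        dist.append(prev)
    for k, parent in enumerate(dist):
        m.add(
            f"syn{k + 1}",
            "distal_dendrite",
            *geometry.branchlet,
            parent=parent,
            conductances=conds("distal_dendrite"),
            ca_pool=CalciumPool(),
        )
    ais = m.add("ais", "ais", *geometry.ais, parent=soma, conductances=conds("ais"))
    m.add("axon", "axon", *geometry.axon, parent=ais, conductances=conds("axon"))
    return SCCell(model=m, geometry=geometry, genome=genome, leak=leak)


# ---------------------------------------------------------------------------
# Experimental feature targets (mean, SEM) used as optimization objectives.
# Firing rates for the +4/+16 pA steps are placed on the model's linear
# frequency-current relation (slope 2.13 Hz/pA through the 24.2-Hz
# spontaneous rate), since the per-step rates are not tabulated.

from .features import FeatureTarget  # noqa: E402

FEATURE_TARGETS: tuple[FeatureTarget, ...] = (
    FeatureTarget("freq_0pA", 24.2, 2.1, "step_0"),
    FeatureTarget("freq_4pA", 32.7, 2.5, "step_4"),
    FeatureTarget("freq_16pA", 58.3, 3.5, "step_16"),
    FeatureTarget("sag_16pA", 10.3, 2.0, "step_-16"),
    FeatureTarget("ap_half_width", 1.0, 0.2, "step_0"),
    FeatureTarget("ap_amplitude", 37.3, 5.2, "step_0"),
    FeatureTarget("rebound_delay", 17.2, 2.3, "step_-16"),
    FeatureTarget("rebound_first_isi", 20.1, 1.0, "step_-16"),
    FeatureTarget("burst_100hz_pct", 154.5, 40.5, "pf_train_100"),
    FeatureTarget("burst_median_latency", 65.0, 8.0, "pf_train_100"),
    FeatureTarget("r_input", 0.75, 0.06, "passive"),
)


def run_step(
    cell: SCCell,
    amp_pA: float,
    duration_ms: float = 2000.0,
    pre_ms: float = 1000.0,
    post_ms: float = 1000.0,
    dt: float = DT_DEFAULT,
    integrator: str = "cn",
    record_stride: int = 1,
) -> TraceSet:
    """Somatic current step on the quiescent/pacemaking cell."""
    sim = Simulation(cell.model, dt=dt, integrator=integrator)
    sim.record_v([cell.soma])
    sim.add_source(cell.soma)
    if amp_pA != 0.0:
        sim.add_step(cell.soma, pre_ms, pre_ms + duration_ms, amp_pA)
    ts = sim.run(pre_ms + duration_ms + post_ms, record_stride=record_stride)
    ts.events["step"] = np.array([pre_ms, pre_ms + duration_ms])
    return ts


def run_train(
    cell: SCCell,
    train: TrainProtocol,
    duration_ms: float = 5000.0,
    nmda: bool = True,
    inhibitory_streams: Optional[Sequence[np.ndarray]] = None,
    placement_seed: int = 0,
    dt: float = DT_DEFAULT,
    record_stride: int = 4,
) -> TraceSet:
    """PF burst onto the pacemaking cell, optionally against a GABA
    background placed randomly over the dendritic compartments."""
    sim = Simulation(cell.model, dt=dt)
    sim.record_v([cell.soma])
    sim.add_source(cell.soma)
    tt = train_times(train)
    dist = cell.pf_target_indices
    for k in range(train.n_synapses):
        comp = dist[k % len(dist)]
        sim.add_synapse(PF_SC_AMPA, comp, tt)
        if nmda:
            sim.add_synapse(PF_SC_NMDA, comp, tt)
    if inhibitory_streams:
        rng = np.random.default_rng(placement_seed)
        dend = cell.dendrite_indices
        for stream in inhibitory_streams:
            comp = dend[rng.integers(len(dend))]
            sim.add_synapse(SC_GABAA, comp, stream)
    ts = sim.run(duration_ms, record_stride=record_stride)
    ts.events["train"] = tt
    return ts
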