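"""PF -> SC -> PC microcircuit: feed-forward inhibition of a reduced
Purkinje cell by stellate cells.

The Purkinje cell here is an explicit *stand-in*: a six-compartment
conductance-based pacemaker with three dendritic branch classes ordered
centrifugally (branch I trunk, branch II spiny region, branch III
distal tuft).  Parallel-fiber synapses land on branch II, ascending-axon
synapses would land on branch III, and inhibitory synapses are
restricted to branches I-II (branch III carries none).  Its PF-synapse
short-term plasticity is calibrated so the EPSC gain half-frequency
falls near 10 Hz, an order of magnitude below the stellate cell's
~50 Hz, which is what makes the pair act as a frequency filter.

Wiring follows the reference circuit counts: 100 PF synapses on the PC,
3 PF synapses on each SC, 25-300 SC synapses on the PC, and (optionally)
32 synapses from a second SC onto the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .channels import CalciumPool
from .models import SCCell, build_sc_cell, run_train
from .features import PSTH, burst_rate_change, psth, response_onset, train_stats
from .protocols import (
    InhibitoryBackground,
    PF_TRAIN_FREQS,
    TrainProtocol,
    realize_events,
    train_times,
)
from .solver import CompartmentalModel, Simulation, TraceSet
from .synapses import (
    PF_SC_AMPA,
    PF_SC_NMDA,
    SC_GABAA,
    ReceptorKinetics,
    SynapseType,
    TMParams,
    gain_curve,
    measure_epsc_amplitudes,
)

__all__ = [
    "PF_PC_AMPA",
    "PCCell",
    "build_pc_cell",
    "CircuitConfig",
    "Circuit",
    "build_circuit",
    "run_filtering",
    "FilterReport",
    "sc_gain_experiment",
    "calibrate_pf_count",
    "epsc_gain_half_frequency",
]

#: PF->PC synapse: long facilitation and slow recovery push the EPSC
#: gain half-frequency down to ~10 Hz (calibrated; the underlying
#: constants are not published numerically).
PF_PC_AMPA = SynapseType(
    "PF-PC AMPA",
    TMParams(p=0.05, tau_r=80.0, tau_f=200.0),
    ReceptorKinetics("exp", tau_decay=0.8, saturating=True),
    g_max_pS=5500.0,
    e_rev_mV=0.0,
)

#: SC->PC inhibition: same recorded presynaptic parameters as SC->SC,
#: but the Purkinje-cell GABA-A receptors decay more slowly than the
#: stellate cell's alpha1-dominated ones (postsynaptic kinetics are a
#: property of the target cell; calibrated within the reported range)
SC_PC_GABAA = SynapseType(
    "SC-PC GABA-A",
    SC_GABAA.tm,
    ReceptorKinetics("exp", tau_decay=18.0),
    g_max_pS=SC_GABAA.g_max_pS,
    e_rev_mV=SC_GABAA.e_rev_mV,
)

#: conductance densities (S/cm^2) of the reduced Purkinje stand-in
_PC_CONDUCTANCES: dict[str, dict[str, float]] = {
    "soma": {
        "leak": 3e-5,
        "Nav1.6": 0.30,
        "Nav1.1": 0.08,
        "Kv3.4": 0.12,
        "Kv1.1": 0.002,
        "Kv7": 0.0003,
        "KCa1.1": 0.0008,
        "KCa2.2": 0.0001,
        "Cav2.1": 0.0015,
        "HCN1": 0.0008,
    },
    "branch1": {
        "leak": 3e-5,
        "Kv4.3": 0.001,
        "Kv1.1": 0.001,
        "KCa1.1": 0.0004,
        "KCa2.2": 0.0001,
        "Cav2.1": 0.001,
        "HCN1": 0.0003,
    },
    "branch2": {
        "leak": 3e-5,
        "Kv4.3": 0.001,
        "Kv1.1": 0.0005,
        "KCa1.1": 0.0003,
        "KCa2.2": 0.0001,
        "Cav2.1": 0.00025,
    },
    "branch3": {
        "leak": 3e-5,
        "Kv4.3": 0.001,
        "Kv1.1": 0.0005,
        "KCa1.1": 0.0003,
        "KCa2.2": 0.0001,
        "Cav2.1": 0.00025,
    },
    "ais": {"leak": 3e-5, "Nav1.6": 1.2, "Kv3.4": 0.15, "Kv1.1": 0.002},
}


@dataclass
class PCCell:
    """Reduced Purkinje cell with named branch compartments."""

    model: CompartmentalModel

    @property
    def soma(self) -> int:
        return self.model.index("soma")

    @property
    def branch2_indices(self) -> list[int]:
        return [self.model.index(n) for n in ("branch2a", "branch2b")]

    @property
    def branch3_index(self) -> int:
        return self.model.index("branch3")

    @property
    def inhibitory_targets(self) -> list[int]:
        """Branches I and II only; branch III never receives inhibition."""
        return [self.model.index(n) for n in ("branch1", "branch2a", "branch2b")]


def build_pc_cell() -> PCCell:
    """Assemble the reduced Purkinje stand-in."""
    m = CompartmentalModel()
    soma = m.add("soma", "soma", 35.0, 35.0,
                 conductances=_PC_CONDUCTANCES["soma"], ca_pool=CalciumPool())
    b1 = m.add("branch1", "proximal_dendrite", 200.0, 6.0, parent=soma,
               conductances=_PC_CONDUCTANCES["branch1"], ca_pool=CalciumPool())
    m.add("branch2a", "distal_dendrite", 160.0, 2.0, parent=b1,
          conductances=_PC_CONDUCTANCES["branch2"], ca_pool=CalciumPool())
    m.add("branch2b", "distal_dendrite", 160.0, 2.0, parent=b1,
          conductances=_PC_CONDUCTANCES["branch2"], ca_pool=CalciumPool())
    m.add("branch3", "distal_dendrite", 250.0, 2.5, parent=b1,
          conductances=_PC_CONDUCTANCES["branch3"], ca_pool=CalciumPool())
    m.add("ais", "ais", 30.0, 1.5, parent=soma,
          conductances=_PC_CONDUCTANCES["ais"])
    return PCCell(model=m)


@dataclass(frozen=True)
class CircuitConfig:
    n_pf_to_pc: int = 100
    n_pf_to_sc: int = 3
    n_sc_to_pc: int = 100  # one of {25, 50, 100, 200, 300} in the sweeps
    n_sc_to_sc: int = 32
    sc_sc_enabled: bool = False
    sc_connected: bool = True  # False disconnects SC->PC (control)
    placement_seed: int = 0

    def __post_init__(self):
        for f in ("n_pf_to_pc", "n_pf_to_sc", "n_sc_to_pc", "n_sc_to_sc"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


class ConstraintError(ValueError):
    pass


@dataclass
class Circuit:
    """Merged multi-cell model plus wiring metadata."""

    model: CompartmentalModel
    config: CircuitConfig
    pc_soma: int
    sc1_soma: int
    sc2_soma: Optional[int]
    pf_pc_targets: list[int]
    pf_sc_targets: list[int]
    sc_pc_synapses: list[int]  # target compartments for SC1->PC GABA
    sc_sc_synapses: list[int]  # target compartments for SC2->SC1 GABA

    def simulation(
        self,
        train: Optional[TrainProtocol] = None,
        dt: float = 0.025,
        synaptic_delay_ms: float = 1.0,
    ) -> Simulation:
        """Build a runnable simulation; PF events drive both PC and SC1
        (and SC2 when present), SC spikes propagate through GABA synapses."""
        sim = Simulation(self.model, dt=dt)
        sim.record_v([self.pc_soma, self.sc1_soma])
        sim.add_source(self.pc_soma)
        sim.add_source(self.sc1_soma)
        if self.sc2_soma is not None:
            sim.add_source(self.sc2_soma)
            sim.record_v([self.pc_soma, self.sc1_soma, self.sc2_soma])
        tt = train_times(train) if train is not None else np.zeros(0)
        for comp in self.pf_pc_targets:
            sim.add_synapse(PF_PC_AMPA, comp, tt)
        for comp in self.pf_sc_targets:
            sim.add_synapse(PF_SC_AMPA, comp, tt)
            sim.add_synapse(PF_SC_NMDA, comp, tt)
        if self.config.sc_connected:
            for comp in self.sc_pc_synapses:
                s = sim.add_synapse(SC_PC_GABAA, comp)
                sim.connect(self.sc1_soma, s, delay_ms=synaptic_delay_ms)
        for comp in self.sc_sc_synapses:
            s = sim.add_synapse(SC_GABAA, comp)
            sim.connect(self.sc2_soma, s, delay_ms=synaptic_delay_ms)
        return sim


def build_circuit(
    config: CircuitConfig,
    sc_genome: Optional[Sequence[float]] = None,
) -> Circuit:
    """Wire the PF -> SC -> PC circuit with seeded random placement."""
    rng = np.random.default_rng(config.placement_seed)
    pc = build_pc_cell()
    merged = CompartmentalModel()
    merged.merge(pc.model, prefix="pc.")
    sc1 = build_sc_cell(sc_genome)
    off1 = merged.merge(sc1.model, prefix="sc1.")
    sc2_soma = None
    sc_sc_targets: list[int] = []
    if config.sc_sc_enabled:
        sc2 = build_sc_cell(sc_genome)
        off2 = merged.merge(sc2.model, prefix="sc2.")
        sc2_soma = merged.index("sc2.soma")

    pc_b2 = [merged.index(n) for n in ("pc.branch2a", "pc.branch2b")]
    pc_inh = [merged.index(n) for n in ("pc.branch1", "pc.branch2a", "pc.branch2b")]
    pc_b3 = merged.index("pc.branch3")
    if pc_b3 in pc_inh:
        raise ConstraintError("branch III must not receive inhibitory synapses")
    sc1_dist = [merged.index(f"sc1.syn{k}") for k in (1, 2, 3)]
    sc1_dend = [merged.index(n) for n in ("sc1.prox", "sc1.dist1", "sc1.dist2", "sc1.dist3")]

    pf_pc = [pc_b2[rng.integers(len(pc_b2))] for _ in range(config.n_pf_to_pc)]
    pf_sc = [sc1_dist[k % 3] for k in range(config.n_pf_to_sc)]
    if config.sc_sc_enabled:
        pf_sc += [merged.index(f"sc2.syn{(k % 3) + 1}") for k in range(config.n_pf_to_sc)]
        sc2_dend = [merged.index(n) for n in ("sc1.prox", "sc1.dist1", "sc1.dist2", "sc1.dist3")]
        sc_sc_targets = [sc1_dend[rng.integers(len(sc1_dend))] for _ in range(config.n_sc_to_sc)]
    sc_pc = [pc_inh[rng.integers(len(pc_inh))] for _ in range(config.n_sc_to_pc)]

    return Circuit(
        model=merged,
        config=config,
        pc_soma=merged.index("pc.soma"),
        sc1_soma=merged.index("sc1.soma"),
        sc2_soma=sc2_soma,
        pf_pc_targets=pf_pc,
        pf_sc_targets=pf_sc,
        sc_pc_synapses=sc_pc,
        sc_sc_synapses=sc_sc_targets,
    )


# ---------------------------------------------------------------------------
# Measurements


@dataclass
class FilterReport:
    """Per (frequency, condition) PC response summary."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def gain(self, condition: str) -> dict[float, float]:
        out = {}
        for r in self.rows:
            if r["condition"] == condition:
                out[r["frequency_hz"]] = r["gain_vs_4hz"]
        return out


def _pc_response(
    circuit: Circuit,
    train: TrainProtocol,
    duration_ms: float,
    settle_ms: float,
    n_trials: int = 4,
    jitter_seed: int = 0,
) -> dict:
    """Trial-averaged PC response; the train onset is jittered against
    the pacemaking phase so rates are not quantized by a single phase."""
    rng = np.random.default_rng(jitter_seed)
    bases, resps, pauses, n_sc = [], [], [], []
    for _ in range(n_trials):
        tr = TrainProtocol(
            train.n_pulses, train.frequency_hz, train.n_synapses,
            train.target, train.onset_ms + float(rng.uniform(0.0, 80.0)),
        )
        sim = circuit.simulation(tr)
        ts = sim.run(duration_ms + 100.0, record_stride=4)
        pc_spikes = ts.spikes["pc.soma"]
        # response epoch: the train plus one inter-pulse interval,
        # with a 120-ms floor so brief high-frequency bursts still span
        # the feed-forward inhibition they recruit
        window = max(tr.span_ms + 1000.0 / tr.frequency_hz, 120.0)
        base, resp, _ = burst_rate_change(
            pc_spikes, tr.onset_ms, window,
            baseline_ms=min(1000.0, tr.onset_ms - 100.0),
        )
        bases.append(base)
        resps.append(resp)
        t_end = tr.onset_ms + tr.span_ms
        after = pc_spikes[pc_spikes >= t_end]
        pauses.append(float(after[0] - t_end) if len(after) else float("nan"))
        n_sc.append(int(np.sum(
            (ts.spikes["sc1.soma"] >= tr.onset_ms)
            & (ts.spikes["sc1.soma"] < t_end + 20.0)
        )))
    base = float(np.mean(bases))
    resp = float(np.mean(resps))
    return {
        "baseline_hz": base,
        "burst_hz": resp,
        "pct_change": (resp - base) / base * 100.0 if base > 0 else float("nan"),
        "pause_ms": float(np.nanmean(pauses)),
        "n_sc_spikes": int(np.mean(n_sc)),
    }


def run_filtering(
    sc_genome: Optional[Sequence[float]] = None,
    frequencies: Sequence[float] = PF_TRAIN_FREQS,
    n_sc_to_pc: int = 100,
    conditions: Sequence[str] = ("sc_off", "sc_pc", "sc_sc_pc"),
    n_pulses: int = 10,
    duration_ms: Optional[float] = None,
    onset_ms: float = 2000.0,
    placement_seed: int = 0,
) -> FilterReport:
    """PC burst gain / pause across input frequencies and inhibition
    conditions.  Gain is each condition's burst rate normalized to its
    own 4-Hz response."""
    report = FilterReport()
    for condition in conditions:
        cfg = CircuitConfig(
            n_sc_to_pc=n_sc_to_pc,
            sc_connected=(condition != "sc_off"),
            sc_sc_enabled=(condition == "sc_sc_pc"),
            placement_seed=placement_seed,
        )
        circuit = build_circuit(cfg, sc_genome)
        rows = []
        for f in frequencies:
            train = TrainProtocol(n_pulses, f, onset_ms=onset_ms)
            dur = duration_ms or (onset_ms + max(train.span_ms + 1000.0 / f, 120.0) + 600.0)
            res = _pc_response(circuit, train, dur, settle_ms=500.0)
            res.update({"frequency_hz": f, "condition": condition,
                        "n_sc_to_pc": n_sc_to_pc})
            rows.append(res)
        ref = next((r["burst_hz"] for r in rows if r["frequency_hz"] == 4.0), None)
        for r in rows:
            r["gain_vs_4hz"] = r["burst_hz"] / ref if ref and ref > 0 else float("nan")
        report.rows.extend(rows)
    return report


def pc_onset_latency(
    sc_genome: Optional[Sequence[float]] = None,
    frequency_hz: float = 100.0,
    n_pulses: int = 10,
    n_sc_to_pc: int = 100,
    sc_connected: bool = True,
    n_trials: int = 16,
    bin_ms: float = 10.0,
    seed: int = 0,
) -> float:
    """PC response-onset latency (ms) from a fine-binned PSTH over trials
    with the train onset jittered against the PC's pacemaking phase."""
    rng = np.random.default_rng(seed)
    cfg = CircuitConfig(
        n_sc_to_pc=n_sc_to_pc, sc_connected=sc_connected, placement_seed=seed
    )
    circuit = build_circuit(cfg, sc_genome)
    trains = []
    for _ in range(n_trials):
        onset = 1500.0 + rng.uniform(0.0, 100.0)
        train = TrainProtocol(n_pulses, frequency_hz, onset_ms=onset)
        sim = circuit.simulation(train)
        ts = sim.run(onset + 600.0, record_stride=4)
        trains.append(ts.spikes["pc.soma"] - onset)
    hist = psth(trains, 0.0, window_ms=(-800.0, 400.0), bin_ms=bin_ms)
    return response_onset(hist, min_sigma=1.5)


def sc_burst_response(
    cell,
    frequency_hz: float,
    n_pulses: int = 10,
    n_synapses: int = 3,
    nmda_on: bool = True,
    inhibitory_streams_fn=None,
    n_trials: int = 6,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Trial-averaged (baseline, during-train rate, % change) for a PF
    burst onto a stellate cell, with the train onset jittered against
    the pacemaking phase."""
    rng = np.random.default_rng(seed)
    bases, resps = [], []
    for k in range(n_trials):
        onset = 2000.0 + float(rng.uniform(0.0, 100.0))
        train = TrainProtocol(n_pulses, frequency_hz, n_synapses, onset_ms=onset)
        span = train.span_ms + 1000.0 / frequency_hz
        streams = inhibitory_streams_fn(onset, onset + span, k) if inhibitory_streams_fn else None
        ts = run_train(cell, train, duration_ms=onset + span + 120.0,
                       nmda=nmda_on, inhibitory_streams=streams,
                       placement_seed=seed + k)
        b, r, _ = burst_rate_change(ts.spikes["soma"], onset, span, baseline_ms=1500.0)
        bases.append(b)
        resps.append(r)
    base = float(np.mean(bases))
    resp = float(np.mean(resps))
    pct = (resp - base) / base * 100.0 if base > 0 else float("nan")
    return base, resp, pct


def sc_gain_experiment(
    sc_genome: Optional[Sequence[float]] = None,
    frequencies: Sequence[float] = PF_TRAIN_FREQS,
    n_synapses: int = 3,
    nmda_on: bool = True,
    n_inhibitory: int = 0,
    inhibition_seed: int = 0,
    n_pulses: int = 10,
    duration_ms: float = 5000.0,
    onset_ms: float = 2000.0,
) -> dict[float, dict]:
    """SC output rate vs PF input frequency, with optional NMDA block and
    a 20-Hz inhibitory background co-activated with the bursts."""
    cell = build_sc_cell(sc_genome)
    out: dict[float, dict] = {}
    for f in frequencies:
        streams_fn = None
        if n_inhibitory > 0:
            def streams_fn(t0, t1, k, _f=f):
                bg = InhibitoryBackground(
                    n_synapses=n_inhibitory, seed=inhibition_seed + k
                )
                streams = realize_events(bg, t1 + 100.0)
                # background co-activated with the PF burst only
                return [s[(s >= t0) & (s < t1)] for s in streams]

        base, resp, pct = sc_burst_response(
            cell, f, n_pulses=n_pulses, n_synapses=n_synapses,
            nmda_on=nmda_on, inhibitory_streams_fn=streams_fn,
            seed=inhibition_seed,
        )
        out[f] = {"baseline_hz": base, "burst_hz": resp, "pct_change": pct}
    return out


def calibrate_pf_count(
    target_burst_hz: float,
    sc_genome: Optional[Sequence[float]] = None,
    frequency_hz: float = 100.0,
    max_count: int = 10,
) -> int:
    """Smallest number of PF synapses whose 100-Hz response meets or
    exceeds the target burst rate."""
    if target_burst_hz <= 0:
        return 0
    cell = build_sc_cell(sc_genome)
    for n in range(1, max_count + 1):
        _, resp, _ = sc_burst_response(cell, frequency_hz, n_synapses=n, seed=n)
        if resp >= target_burst_hz:
            return n
    raise RuntimeError(f"target {target_burst_hz} Hz not reached with {max_count} synapses")


def epsc_gain_half_frequency(
    target: str = "sc",
    sc_genome: Optional[Sequence[float]] = None,
    frequencies: Sequence[float] = PF_TRAIN_FREQS,
    n_pulses: int = 20,
    clamp_mV: float = -70.0,
) -> tuple[float, dict[float, float]]:
    """Half-maximal frequency of the EPSC gain curve under somatic
    voltage clamp (gain = maximum train response / first EPSC)."""
    if target == "sc":
        cell = build_sc_cell(sc_genome)
        model, soma = cell.model, cell.soma
        placements = [(syn, c) for c in cell.pf_target_indices
                      for syn in (PF_SC_AMPA, PF_SC_NMDA)]
    elif target == "pc":
        pc = build_pc_cell()
        model, soma = pc.model, pc.soma
        placements = [(PF_PC_AMPA, c) for c in pc.branch2_indices]
    else:
        raise ValueError("target must be 'sc' or 'pc'")
    gains = {}
    for f in frequencies:
        tt = 200.0 + np.arange(n_pulses) * 1000.0 / f
        sim = Simulation(model)
        sim.set_clamp(soma, clamp_mV)
        for syn, comp in placements:
            sim.add_synapse(syn, comp, tt)
        ts = sim.run(tt[-1] + 150.0)
        i = ts.i_clamp * 1000.0  # pA
        first = measure_epsc_amplitudes(ts.t, i, tt)[0]
        base0 = float(np.mean(i[(ts.t >= tt[0] - 1.0) & (ts.t < tt[0])]))
        resp_max = base0 - float(np.min(i[ts.t >= tt[0]]))
        gains[f] = resp_max / first
    fh, _ = gain_curve(list(gains), list(gains.values()))
    return fh, gains
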