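"""Multi-compartment cable solver.

A :class:`CompartmentalModel` is a tree (or forest, for multi-cell
circuits) of cylindrical compartments carrying capacitance, channel
conductance densities and calcium pools.  :class:`Simulation` packs the
model plus synapses, current steps and an optional ideal voltage clamp
into flat arrays and hands them to the numba kernel.

Conventions: mV, ms, nA, uS, nF; lengths in um.  Axial coupling between
adjacent compartments is the series combination of the two half-cylinder
conductances ``g = (pi d^2/4) / (R_axial L/2)``.  The default time step
is 0.025 ms at 32 degC; membrane capacitance defaults to 1.5 uF/cm^2 on
dendritic classes and 1.0 uF/cm^2 elsewhere, axial resistivity to
110 Ohm cm everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernel
from .channels import (
    CalciumPool,
    REVERSALS,
    GateSpec,
    builtin_channel_library,
    get_channel,
)
from .synapses import SynapseType

__all__ = [
    "run_protocol",
    "Compartment",
    "CompartmentalModel",
    "Simulation",
    "TraceSet",
    "IntegrationError",
    "input_resistance",
    "DT_DEFAULT",
    "TEMPERATURE_DEFAULT",
]

DT_DEFAULT = 0.025  # ms
TEMPERATURE_DEFAULT = 32.0  # degC
R_AXIAL_DEFAULT = 110.0  # Ohm cm

_CM_BY_CLASS = {
    "soma": 1.0,
    "proximal_dendrite": 1.5,
    "distal_dendrite": 1.5,
    "ais": 1.0,
    "axon": 1.0,
}


class IntegrationError(RuntimeError):
    pass


@dataclass
class Compartment:
    name: str
    cls: str  # compartment class (soma, proximal_dendrite, ...)
    length_um: float
    diam_um: float
    parent: int = -1  # index into the model's compartment list
    cm: Optional[float] = None  # uF/cm^2; None -> class default

    @property
    def area_um2(self) -> float:
        return math.pi * self.diam_um * self.length_um

    @property
    def cm_eff(self) -> float:
        return self.cm if self.cm is not None else _CM_BY_CLASS.get(self.cls, 1.0)


@dataclass
class CompartmentalModel:
    """Compartments + channel conductance densities + calcium pools."""

    compartments: list[Compartment] = field(default_factory=list)
    conductances: list[dict[str, float]] = field(default_factory=list)  # S/cm^2
    ca_pools: list[Optional[CalciumPool]] = field(default_factory=list)
    r_axial: float = R_AXIAL_DEFAULT
    reversals: dict[str, float] = field(default_factory=lambda: dict(REVERSALS))

    def add(
        self,
        name: str,
        cls: str,
        length_um: float,
        diam_um: float,
        parent: int = -1,
        conductances: Optional[dict[str, float]] = None,
        ca_pool: Optional[CalciumPool] = None,
    ) -> int:
        idx = len(self.compartments)
        if parent >= idx:
            raise ValueError("parent index must precede child")
        self.compartments.append(Compartment(name, cls, length_um, diam_um, parent))
        self.conductances.append(dict(conductances or {}))
        self.ca_pools.append(ca_pool)
        return idx

    def index(self, name: str) -> int:
        for i, c in enumerate(self.compartments):
            if c.name == name:
                return i
        raise KeyError(name)

    def merge(self, other: "CompartmentalModel", prefix: str) -> int:
        """Append another cell as a disconnected tree; returns the offset."""
        off = len(self.compartments)
        for c, g, p in zip(other.compartments, other.conductances, other.ca_pools):
            self.compartments.append(
                Compartment(
                    f"{prefix}{c.name}",
                    c.cls,
                    c.length_um,
                    c.diam_um,
                    c.parent + off if c.parent >= 0 else -1,
                    c.cm,
                )
            )
            self.conductances.append(dict(g))
            self.ca_pools.append(p)
        return off

    def validate(self) -> None:
        n = len(self.compartments)
        if n == 0:
            raise ValueError("empty model")
        seen_root = False
        for i, c in enumerate(self.compartments):
            if c.parent >= i:
                raise ValueError("compartments must be ordered parent-first")
            if c.parent == -1:
                seen_root = True
        if not seen_root:
            raise ValueError("no root compartment")

    def total_area_um2(self) -> float:
        return sum(c.area_um2 for c in self.compartments)

    def axial_g_uS(self) -> np.ndarray:
        """Coupling conductance of each compartment to its parent (uS)."""
        n = len(self.compartments)
        g = np.zeros(n)

        def g_half(c: Compartment) -> float:
            d_cm = c.diam_um * 1e-4
            l_cm = c.length_um * 1e-4
            return (math.pi * d_cm**2 / 4.0) / (self.r_axial * l_cm / 2.0)

        for i, c in enumerate(self.compartments):
            if c.parent >= 0:
                gh_i = g_half(c)
                gh_p = g_half(self.compartments[c.parent])
                g[i] = 1e6 * (gh_i * gh_p) / (gh_i + gh_p)
        return g


@dataclass
class TraceSet:
    """Recorded simulation output on a uniform time base."""

    t: np.ndarray  # ms
    dt: float  # recording interval, ms
    v: dict[str, np.ndarray] = field(default_factory=dict)  # mV
    ca: dict[str, np.ndarray] = field(default_factory=dict)  # mM
    i_clamp: Optional[np.ndarray] = None  # nA
    spikes: dict[str, np.ndarray] = field(default_factory=dict)  # ms
    events: dict[str, np.ndarray] = field(default_factory=dict)  # stimulus times

    def to_frame(self):
        import pandas as pd

        data = {"t_ms": self.t}
        for k, tr in self.v.items():
            data[f"v_{k}_mV"] = tr
        for k, tr in self.ca.items():
            data[f"ca_{k}_mM"] = tr
        if self.i_clamp is not None:
            data["i_clamp_nA"] = self.i_clamp
        return pd.DataFrame(data)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class Simulation:
    """One runnable experiment: model + synapses + stimuli + recordings."""

    def __init__(
        self,
        model: CompartmentalModel,
        dt: float = DT_DEFAULT,
        integrator: str = "cn",
        temperature: float = TEMPERATURE_DEFAULT,
    ):
        model.validate()
        self.model = model
        self.dt = float(dt)
        if integrator not in ("cn", "be"):
            raise ValueError("integrator must be 'cn' or 'be'")
        self.theta = 0.5 if integrator == "cn" else 1.0
        self.temperature = temperature
        self._syn: list[tuple[SynapseType, int, np.ndarray]] = []
        self._con: list[tuple[int, int, float]] = []  # (source idx, syn idx, delay)
        self._sources: list[int] = []  # spike-source compartment indices
        self._stim: list[tuple[int, float, float, float]] = []
        self._clamp: tuple[int, float] | None = None
        self._clamp_step: tuple[float, float] | None = None
        self._rec_v: list[int] = []
        self._rec_ca: list[int] = []
        self.v_init = -60.0

    # -- construction -------------------------------------------------
    def add_synapse(
        self, syn: SynapseType, comp: int, events: Optional[Sequence[float]] = None
    ) -> int:
        ev = np.asarray(events if events is not None else [], dtype=float)
        if len(ev) > 1 and np.any(np.diff(ev) < 0):
            raise ValueError("synaptic events must be time-ordered")
        if len(ev) > 1 and np.any(np.diff(ev) < self.dt):
            raise ValueError("synaptic events closer than dt")
        self._syn.append((syn, int(comp), ev))
        return len(self._syn) - 1

    def add_source(self, comp: int) -> int:
        """Register a compartment as a spike source (for recording and
        for driving network connections)."""
        if comp not in self._sources:
            self._sources.append(int(comp))
        return self._sources.index(int(comp))

    def connect(self, source_comp: int, syn_index: int, delay_ms: float = 1.0) -> None:
        src = self.add_source(source_comp)
        self._con.append((src, int(syn_index), float(delay_ms)))

    def add_step(self, comp: int, t0: float, t1: float, amp_pA: float) -> None:
        self._stim.append((int(comp), float(t0), float(t1), amp_pA * 1e-3))

    def set_clamp(
        self,
        comp: int,
        v_mV: float,
        v2_mV: Optional[float] = None,
        switch_ms: Optional[float] = None,
    ) -> None:
        """Ideal voltage clamp; optionally steps the command to
        ``v2_mV`` at ``switch_ms``."""
        self._clamp = (int(comp), float(v_mV))
        self._clamp_step = (
            (float(v2_mV), float(switch_ms))
            if v2_mV is not None and switch_ms is not None
            else None
        )

    def record_v(self, comps: Sequence[int]) -> None:
        self._rec_v = [int(c) for c in comps]

    def record_ca(self, comps: Sequence[int]) -> None:
        self._rec_ca = [int(c) for c in comps]

    # -- packing ------------------------------------------------------
    def _pack_channels(self):
        m = self.model
        lib = {c.name: c for c in builtin_channel_library()}
        inst_comp, inst_g, inst_e, inst_isca, inst_g0, inst_ng = [], [], [], [], [], []
        gp_rows, gate_comp, gate_init = [], [], []
        q10scale = {}
        for i, (comp, gdict) in enumerate(zip(m.compartments, m.conductances)):
            area_cm2 = comp.area_um2 * 1e-8
            for name, dens in gdict.items():
                if dens < 0:
                    raise ValueError(f"negative conductance for {name}")
                if dens == 0.0:
                    continue
                ch = lib[name]
                inst_comp.append(i)
                inst_g.append(dens * area_cm2 * 1e6)  # uS
                inst_e.append(m.reversals[ch.ion])
                inst_isca.append(1 if ch.ion == "Ca" else 0)
                inst_g0.append(len(gp_rows))
                inst_ng.append(len(ch.gates))
                for g in ch.gates:
                    tf = g.q10 ** ((g.t_ref - self.temperature) / 10.0)
                    gp_rows.append(
                        [
                            g.kind,
                            g.vhalf,
                            g.k,
                            g.tau_min * tf,
                            g.tau_amp * tf,
                            g.vt,
                            g.s1,
                            g.s2,
                            g.kd,
                            g.hill_n,
                            g.exponent,
                        ]
                    )
                    gate_comp.append(i)
                    gate_init.append(g)
        gp = np.array(gp_rows, dtype=float).reshape(-1, 11)
        return (
            np.array(inst_comp, dtype=np.int64),
            np.array(inst_g, dtype=float),
            np.array(inst_e, dtype=float),
            np.array(inst_isca, dtype=np.uint8),
            np.array(inst_g0, dtype=np.int64),
            np.array(inst_ng, dtype=np.int64),
            gp,
            np.array(gate_comp, dtype=np.int64),
            gate_init,
        )

    # -- execution ----------------------------------------------------
    def run(self, duration_ms: float, record_stride: int = 1) -> TraceSet:
        m = self.model
        n = len(m.compartments)
        dt = self.dt
        n_steps = int(round(duration_ms / dt))

        parent = np.array([c.parent for c in m.compartments], dtype=np.int64)
        area = np.array([c.area_um2 for c in m.compartments])
        c_nf = np.array(
            [c.cm_eff * c.area_um2 * 1e-8 * 1e3 for c in m.compartments]
        )  # uF/cm^2 * cm^2 -> uF; *1e3 -> nF
        gax = m.axial_g_uS()
        gax_sum = gax.copy()
        for i, p in enumerate(parent):
            if p >= 0:
                gax_sum[p] += gax[i]

        (
            inst_comp,
            inst_g,
            inst_e,
            inst_isca,
            inst_g0,
            inst_ng,
            gp,
            gate_comp,
            gate_specs,
        ) = self._pack_channels()

        clamp_comp, clamp_v = self._clamp if self._clamp else (-1, 0.0)
        if self._clamp_step is not None:
            clamp_v2 = self._clamp_step[0]
            clamp_switch = int(round(self._clamp_step[1] / dt))
        else:
            clamp_v2, clamp_switch = 0.0, -1
        v0 = np.full(n, self.v_init)
        if clamp_comp >= 0:
            v0[:] = clamp_v
        ca0 = np.empty(n)
        ca_rest = np.empty(n)
        ca_tau = np.ones(n)
        ca_coef = np.zeros(n)
        for i, pool in enumerate(m.ca_pools):
            p = pool or CalciumPool()
            ca0[i] = p.ca_rest
            ca_rest[i] = p.ca_rest
            ca_tau[i] = p.tau_ms
            if pool is not None:
                vol = area[i] * p.depth_um
                ca_coef[i] = 1e6 / (2.0 * 96485.332 * vol) / (1.0 + p.kappa)

        gates0 = np.array(
            [g.inf(v0[c], ca0[c]) for g, c in zip(gate_specs, gate_comp)], dtype=float
        )

        # synapses
        ns = len(self._syn)
        syn_comp = np.array([c for _, c, _ in self._syn], dtype=np.int64)
        syn_kind = np.array(
            [0 if s.kinetics.scheme == "exp" else 1 for s, _, _ in self._syn],
            dtype=np.int64,
        )
        syn_g = np.array(
            [
                s.g_max_pS * 1e-6 * (s.kinetics.peak_open if s.kinetics.scheme == 'exp' else 1.0)
                for s, _, _ in self._syn
            ]
        )  # pS -> uS, scaled by the scheme's peak open probability
        syn_e = np.array([s.e_rev_mV for s, _, _ in self._syn])
        syn_taur = np.array([max(s.kinetics.tau_rise, 1e-3) for s, _, _ in self._syn])
        syn_taud = np.array([s.kinetics.tau_decay for s, _, _ in self._syn])
        syn_norm = np.array([s.kinetics.norm for s, _, _ in self._syn])
        syn_mg = np.array(
            [s.kinetics.mg_mM / s.kinetics.mg_scale_mM for s, _, _ in self._syn]
        )
        syn_vsens = np.array([s.kinetics.mg_vsens for s, _, _ in self._syn])
        syn_sat = np.array(
            [1 if s.kinetics.saturating else 0 for s, _, _ in self._syn], dtype=np.int64
        )
        syn_p = np.array([s.tm.p for s, _, _ in self._syn])
        syn_tr = np.array([s.tm.tau_r for s, _, _ in self._syn])
        syn_tf = np.array([s.tm.tau_f for s, _, _ in self._syn])
        ev_off = np.zeros(ns + 1, dtype=np.int64)
        for i, (_, _, ev) in enumerate(self._syn):
            ev_off[i + 1] = ev_off[i] + len(ev)
        ev_t = (
            np.concatenate([ev for _, _, ev in self._syn])
            if ns and ev_off[-1] > 0
            else np.zeros(0)
        )

        src_comp = np.array(self._sources, dtype=np.int64)
        con_src = np.array([c[0] for c in self._con], dtype=np.int64)
        con_syn = np.array([c[1] for c in self._con], dtype=np.int64)
        con_delay = np.array([c[2] for c in self._con], dtype=float)

        stim_comp = np.array([s[0] for s in self._stim], dtype=np.int64)
        stim_t0 = np.array([s[1] for s in self._stim])
        stim_t1 = np.array([s[2] for s in self._stim])
        stim_amp = np.array([s[3] for s in self._stim])

        n_rec = (n_steps + record_stride - 1) // record_stride
        rec_v_idx = np.array(self._rec_v, dtype=np.int64)
        rec_ca_idx = np.array(self._rec_ca, dtype=np.int64)
        v_out = np.zeros((n_rec, len(rec_v_idx)))
        ca_out = np.zeros((n_rec, len(rec_ca_idx)))
        ic_out = np.zeros(n_rec if clamp_comp >= 0 else 0)
        max_spk = max(16, int(duration_ms * 1.0))  # 1 kHz headroom
        spk_t = np.zeros((max(len(src_comp), 1), max_spk))
        spk_n = np.zeros(max(len(src_comp), 1), dtype=np.int64)

        status = _kernel.run_kernel(
            parent,
            c_nf,
            gax,
            gax_sum,
            v0,
            inst_comp,
            inst_g,
            inst_e,
            inst_isca,
            inst_g0,
            inst_ng,
            gp,
            gate_comp,
            gates0,
            ca0,
            ca_rest,
            ca_tau,
            ca_coef,
            syn_comp,
            syn_kind,
            syn_g,
            syn_e,
            syn_taur,
            syn_taud,
            syn_norm,
            syn_mg,
            syn_vsens,
            syn_sat,
            syn_p,
            syn_tr,
            syn_tf,
            ev_t,
            ev_off,
            src_comp,
            con_src,
            con_syn,
            con_delay,
            stim_comp,
            stim_t0,
            stim_t1,
            stim_amp,
            clamp_comp,
            clamp_v,
            clamp_v2,
            clamp_switch,
            dt,
            n_steps,
            self.theta,
            rec_v_idx,
            rec_ca_idx,
            record_stride,
            v_out,
            ca_out,
            ic_out,
            spk_t,
            spk_n,
        )
        if status >= 0:
            raise IntegrationError(
                f"non-finite membrane potential at t = {status * dt:.3f} ms"
            )
        bad = ~np.isfinite(v_out)
        if np.any(bad) or not np.all(np.isfinite(v0)):
            if np.any(bad):
                step_bad = int(np.argwhere(bad.any(axis=1))[0][0]) * record_stride
            else:
                step_bad = n_steps
            raise IntegrationError(
                f"non-finite membrane potential at t = {step_bad * dt:.3f} ms"
            )

        names = [m.compartments[i].name for i in self._rec_v]
        ca_names = [m.compartments[i].name for i in self._rec_ca]
        t = np.arange(n_rec) * dt * record_stride
        ts = TraceSet(
            t=t,
            dt=dt * record_stride,
            v={nm: v_out[:, k] for k, nm in enumerate(names)},
            ca={nm: ca_out[:, k] for k, nm in enumerate(ca_names)},
            i_clamp=ic_out if clamp_comp >= 0 else None,
        )
        for k, comp in enumerate(self._sources):
            ts.spikes[m.compartments[comp].name] = spk_t[k, : spk_n[k]].copy()
        return ts


def input_resistance(
    cell_model: CompartmentalModel,
    soma_index: int = 0,
    hold_mV: float = -70.0,
    step_mV: float = -10.0,
    pulse_ms: float = 200.0,
    settle_ms: float = 1000.0,
    dt: float = 0.05,
) -> float:
    """Sub-threshold input resistance (GOhm) under ideal somatic voltage
    clamp: a brief hyperpolarizing command pulse from an equilibrated
    -70 mV hold, with the current read at the end of the pulse --
    mirroring the experimental whole-cell pulse protocol (the clamp
    itself silences spiking; slow conductances are only partially
    recruited within the pulse, as in the recordings)."""
    sim = Simulation(cell_model, dt=dt)
    sim.set_clamp(soma_index, hold_mV, hold_mV + step_mV, settle_ms)
    ts = sim.run(settle_ms + pulse_ms, record_stride=4)
    rec = ts.dt
    i_hold = float(np.mean(ts.i_clamp[int((settle_ms - 50.0) / rec) : int(settle_ms / rec)]))
    i_pulse = float(
        np.mean(ts.i_clamp[int((settle_ms + pulse_ms - 50.0) / rec) :])
    )
    if not (np.isfinite(i_hold) and np.isfinite(i_pulse)):
        raise IntegrationError("clamp current did not converge")
    return step_mV / ((i_pulse - i_hold) * 1e3)  # mV / pA == GOhm


def run_protocol(cell, protocol, seed: int = 0, **kwargs):
    """Run a declarative protocol on a stellate cell.

    Dispatches on the protocol type: current steps run through
    :func:`stellate.models.run_step` (one trace per amplitude),
    synaptic trains through :func:`stellate.models.run_train`; a clamped
    train builds the voltage-clamp EPSC experiment.  Reproducible given
    the seed (stochastic elements only).
    """
    from .models import run_step, run_train
    from .protocols import ClampProtocol, StepProtocol, TrainProtocol

    if isinstance(protocol, StepProtocol):
        return [
            run_step(cell, amp, duration_ms=protocol.duration_ms,
                     pre_ms=protocol.pre_ms, post_ms=protocol.post_ms, **kwargs)
            for amp in protocol.amplitudes_pA
        ]
    if isinstance(protocol, TrainProtocol):
        return run_train(cell, protocol, **kwargs)
    if isinstance(protocol, ClampProtocol):
        from .synapses import epsc_train

        return epsc_train(cell, protocol.train, clamp_mV=protocol.clamp_mV)
    raise TypeError(f"unknown protocol type {type(protocol).__name__}")
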