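"""Short-term plasticity synapses: Tsodyks-Markram release dynamics with
AMPA, NMDA (NR2B-like) and GABA-A receptor conductances.

The presynaptic model tracks a resource fraction ``R`` (recovering with
``tau_r``) and a utilization ``u`` (decaying with ``tau_f``).  The
variant used everywhere in this package applies the facilitation
increment *before* computing release, so the very first pulse from rest
releases exactly ``p``:

    u <- u*exp(-dt/tau_f);  u <- u + p*(1 - u)
    R <- 1 - (1 - R)*exp(-dt/tau_r)
    release = u * R;  R <- R - release

Receptor conductances are event-triggered waveforms scaled by the
released fraction: a single-exponential decay for AMPA and GABA-A
(sub-millisecond rise folded into the instantaneous jump) and a
normalized difference of exponentials for NMDA, whose voltage-dependent
Mg block follows the standard sigmoidal form.  The stellate-cell
parameter set (release probability, recovery/facilitation time
constants, per-synapse peak conductance and reversal) is the one
constrained by paired recordings: AMPA p=0.15, tau_r=35.1 ms,
tau_f=10.8 ms, 2300 pS; NMDA p=0.15, tau_r=8 ms, tau_f=5 ms, 10000 pS,
E=-3.7 mV; GABA-A p=0.42, tau_r=38.7 ms, tau_f=0, 1600 pS, E=-65 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TMParams",
    "ReceptorKinetics",
    "SynapseType",
    "PF_SC_AMPA",
    "PF_SC_NMDA",
    "SC_GABAA",
    "tm_update",
    "tm_train",
    "tm_fixed_point",
    "receptor_g",
    "nmda_block",
    "stp_switch",
    "gain_curve",
    "measure_epsc_amplitudes",
    "epsc_train",
]


@dataclass(frozen=True)
class TMParams:
    """Presynaptic short-term plasticity parameters."""

    p: float  # baseline release probability
    tau_r: float  # recovery from depression, ms (0 = instant)
    tau_f: float  # facilitation decay, ms (0 = none)

    def __post_init__(self):
        if not (0.0 < self.p <= 1.0):
            raise ValueError("release probability must be in (0, 1]")
        if self.tau_r < 0 or self.tau_f < 0:
            raise ValueError("time constants must be non-negative")


@dataclass(frozen=True)
class ReceptorKinetics:
    """Postsynaptic conductance waveform parameters."""

    scheme: str  # "exp" (instant rise) or "nmda" (rise/decay + Mg block)
    tau_rise: float = 0.0  # ms, used by "nmda"
    tau_decay: float = 2.0  # ms
    mg_mM: float = 1.0  # Mg concentration for the block, "nmda" only
    mg_scale_mM: float = 3.57  # Mg block IC50 scale
    mg_vsens: float = 0.062  # Mg block voltage sensitivity, 1/mV
    peak_open: float = 1.0  # peak open probability of the underlying scheme
    saturating: bool = False  # receptor occupancy saturation on increments

    @property
    def norm(self) -> float:
        """Scale making a unitary event's conductance peak equal 1."""
        if self.scheme != "nmda":
            return self.peak_open
        tr, td = self.tau_rise, self.tau_decay
        tp = math.log(td / tr) * tr * td / (td - tr)
        return self.peak_open / (math.exp(-tp / td) - math.exp(-tp / tr))

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak conductance time course for an event at t=0."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t >= 0
        if self.scheme == "nmda":
            out[pos] = self.norm * (
                np.exp(-t[pos] / self.tau_decay) - np.exp(-t[pos] / self.tau_rise)
            )
        else:
            out[pos] = self.peak_open * np.exp(-t[pos] / self.tau_decay)
        return out


@dataclass(frozen=True)
class SynapseType:
    """Complete synapse description: presynaptic STP + receptor + scale."""

    name: str
    tm: TMParams
    kinetics: ReceptorKinetics
    g_max_pS: float
    e_rev_mV: float

    def __post_init__(self):
        if self.g_max_pS <= 0:
            raise ValueError("G_max must be positive")


# stellate-cell synapse library (per-synapse values)
PF_SC_AMPA = SynapseType(
    "PF-SC AMPA",
    TMParams(p=0.15, tau_r=35.1, tau_f=10.8),
    ReceptorKinetics("exp", tau_decay=1.8),
    g_max_pS=2300.0,
    e_rev_mV=0.0,
)
PF_SC_NMDA = SynapseType(
    "PF-SC NMDA (NR2B)",
    TMParams(p=0.15, tau_r=8.0, tau_f=5.0),
    ReceptorKinetics("nmda", tau_rise=10.0, tau_decay=220.0, mg_mM=1.0,
                     mg_vsens=0.045, peak_open=0.07, saturating=True),
    g_max_pS=10000.0,
    e_rev_mV=-3.7,
)
SC_GABAA = SynapseType(
    "SC GABA-A (alpha1)",
    TMParams(p=0.42, tau_r=38.7, tau_f=0.0),
    ReceptorKinetics("exp", tau_decay=11.0),
    g_max_pS=1600.0,
    e_rev_mV=-65.0,
)


# ---------------------------------------------------------------------------
# Presynaptic recursion


def tm_update(state: tuple[float, float, float], spike_time: float, params: TMParams):
    """Advance one presynaptic spike; returns (released fraction, new state).

    ``state`` is ``(R, u, t_last)``; pass ``(1.0, 0.0, -inf)`` for rest.
    """
    r, u, t_last = state
    dt = spike_time - t_last
    if dt < 0:
        raise ValueError("spike times must be non-decreasing")
    u = u * math.exp(-dt / params.tau_f) if params.tau_f > 0 else 0.0
    r = 1.0 - (1.0 - r) * math.exp(-dt / params.tau_r) if params.tau_r > 0 else 1.0
    u = u + params.p * (1.0 - u)
    release = u * r
    return release, (r - release, u, spike_time)


def tm_train(spike_times: Sequence[float], params: TMParams) -> np.ndarray:
    """Released fractions for an ordered spike train (event recursion)."""
    state = (1.0, 0.0, -math.inf)
    out = np.empty(len(spike_times))
    for i, t in enumerate(spike_times):
        out[i], state = tm_update(state, float(t), params)
    return out


def tm_fixed_point(freq_hz: float, params: TMParams) -> float:
    """Analytic steady-state release at a fixed stimulation frequency.

    Closed form of the two-map recursion fixed point:
    ``u* = p / (1 - (1-p) ef)`` and
    ``R*(1-er) ... `` with ``ef = exp(-T/tau_f)``, ``er = exp(-T/tau_r)``.
    """
    t_isi = 1000.0 / freq_hz
    ef = math.exp(-t_isi / params.tau_f) if params.tau_f > 0 else 0.0
    er = math.exp(-t_isi / params.tau_r) if params.tau_r > 0 else 0.0
    u_star = params.p / (1.0 - (1.0 - params.p) * ef)
    # R_{k+1} = 1 - (1 - R_k(1-u*)) er  ->  R* = (1-er)/(1-(1-u*) er)
    r_star = (1.0 - er) / (1.0 - (1.0 - u_star) * er)
    return u_star * r_star


# ---------------------------------------------------------------------------
# Receptor conductance


def receptor_g(
    t: np.ndarray,
    events: Iterable[tuple[float, float]],
    kinetics: ReceptorKinetics,
    g_max_pS: float,
) -> np.ndarray:
    """Conductance (pS) from linear superposition of event-triggered
    waveforms; each event is ``(time, released fraction)``."""
    t = np.asarray(t, dtype=float)
    g = np.zeros_like(t)
    last = -math.inf
    for te, rel in events:
        if te < last:
            raise ValueError("events must be time-ordered")
        last = te
        g += rel * g_max_pS * kinetics.waveform(t - te)
    return g


def nmda_block(
    v_mV: float, mg_mM: float = 1.0, scale_mM: float = 3.57, vsens: float = 0.062
) -> float:
    """Voltage-dependent Mg unblock factor in (0, 1], sigmoidal form
    ``1 / (1 + [Mg]/scale * exp(-vsens V))``."""
    if mg_mM < 0:
        raise ValueError("[Mg] must be non-negative")
    return 1.0 / (1.0 + (mg_mM / scale_mM) * math.exp(-vsens * v_mV))


def stp_switch(params: TMParams, mode: str) -> TMParams:
    """Return parameters with facilitation or depression switched off.

    ``STF_off`` multiplies ``tau_f`` by 10 (facilitation saturates and no
    longer shapes the train); ``STD_off`` sets ``tau_r`` to 0 (instant
    resource recovery).
    """
    if mode == "STF_off":
        return replace(params, tau_f=params.tau_f * 10.0)
    if mode == "STD_off":
        return replace(params, tau_r=0.0)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Train analysis


def measure_epsc_amplitudes(
    t: np.ndarray,
    i_clamp: np.ndarray,
    stim_times: Sequence[float],
    base_window_ms: float = 1.0,
) -> np.ndarray:
    """Per-pulse EPSC amplitudes (positive, pA-or-nA as given) from a
    voltage-clamp current trace.

    For each stimulus the base is the mean current over the
    ``base_window_ms`` preceding it and the amplitude is base minus the
    most negative (inward) current before the next stimulus.
    """
    t = np.asarray(t)
    i = np.asarray(i_clamp)
    stim = np.asarray(stim_times, dtype=float)
    isi = np.min(np.diff(stim)) if len(stim) > 1 else 50.0
    amps = np.empty(len(stim))
    for k, ts in enumerate(stim):
        b = (t >= ts - base_window_ms) & (t < ts)
        base = float(np.mean(i[b])) if np.any(b) else 0.0
        t_end = stim[k + 1] if k + 1 < len(stim) else ts + isi
        w = (t >= ts) & (t < t_end)
        amps[k] = base - float(np.min(i[w]))
    return amps


def _logistic(x, base, top, x50, slope):
    return base + (top - base) / (1.0 + np.exp((x50 - x) / slope))


def gain_curve(freqs_hz: Sequence[float], gains: Sequence[float]):
    """Fit a 4-parameter logistic in log10-frequency to a gain curve.

    Returns ``(f_half_hz, fit_params)`` where ``fit_params`` is
    ``(base, top, log10_f50, slope)``.  The half-maximal frequency is
    the frequency at which the fitted gain crosses midway between the
    lower and upper asymptotes.  A flat curve raises a warning-carrying
    ``RuntimeError`` since the half-frequency is then undefined.
    """
    f = np.asarray(freqs_hz, dtype=float)
    g = np.asarray(gains, dtype=float)
    if len(f) < 4:
        raise ValueError("need at least 4 frequencies")
    if np.ptp(g) < 1e-6:
        raise RuntimeError("flat gain curve: half-frequency undefined")
    x = np.log10(f)
    bounds = (
        [0.0, 0.0, x.min() - 0.5, 0.01],
        [np.inf, np.inf, x.max() + 0.5, 5.0],
    )
    best = None
    for x50_init in np.linspace(x.min(), x.max(), 5):
        for slope_init in (0.15, 0.3, 0.6):
            p0 = (float(g.min()), float(g.max()), float(x50_init), slope_init)
            try:
                popt, _ = curve_fit(
                    _logistic, x, g, p0=p0, bounds=bounds, maxfev=20000
                )
            except RuntimeError:
                continue
            resid = float(np.sum((_logistic(x, *popt) - g) ** 2))
            in_range = x.min() <= popt[2] <= x.max()
            key = (not in_range, resid)
            if best is None or key < best[0]:
                best = (key, popt)
    if best is None:
        raise RuntimeError("logistic fit failed")
    popt = best[1]
    return float(10.0 ** popt[2]), tuple(float(v) for v in popt)


def epsc_train(cell, train, clamp_mV: float = -70.0, nmda: bool = True,
               normalized: bool = False):
    """Per-pulse EPSC amplitudes for a PF train under somatic voltage
    clamp (peak minus the mean of the 1 ms preceding each stimulus).

    ``cell`` is a stellate cell (see :mod:`stellate.models`); amplitudes
    are in pA, optionally normalized to the first EPSC.
    """
    import numpy as _np

    from .protocols import train_times
    from .solver import Simulation

    tt = train_times(train)
    sim = Simulation(cell.model)
    sim.set_clamp(cell.soma, clamp_mV)
    targets = cell.pf_target_indices
    for k in range(train.n_synapses):
        comp = targets[k % len(targets)]
        sim.add_synapse(PF_SC_AMPA, comp, tt)
        if nmda:
            sim.add_synapse(PF_SC_NMDA, comp, tt)
    ts = sim.run(tt[-1] + 150.0)
    amps = measure_epsc_amplitudes(ts.t, ts.i_clamp * 1e3, tt)
    return amps / amps[0] if normalized else amps
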