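"""Voltage- and calcium-gated channel kinetics for the stellate-cell model.

Fourteen mechanisms populate the model: Nav1.1, Nav1.6, Kv3.4, Kv4.3,
Kv1.1, Kir2.3, Kv7, KCa1.1 (BK), KCa2.2 (SK), Cav2.1 (P/Q), Cav3.2,
Cav3.3 (T-type), HCN1 and an ohmic leak.  Every gate is expressed in a
uniform Hodgkin-Huxley parameterization:

* steady state: Boltzmann ``x_inf = 1 / (1 + exp((vh - V)/k))`` (the sign
  of ``k`` distinguishes activation from inactivation), a Hill function
  of [Ca] for SK, or a Boltzmann whose half-voltage shifts with log[Ca]
  for BK;
* time constant: ``tau = tau_min + tau_amp / (exp((V-vt)/s1) +
  exp(-(V-vt)/s2))`` (bell-shaped; ``tau_amp = 0`` gives a constant).

Kinetic constants are HH-style fits in the spirit of the cerebellar
granule/Golgi/Purkinje modelling literature for each named isoform,
expressed at 32 degC (the simulation temperature); taus scale with
``Q10 = 3`` when run at other temperatures.  All constants are plain
data on the specs and can be overridden from configuration.

Calcium entering through Cav channels feeds a single sub-membrane shell
per compartment with parvalbumin-like fast buffering (treated as a
constant buffering capacity ratio) and first-order extrusion back to the
resting concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "CalciumPool",
    "REVERSALS",
    "ION_OF_CHANNEL",
    "CHANNEL_NAMES",
    "CONDUCTANCE_LAYOUT",
    "builtin_channel_library",
    "get_channel",
    "gate_dynamics",
    "channel_current",
    "step_calcium",
]

FARADAY = 96485.332  # C/mol

#: fixed reversal potentials, mV (no Nernst updating during simulation)
REVERSALS = {"Na": 60.0, "K": -84.0, "Ca": 137.5, "h": -34.0, "leak": -48.0}

#: leak conductance density, S/cm^2, applied to every compartment
G_LEAK_DEFAULT = 3e-5

# gate "kind" codes shared with the numba kernel
KIND_VOLTAGE = 0  # Boltzmann(V)
KIND_CA_HILL = 1  # Hill([Ca])
KIND_BK = 2  # Boltzmann(V) with vh shifted by log10([Ca]/ca0)


@dataclass(frozen=True)
class GateSpec:
    """One gating particle: steady state and time constant of (V, [Ca])."""

    name: str
    exponent: int
    kind: int = KIND_VOLTAGE
    vhalf: float = 0.0  # mV
    k: float = 1.0  # mV; >0 activation, <0 inactivation
    tau_min: float = 1.0  # ms at T_ref
    tau_amp: float = 0.0  # ms
    vt: float = 0.0  # mV, tau bell centre
    s1: float = 10.0
    s2: float = 10.0
    kd: float = 3e-4  # mM (Hill) or mV/decade shift (BK)
    hill_n: float = 4.0  # Hill coefficient, or ca0 (mM) for BK
    q10: float = 3.0
    t_ref: float = 32.0  # degC at which tau_min/tau_amp are stated

    def inf(self, v: float, ca: float = 5e-5) -> float:
        if self.kind == KIND_CA_HILL:
            can = ca**self.hill_n
            return can / (can + self.kd**self.hill_n)
        vh = self.vhalf
        if self.kind == KIND_BK:
            vh = vh - self.kd * math.log10(max(ca, 1e-9) / self.hill_n)
        return 1.0 / (1.0 + math.exp((vh - v) / self.k))

    def tau(self, v: float, ca: float = 5e-5, temperature: float | None = None) -> float:
        if self.kind == KIND_CA_HILL or self.tau_amp == 0.0:
            t = self.tau_min
        else:
            x = v - self.vt
            t = self.tau_min + self.tau_amp / (math.exp(x / self.s1) + math.exp(-x / self.s2))
        if temperature is not None:
            t *= self.q10 ** ((self.t_ref - temperature) / 10.0)
        return t


@dataclass(frozen=True)
class ChannelSpec:
    """Named channel: list of gates with exponents, ion selectivity, source."""

    name: str
    ion: str  # Na | K | Ca | h | leak
    gates: tuple[GateSpec, ...] = ()
    source: str = ""

    def open_fraction(self, v: float, ca: float = 5e-5) -> float:
        p = 1.0
        for g in self.gates:
            p *= g.inf(v, ca) ** g.exponent
        return p

    def validate(self) -> None:
        if self.ion not in REVERSALS:
            raise ValueError(f"unknown ion {self.ion!r}")
        for g in self.gates:
            for v in np.linspace(-120.0, 60.0, 37):
                x = g.inf(v)
                if not (0.0 <= x <= 1.0):
                    raise ValueError(f"{self.name}/{g.name}: steady state outside [0,1]")
                if g.tau(v) <= 0.0:
                    raise ValueError(f"{self.name}/{g.name}: non-positive tau at {v} mV")


def gate_dynamics(spec: GateSpec, v: float, ca: float, temperature: float):
    """(steady state, tau at ``temperature``) for one gate.

    The Q10=3 correction is multiplicative on tau only:
    ``tau(T) = tau(T_ref) * q10**((T_ref - T)/10)``.
    """
    tau = spec.tau(v, ca, temperature)
    if tau <= 0.0:
        raise ValueError(f"gate {spec.name}: tau <= 0")
    return spec.inf(v, ca), tau


def channel_current(
    spec: ChannelSpec,
    gate_states,
    g_max: float,
    v: float,
    reversals: dict | None = None,
) -> float:
    """Ohmic current density ``I = G_max * prod(g_i^n_i) * (V - E_ion)``,
    outward positive, mA/cm^2 for ``g_max`` in S/cm^2."""
    reversals = reversals or REVERSALS
    if spec.ion not in reversals:
        raise ValueError(f"unknown ion {spec.ion!r}")
    p = 1.0
    for g, x in zip(spec.gates, gate_states):
        if not (0.0 <= x <= 1.0):
            raise ValueError("gate state outside [0,1]")
        p *= x**g.exponent
    return g_max * p * (v - reversals[spec.ion])


# ---------------------------------------------------------------------------
# Calcium pool


@dataclass
class CalciumPool:
    """Sub-membrane calcium shell with fast-buffer approximation.

    Parvalbumin-like buffering is folded into a constant capacity ratio
    ``kappa`` (bound/free), which scales the effective influx; free
    calcium relaxes back to ``ca_rest`` with time constant ``tau_ms``.
    """

    ca_rest: float = 5e-5  # mM (50 nM)
    depth_um: float = 0.2  # shell depth
    kappa: float = 60.0  # buffer capacity ratio
    tau_ms: float = 20.0  # extrusion time constant

    def influx_rate(self, i_ca_na: float, area_um2: float) -> float:
        """d[Ca]/dt (mM/ms) from an absolute Ca current in nA (inward < 0)."""
        vol_um3 = area_um2 * self.depth_um
        # I[nA]*1e-9 A / (2F * vol[L]); 1 um^3 = 1e-15 L; M/s == mM/ms
        return -i_ca_na * 1e6 / (2.0 * FARADAY * vol_um3) / (1.0 + self.kappa)


def step_calcium(pool: CalciumPool, ca: float, i_ca_na: float, area_um2: float, dt: float) -> float:
    """One exponential-Euler update of the pool; [Ca] never goes negative."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    j = pool.influx_rate(i_ca_na, area_um2)
    # dCa/dt = j - (ca - rest)/tau -> exact update against the fixed point
    target = pool.ca_rest + j * pool.tau_ms
    ca_new = target + (ca - target) * math.exp(-dt / pool.tau_ms)
    return max(ca_new, 0.0)


# ---------------------------------------------------------------------------
# Built-in library


def _bolt(name, n, vh, k, tmin, tamp, vt, s1, s2) -> GateSpec:
    return GateSpec(name, n, KIND_VOLTAGE, vh, k, tmin, tamp, vt, s1, s2)


_LIBRARY: tuple[ChannelSpec, ...] = (
    ChannelSpec(
        "Nav1.1",
        "Na",
        (
            _bolt("m", 3, -30.0, 5.0, 0.03, 0.15, -35.0, 12.0, 12.0),
            _bolt("h", 1, -55.0, -6.5, 0.8, 12.0, -55.0, 10.0, 12.0),
        ),
        source="transient Na, HH m3h fit (cortical/cerebellar interneuron literature)",
    ),
    ChannelSpec(
        "Nav1.6",
        "Na",
        (
            _bolt("m", 3, -40.0, 6.0, 0.03, 0.15, -42.0, 12.0, 12.0),
            _bolt("h", 1, -60.0, -6.5, 0.8, 12.0, -58.0, 10.0, 12.0),
        ),
        source="low-threshold Na with window current sustaining pacemaking",
    ),
    ChannelSpec(
        "Kv3.4",
        "K",
        (_bolt("n", 2, -16.0, 7.8, 0.20, 5.0, -50.0, 15.0, 30.0),),
        source="high-threshold fast-delayed rectifier (spike repolarization)",
    ),
    ChannelSpec(
        "Kv4.3",
        "K",
        (
            _bolt("a", 3, -45.0, 8.0, 0.30, 1.5, -50.0, 20.0, 20.0),
            _bolt("b", 1, -69.0, -6.5, 8.0, 30.0, -65.0, 10.0, 10.0),
        ),
        source="A-type, fast activation with slow inactivation (spike-delay control)",
    ),
    ChannelSpec(
        "Kv1.1",
        "K",
        (_bolt("n", 4, -30.0, 8.0, 1.0, 8.0, -35.0, 20.0, 20.0),),
        source="low-threshold slow delayed rectifier",
    ),
    ChannelSpec(
        "Kir2.3",
        "K",
        (_bolt("n", 1, -98.0, -10.0, 0.5, 0.0, 0.0, 10.0, 10.0),),
        source="inward rectifier: open fraction grows with hyperpolarization",
    ),
    ChannelSpec(
        "Kv7",
        "K",
        (_bolt("n", 1, -35.0, 9.0, 20.0, 80.0, -40.0, 15.0, 15.0),),
        source="M-type slow non-inactivating K",
    ),
    ChannelSpec(
        "KCa1.1",
        "K",
        (
            GateSpec(
                "o",
                1,
                KIND_BK,
                vhalf=-10.0,
                k=10.0,
                tau_min=0.5,
                tau_amp=1.0,
                vt=-20.0,
                s1=20.0,
                s2=20.0,
                kd=45.0,  # mV shift per decade of [Ca]
                hill_n=1e-3,  # reference [Ca], mM
            ),
        ),
        source="BK: V-dependent gate whose half-voltage shifts -45 mV/decade [Ca]",
    ),
    ChannelSpec(
        "KCa2.2",
        "K",
        (
            GateSpec(
                "z", 1, KIND_CA_HILL, tau_min=8.0, kd=3e-4, hill_n=4.0
            ),
        ),
        source="SK: purely Ca-dependent Hill activation (Kd 300 nM, n=4)",
    ),
    ChannelSpec(
        "Cav2.1",
        "Ca",
        (_bolt("m", 2, -18.0, 6.0, 0.20, 0.8, -25.0, 15.0, 15.0),),
        source="P/Q-type HVA, non-inactivating m2; feeds BK/SK",
    ),
    ChannelSpec(
        "Cav3.2",
        "Ca",
        (
            _bolt("m", 2, -52.0, 5.5, 1.0, 3.0, -55.0, 12.0, 12.0),
            _bolt("h", 1, -78.0, -5.5, 10.0, 40.0, -75.0, 10.0, 12.0),
        ),
        source="T-type LVA (fast variant): rebound burst generator",
    ),
    ChannelSpec(
        "Cav3.3",
        "Ca",
        (
            _bolt("m", 2, -50.0, 6.0, 4.0, 10.0, -55.0, 12.0, 12.0),
            _bolt("h", 1, -74.0, -6.0, 60.0, 120.0, -75.0, 10.0, 12.0),
        ),
        source="T-type LVA (slow variant)",
    ),
    ChannelSpec(
        "HCN1",
        "h",
        (_bolt("q", 1, -68.0, -4.0, 100.0, 1500.0, -72.0, 12.0, 25.0),),
        source="hyperpolarization-activated cation current (sag/rebound)",
    ),
    ChannelSpec("leak", "leak", (), source="ohmic leak, E=-48 mV"),
)

CHANNEL_NAMES = tuple(c.name for c in _LIBRARY)
ION_OF_CHANNEL = {c.name: c.ion for c in _LIBRARY}


def builtin_channel_library() -> list[ChannelSpec]:
    """All 14 channel specs (validated)."""
    for c in _LIBRARY:
        c.validate()
    return list(_LIBRARY)


def get_channel(name: str) -> ChannelSpec:
    for c in _LIBRARY:
        if c.name == name:
            return c
    raise KeyError(name)


#: the canonical 36-slot channel x compartment-class layout.  The source
#: figure shows the distribution graphically only, so this layout is an
#: explicit, overridable assumption: Na and the fast rectifier
#: concentrate in soma/AIS/axon, A-type / Ca / Ca-activated K extend
#: into the dendrites, HCN1 is somatodendritic.
CONDUCTANCE_LAYOUT: dict[str, tuple[str, ...]] = {
    "soma": (
        "Nav1.1",
        "Nav1.6",
        "Kv3.4",
        "Kv4.3",
        "Kv1.1",
        "Kir2.3",
        "Kv7",
        "KCa1.1",
        "KCa2.2",
        "Cav2.1",
        "Cav3.2",
        "HCN1",
    ),
    "proximal_dendrite": (
        "Kv4.3",
        "Kv1.1",
        "KCa1.1",
        "KCa2.2",
        "Cav2.1",
        "Cav3.2",
        "Cav3.3",
        "HCN1",
    ),
    "distal_dendrite": (
        "Kv4.3",
        "Kv1.1",
        "KCa1.1",
        "KCa2.2",
        "Cav2.1",
        "Cav3.2",
        "Cav3.3",
    ),
    "ais": ("Nav1.6", "Kv3.4", "Kv1.1", "Kv7", "Cav2.1"),
    "axon": ("Nav1.6", "Kv3.4", "Kv1.1", "KCa1.1"),
}

#: flat, ordered list of the 36 free (class, channel) conductance slots
CONDUCTANCE_SLOTS: tuple[tuple[str, str], ...] = tuple(
    (cls, ch) for cls in CONDUCTANCE_LAYOUT for ch in CONDUCTANCE_LAYOUT[cls]
)

assert len(CONDUCTANCE_SLOTS) == 36
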