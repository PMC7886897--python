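"""Declarative stimulation protocols.

These mirror the experimental paradigms used to constrain and probe the
stellate-cell model: 2-s somatic current steps (-16..+20 pA in 4-pA
increments), parallel-fiber pulse trains of 10-20 pulses at
4/10/20/50/100/200/500 Hz, a 20-Hz inhibitory background delivered
through 20, 27 or 32 GABA-A synapses, and ideal voltage clamp at
-70 mV for EPSC measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = [
    "StepProtocol",
    "TrainProtocol",
    "InhibitoryBackground",
    "ClampProtocol",
    "standard_battery",
    "optimization_battery",
    "pf_train_set",
    "train_times",
    "realize_events",
    "PF_TRAIN_FREQS",
]

PF_TRAIN_FREQS = (4.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0)


@dataclass(frozen=True)
class StepProtocol:
    """Somatic current step(s) on a holding current."""

    amplitudes_pA: tuple[float, ...]
    duration_ms: float = 2000.0
    holding_pA: float = 0.0
    pre_ms: float = 1000.0
    post_ms: float = 1000.0

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("step duration must be positive")

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.duration_ms + self.post_ms


@dataclass(frozen=True)
class TrainProtocol:
    """Pulse train delivered through a group of synapses."""

    n_pulses: int
    frequency_hz: float
    n_synapses: int = 3
    target: str = "pf"  # synapse group name
    onset_ms: float = 1000.0

    def __post_init__(self):
        if self.n_pulses < 1 or self.frequency_hz <= 0:
            raise ValueError("invalid train")

    @property
    def span_ms(self) -> float:
        return (self.n_pulses - 1) * 1000.0 / self.frequency_hz


@dataclass(frozen=True)
class InhibitoryBackground:
    """Sustained GABA-A drive from neighbouring stellate cells."""

    rate_hz: float = 20.0
    n_synapses: int = 32
    process: str = "periodic"  # periodic (random phase per synapse) | poisson
    seed: int = 0

    def __post_init__(self):
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")
        if self.process not in ("periodic", "poisson"):
            raise ValueError("process must be 'periodic' or 'poisson'")


@dataclass(frozen=True)
class ClampProtocol:
    """Ideal somatic voltage clamp with a concurrent synaptic train."""

    train: TrainProtocol
    clamp_mV: float = -70.0

    def __post_init__(self):
        if not (-120.0 <= self.clamp_mV <= 40.0):
            raise ValueError("clamp voltage out of range")


def optimization_battery(duration_ms: float = 2000.0) -> list[StepProtocol]:
    """The four-step optimization set: spontaneous (0 pA), +4, +16,
    -16 pA, each 2 s."""
    return [
        StepProtocol((0.0,), duration_ms),
        StepProtocol((4.0,), duration_ms),
        StepProtocol((16.0,), duration_ms),
        StepProtocol((-16.0,), duration_ms),
    ]


def standard_battery(duration_ms: float = 2000.0) -> list[StepProtocol]:
    """Optimization steps plus the extended -16..+20 pA / 4 pA ladder."""
    ladder = tuple(float(a) for a in range(-16, 21, 4))
    return optimization_battery(duration_ms) + [StepProtocol(ladder, duration_ms)]


def pf_train_set(n_pulses: int = 10, n_synapses: int = 3) -> list[TrainProtocol]:
    """Train protocols at the seven canonical frequencies."""
    return [TrainProtocol(n_pulses, f, n_synapses) for f in PF_TRAIN_FREQS]


def train_times(train: TrainProtocol) -> np.ndarray:
    """Deterministic pulse times of a train (ms)."""
    return train.onset_ms + np.arange(train.n_pulses) * 1000.0 / train.frequency_hz


def realize_events(
    background: InhibitoryBackground,
    duration_ms: float,
    seed: Optional[int] = None,
) -> list[np.ndarray]:
    """Per-synapse event streams for an inhibitory background.

    ``periodic``: each synapse fires strictly at the nominal rate with an
    independent uniformly random phase.  ``poisson``: independent Poisson
    trains at the nominal rate.  Reproducible given the seed.
    """
    rng = np.random.default_rng(background.seed if seed is None else seed)
    period = 1000.0 / background.rate_hz
    streams = []
    for _ in range(background.n_synapses):
        if background.process == "periodic":
            phase = rng.uniform(0.0, period)
            tt = np.arange(phase, duration_ms, period)
        else:
            n_exp = background.rate_hz * duration_ms / 1000.0
            n = rng.poisson(n_exp)
            tt = np.sort(rng.uniform(0.0, duration_ms, size=n))
        streams.append(tt)
    return streams
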