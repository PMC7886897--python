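"""Run configuration: schema-checked YAML for simulations.

A run config ties together a morphology source, a conductance genome,
protocols, recordings and global numerics.  Every stochastic element
carries a seed.  Units: ms, mV, pA, S/cm^2, um; documented per key in
the example emitted by :func:`example_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from .channels import CONDUCTANCE_SLOTS

__all__ = ["RunConfig", "ConfigError", "load_config", "example_config"]


class ConfigError(ValueError):
    pass


_PROTOCOL_KINDS = ("step", "train", "clamp_train")


@dataclass
class RunConfig:
    seed: int = 0
    dt_ms: float = 0.025
    temperature_C: float = 32.0
    morphology: dict = field(default_factory=lambda: {"source": "generate", "seed": 0})
    genome: Optional[list[float]] = None  # None -> reference optimized set
    protocols: list[dict] = field(default_factory=list)
    record: list[str] = field(default_factory=lambda: ["soma.v"])
    output_dir: str = "results"
    output_format: str = "csv"

    def validate(self) -> None:
        if self.dt_ms <= 0:
            raise ConfigError("dt_ms must be positive")
        if self.output_format not in ("csv",):
            raise ConfigError(f"unsupported output format {self.output_format!r}")
        src = self.morphology.get("source")
        if src not in ("generate", "swc"):
            raise ConfigError("morphology.source must be 'generate' or 'swc'")
        if src == "swc" and "path" not in self.morphology:
            raise ConfigError("morphology.source=swc requires morphology.path")
        if src == "generate" and "seed" not in self.morphology:
            raise ConfigError("morphology.source=generate requires morphology.seed")
        if self.genome is not None:
            if len(self.genome) != len(CONDUCTANCE_SLOTS):
                raise ConfigError(
                    f"genome must have {len(CONDUCTANCE_SLOTS)} entries, got {len(self.genome)}"
                )
            if any(g < 0 for g in self.genome):
                raise ConfigError("genome entries must be non-negative")
        for i, p in enumerate(self.protocols):
            kind = p.get("kind")
            if kind not in _PROTOCOL_KINDS:
                raise ConfigError(f"protocol {i}: unknown kind {kind!r}")
            if kind == "step":
                if "amplitudes_pA" not in p:
                    raise ConfigError(f"protocol {i}: step needs amplitudes_pA")
            else:
                for key in ("n_pulses", "frequency_hz"):
                    if key not in p:
                        raise ConfigError(f"protocol {i}: {kind} needs {key}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def example_config() -> str:
    return """\
# stellate run configuration (units in comments)
seed: 0               # global seed for stochastic elements
dt_ms: 0.025          # integration step, ms
temperature_C: 32.0   # simulation temperature
morphology:
  source: generate    # generate | swc
  seed: 1             # generator seed (generate)
  # path: cell.swc    # (swc)
genome: null          # 36 conductance densities S/cm^2; null = reference set
protocols:
  - kind: step        # somatic current step
    amplitudes_pA: [0, 4, 16, -16]
    duration_ms: 2000
  - kind: train       # PF burst onto distal dendrites
    n_pulses: 10
    frequency_hz: 100
    n_synapses: 3
record: [soma.v]
output_dir: results
output_format: csv
"""
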