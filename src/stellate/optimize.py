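"""Multi-objective evolutionary optimization of the 36 maximum
conductances.

The genome is the vector of (compartment class, channel) maximum
conductance densities; objectives are SEM-normalized absolute errors of
the electrophysiological features extracted from the standard somatic
step battery (spontaneous, +4, +16, -16 pA, 2 s each).  Selection uses
the Indicator-Based Evolutionary Algorithm (IBEA) with the additive
epsilon indicator; NSGA-II-style non-dominated sorting is available as
an alternative.  Search operates in log-conductance space (uniform
crossover plus multiplicative Gaussian mutation), which matches the
orders-of-magnitude spread of channel densities.

The full-scale preset is 100 individuals for 50 generations; the desk
preset (20 x 10) is the default and is meant to refine bounds centred
on a previously optimized parameter set.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np

from .channels import CONDUCTANCE_SLOTS
from .features import (
    FeatureTarget,
    MISSING_PENALTY,
    ap_shape,
    fitness,
    sag_rebound,
    train_stats,
)
from .solver import IntegrationError

__all__ = [
    "ParameterSpace",
    "OptimizerConfig",
    "Individual",
    "sc_parameter_space",
    "evaluate_sc",
    "sc_features",
    "optimize",
    "select_best",
    "pareto_front",
    "hypervolume_2d",
]


@dataclass(frozen=True)
class ParameterSpace:
    names: tuple[str, ...]
    low: np.ndarray
    high: np.ndarray

    def __post_init__(self):
        if not (len(self.names) == len(self.low) == len(self.high)):
            raise ValueError("inconsistent space")
        if np.any(self.low <= 0) or np.any(self.low >= self.high):
            raise ValueError("bounds must satisfy 0 < low < high")

    @property
    def n(self) -> int:
        return len(self.names)

    def clip(self, genome: np.ndarray) -> np.ndarray:
        return np.clip(genome, self.low, self.high)


def sc_parameter_space(
    center: Sequence[float], span: float = 2.0
) -> ParameterSpace:
    """Bounds ``center/span .. center*span`` for the 36 conductance slots."""
    c = np.asarray(center, dtype=float)
    if len(c) != len(CONDUCTANCE_SLOTS):
        raise ValueError("center must cover the 36 slots")
    names = tuple(f"{cls}.{ch}" for cls, ch in CONDUCTANCE_SLOTS)
    return ParameterSpace(names, c / span, c * span)


@dataclass(eq=False)
class Individual:
    genome: np.ndarray
    objectives: Optional[np.ndarray] = None
    features: dict = field(default_factory=dict)

    @property
    def total_error(self) -> float:
        return float(np.sum(self.objectives))


@dataclass
class OptimizerConfig:
    population: int = 20
    generations: int = 10
    algorithm: str = "ibea"  # or "nsga2"
    seed: int = 0
    kappa: float = 0.05
    mutation_sigma: float = 0.12  # log10 units
    mutation_prob: float = 0.35
    crossover_prob: float = 0.6
    center: Optional[Sequence[float]] = None  # seeds half the population
    checkpoint_dir: Optional[str] = None

    def __post_init__(self):
        if self.population < 2 or self.generations < 1:
            raise ValueError("population >= 2 and generations >= 1 required")
        if self.algorithm not in ("ibea", "nsga2"):
            raise ValueError("algorithm must be 'ibea' or 'nsga2'")


# ---------------------------------------------------------------------------
# Stellate-cell evaluation


def sc_features(
    cell,
    dt: float = 0.025,
    settle_ms: float = 400.0,
    step_ms: float = 2000.0,
) -> dict[str, float]:
    """Feature vector of the optimization battery for one cell."""
    from .models import run_step  # local import to avoid a cycle

    out: dict[str, float] = {}
    stride = 2

    # spontaneous: rate and spike shape
    ts = run_step(cell, 0.0, duration_ms=step_ms, pre_ms=settle_ms, post_ms=0.0,
                  dt=dt, record_stride=stride)
    sp = ts.spikes["soma"]
    stats = train_stats(sp, (settle_ms, settle_ms + step_ms))
    out["freq_0pA"] = stats.frequency_hz
    t, v = ts.t, ts.v["soma"]
    mid = [s for s in sp if settle_ms + 200 < s < settle_ms + step_ms - 100]
    if mid:
        shp = ap_shape(t, v, mid[len(mid) // 2])
        out["ap_half_width"] = shp.half_width_ms
        out["ap_amplitude"] = shp.amplitude_mV
        out["ap_threshold"] = shp.threshold_mV
        out["ap_ahp"] = shp.ahp_mV
    # depolarizing steps
    for amp in (4.0, 16.0):
        ts = run_step(cell, amp, duration_ms=step_ms, pre_ms=settle_ms, post_ms=0.0,
                      dt=dt, record_stride=stride)
        st = train_stats(ts.spikes["soma"], (settle_ms, settle_ms + step_ms))
        out[f"freq_{amp:.0f}pA"] = st.frequency_hz
    # hyperpolarizing step: sag and rebound
    ts = run_step(cell, -16.0, duration_ms=step_ms, pre_ms=settle_ms, post_ms=600.0,
                  dt=dt, record_stride=stride)
    sr = sag_rebound(
        ts.t, ts.v["soma"], (settle_ms, settle_ms + step_ms), ts.spikes["soma"]
    )
    out["sag_16pA"] = sr.sag_mV
    out["rebound_delay"] = sr.first_spike_delay_ms
    out["rebound_first_isi"] = sr.first_isi_ms
    # synaptic responsiveness: 10-pulse 100-Hz PF burst through 3 synapses
    from .models import run_train
    from .features import burst_rate_change
    from .protocols import TrainProtocol

    train = TrainProtocol(10, 100.0, n_synapses=3, onset_ms=settle_ms + 1100.0)
    ts = run_train(cell, train, duration_ms=settle_ms + 1300.0, dt=dt,
                   record_stride=stride)
    base, resp, pct = burst_rate_change(
        ts.spikes["soma"], train.onset_ms, train.span_ms + 10.0,
        baseline_ms=1000.0,
    )
    out["burst_100hz_pct"] = pct
    # latency of the burst: median spike time within the train window,
    # a cheap single-trial proxy for the PSTH rise latency
    sp = ts.spikes["soma"]
    in_train = sp[(sp >= train.onset_ms) & (sp < train.onset_ms + train.span_ms + 10.0)]
    if len(in_train):
        out["burst_median_latency"] = float(np.median(in_train) - train.onset_ms)
    # passive input resistance
    from .solver import input_resistance

    try:
        out["r_input"] = input_resistance(cell.model, cell.soma, dt=0.05)
    except Exception:
        pass
    return out


def evaluate_sc(
    genome: Sequence[float],
    targets: Optional[Sequence[FeatureTarget]] = None,
    geometry=None,
    dt: float = 0.025,
) -> tuple[np.ndarray, dict[str, float]]:
    """Objective vector (SEM-normalized errors) + raw features for one
    genome; integration failures yield the penalty fitness."""
    from .models import FEATURE_TARGETS, build_sc_cell

    targets = tuple(targets) if targets is not None else FEATURE_TARGETS
    try:
        cell = build_sc_cell(genome, geometry=geometry)
        feats = sc_features(cell, dt=dt)
    except IntegrationError:
        return np.full(len(targets), MISSING_PENALTY), {}
    return fitness(feats, targets), feats


# ---------------------------------------------------------------------------
# Selection machinery


def pareto_front(individuals: Sequence[Individual]) -> list[Individual]:
    """Non-dominated subset (minimization)."""
    front = []
    for a in individuals:
        dominated = False
        for b in individuals:
            if b is a:
                continue
            if np.all(b.objectives <= a.objectives) and np.any(
                b.objectives < a.objectives
            ):
                dominated = True
                break
        if not dominated:
            front.append(a)
    return front


def hypervolume_2d(points: np.ndarray, ref: tuple[float, float]) -> float:
    """Dominated hypervolume of 2-objective minimization points."""
    pts = np.asarray(points, dtype=float)
    pts = pts[np.argsort(pts[:, 0])]
    hv = 0.0
    prev_y = ref[1]
    for x, y in pts:
        if x >= ref[0] or y >= prev_y:
            continue
        hv += (ref[0] - x) * (prev_y - y)
        prev_y = y
    return hv


def _ibea_fitness(objs: np.ndarray, kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """IBEA fitness from the additive epsilon indicator on scaled
    objectives; returns (fitness, indicator matrix)."""
    lo = objs.min(axis=0)
    hi = objs.max(axis=0)
    span = np.where(hi - lo > 1e-12, hi - lo, 1.0)
    f = (objs - lo) / span
    n = len(f)
    ind = np.empty((n, n))
    for i in range(n):
        ind[i] = np.max(f[i][None, :] - f, axis=1) * -1.0  # I(j, i) per row? see below
    # ind[i, j] = I(i -> j) = max_k (f_i[k] - f_j[k])
    for i in range(n):
        for j in range(n):
            ind[i, j] = np.max(f[i] - f[j])
    c = max(np.abs(ind).max(), 1e-12)
    fit = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if j != i:
                fit[i] -= math.exp(-ind[j, i] / (kappa * c))
    return fit, ind / c


def _environmental_selection_ibea(
    pool: list[Individual], n_keep: int, kappa: float
) -> list[Individual]:
    objs = np.array([ind.objectives for ind in pool])
    fit, indmat = _ibea_fitness(objs, kappa)
    alive = list(range(len(pool)))
    while len(alive) > n_keep:
        worst_pos = int(np.argmin([fit[i] for i in alive]))
        worst = alive.pop(worst_pos)
        for i in alive:
            fit[i] += math.exp(-indmat[worst, i] / kappa)
    return [pool[i] for i in alive]


def _nsga2_selection(pool: list[Individual], n_keep: int) -> list[Individual]:
    remaining = list(pool)
    kept: list[Individual] = []
    while remaining and len(kept) < n_keep:
        front = pareto_front(remaining)
        if len(kept) + len(front) <= n_keep:
            kept.extend(front)
            remaining = [r for r in remaining if r not in front]
        else:
            # crowding distance on the splitting front
            objs = np.array([f.objectives for f in front])
            crowd = np.zeros(len(front))
            for k in range(objs.shape[1]):
                order = np.argsort(objs[:, k])
                crowd[order[0]] = crowd[order[-1]] = np.inf
                span = objs[order[-1], k] - objs[order[0], k]
                if span > 0:
                    for pos in range(1, len(order) - 1):
                        crowd[order[pos]] += (
                            objs[order[pos + 1], k] - objs[order[pos - 1], k]
                        ) / span
            take = np.argsort(-crowd)[: n_keep - len(kept)]
            kept.extend(front[i] for i in take)
            break
    return kept


# ---------------------------------------------------------------------------
# Main loop


def optimize(
    space: ParameterSpace,
    config: OptimizerConfig,
    eval_fn: Callable[[np.ndarray], tuple[np.ndarray, dict]],
    progress: Optional[Callable[[int, "OptimizeResult"], None]] = None,
) -> "OptimizeResult":
    """Run the evolutionary optimization; reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    log_lo = np.log10(space.low)
    log_hi = np.log10(space.high)

    def sample() -> np.ndarray:
        return 10.0 ** rng.uniform(log_lo, log_hi)

    def jitter_center() -> np.ndarray:
        c = np.asarray(config.center, dtype=float)
        return space.clip(c * 10.0 ** rng.normal(0.0, 0.08, size=space.n))

    pop: list[Individual] = []
    for i in range(config.population):
        if config.center is not None and i < config.population // 2:
            g = jitter_center() if i > 0 else space.clip(np.asarray(config.center, float))
        else:
            g = sample()
        pop.append(Individual(genome=g))

    def evaluate(batch: list[Individual]) -> None:
        for ind in batch:
            obj, feats = eval_fn(ind.genome)
            ind.objectives = np.asarray(obj, dtype=float)
            ind.features = feats

    evaluate(pop)
    result = OptimizeResult(space=space, config=config)
    result.update(pop, generation=0)

    for gen in range(1, config.generations + 1):
        offspring: list[Individual] = []
        while len(offspring) < config.population:
            a, b = _tournament(pop, rng), _tournament(pop, rng)
            g = a.genome.copy()
            if rng.random() < config.crossover_prob:
                swap = rng.random(space.n) < 0.5
                g[swap] = b.genome[swap]
            mut = rng.random(space.n) < config.mutation_prob
            g[mut] *= 10.0 ** rng.normal(0.0, config.mutation_sigma, size=int(mut.sum()))
            offspring.append(Individual(genome=space.clip(g)))
        evaluate(offspring)
        pool = pop + offspring
        if np.all([np.all(ind.objectives >= MISSING_PENALTY) for ind in pool]):
            raise RuntimeError("all individuals failed to integrate")
        if config.algorithm == "ibea":
            pop = _environmental_selection_ibea(pool, config.population, config.kappa)
        else:
            pop = _nsga2_selection(pool, config.population)
        result.update(pop, generation=gen)
        if config.checkpoint_dir:
            result.checkpoint(gen)
        if progress:
            progress(gen, result)
    return result


def _tournament(pop: list[Individual], rng) -> Individual:
    a, b = rng.integers(len(pop)), rng.integers(len(pop))
    return pop[a] if pop[a].total_error <= pop[b].total_error else pop[b]


@dataclass
class OptimizeResult:
    space: ParameterSpace
    config: OptimizerConfig
    population: list[Individual] = field(default_factory=list)
    archive: list[Individual] = field(default_factory=list)
    hall_of_fame: list[Individual] = field(default_factory=list)
    best_per_generation: list[float] = field(default_factory=list)

    def update(self, pop: list[Individual], generation: int) -> None:
        self.population = pop
        merged = {id(i): i for i in self.archive + pop}
        self.archive = pareto_front(list(merged.values()))
        ranked = sorted(self.archive, key=lambda i: i.total_error)
        self.hall_of_fame = ranked[:10]
        best = min(i.total_error for i in pop)
        if self.best_per_generation:
            best = min(best, self.best_per_generation[-1])
        self.best_per_generation.append(best)

    @property
    def best(self) -> Individual:
        return self.hall_of_fame[0]

    def checkpoint(self, gen: int) -> None:
        os.makedirs(self.config.checkpoint_dir, exist_ok=True)
        path = os.path.join(self.config.checkpoint_dir, f"gen{gen:04d}.json")
        with open(path, "w") as fh:
            json.dump(
                {
                    "generation": gen,
                    "best_per_generation": self.best_per_generation,
                    "hall_of_fame": [
                        {
                            "genome": ind.genome.tolist(),
                            "objectives": ind.objectives.tolist(),
                            "total_error": ind.total_error,
                            "features": ind.features,
                        }
                        for ind in self.hall_of_fame
                    ],
                },
                fh,
                indent=1,
            )


def select_best(
    archive: Sequence[Individual],
    n: int = 4,
    weights: Optional[np.ndarray] = None,
) -> list[Individual]:
    """Top-n archive members by weighted total error; ties broken by
    lower total conductance."""
    if not archive:
        raise ValueError("empty archive")

    def key(ind: Individual):
        err = (
            float(np.dot(weights, ind.objectives))
            if weights is not None
            else ind.total_error
        )
        return (round(err, 9), float(np.sum(ind.genome)))

    return sorted(archive, key=key)[:n]
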