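"""Electrophysiological feature extraction.

Features follow the conventions used to characterize stellate cells:

* spike *detection* is an upward crossing of -20 mV with a 1-ms
  refractory;
* the spike *threshold* (AP_thr) is the voltage at the maximum of the
  second derivative of V on the rising phase within 5 ms before the
  peak, after light Savitzky-Golay smoothing;
* AP_Ampl = peak - threshold; AP_HW = width at the threshold/peak
  midpoint; AP_AHP = threshold - post-peak minimum;
* AP_Freq = spike count / window duration; PSTHs use 40-ms bins;
* the hyperpolarizing sag is the early minimum minus the late steady
  state during the step, with a single-exponential fit of the
  relaxation;
* fitness for optimization is the per-feature |model - mean| / SEM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

__all__ = [
    "detect_spikes",
    "ap_threshold",
    "ap_shape",
    "APShape",
    "train_stats",
    "SpikeTrainStats",
    "psth",
    "PSTH",
    "sag_rebound",
    "SagRebound",
    "pause_length",
    "FeatureTarget",
    "fitness",
    "io_gain_curve",
    "burst_rate_change",
    "response_onset",
]

SPIKE_THRESHOLD_MV = -20.0
SPIKE_REFRACTORY_MS = 1.0
PSTH_BIN_MS = 40.0
MISSING_PENALTY = 250.0


def detect_spikes(
    t: np.ndarray, v: np.ndarray, threshold: float = SPIKE_THRESHOLD_MV
) -> np.ndarray:
    """Spike peak times from upward threshold crossings (1-ms refractory)."""
    t = np.asarray(t)
    v = np.asarray(v)
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    times = []
    last = -math.inf
    for i in up:
        if t[i] - last < SPIKE_REFRACTORY_MS:
            continue
        last = t[i]
        # refine to the local maximum within 2 ms
        j1 = min(len(v), i + int(round(2.0 / (t[1] - t[0]))))
        times.append(t[i + int(np.argmax(v[i:j1]))])
    return np.asarray(times)


def _peak_index(t: np.ndarray, spike_time: float) -> int:
    return int(np.searchsorted(t, spike_time))


def ap_threshold(
    t: np.ndarray,
    v: np.ndarray,
    spike_time: float,
    window_ms: float = 5.0,
    smooth_ms: float = 0.3,
) -> float:
    """Threshold voltage at the maximum of d2V/dt2 on the rising phase.

    Returns NaN (with a warning) when no rising phase precedes the peak.
    """
    t = np.asarray(t)
    v = np.asarray(v)
    dt = t[1] - t[0]
    ip = _peak_index(t, spike_time)
    ip = min(ip + int(np.argmax(v[ip : ip + int(2.0 / dt) + 1])), len(v) - 1)
    i0 = max(0, ip - int(round(window_ms / dt)))
    seg = v[i0 : ip + 1]
    if len(seg) < 7 or seg[-1] <= seg[0] or v[ip] < SPIKE_THRESHOLD_MV:
        warnings.warn("no rising phase found; threshold undefined")
        return float("nan")
    win = max(5, int(round(smooth_ms / dt)) | 1)
    if win >= len(seg):
        win = (len(seg) - 1) | 1
    sm = savgol_filter(seg, win, 3)
    d2 = np.gradient(np.gradient(sm, dt), dt)
    return float(sm[int(np.argmax(d2[: len(d2) - 1]))])


@dataclass
class APShape:
    threshold_mV: float
    amplitude_mV: float
    half_width_ms: float
    ahp_mV: float


def ap_shape(t: np.ndarray, v: np.ndarray, spike_time: float) -> APShape:
    """Shape of one action potential (NaN fields if truncated)."""
    t = np.asarray(t)
    v = np.asarray(v)
    dt = t[1] - t[0]
    thr = ap_threshold(t, v, spike_time)
    ip = _peak_index(t, spike_time)
    ip = min(ip + int(np.argmax(v[ip : ip + int(2.0 / dt) + 1])), len(v) - 1)
    peak = float(v[ip])
    nan = float("nan")
    if math.isnan(thr):
        return APShape(nan, nan, nan, nan)
    ampl = peak - thr
    mid = 0.5 * (thr + peak)
    # half-width: crossings of mid around the peak
    i_up = ip
    while i_up > 0 and v[i_up] > mid:
        i_up -= 1
    i_dn = ip
    while i_dn < len(v) - 1 and v[i_dn] > mid:
        i_dn += 1
    if i_up == 0 or i_dn >= len(v) - 1:
        return APShape(thr, ampl, nan, nan)

    def cross(i, j):  # linear interpolation of the mid crossing
        return t[i] + (mid - v[i]) / (v[j] - v[i]) * dt

    hw = cross(i_dn - 1, i_dn) - cross(i_up + 1, i_up)
    # AHP: minimum between the fall below the detection level and the
    # next spike's rise above it (or within 25 ms)
    j1 = min(len(v), ip + int(25.0 / dt))
    below = np.flatnonzero(v[ip:j1] < SPIKE_THRESHOLD_MV)
    if len(below) == 0:
        return APShape(thr, ampl, hw, nan)
    fall = ip + below[0]
    nxt = np.flatnonzero(v[fall:j1] >= SPIKE_THRESHOLD_MV)
    seg_end = fall + (nxt[0] if len(nxt) else j1 - fall)
    ahp = thr - float(np.min(v[fall:seg_end]))
    return APShape(thr, ampl, hw, ahp)


@dataclass
class SpikeTrainStats:
    spike_times: np.ndarray
    frequency_hz: float
    isi_ms: np.ndarray
    isi_hist: tuple[np.ndarray, np.ndarray]  # (counts, bin edges)


def train_stats(
    spike_times: Sequence[float],
    window_ms: tuple[float, float],
    isi_bin_ms: float = 5.0,
) -> SpikeTrainStats:
    st = np.asarray(spike_times, dtype=float)
    t0, t1 = window_ms
    st = st[(st >= t0) & (st < t1)]
    freq = len(st) / ((t1 - t0) / 1000.0)
    isi = np.diff(st)
    if len(isi):
        edges = np.arange(0.0, isi.max() + isi_bin_ms, isi_bin_ms)
        counts, edges = np.histogram(isi, bins=edges)
    else:
        counts, edges = np.zeros(0, dtype=int), np.zeros(1)
    return SpikeTrainStats(st, freq, isi, (counts, edges))


@dataclass
class PSTH:
    edges_ms: np.ndarray  # relative to stimulus onset
    counts: np.ndarray
    n_trials: int

    @property
    def rate_hz(self) -> np.ndarray:
        bw = self.edges_ms[1] - self.edges_ms[0]
        return self.counts / self.n_trials / (bw / 1000.0)


def psth(
    spike_trains: Sequence[Sequence[float]],
    onset_ms: float,
    window_ms: tuple[float, float] = (-1000.0, 1000.0),
    bin_ms: float = PSTH_BIN_MS,
) -> PSTH:
    """Peri-stimulus time histogram across trials, aligned to onset."""
    edges = np.arange(window_ms[0], window_ms[1] + bin_ms, bin_ms)
    counts = np.zeros(len(edges) - 1, dtype=float)
    for train in spike_trains:
        rel = np.asarray(train, dtype=float) - onset_ms
        c, _ = np.histogram(rel, bins=edges)
        counts += c
    return PSTH(edges, counts, len(spike_trains))


@dataclass
class SagRebound:
    sag_mV: float
    sag_tau_ms: float
    first_spike_delay_ms: float
    first_isi_ms: float


def sag_rebound(
    t: np.ndarray,
    v: np.ndarray,
    step_window_ms: tuple[float, float],
    spike_times: Optional[np.ndarray] = None,
) -> SagRebound:
    """Sag amplitude/decay during a hyperpolarizing step and rebound
    timing after it.

    Sag = early minimum minus late steady state (mean of the last 20% of
    the step); its decay time constant comes from a single-exponential
    fit between the minimum and step offset.  First-spike delay and
    first ISI are measured from the step offset (NaN without rebound
    spikes).
    """
    t = np.asarray(t)
    v = np.asarray(v)
    t0, t1 = step_window_ms
    dt = t[1] - t[0]
    in_step = (t >= t0) & (t < t1)
    vs = v[in_step]
    ts = t[in_step]
    # search the early minimum in the first half of the step
    half = len(vs) // 2
    imin = int(np.argmin(vs[:half]))
    late = vs[int(0.8 * len(vs)) :]
    v_steady = float(np.mean(late))
    sag = float(v_steady - vs[imin])
    # exponential fit of the relaxation from the minimum to step offset
    tau = float("nan")
    seg_t = ts[imin:] - ts[imin]
    seg_v = vs[imin:]
    if len(seg_t) > 10 and sag > 1e-3:
        try:
            popt, _ = curve_fit(
                lambda x, a, tau_, c: c - a * np.exp(-x / tau_),
                seg_t,
                seg_v,
                p0=(sag, max(50.0, seg_t[-1] / 5), v_steady),
                maxfev=10000,
            )
            tau = float(popt[1])
        except RuntimeError:
            pass
    if spike_times is None:
        spike_times = detect_spikes(t, v)
    reb = spike_times[spike_times >= t1]
    if len(reb) == 0:
        return SagRebound(max(sag, 0.0), tau, float("nan"), float("nan"))
    delay = float(reb[0] - t1)
    first_isi = float(reb[1] - reb[0]) if len(reb) > 1 else float("nan")
    return SagRebound(max(sag, 0.0), tau, delay, first_isi)


def pause_length(
    spike_times: Sequence[float],
    step_offset_ms: float,
    baseline_window_ms: tuple[float, float],
) -> float:
    """Time from a depolarizing-step offset to the first resumed spike."""
    st = np.asarray(spike_times, dtype=float)
    after = st[st >= step_offset_ms]
    if len(after) == 0:
        return float("nan")
    return float(after[0] - step_offset_ms)


@dataclass(frozen=True)
class FeatureTarget:
    name: str
    mean: float
    sem: float
    protocol: str = ""

    def __post_init__(self):
        if self.sem <= 0:
            raise ValueError("SEM must be positive")


def fitness(
    values: dict[str, float],
    targets: Sequence[FeatureTarget],
    penalty: float = MISSING_PENALTY,
) -> np.ndarray:
    """SEM-normalized absolute errors, one per target; missing or NaN
    features receive the penalty constant."""
    out = np.empty(len(targets))
    for i, tg in enumerate(targets):
        val = values.get(tg.name)
        if val is None or not np.isfinite(val):
            out[i] = penalty
        else:
            out[i] = abs(val - tg.mean) / tg.sem
    return out


def io_gain_curve(x: Sequence[float], rates_hz: Sequence[float]) -> float:
    """Least-squares slope of an input/output rate curve (Hz per unit x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(rates_hz, dtype=float)
    a = np.vstack([x, np.ones_like(x)]).T
    slope, _ = np.linalg.lstsq(a, y, rcond=None)[0]
    return float(slope)


def burst_rate_change(
    spike_times: Sequence[float],
    train_onset_ms: float,
    train_span_ms: float,
    baseline_ms: float = 1000.0,
) -> tuple[float, float, float]:
    """(baseline rate, during-train rate, percent change).

    Baseline is the mean rate in the ``baseline_ms`` window preceding the
    train; the response is the mean rate during the train window.
    """
    st = np.asarray(spike_times, dtype=float)
    nb = np.sum((st >= train_onset_ms - baseline_ms) & (st < train_onset_ms))
    base = nb / (baseline_ms / 1000.0)
    span = max(train_span_ms, 1.0)
    nr = np.sum((st >= train_onset_ms) & (st < train_onset_ms + span))
    resp = nr / (span / 1000.0)
    pct = (resp - base) / base * 100.0 if base > 0 else float("nan")
    return float(base), float(resp), float(pct)


def response_onset(
    hist: PSTH,
    min_sigma: float = 2.0,
    criterion: str = "sigma",
) -> float:
    """Latency (ms) of the post-onset rate rise in a PSTH.

    ``criterion="sigma"``: first *sustained* increase -- two consecutive
    bins exceeding the pre-onset baseline by ``min_sigma`` baseline
    standard deviations (a single elevated bin, e.g. one phase-advanced
    spike, does not count).  ``criterion="half_peak"``: first bin
    reaching halfway between the baseline and the peak response -- the
    half-rise latency, robust for ramping responses whose early bins are
    weakly elevated.

    Returns NaN when no bin crosses the criterion.
    """
    centers = 0.5 * (hist.edges_ms[:-1] + hist.edges_ms[1:])
    rate = hist.rate_hz
    pre = rate[centers < 0]
    if len(pre) < 2:
        raise ValueError("need pre-onset bins for a baseline")
    mu, sd = float(np.mean(pre)), float(np.std(pre))
    half_bin = 0.5 * (hist.edges_ms[1] - hist.edges_ms[0])
    post = np.flatnonzero(centers >= 0)
    if criterion == "half_peak":
        peak = float(np.max(rate[post]))
        if peak <= mu:
            return float("nan")
        crit = mu + 0.5 * (peak - mu)
        for i, j in zip(post[:-1], post[1:]):
            if rate[i] >= crit and rate[j] >= crit * 0.75:
                return float(centers[i] - half_bin)
        return float("nan")
    crit = mu + min_sigma * max(sd, 1e-9)
    for i, j in zip(post[:-1], post[1:]):
        if rate[i] > crit and rate[j] > crit:
            return float(centers[i] - half_bin)
    return float("nan")
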