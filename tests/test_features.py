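"""Feature extraction on constructed analytic waveforms."""

import math

import numpy as np
import pytest

from stellate.features import (
    FeatureTarget,
    PSTH_BIN_MS,
    ap_shape,
    ap_threshold,
    burst_rate_change,
    detect_spikes,
    fitness,
    io_gain_curve,
    pause_length,
    psth,
    response_onset,
    sag_rebound,
    train_stats,
)

DT = 0.025


def _synthetic_spike_train(rate_hz=25.0, duration_ms=2000.0,
                           thr=-40.0, peak=5.0, rest=-58.0):
    """Piecewise-analytic pacemaking trace with known spike geometry."""
    t = np.arange(0.0, duration_ms, DT)
    v = np.full_like(t, rest)
    period = 1000.0 / rate_hz
    spikes = np.arange(period, duration_ms - 5.0, period)
    for s in spikes:
        # slow exponential approach to threshold, sharp rise, fall, AHP
        ramp = (t >= s - 12.0) & (t < s - 1.0)
        v[ramp] = rest + (thr - rest) * (t[ramp] - (s - 12.0)) / 11.0
        # abrupt slope change at the threshold knee puts the curvature
        # maximum exactly at thr
        rise = (t >= s - 1.0) & (t < s)
        v[rise] = thr + (peak - thr) * (t[rise] - (s - 1.0)) / 1.0
        fall = (t >= s) & (t < s + 1.5)
        v[fall] = peak - (peak - (rest - 7.0)) * (t[fall] - s) / 1.5
        ahp = (t >= s + 1.5) & (t < s + 8.0)
        v[ahp] = (rest - 7.0) + 7.0 * (t[ahp] - (s + 1.5)) / 6.5
    return t, v, spikes


class TestThresholdAndShape:
    def test_constructed_threshold_recovered(self):
        t, v, spikes = _synthetic_spike_train()
        det = detect_spikes(t, v)
        assert len(det) == len(spikes)
        thr = ap_threshold(t, v, det[2])
        # the curvature maximum sits at the ramp->rise knee near -40 mV
        assert thr == pytest.approx(-40.0, abs=2.0)

    def test_no_spike_returns_nan(self):
        t = np.arange(0, 100, DT)
        v = -60 + 0.1 * t  # linear ramp
        with pytest.warns(UserWarning):
            assert math.isnan(ap_threshold(t, v, 50.0))

    def test_triangle_pulse_geometry(self):
        t = np.arange(0.0, 40.0, DT)
        v = np.full_like(t, 0.0) - 60.0
        # triangle: rises 0->40 over 2 ms, falls back over 2 ms
        up = (t >= 10.0) & (t < 12.0)
        dn = (t >= 12.0) & (t < 14.0)
        v[up] = -60 + (40 + 60) * (t[up] - 10.0) / 2.0
        v[dn] = 40 - (40 + 60) * (t[dn] - 12.0) / 2.0
        shp = ap_shape(t, v, 12.0)
        # amplitude = peak - threshold; half-width measured at midpoint
        assert shp.amplitude_mV == pytest.approx(40 - shp.threshold_mV, abs=1.0)
        mid = 0.5 * (shp.threshold_mV + 40)
        # width of the triangle at the mid level (rise+fall are symmetric)
        expected_hw = 2 * 2.0 * (40 - mid) / 100.0
        assert shp.half_width_ms == pytest.approx(expected_hw, abs=0.1)


class TestTrainStats:
    def test_rate_definition(self):
        st = train_stats(np.linspace(100, 1900, 10), (0.0, 2000.0))
        assert st.frequency_hz == 5.0

    def test_empty_train(self):
        st = train_stats([], (0.0, 1000.0))
        assert st.frequency_hz == 0.0
        assert len(st.isi_ms) == 0

    def test_jittered_periodic_train_histogram_peaks_at_period(self, rng):
        period = 40.0
        spikes = np.cumsum(period + rng.normal(0, 1.0, 500))
        st = train_stats(spikes, (0.0, spikes[-1] + 1), isi_bin_ms=5.0)
        counts, edges = st.isi_hist
        peak_bin = edges[np.argmax(counts)]
        assert abs(peak_bin + 2.5 - period) <= 5.0


class TestPSTH:
    def test_single_spike_lands_in_first_bin(self):
        h = psth([[1010.0]], onset_ms=1000.0, window_ms=(-200, 200))
        centers = 0.5 * (h.edges_ms[:-1] + h.edges_ms[1:])
        assert h.counts[np.flatnonzero(centers == PSTH_BIN_MS / 2)[0]] == 1

    def test_count_conservation(self, rng):
        trains = [rng.uniform(0, 2000, 50) for _ in range(10)]
        h = psth(trains, onset_ms=1000.0, window_ms=(-1000, 1000))
        assert h.counts.sum() == 500

    def test_uniform_rate_expectation(self, rng):
        rate = 50.0  # Hz
        trains = [
            np.sort(rng.uniform(0, 2000, rng.poisson(rate * 2.0)))
            for _ in range(200)
        ]
        h = psth(trains, onset_ms=1000.0, window_ms=(-1000, 1000))
        np.testing.assert_allclose(h.rate_hz.mean(), rate, rtol=0.05)


class TestSagRebound:
    def test_constructed_double_exponential_sag(self):
        dt = 0.05
        t = np.arange(0.0, 3000.0, dt)
        v = np.full_like(t, -58.0)
        t0, t1 = 500.0, 2500.0
        tau_in, tau_sag, v_min, v_ss = 30.0, 150.0, -75.0, -65.0
        inside = (t >= t0) & (t < t1)
        ti = t[inside] - t0
        # instantaneous drop to v_min then relaxation to v_ss with tau_sag
        v[inside] = v_ss - (v_ss - v_min) * np.exp(-ti / tau_sag)
        sr = sag_rebound(t, v, (t0, t1), spike_times=np.array([2510.0, 2530.0]))
        assert sr.sag_mV == pytest.approx(v_ss - v_min, abs=0.3)
        assert sr.sag_tau_ms == pytest.approx(tau_sag, rel=0.05)
        assert sr.first_spike_delay_ms == pytest.approx(10.0)
        assert sr.first_isi_ms == pytest.approx(20.0)

    def test_passive_trace_has_zero_sag(self):
        t = np.arange(0.0, 2000.0, 0.05)
        v = np.full_like(t, -58.0)
        v[(t >= 500) & (t < 1500)] = -70.0
        sr = sag_rebound(t, v, (500.0, 1500.0), spike_times=np.array([]))
        assert sr.sag_mV == pytest.approx(0.0, abs=1e-9)
        assert math.isnan(sr.first_spike_delay_ms)


class TestPauseAndRates:
    def test_constructed_silent_gap(self):
        spikes = np.concatenate([np.arange(0, 1000, 40.0), [1300.0, 1340.0]])
        assert pause_length(spikes, 1000.0, (0.0, 1000.0)) == pytest.approx(300.0)

    def test_immediate_resumption_is_baseline_isi(self):
        spikes = np.arange(0.0, 2000.0, 40.0)
        p = pause_length(spikes, 1000.0, (0.0, 1000.0))
        assert p <= 40.0

    def test_burst_rate_change_definition(self):
        spikes = np.concatenate([np.arange(0, 1000, 50.0),
                                 np.arange(1000, 1100, 10.0)])
        base, resp, pct = burst_rate_change(spikes, 1000.0, 100.0)
        assert base == 20.0
        assert resp == 100.0
        assert pct == pytest.approx(400.0)

    def test_response_onset_detects_shifted_burst(self, rng):
        trains = []
        for _ in range(20):
            baseline = rng.uniform(-1000, 0, 20)
            burst = rng.uniform(50, 150, 15)
            trains.append(np.concatenate([baseline, burst]))
        h = psth(trains, 0.0, window_ms=(-1000, 400), bin_ms=10.0)
        onset = response_onset(h)
        assert 30.0 <= onset <= 70.0


class TestFitness:
    TARGETS = (
        FeatureTarget("a", 10.0, 2.0),
        FeatureTarget("b", -5.0, 1.0),
    )

    def test_zero_iff_equal_to_means(self):
        f = fitness({"a": 10.0, "b": -5.0}, self.TARGETS)
        np.testing.assert_array_equal(f, [0.0, 0.0])

    def test_sem_normalization(self):
        f = fitness({"a": 14.0, "b": -5.0}, self.TARGETS)
        assert f[0] == pytest.approx(2.0)

    def test_missing_feature_penalized(self):
        f = fitness({"a": 10.0}, self.TARGETS, penalty=99.0)
        assert f[1] == 99.0

    def test_nan_feature_penalized(self):
        f = fitness({"a": float("nan"), "b": -5.0}, self.TARGETS, penalty=99.0)
        assert f[0] == 99.0


class TestIOGain:
    def test_linear_curve_slope(self):
        x = np.array([4, 8, 12, 16, 20.0])
        assert io_gain_curve(x, 2.0 * x + 24.0) == pytest.approx(2.0)

    def test_flat_curve_zero_slope(self):
        assert io_gain_curve([4, 8, 12.0], [30.0, 30.0, 30.0]) == pytest.approx(0.0)
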