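"""Tsodyks-Markram release dynamics and receptor conductances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stellate.synapses import (
    PF_SC_AMPA,
    PF_SC_NMDA,
    SC_GABAA,
    ReceptorKinetics,
    TMParams,
    gain_curve,
    nmda_block,
    receptor_g,
    stp_switch,
    tm_fixed_point,
    tm_train,
    tm_update,
)


class TestTMRecursion:
    def test_first_release_is_p(self):
        rel = tm_train([0.0], PF_SC_AMPA.tm)
        assert rel[0] == pytest.approx(PF_SC_AMPA.tm.p)

    def test_full_recovery_for_distant_spikes(self):
        rel = tm_train([0.0, 1e7], PF_SC_AMPA.tm)
        assert rel[1] == pytest.approx(rel[0], rel=1e-9)

    @pytest.mark.parametrize("freq", [50.0, 100.0, 200.0])
    def test_pf_train_facilitates_then_depresses(self, freq):
        tt = np.arange(20) * 1000.0 / freq
        rel = tm_train(tt, PF_SC_AMPA.tm)
        assert rel[1] > rel[0]  # early facilitation
        assert rel[-1] < rel.max()  # later depression

    def test_negative_interval_rejected(self):
        with pytest.raises(ValueError):
            tm_update((1.0, 0.0, 10.0), 5.0, PF_SC_AMPA.tm)

    @pytest.mark.parametrize("freq", [4.0, 20.0, 100.0, 500.0])
    def test_recursion_converges_to_analytic_fixed_point(self, freq):
        tt = np.arange(3000) * 1000.0 / freq
        rel = tm_train(tt, PF_SC_AMPA.tm)
        assert rel[-1] == pytest.approx(tm_fixed_point(freq, PF_SC_AMPA.tm), abs=1e-9)

    def test_gaba_train_purely_depressing(self):
        for freq in (20.0, 50.0, 100.0):
            tt = np.arange(20) * 1000.0 / freq
            rel = tm_train(tt, SC_GABAA.tm)
            assert np.all(np.diff(rel) <= 1e-12)

    @given(
        isis=st.lists(st.floats(0.1, 500.0), min_size=1, max_size=60),
        p=st.floats(0.01, 1.0),
        tau_r=st.floats(0.0, 200.0),
        tau_f=st.floats(0.0, 200.0),
    )
    @settings(deadline=None, max_examples=80)
    def test_state_variables_stay_in_unit_interval(self, isis, p, tau_r, tau_f):
        params = TMParams(p=p, tau_r=tau_r, tau_f=tau_f)
        state = (1.0, 0.0, -math.inf)
        t = 0.0
        for isi in isis:
            t += isi
            release, state = tm_update(state, t, params)
            r, u, _ = state
            assert 0.0 <= r <= 1.0
            assert 0.0 <= u <= 1.0
            assert 0.0 <= release <= 1.0


class TestReceptor:
    def test_no_events_no_conductance(self):
        t = np.linspace(0, 50, 500)
        g = receptor_g(t, [], PF_SC_AMPA.kinetics, 2300.0)
        assert np.all(g == 0)

    def test_single_event_peak_closed_form(self):
        t = np.linspace(0, 200, 20000)
        g = receptor_g(t, [(10.0, 0.5)], PF_SC_NMDA.kinetics, 10000.0)
        kin = PF_SC_NMDA.kinetics
        assert g.max() == pytest.approx(0.5 * 10000.0 * kin.peak_open, rel=1e-3)

    def test_coincident_events_additive(self):
        t = np.linspace(0, 50, 5000)
        one = receptor_g(t, [(5.0, 0.2)], PF_SC_AMPA.kinetics, 2300.0)
        two = receptor_g(t, [(5.0, 0.2), (5.0, 0.2)], PF_SC_AMPA.kinetics, 2300.0)
        np.testing.assert_allclose(two, 2 * one, rtol=1e-12)

    def test_unordered_events_rejected(self):
        with pytest.raises(ValueError):
            receptor_g(np.arange(10.0), [(5.0, 0.1), (1.0, 0.1)],
                       PF_SC_AMPA.kinetics, 100.0)


class TestMgBlock:
    def test_zero_mg_fully_unblocked(self):
        assert nmda_block(-70.0, 0.0) == 1.0

    def test_monotone_in_voltage(self):
        assert nmda_block(-70.0) < nmda_block(0.0)

    def test_standard_parameters_closed_form(self):
        v, mg = -70.0, 1.0
        expected = 1.0 / (1.0 + mg / 3.57 * math.exp(-0.062 * v))
        assert nmda_block(v, mg) == pytest.approx(expected, rel=1e-12)


class TestSTPSwitch:
    def test_stf_off_scales_tau_f_tenfold(self):
        out = stp_switch(PF_SC_AMPA.tm, "STF_off")
        assert out.tau_f == pytest.approx(108.0)

    def test_std_off_zeroes_tau_r(self):
        assert stp_switch(PF_SC_AMPA.tm, "STD_off").tau_r == 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            stp_switch(PF_SC_AMPA.tm, "both_off")

    def test_no_facilitation_train_monotone_non_increasing(self):
        # facilitation disabled analog: tau_f -> ~0
        params = TMParams(p=PF_SC_AMPA.tm.p, tau_r=PF_SC_AMPA.tm.tau_r, tau_f=1e-9)
        tt = np.arange(20) * 10.0
        rel = tm_train(tt, params)
        assert np.all(np.diff(rel) <= 1e-12)


class TestGainCurve:
    def test_flat_curve_has_no_half_frequency(self):
        with pytest.raises(RuntimeError):
            gain_curve([4, 10, 20, 50], [1.0, 1.0, 1.0, 1.0])

    def test_too_few_frequencies_rejected(self):
        with pytest.raises(ValueError):
            gain_curve([4, 10, 20], [1, 2, 3])

    def test_recovers_known_sigmoid_midpoint(self):
        freqs = np.array([4, 10, 20, 50, 100, 200, 500], dtype=float)
        x = np.log10(freqs)
        gains = 1.0 + 2.0 / (1.0 + np.exp((np.log10(50.0) - x) / 0.25))
        fh, _ = gain_curve(freqs, gains)
        assert fh == pytest.approx(50.0, rel=0.02)

    def test_frequency_insensitive_synapse_gain_is_one(self):
        # p=1, no facilitation: every release equals the first
        params = TMParams(p=1.0, tau_r=0.0, tau_f=0.0)
        for freq in (4.0, 100.0, 500.0):
            rel = tm_train(np.arange(20) * 1000.0 / freq, params)
            np.testing.assert_allclose(rel, rel[0])
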