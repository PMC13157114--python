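"""Spectral amplitude extraction and attentional-bias scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressphys.containers import EpochSet, TrialCondition
from stressphys.preprocess import epoch
from stressphys.ssvep import (SSVEP_CLUSTER, WINDOWS, abs_score, abs_table,
                              fft_amplitude, morlet_amplitude,
                              tagged_amplitude)
from stressphys.synthetic_data import generate_session
from tests.conftest import quiet_config

FS = 512.0


def _tone_epochs(freq_amps, n_trials=2, n_channels=3, phase=0.3):
    """EpochSet holding a superposition of stationary tones."""
    n = int(round(3.2 * FS)) + 1
    t_ms = -200.0 + np.arange(n) / FS * 1000.0
    t = t_ms / 1000.0
    sig = np.zeros(n)
    for f, a in freq_amps:
        sig += a * np.sin(2 * np.pi * f * t + phase)
    data = np.tile(sig, (n_trials, n_channels, 1))
    conds = [TrialCondition("viewing", i, 0, expression="angry")
             for i in range(n_trials)]
    return EpochSet(data, t_ms, [f"C{i}" for i in range(n_channels)], FS,
                    conds, np.zeros(n_trials, bool))


class TestFftAmplitude:
    def test_unit_sinusoid_reads_one(self):
        ep = _tone_epochs([(12.0, 1.0)])
        out = fft_amplitude(ep, (0.0, 3000.0), freqs=(12.0, 15.0))
        a12 = out[out.freq == 12.0].amplitude
        assert np.allclose(a12, 1.0, atol=0.01)

    def test_superposed_tones_resolved(self):
        ep = _tone_epochs([(12.0, 1.0), (15.0, 2.0)])
        out = fft_amplitude(ep, (0.0, 3000.0), freqs=(12.0, 15.0))
        assert out[out.freq == 12.0].amplitude.iloc[0] == pytest.approx(1.0, rel=0.02)
        assert out[out.freq == 15.0].amplitude.iloc[0] == pytest.approx(2.0, rel=0.02)

    def test_silence_reads_zero(self):
        ep = _tone_epochs([(12.0, 0.0)])
        out = fft_amplitude(ep, (0.0, 3000.0))
        assert np.allclose(out.amplitude, 0.0, atol=1e-12)

    def test_non_integer_cycles_warn(self):
        ep = _tone_epochs([(12.0, 1.0)])
        with pytest.warns(UserWarning, match="cycles"):
            fft_amplitude(ep, (100.0, 3000.0), freqs=(12.0,))

    def test_window_outside_epoch_rejected(self):
        ep = _tone_epochs([(12.0, 1.0)])
        with pytest.raises(ValueError):
            fft_amplitude(ep, (0.0, 5000.0))


class TestMorletAmplitude:
    def test_unit_tone_gain(self):
        ep = _tone_epochs([(12.0, 1.0)])
        tfr = morlet_amplitude(ep, freqs=[12.0])
        mask = (tfr.time_ms >= 500) & (tfr.time_ms <= 2500)
        assert tfr.amplitude[0][:, :, mask].mean() == pytest.approx(1.0, abs=0.05)

    def test_zero_signal_zero_envelope(self):
        ep = _tone_epochs([(12.0, 0.0)])
        tfr = morlet_amplitude(ep, freqs=[12.0, 15.0])
        assert np.allclose(tfr.amplitude, 0.0, atol=1e-12)

    def test_amplitude_step_transitions_between_plateaus(self):
        n = int(round(3.2 * FS)) + 1
        t_ms = -200.0 + np.arange(n) / FS * 1000.0
        amp = np.where(t_ms < 1500.0, 1.0, 2.0)
        sig = amp * np.sin(2 * np.pi * 12.0 * t_ms / 1000.0)
        ep = _tone_epochs([(12.0, 0.0)])
        ep.data[:] = sig
        tfr = morlet_amplitude(ep, freqs=[12.0])
        env = tfr.amplitude[0, 0, 0]
        pre = env[(t_ms > 800) & (t_ms < 1200)].mean()
        post = env[(t_ms > 1800) & (t_ms < 2200)].mean()
        assert pre == pytest.approx(1.0, abs=0.05)
        assert post == pytest.approx(2.0, abs=0.1)
        trans = env[(t_ms >= 1200) & (t_ms <= 1800)]
        assert np.all(np.diff(trans) > -0.01)  # monotone rise up to jitter

    def test_morlet_agrees_with_fft_on_stationary_tones(self):
        """Dual-route check: windowed wavelet envelope vs leakage-free
        FFT amplitude within 5% on stationary tones."""
        for f, a in ((12.0, 1.0), (15.0, 0.7)):
            ep = _tone_epochs([(f, a)])
            fft_amp = fft_amplitude(ep, (0.0, 3000.0), freqs=(f,)
                                    ).amplitude.iloc[0]
            tfr = morlet_amplitude(ep, freqs=[f])
            m = (tfr.time_ms >= 500) & (tfr.time_ms <= 2500)
            mor = tfr.amplitude[0][:, :, m].mean()
            assert mor == pytest.approx(fft_amp, rel=0.05)

    def test_envelope_matches_mne_up_to_gain_convention(self):
        """Independent cross-check: away from epoch edges the envelope
        equals mne's complex Morlet magnitude up to one global scale
        constant (the conventions differ only in normalization)."""
        import mne

        fs = 512.0
        t = np.arange(1639) / fs
        x = np.sin(2 * np.pi * 12.0 * t) * np.where(t < 1.5, 1.0, 2.0)
        from stressphys.spectral import morlet_envelope

        ref = np.abs(mne.time_frequency.tfr_array_morlet(
            x[None, None, :], fs, [12.0], n_cycles=[6.0],
            output="complex", zero_mean=False, verbose=False)).squeeze()
        mine = morlet_envelope(x, fs, [12.0])[0][0]
        mid = slice(200, 1400)
        scale = (mine[mid] / ref[mid]).mean()
        dev = np.abs(mine[mid] - scale * ref[mid]).max() / mine[mid].mean()
        assert dev < 1e-4

    def test_above_nyquist_rejected(self):
        ep = _tone_epochs([(12.0, 1.0)])
        with pytest.raises(ValueError):
            morlet_amplitude(ep, freqs=[300.0])


class TestAbsScore:
    @pytest.mark.parametrize("a,b,expected", [
        (1.5, 0.5, 0.5), (2.0, 0.0, 1.0), (3.3, 3.3, 0.0)])
    def test_worked_examples(self, a, b, expected):
        assert abs_score(a, b) == pytest.approx(expected)

    def test_undefined_when_both_zero(self):
        assert np.isnan(abs_score(0.0, 0.0))

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            abs_score(-1.0, 1.0)

    @settings(max_examples=200, derandomize=True)
    @given(a=st.floats(0.0, 1e6), b=st.floats(0.0, 1e6))
    def test_range_and_antisymmetry(self, a, b):
        if a + b == 0:
            return
        s = abs_score(a, b)
        assert -1.0 <= s <= 1.0
        assert abs_score(b, a) == pytest.approx(-s, abs=1e-12)


class TestTaggedAmplitudeRecovery:
    def _session(self):
        cfg = quiet_config()
        cfg.ssvep.attention_weights = {"angry": 1.5, "happy": 1.0,
                                       "neutral": 1.0}
        cfg.hemifield_bias = {"stress": 0.0, "control": 0.0}
        return generate_session(cfg, "stress", 0)

    def test_attended_gain_ratio_recovered_fft(self):
        """Attention weight 1.5 vs 1.0 at zero noise: the leakage-free
        FFT route (orthogonal 3 s bins) recovers the 1.5 amplitude ratio
        exactly up to windowing."""
        sess = self._session()
        ep = epoch(sess.atb, sess.atb_conditions)
        ratios = []
        for i, c in enumerate(ep.conditions):
            if c.combination != "angry-neutral":
                continue
            sub = ep.copy_with(ep.data[[i]], conditions=[c],
                               rejected=np.zeros(1, bool),
                               rejection_reasons=[""])
            f_hi = c.freq_assignment[c.side_of_higher_arousal]
            f_lo = c.freq_assignment["left" if c.side_of_higher_arousal
                                     == "right" else "right"]
            out = fft_amplitude(sub, (0.0, 3000.0), freqs=(f_hi, f_lo),
                                channels=list(SSVEP_CLUSTER))
            hi = out[out.freq == f_hi].amplitude.mean()
            lo = out[out.freq == f_lo].amplitude.mean()
            ratios.append(hi / lo)
        assert np.mean(ratios) == pytest.approx(1.5, abs=0.1)

    def test_attended_gain_ratio_morlet_compressed_by_crosstalk(self):
        """The Morlet route at 12/15 Hz with cycles = freq/2 has ~2 Hz
        spectral width, so each tag's envelope picks up part of the
        other stimulus; the recovered ratio is compressed toward 1 but
        the attended stimulus stays clearly dominant."""
        sess = self._session()
        ep = epoch(sess.atb, sess.atb_conditions)
        tfr = morlet_amplitude(ep, freqs=[12.0, 15.0],
                               channels=list(SSVEP_CLUSTER))
        ratios = []
        for i, c in enumerate(ep.conditions):
            if c.combination != "angry-neutral":
                continue
            f_hi = c.freq_assignment[c.side_of_higher_arousal]
            f_lo = c.freq_assignment["left" if c.side_of_higher_arousal
                                     == "right" else "right"]
            hi = tagged_amplitude(tfr, f_hi, (500, 2500))[i]
            lo = tagged_amplitude(tfr, f_lo, (500, 2500))[i]
            ratios.append(hi / lo)
        assert 1.25 < np.mean(ratios) < 1.5


class TestAmplitudeModelConsistency:
    def test_eeg_route_matches_analytic_cell_scores(self):
        """At zero noise the leakage-free FFT route through the raw EEG
        reproduces the analytic cell bias scores that the amplitude-level
        experiment sampler draws around, tying the two generator routes
        to one parametric model."""
        from stressphys.containers import HIGH_AROUSAL, LOW_AROUSAL

        cfg = quiet_config()
        cfg.hemifield_bias = {"stress": 0.2, "control": 0.0}
        sess = generate_session(cfg, "stress", 0)
        ep = epoch(sess.atb, sess.atb_conditions)
        w = cfg.ssvep.attention_weights
        for i, c in enumerate(ep.conditions):
            sub = ep.copy_with(ep.data[[i]], conditions=[c],
                               rejected=np.zeros(1, bool),
                               rejection_reasons=[""])
            side = c.side_of_higher_arousal
            f_hi, f_lo = (c.freq_assignment[side],
                          c.freq_assignment["left" if side == "right"
                                            else "right"])
            out = fft_amplitude(sub, (0.0, 3000.0), freqs=(f_hi, f_lo),
                                channels=list(SSVEP_CLUSTER))
            hi = out[out.freq == f_hi].amplitude.mean()
            lo = out[out.freq == f_lo].amplitude.mean()
            g_hi = 1.2 if side == "left" else 0.8
            g_lo = 0.8 if side == "left" else 1.2
            a = w[HIGH_AROUSAL[c.combination]] * g_hi
            b = w[LOW_AROUSAL[c.combination]] * g_lo
            expected = (a - b) / (a + b)
            assert abs_score(hi, lo) == pytest.approx(expected, abs=0.02)


class TestAbsTable:
    def test_row_bookkeeping(self, small_session):
        ep = epoch(small_session.atb, small_session.atb_conditions)
        tab = abs_table(ep, "p0", "stress")
        assert len(tab) == len(WINDOWS) * 3 * 2
        assert set(tab.window) == set(WINDOWS)
        assert tab["abs"].between(-1, 1).all()

    def test_symmetric_generator_scores_near_zero(self, symmetric_session):
        ep = epoch(symmetric_session.atb, symmetric_session.atb_conditions)
        tab = abs_table(ep, "p0", "stress")
        assert np.abs(tab["abs"]).max() < 0.03

    def test_injected_attention_weight_positive_bias(self):
        cfg = quiet_config()
        cfg.ssvep.attention_weights = {"angry": 1.5, "happy": 1.0,
                                       "neutral": 1.0}
        cfg.hemifield_bias = {"stress": 0.0, "control": 0.0}
        sess = generate_session(cfg, "stress", 0)
        ep = epoch(sess.atb, sess.atb_conditions)
        tab = abs_table(ep, "p0", "stress")
        angry_cells = tab[tab.combination.isin(["angry-neutral",
                                                "angry-happy"])]
        assert (angry_cells["abs"] > 0.05).all()

    def test_rejected_trials_excluded(self, small_session):
        ep = epoch(small_session.atb, small_session.atb_conditions)
        ep.rejected[:] = True
        ep.rejected[0] = False
        tab = abs_table(ep, "p0", "stress")
        c0 = ep.conditions[0]
        used = tab[tab.n_trials > 0]
        assert len(used) == len(WINDOWS)
        assert (used.combination == c0.combination).all()
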