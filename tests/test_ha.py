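"""Hearing-aid chain: filterbank, suppressor, WDRC, lowering, delay, vent."""

import math

import numpy as np
import pytest
from scipy import signal as sps

from binsim import ha
from binsim.fitting import Prescription, nalr_prescription, wdrc_params, Audiogram
from binsim.ha import (
    FilterbankSpec,
    SuppressorConfig,
    analyze,
    apply_delay,
    freq_lower,
    process_ear,
    synthesize,
    vent_frequency_response,
    vent_mix,
    wdrc,
    wiener_suppress,
)
from binsim.scenes import speech_shaped_noise
from binsim.stimuli import EarStimulus

FS = 16000.0


@pytest.fixture(scope="module")
def fb():
    return FilterbankSpec(fs=FS)


def _rms_db(x):
    return 20 * math.log10(np.sqrt(np.mean(x**2)))


class TestFilterbank:
    def test_impulse_reconstruction_below_minus40(self, fb):
        x = np.zeros(4096)
        x[50] = 1.0
        y = synthesize(analyze(fb, x))
        err = y.copy()
        err[50 + fb.delay] -= 1.0
        assert 10 * math.log10(np.sum(err**2) + 1e-300) < -40.0

    def test_tone_lands_in_its_band(self, fb):
        t = np.arange(int(0.3 * FS)) / FS
        bands = analyze(fb, np.sin(2 * np.pi * 1000 * t))
        energies = np.sum(bands**2, axis=1)
        assert np.argmax(energies) == 2  # 1000-Hz band

    def test_linear_phase_symmetric_taps(self, fb):
        for h in fb.band_filters()[:-1]:
            np.testing.assert_allclose(h, h[::-1], atol=1e-12)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            FilterbankSpec(fs=8000.0)


class TestWienerSuppressor:
    def test_zero_setting_is_identity(self, fb):
        bands = analyze(fb, speech_shaped_noise(0, 1.0, FS))
        out, g = wiener_suppress(bands, SuppressorConfig(0.0), FS)
        np.testing.assert_array_equal(out, bands)
        assert np.all(g == 0)

    @pytest.mark.parametrize("max_att", [6.0, 12.0])
    def test_stationary_noise_reaches_floor(self, fb, max_att):
        # noise-only input: frame power ~ long-term power -> gain at floor
        bands = analyze(fb, speech_shaped_noise(1, 3.0, FS))
        _, g = wiener_suppress(bands, SuppressorConfig(max_att), FS)
        steady = g[:, 5:-5]
        assert steady.min() == pytest.approx(-max_att, abs=1e-9)
        assert np.median(steady) == pytest.approx(-max_att, abs=0.5)

    def test_frame_gain_matches_hand_wiener(self):
        # synthetic one-band case with known frame SNR of 10 dB:
        # g = s/(s+n) = 10/11 -> -0.414 dB
        n_frames = 50
        frame = int(8e-3 * FS)
        rng = np.random.default_rng(0)
        noise_pow = 1.0
        sig_pow = 10.0
        x = rng.standard_normal(n_frames * frame) * math.sqrt(noise_pow + sig_pow)
        bands = x[None, :]
        cfg = SuppressorConfig(12.0, noise_estimate=np.array([noise_pow]))
        _, g = wiener_suppress(bands, cfg, FS)
        expected = 20 * math.log10(10 / 11)
        assert np.median(g) == pytest.approx(expected, abs=0.35)

    def test_exact_wiener_gain_on_constant_power(self):
        # deterministic frame powers: gain error < 0.01 dB
        frame = int(8e-3 * FS)
        x = np.full(frame * 10, math.sqrt(11.0))
        cfg = SuppressorConfig(12.0, noise_estimate=np.array([1.0]))
        _, g = wiener_suppress(x[None, :], cfg, FS)
        assert np.max(np.abs(g - 20 * math.log10(10 / 11))) < 0.01

    def test_gains_bounded(self, fb):
        bands = analyze(fb, speech_shaped_noise(2, 2.0, FS))
        _, g = wiener_suppress(bands, SuppressorConfig(12.0), FS)
        assert g.max() <= 1e-12
        assert g.min() >= -12.0 - 1e-9


def _flat_rx(gain_db=0.0, cr=1.0, knee=45.0, attack=5.0, release=70.0):
    return Prescription(
        band_gains=np.full(6, gain_db), compression_ratios=np.full(6, cr),
        kneepoints=np.full(6, knee), attack_ms=attack, release_ms=release,
    )


class TestWdrc:
    def test_cr1_is_pure_gain(self, fb):
        x = speech_shaped_noise(3, 1.0, FS)
        bands = analyze(fb, x)
        out, g = wdrc(bands, _flat_rx(gain_db=12.0, cr=1.0), FS)
        np.testing.assert_allclose(out, bands * 10 ** (12 / 20), rtol=1e-9)
        assert np.all(g == 12.0)

    def test_static_curve_slope_half_for_cr2(self, fb):
        # +10 dB input step above knee -> +5 dB output step at CR=2
        t = np.arange(int(FS)) / FS
        levels = []
        for amp_db in (-30.0, -20.0):
            tone = 10 ** (amp_db / 20) * math.sqrt(2) * np.sin(2 * np.pi * 1000 * t)
            out, _ = wdrc(analyze(fb, tone), _flat_rx(20.0, 2.0), FS)
            levels.append(_rms_db(synthesize(out)[8000:]))
        assert levels[1] - levels[0] == pytest.approx(5.0, rel=0.02)

    def test_step_response_settles_within_attack(self):
        # gain recovers to within 2 dB of its final value ~attack ms after
        # a +25-dB level step (single-band input, no filterbank smearing)
        t = np.arange(int(0.4 * FS)) / FS
        x = np.sin(2 * np.pi * 1000 * t) * math.sqrt(2) * 10 ** (-30 / 20)
        x[int(0.2 * FS):] *= 10 ** (25 / 20)
        rx = _flat_rx(20.0, 2.0, attack=5.0, release=70.0)
        _, g = wdrc(x[None, :].repeat(6, axis=0), rx, FS)
        hop_ms = 1.0
        step_f = int(200 / hop_ms)
        final = g[0, step_f + 40]
        at_attack = g[0, step_f + 6]
        assert abs(at_attack - final) < 2.0

    def test_invalid_cr_rejected(self, fb):
        with pytest.raises(ValueError):
            Prescription(band_gains=np.zeros(6), compression_ratios=np.full(6, 0.5),
                         kneepoints=np.full(6, 45.0))


class TestFreqLower:
    def test_below_cutoff_unchanged(self):
        t = np.arange(int(FS)) / FS
        x = 0.1 * np.sin(2 * np.pi * 1000 * t)
        y = freq_lower(x, FS, 2000.0, 2.0)
        f = np.fft.rfftfreq(8192, 1 / FS)
        peak = f[np.argmax(np.abs(np.fft.rfft(y[4000:12192] * np.hanning(8192))))]
        assert peak == pytest.approx(1000.0, abs=2.0)

    def test_tone_mapping_oracle(self):
        # f' = fc + (f-fc)/cr: 4 kHz, fc=2 kHz, cr=2 -> 3 kHz, exact to a bin
        t = np.arange(int(FS)) / FS
        x = 0.1 * np.sin(2 * np.pi * 4000 * t)
        y = freq_lower(x, FS, 2000.0, 2.0)
        n = 8192
        f = np.fft.rfftfreq(n, 1 / FS)
        peak = f[np.argmax(np.abs(np.fft.rfft(y[4000:4000 + n] * np.hanning(n))))]
        assert abs(peak - 3000.0) <= FS / n

    def test_cr1_identity(self):
        x = speech_shaped_noise(4, 1.0, FS)
        np.testing.assert_array_equal(freq_lower(x, FS, 2000.0, 1.0), x)

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            freq_lower(np.zeros(100), FS, 9000.0, 2.0)
        with pytest.raises(ValueError):
            freq_lower(np.zeros(100), FS, 2000.0, 0.5)


class TestDelayAndVent:
    def test_impulse_delayed_10ms(self):
        x = np.zeros(1000)
        x[0] = 1.0
        y = apply_delay(x, FS)
        assert np.argmax(y) == round(0.010 * FS)

    def test_zero_delay_identity(self):
        x = np.arange(50.0)
        np.testing.assert_array_equal(apply_delay(x, FS, 0.0), x)

    def test_crosscorr_lag_equals_rounded_delay(self):
        x = speech_shaped_noise(5, 0.5, FS)
        y = apply_delay(x, FS)
        lag = np.argmax(sps.correlate(y, x)) - (x.size - 1)
        assert lag == round(0.010 * FS)

    def test_half_power_at_350(self):
        freqs, h_hp, h_lp = vent_frequency_response(FS)
        i350 = np.argmin(np.abs(freqs - 350.0))
        assert 20 * math.log10(abs(h_hp[i350])) == pytest.approx(-3.01, abs=0.02)
        assert 20 * math.log10(abs(h_lp[i350])) == pytest.approx(-3.01, abs=0.02)

    def test_power_complementary_flat(self):
        freqs, h_hp, h_lp = vent_frequency_response(FS)
        total_db = 10 * np.log10(np.abs(h_hp) ** 2 + np.abs(h_lp) ** 2)
        assert np.max(np.abs(total_db)) < 0.1

    def test_disabled_vent_passes_ha_output(self):
        x = speech_shaped_noise(6, 0.5, FS)
        np.testing.assert_array_equal(vent_mix(x, np.zeros_like(x), FS, fc=0.0), x)


def _stim(x):
    lr = np.stack([x, x])
    return EarStimulus(ha_mic=lr, ear_canal=lr.copy(), fs=FS,
                      target_span=slice(0, x.size))


class TestProcessEar:
    def test_nh_linear_is_vent_mixed_delayed_input(self, fb):
        x = speech_shaped_noise(7, 1.0, FS)
        left, _ = process_ear(_stim(x), "linear", "NH", spec=fb)
        manual = vent_mix(apply_delay(np.concatenate([np.zeros(fb.delay), x]), FS),
                          x, FS)
        n = min(left.combined.size, manual.size)
        err = left.combined[:n] - manual[:n]
        assert 10 * math.log10(np.sum(err**2) / np.sum(manual[:n] ** 2) + 1e-300) < -40

    def test_hi_strong_floors_at_minus12(self):
        # stationary noise-only input: suppressor log bottoms out at -12 dB
        audio = Audiogram(thresholds_left=(30, 35, 40, 50, 60, 65),
                          thresholds_right=(30, 35, 40, 50, 60, 65))
        rx = wdrc_params(audio, "left")
        x = speech_shaped_noise(8, 2.0, FS)
        left, _ = process_ear(_stim(x), "strong", "HI", prescription=rx)
        g = left.applied_gains["suppressor_db"]
        assert g.min() == pytest.approx(-12.0, abs=1e-9)
        assert left.applied_gains["stages"] == ["suppress", "wdrc", "lower", "delay", "vent"]

    def test_stage_order_mild_hi(self):
        audio = Audiogram(thresholds_left=(30, 35, 40, 50, 60, 65),
                          thresholds_right=(30, 35, 40, 50, 60, 65))
        rx = wdrc_params(audio, "left")
        x = speech_shaped_noise(9, 1.0, FS)
        left, _ = process_ear(_stim(x), "mild", "HI", prescription=rx)
        assert left.applied_gains["stages"] == ["suppress", "wdrc", "delay", "vent"]

    def test_swapping_ears_swaps_outputs(self):
        a = speech_shaped_noise(10, 1.0, FS)
        b = speech_shaped_noise(11, 1.0, FS)
        s1 = EarStimulus(np.stack([a, b]), np.stack([a, b]), FS, slice(0, a.size))
        s2 = EarStimulus(np.stack([b, a]), np.stack([b, a]), FS, slice(0, a.size))
        l1, r1 = process_ear(s1, "mild", "NH")
        l2, r2 = process_ear(s2, "mild", "NH")
        np.testing.assert_array_equal(l1.combined, r2.combined)
        np.testing.assert_array_equal(r1.combined, l2.combined)

    def test_unknown_level_or_group_rejected(self):
        x = speech_shaped_noise(12, 1.0, FS)
        with pytest.raises(ValueError):
            process_ear(_stim(x), "extreme", "NH")
        with pytest.raises(ValueError):
            process_ear(_stim(x), "linear", "XX")

    def test_hi_linear_applies_nalr_gains(self):
        audio = Audiogram(thresholds_left=(40,) * 6, thresholds_right=(40,) * 6)
        rx = nalr_prescription(audio, "left")
        x = speech_shaped_noise(13, 1.0, FS)
        left, _ = process_ear(_stim(x), "linear", "HI", prescription=rx, vent_fc=0.0)
        # 1-kHz-band gain 19.4 dB shows up in the band level
        ref, _ = process_ear(_stim(x), "linear", "NH", vent_fc=0.0)
        fb = FilterbankSpec(fs=FS)
        band = lambda y: analyze(fb, y)[2]
        boost = _rms_db(band(left.combined)) - _rms_db(band(ref.combined))
        assert boost == pytest.approx(19.4, abs=1.0)
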