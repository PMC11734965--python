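"""Stimulus builder: condition grid, precursor protocol, SNR, spatialization."""

import math

import numpy as np
import pytest
from scipy import signal as sps

from binsim import stimuli
from binsim.scenes import gen_sentence
from binsim.stimuli import (
    SPATIAL_CONFIGS,
    TrialSpec,
    add_precursor,
    build_condition_grid,
    condition_cells,
    mix_at_snr,
    spatialize_and_prune,
)

FS = 16000.0


def _measured_snr_db(speech, n1, n2, span):
    p_s = np.mean(speech[:, span] ** 2)
    p_n = np.mean((n1[:, span] + n2[:, span]) ** 2)
    return 10 * math.log10(p_s / p_n)


class TestConditionGrid:
    def test_54_unique_cells(self):
        cells = condition_cells("NH")
        assert len(cells) == 54
        assert len({tuple(sorted(c.items())) for c in cells}) == 54

    def test_540_trials_per_listener(self):
        grid = build_condition_grid(groups=("NH",), repetitions=10, master_seed=1)
        trials = grid[("NH", 0)]
        assert len(trials) == 540
        # every cell appears exactly 10 times
        from collections import Counter

        counts = Counter((t.room, t.snr, t.config, t.processing) for t in trials)
        assert set(counts.values()) == {10}

    def test_listeners_share_cells_but_not_order(self):
        grid = build_condition_grid(groups=("NH",), listeners_per_group=2,
                                    repetitions=2, master_seed=3)
        a, b = grid[("NH", 0)], grid[("NH", 1)]
        key = lambda ts: sorted((t.room, t.snr, t.config, t.processing) for t in ts)
        assert key(a) == key(b)
        assert [(t.room, t.snr, t.config, t.processing) for t in a] != [
            (t.room, t.snr, t.config, t.processing) for t in b
        ]

    def test_babble_seeds_distinct(self):
        grid = build_condition_grid(groups=("HI",), repetitions=2, master_seed=0)
        for t in grid[("HI", 0)]:
            assert t.seeds[1] != t.seeds[2]
            assert t.babble_segments[0] != t.babble_segments[1]

    def test_deterministic_given_master_seed(self):
        g1 = build_condition_grid(groups=("NH",), repetitions=1, master_seed=9)
        g2 = build_condition_grid(groups=("NH",), repetitions=1, master_seed=9)
        assert g1 == g2

    def test_spatial_configs_match_study_layout(self):
        assert SPATIAL_CONFIGS["colocated"].speech_azimuth == 0
        assert SPATIAL_CONFIGS["colocated"].noise_azimuths == (0, 0)
        assert SPATIAL_CONFIGS["front"].noise_azimuths == (60, -60)
        assert SPATIAL_CONFIGS["side"].speech_azimuth == 60
        assert SPATIAL_CONFIGS["side"].noise_azimuths == (0, -60)


class TestPrecursor:
    def test_length_arithmetic(self):
        x = np.ones(int(2.0 * FS))
        out, span = add_precursor(x, FS, gap_ms=200.0)
        assert out.size == int(4.2 * FS)
        assert span == slice(int(2.2 * FS), int(4.2 * FS))

    def test_prefix_is_time_reversed_target(self):
        x = gen_sentence(5, 1.5, FS).samples
        out, span = add_precursor(x, FS)
        np.testing.assert_array_equal(out[: x.size], out[span][::-1])

    def test_zero_gap(self):
        x = np.ones(int(2.0 * FS))
        out, span = add_precursor(x, FS, gap_ms=0.0)
        assert out.size == int(4.0 * FS)
        assert span.start == x.size

    def test_empty_sentence_rejected(self):
        with pytest.raises(ValueError):
            add_precursor(np.array([]), FS)


class TestMixAtSnr:
    def test_equal_powers_snr0_scale_unity(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal((2, 8000))
        n = rng.standard_normal((2, 8000))
        p = math.sqrt(np.mean(s**2) / np.mean((2 * n) ** 2))
        n1, n2 = mix_at_snr(s, n * p, n * p, 0.0)
        np.testing.assert_allclose(n1, n * p, rtol=1e-12)

    def test_scale_ratio_between_snrs(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal((2, 4000))
        na = rng.standard_normal((2, 4000))
        nb = rng.standard_normal((2, 4000))
        hi, _ = mix_at_snr(s, na, nb, 20.0)
        lo, _ = mix_at_snr(s, na, nb, 3.0)
        assert np.max(np.abs(hi)) / np.max(np.abs(lo)) == pytest.approx(
            10 ** (-17 / 20), rel=1e-9
        )

    def test_achieved_snr_remeasures_exactly(self):
        rng = np.random.default_rng(2)
        s = rng.standard_normal((2, 16000))
        na = rng.standard_normal((2, 16000)) * 0.3
        nb = rng.standard_normal((2, 16000)) * 1.7
        span = slice(4000, 12000)
        for snr in (3.0, 8.0, 20.0):
            n1, n2 = mix_at_snr(s, na, nb, snr, span)
            assert _measured_snr_db(s, n1, n2, span) == pytest.approx(snr, abs=0.01)

    def test_zero_noise_rejected(self):
        s = np.ones((2, 100))
        z = np.zeros((2, 100))
        with pytest.raises(ValueError):
            mix_at_snr(s, z, z, 0.0)


def _trial(config, room="anechoic", snr=8):
    return TrialSpec(room=room, snr=snr, config=config, processing="linear",
                     group="NH", repetition=1, seeds=(11, 21, 31))


class TestSpatializeAndPrune:
    def test_missing_brir_names_azimuth(self, anechoic_brirs):
        partial = {0.0: anechoic_brirs[0.0]}
        with pytest.raises(KeyError, match="60"):
            spatialize_and_prune(_trial("front"), partial, FS, 1.0)

    def test_anechoic_alignment_lag_zero(self, anechoic_brirs):
        # pruning maps the target span onto the same speech samples: the
        # pruned mix cross-correlates with the dry target at lag 0 (the
        # prune index absorbs the full direct-path latency)
        t = _trial("colocated", snr=20)
        stim = spatialize_and_prune(t, anechoic_brirs, FS, 1.5)
        dry = gen_sentence(t.seeds[0], 1.5, FS).samples
        seg = stim.ha_mic[0][stim.target_span]
        xc = sps.correlate(seg, dry)
        lag = np.argmax(np.abs(xc)) - (dry.size - 1)
        assert abs(lag) <= 1

    @pytest.mark.parametrize("config", ["colocated", "front"])
    def test_symmetric_configs_have_equal_ear_levels(self, anechoic_brirs, config):
        stim = spatialize_and_prune(_trial(config), anechoic_brirs, FS, 1.2)
        lvl = 10 * np.log10(np.mean(stim.ha_mic**2, axis=1))
        assert abs(lvl[0] - lvl[1]) < 0.1

    def test_requested_snr_achieved_for_all_cells(self, anechoic_brirs):
        # re-measure the construction across SNRs and configurations
        for snr in (3, 8, 20):
            for config in SPATIAL_CONFIGS:
                t = TrialSpec(room="anechoic", snr=snr, config=config,
                              processing="linear", group="NH", repetition=1,
                              seeds=(41, 51, 61))
                cfg = SPATIAL_CONFIGS[config]
                sent = gen_sentence(t.seeds[0], 1.2, FS).samples
                ext, span = add_precursor(sent, FS)
                b = anechoic_brirs[cfg.speech_azimuth]
                sp = np.stack([sps.fftconvolve(ext, b.left), sps.fftconvolve(ext, b.right)])
                noises = []
                from binsim.scenes import gen_babble

                for az, seed in zip(cfg.noise_azimuths, t.seeds[1:]):
                    bb = anechoic_brirs[az]
                    bab = gen_babble(seed, ext.size / FS, FS).samples
                    noises.append(np.stack([sps.fftconvolve(bab, bb.left),
                                            sps.fftconvolve(bab, bb.right)]))
                n = min(sp.shape[1], *(x.shape[1] for x in noises))
                sp = sp[:, :n]
                onset = b.meta["onset"]
                cspan = slice(span.start + onset, span.stop + onset)
                n1, n2 = mix_at_snr(sp, noises[0][:, :n], noises[1][:, :n], snr, cspan)
                assert _measured_snr_db(sp, n1, n2, cspan) == pytest.approx(snr, abs=0.01)

    def test_side_config_right_ear_better_snr(self, anechoic_brirs):
        # speech from +60: the right ear enjoys the higher target-to-noise ratio
        cfg = SPATIAL_CONFIGS["side"]
        sent = gen_sentence(77, 1.2, FS).samples
        ext, span = add_precursor(sent, FS)
        b = anechoic_brirs[60.0]
        sp = np.stack([sps.fftconvolve(ext, b.left), sps.fftconvolve(ext, b.right)])
        from binsim.scenes import gen_babble

        noises = []
        for az, seed in zip(cfg.noise_azimuths, (88, 99)):
            bb = anechoic_brirs[az]
            bab = gen_babble(seed, ext.size / FS, FS).samples
            noises.append(np.stack([sps.fftconvolve(bab, bb.left),
                                    sps.fftconvolve(bab, bb.right)]))
        n = min(sp.shape[1], *(x.shape[1] for x in noises))
        snr_per_ear = [
            10 * math.log10(np.mean(sp[e, :n] ** 2)
                            / np.mean((noises[0][e, :n] + noises[1][e, :n]) ** 2))
            for e in (0, 1)
        ]
        assert snr_per_ear[1] > snr_per_ear[0]

    def test_hall_tail_masks_target_onset(self, anechoic_brirs, hall_brirs):
        # reverberant precursor energy overlaps the retained segment onset
        t = _trial("colocated")
        an = spatialize_and_prune(t, anechoic_brirs, FS, 1.2)
        ha = spatialize_and_prune(_trial("colocated", room="hall"), hall_brirs, FS, 1.2)
        win = int(0.05 * FS)

        def onset_ratio(stim):
            sent_e = np.mean(stim.ha_mic[:, :win] ** 2)
            total_e = np.mean(stim.ha_mic**2)
            return sent_e / total_e

        assert onset_ratio(ha) > 0  # tail present
        # normalized onset energy is larger in the hall (tail) than anechoic
        dry = gen_sentence(t.seeds[0], 1.2, FS).samples
        lead = np.mean(dry[:win] ** 2) / np.mean(dry**2)
        assert onset_ratio(ha) > onset_ratio(an) or lead < 1e-3

    def test_four_channels_equal_length(self, anechoic_brirs):
        stim = spatialize_and_prune(_trial("front"), anechoic_brirs, FS, 1.0)
        assert stim.ha_mic.shape == stim.ear_canal.shape
        assert stim.ha_mic.shape[0] == 2
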