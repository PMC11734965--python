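"""Factorial stimulus construction.

Builds the 54-cell condition grid (2 rooms x 3 SNRs x 3 spatial
configurations x 3 processing settings), the reversed-sentence precursor
protocol that masks the target onset with a reverberant tail, SNR scaling
defined on the ear-averaged powers, and the spatialize-then-prune operation
that assembles one binaural trial stimulus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .scenes import (
    BinauralImpulseResponse,
    SourceSignal,
    gen_babble,
    gen_sentence,
    quantize_azimuth,
)

__all__ = [
    "SpatialConfig",
    "SPATIAL_CONFIGS",
    "ROOMS",
    "SNRS_DB",
    "PROCESSING_LEVELS",
    "TrialSpec",
    "EarStimulus",
    "condition_cells",
    "build_condition_grid",
    "add_precursor",
    "mix_at_snr",
    "spatialize_and_prune",
]

ROOMS = ("anechoic", "hall")
SNRS_DB = (3, 8, 20)
PROCESSING_LEVELS = ("linear", "mild", "strong")
N_BABBLE_SEGMENTS = 9  # random draws without replacement come from this pool


@dataclass(frozen=True)
class SpatialConfig:
    """Speech/noise azimuth layout. Positive azimuth = source to the right."""

    name: str
    speech_azimuth: float
    noise_azimuths: tuple[float, float]


SPATIAL_CONFIGS = {
    "colocated": SpatialConfig("colocated", 0.0, (0.0, 0.0)),
    "front": SpatialConfig("front", 0.0, (60.0, -60.0)),
    "side": SpatialConfig("side", 60.0, (0.0, -60.0)),
}


@dataclass(frozen=True)
class TrialSpec:
    """One factorial cell plus repetition number and per-trial seeds.

    ``seeds`` is (sentence_seed, babble1_seed, babble2_seed); the two babble
    seeds are always distinct because the underlying segments are drawn
    without replacement from the 9-segment pool.
    """

    room: str
    snr: int
    config: str
    processing: str
    group: str
    repetition: int
    seeds: tuple[int, int, int]
    babble_segments: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if self.snr not in SNRS_DB:
            raise ValueError(f"snr must be one of {SNRS_DB}")
        if self.seeds[1] == self.seeds[2]:
            raise ValueError("babble seeds must be distinct")


@dataclass
class EarStimulus:
    """Binaural trial stimulus on the two acoustic paths.

    ``ha_mic`` carries the (2, N) signals at the hearing-aid microphones and
    ``ear_canal`` the (2, N) signals on the open vent-leak path;
    ``target_span`` marks the sample interval occupied by the target
    sentence after pruning.
    """

    ha_mic: np.ndarray
    ear_canal: np.ndarray
    fs: float
    target_span: slice

    def __post_init__(self) -> None:
        self.ha_mic = np.atleast_2d(np.asarray(self.ha_mic, dtype=float))
        self.ear_canal = np.atleast_2d(np.asarray(self.ear_canal, dtype=float))
        if self.ha_mic.shape != self.ear_canal.shape:
            raise ValueError("the four channels must have equal length")
        n = self.ha_mic.shape[1]
        if not (0 <= self.target_span.start < self.target_span.stop <= n):
            raise ValueError("target_span must lie within the signal")


def condition_cells(group: str = "NH") -> list[dict]:
    """The 54 unique factorial cells for one listener group."""
    return [
        {"room": r, "snr": s, "config": c, "processing": p, "group": group}
        for r, s, c, p in itertools.product(ROOMS, SNRS_DB, SPATIAL_CONFIGS, PROCESSING_LEVELS)
    ]


def _segment_seed(master_seed: int, segment: int) -> int:
    # stable per-run babble segment pool, shared by every trial of the run
    return int(np.random.SeedSequence([master_seed, 7919, segment]).generate_state(1)[0])


def build_condition_grid(
    groups=("NH", "HI"),
    listeners_per_group: int = 1,
    repetitions: int = 10,
    master_seed: int = 0,
) -> dict[tuple[str, int], list[TrialSpec]]:
    """Full trial lists, one per (group, listener).

    Each listener receives ``54 * repetitions`` trials: every cell repeated
    with a fresh sentence seed and a fresh draw of two babble segments
    (without replacement from the 9-segment pool), presented in a unique
    random order.
    """
    grid: dict[tuple[str, int], list[TrialSpec]] = {}
    for gi, group in enumerate(groups):
        for li in range(listeners_per_group):
            rng = np.random.default_rng(
                np.random.SeedSequence([master_seed, gi, li])
            )
            trials = []
            for rep in range(1, repetitions + 1):
                for cell in condition_cells(group):
                    segs = rng.choice(N_BABBLE_SEGMENTS, size=2, replace=False)
                    trials.append(
                        TrialSpec(
                            room=cell["room"],
                            snr=cell["snr"],
                            config=cell["config"],
                            processing=cell["processing"],
                            group=group,
                            repetition=rep,
                            seeds=(
                                int(rng.integers(2**31 - 1)),
                                _segment_seed(master_seed, int(segs[0])),
                                _segment_seed(master_seed, int(segs[1])),
                            ),
                            babble_segments=(int(segs[0]), int(segs[1])),
                        )
                    )
            order = rng.permutation(len(trials))
            grid[(group, li)] = [trials[i] for i in order]
    return grid


def add_precursor(sentence: np.ndarray, fs: float, gap_ms: float = 200.0):
    """Prefix a sentence with its time reversal and a silent gap.

    Returns ``(extended, target_span)`` where the extended signal is
    ``reverse(sentence) + silence(gap) + sentence`` and ``target_span``
    marks the final (target) sentence.  In continuous discourse the
    reverberant tail of a preceding sentence masks the target onset; the
    reversed copy reproduces that masking with matched spectrum and level.
    """
    x = np.asarray(sentence, dtype=float)
    if x.size == 0:
        raise ValueError("sentence must be non-empty")
    gap = np.zeros(int(round(gap_ms * 1e-3 * fs)))
    out = np.concatenate([x[::-1], gap, x])
    start = x.size + gap.size
    return out, slice(start, start + x.size)


def mix_at_snr(
    speech_lr: np.ndarray,
    noise1_lr: np.ndarray,
    noise2_lr: np.ndarray,
    snr_db: float,
    span: slice | None = None,
):
    """Scale both noises by one scalar to hit the requested broadband SNR.

    The SNR is the ratio of speech power, averaged across the left and
    right channels, to the power of the summed noise pair averaged across
    the channels, measured over ``span`` (the target-sentence interval;
    full duration when omitted).  Returns the scaled ``(noise1, noise2)``.
    """
    s = np.atleast_2d(np.asarray(speech_lr, dtype=float))
    n1 = np.atleast_2d(np.asarray(noise1_lr, dtype=float))
    n2 = np.atleast_2d(np.asarray(noise2_lr, dtype=float))
    if span is None:
        span = slice(0, s.shape[1])
    p_s = float(np.mean(s[:, span] ** 2))
    combined = n1[:, span] + n2[:, span]
    p_n = float(np.mean(combined**2))
    if p_n <= 0:
        raise ValueError("noise power is zero; cannot set an SNR")
    scale = float(np.sqrt(p_s / (p_n * 10.0 ** (snr_db / 10.0))))
    return n1 * scale, n2 * scale


def _convolve_binaural(x: np.ndarray, brir: BinauralImpulseResponse) -> np.ndarray:
    return np.stack(
        [sps.fftconvolve(x, brir.left), sps.fftconvolve(x, brir.right)]
    )


def spatialize_and_prune(
    trial: TrialSpec,
    brirs: dict[float, BinauralImpulseResponse],
    fs: float = 16000.0,
    sentence_duration: float = 2.0,
    gap_ms: float = 200.0,
) -> EarStimulus:
    """Assemble one binaural trial stimulus from a TrialSpec.

    The precursor-extended sentence is convolved with the BRIR at the
    speech azimuth, each babble with the BRIR at its (quantized) noise
    azimuth; the noises are scaled to the trial SNR over the target span;
    then everything before the target-sentence onset is pruned so the
    retained segment starts with the precursor's reverberant tail
    overlapping the target onset.  ``brirs`` maps quantized azimuths to the
    BRIRs of the trial's room; a missing azimuth raises ``KeyError`` naming
    it.
    """
    cfg = SPATIAL_CONFIGS[trial.config]
    sent = gen_sentence(trial.seeds[0], sentence_duration, fs)
    ext, span = add_precursor(sent.samples, fs, gap_ms)

    def _brir(az: float) -> BinauralImpulseResponse:
        q = quantize_azimuth(az)
        if q not in brirs:
            raise KeyError(f"no BRIR available for azimuth {q:+.0f} deg")
        return brirs[q]

    b_sp = _brir(cfg.speech_azimuth)
    sp = _convolve_binaural(ext, b_sp)

    dur_ext = ext.size / fs
    noises = []
    for az, seed in zip(cfg.noise_azimuths, trial.seeds[1:]):
        bab = gen_babble(seed, dur_ext, fs)
        noises.append(_convolve_binaural(bab.samples, _brir(az)))
    n_len = min(sp.shape[1], *(n.shape[1] for n in noises))
    sp = sp[:, :n_len]
    noises = [n[:, :n_len] for n in noises]

    onset = int(b_sp.meta.get("onset", 0))
    conv_span = slice(span.start + onset, min(span.stop + onset, n_len))
    n1, n2 = mix_at_snr(sp, noises[0], noises[1], trial.snr, conv_span)
    mix = sp + n1 + n2

    prune_at = span.start + onset
    out = mix[:, prune_at:]
    target = slice(0, span.stop - span.start)
    return EarStimulus(ha_mic=out, ear_canal=out.copy(), fs=fs, target_span=target)
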