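"""Bilateral hearing-aid simulator.

Per-ear processing chain, in fixed series order:

    6-band linear-phase FIR analysis
      -> Wiener-filter noise suppression (stimulus-long noise estimate)
      -> wide dynamic-range compression (or static linear gain)
      -> resynthesis
      -> sinusoidal-model frequency lowering
      -> 10-ms broadband output delay
      -> earmold-vent mixing with the direct ear-canal leak

The two ears are processed with no shared state.  The noise estimate for
the suppressor is deliberately the long-term RMS of the *mixture* over the
whole stimulus, reproducing a suppressor configuration known to give no
intelligibility benefit; on stationary noise the frame gain settles at the
configured attenuation floor (6 or 12 dB).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .fitting import BAND_FREQUENCIES, Prescription, nh_prescription
from .stimuli import EarStimulus

__all__ = [
    "FilterbankSpec",
    "SuppressorConfig",
    "ProcessedOutput",
    "SUPPRESSION_DB",
    "REF_LEVEL_DB",
    "analyze",
    "synthesize",
    "wiener_suppress",
    "wdrc",
    "freq_lower",
    "apply_delay",
    "vent_mix",
    "vent_frequency_response",
    "process_ear",
]

#: maximum suppressor attenuation per processing level, dB
SUPPRESSION_DB = {"linear": 0.0, "mild": 6.0, "strong": 12.0}

#: dB offset mapping full-scale RMS to the prescription's level scale:
#: an RMS of 1.0 reads as 100 dB, so typical stimuli sit near 65 dB.
REF_LEVEL_DB = 100.0

SUPPRESSOR_FRAME_MS = 8.0
LOWERING_FRAME_MS = 16.0
OUTPUT_DELAY_MS = 10.0
VENT_CUTOFF_HZ = 350.0


@dataclass(frozen=True)
class FilterbankSpec:
    """Six-channel linear-phase FIR filterbank.

    Bands are built as differences of linear-phase lowpass prototypes with
    crossovers at the geometric means of adjacent centre frequencies, so
    the band filters sum *exactly* to a delayed unit impulse (flat
    reconstruction) and every filter is symmetric (exact linear phase).
    """

    centers: tuple = BAND_FREQUENCIES
    fs: float = 16000.0
    taps: int | None = None

    def __post_init__(self) -> None:
        if self.fs < 16000:
            raise ValueError("filterbank requires fs >= 16 kHz")

    @property
    def numtaps(self) -> int:
        if self.taps is not None:
            return self.taps
        n = int(round(0.03 * self.fs))
        return n + 1 if n % 2 == 0 else n

    @property
    def delay(self) -> int:
        return (self.numtaps - 1) // 2

    @property
    def crossovers(self) -> np.ndarray:
        c = np.asarray(self.centers, dtype=float)
        return np.sqrt(c[:-1] * c[1:])

    def band_filters(self) -> np.ndarray:
        n = self.numtaps
        lps = [sps.firwin(n, f, fs=self.fs) for f in self.crossovers]
        delta = np.zeros(n)
        delta[self.delay] = 1.0
        bands = [lps[0]]
        for lo, hi in zip(lps[:-1], lps[1:]):
            bands.append(hi - lo)
        bands.append(delta - lps[-1])
        return np.stack(bands)


def analyze(spec: FilterbankSpec, x: np.ndarray) -> np.ndarray:
    """Split ``x`` into the six band signals (each delayed by spec.delay)."""
    h = spec.band_filters()
    x = np.asarray(x, dtype=float)
    return np.stack([sps.fftconvolve(x, hk)[: x.size] for hk in h])


def synthesize(bands: np.ndarray) -> np.ndarray:
    """Recombine band signals; inverse of :func:`analyze` up to the delay."""
    return np.sum(np.asarray(bands, dtype=float), axis=0)


@dataclass
class SuppressorConfig:
    """Wiener suppressor setting.

    ``max_attenuation`` in dB bounds the per-band gain from below at
    ``10**(-max_attenuation/20)``; ``noise_estimate`` holds the per-band
    noise power and is computed from the full stimulus when omitted.
    """

    max_attenuation: float = 0.0
    noise_estimate: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.max_attenuation not in (0.0, 6.0, 12.0):
            # the study's settings; other floors are allowed but flagged
            if self.max_attenuation < 0:
                raise ValueError("max_attenuation must be >= 0 dB")


def wiener_suppress(
    bands: np.ndarray,
    config: SuppressorConfig,
    fs: float,
    frame_ms: float = SUPPRESSOR_FRAME_MS,
):
    """Frame-wise Wiener gain per band with a stimulus-long noise estimate.

    Per band and 8-ms frame, with frame power p and noise estimate n, the
    speech estimate is s = max(p - n, 0) and the applied gain is
    g = max(s / p, floor) = max(s / (s + n), floor).  A zero
    ``max_attenuation`` is an exact identity.  Returns ``(bands, gains_db)``
    where ``gains_db`` is the (bands x frames) applied-gain log.
    """
    bands = np.asarray(bands, dtype=float)
    floor = 10.0 ** (-config.max_attenuation / 20.0)
    frame = max(1, int(round(frame_ms * 1e-3 * fs)))
    n_frames = int(math.ceil(bands.shape[1] / frame))
    if config.max_attenuation == 0.0:
        return bands.copy(), np.zeros((bands.shape[0], n_frames))

    noise = config.noise_estimate
    if noise is None:
        noise = np.mean(bands**2, axis=1)

    out = np.empty_like(bands)
    gains_db = np.empty((bands.shape[0], n_frames))
    for b in range(bands.shape[0]):
        x = bands[b]
        pad = n_frames * frame - x.size
        frames = np.pad(x, (0, pad)).reshape(n_frames, frame)
        p = np.mean(frames**2, axis=1)
        s = np.maximum(p - noise[b], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(p > 0, s / np.maximum(p, 1e-30), floor)
        g = np.clip(g, floor, 1.0)
        gains_db[b] = 20.0 * np.log10(g)
        g_samp = np.repeat(g, frame)[: x.size]
        # short moving average smooths frame-boundary steps
        k = np.ones(frame) / frame
        g_smooth = sps.fftconvolve(np.pad(g_samp, (frame // 2, frame // 2), mode="edge"), k)[
            frame - 1 : frame - 1 + x.size
        ]
        out[b] = x * g_smooth
    return out, gains_db


def _envelope_db(x: np.ndarray, fs: float, attack_ms: float, release_ms: float,
                 hop_ms: float = 1.0) -> np.ndarray:
    """Attack/release level tracker, returned per 1-ms hop in dB."""
    hop = max(1, int(round(hop_ms * 1e-3 * fs)))
    n_frames = int(math.ceil(x.size / hop))
    pad = n_frames * hop - x.size
    p = np.mean(np.pad(x, (0, pad)).reshape(n_frames, hop) ** 2, axis=1)
    a_att = math.exp(-hop / (attack_ms * 1e-3 * fs))
    a_rel = math.exp(-hop / (release_ms * 1e-3 * fs))
    env = np.empty(n_frames)
    e = p[0]
    for i, pi in enumerate(p):
        a = a_att if pi > e else a_rel
        e = a * e + (1.0 - a) * pi
        env[i] = e
    return 10.0 * np.log10(np.maximum(env, 1e-12)) + REF_LEVEL_DB


def wdrc(
    bands: np.ndarray,
    prescription: Prescription,
    fs: float,
):
    """Per-band wide dynamic-range compression.

    Below the kneepoint the static curve applies the prescribed band gain;
    above it the output grows with slope 1/CR.  Dynamics come from a
    one-pole attack/release envelope tracker initialised at the first-frame
    level.  Returns ``(bands, gains_db)`` with the per-band, per-1-ms-hop
    applied gain.
    """
    bands = np.asarray(bands, dtype=float)
    cr = prescription.compression_ratios
    if np.any(cr < 1):
        raise ValueError("compression ratio must be >= 1")
    out = np.empty_like(bands)
    logs = []
    hop = max(1, int(round(1e-3 * fs)))
    for b in range(bands.shape[0]):
        lev = _envelope_db(bands[b], fs, prescription.attack_ms, prescription.release_ms)
        knee = prescription.kneepoints[b]
        g0 = prescription.band_gains[b]
        gain_db = np.where(lev <= knee, g0, g0 - (lev - knee) * (1.0 - 1.0 / cr[b]))
        logs.append(gain_db)
        g_samp = np.repeat(10.0 ** (gain_db / 20.0), hop)[: bands.shape[1]]
        out[b] = bands[b] * g_samp
    return out, np.stack(logs)


def freq_lower(x: np.ndarray, fs: float, fc: float, cr: float,
               frame_ms: float = LOWERING_FRAME_MS) -> np.ndarray:
    """Sinusoidal-model frequency compression above a cutoff.

    Content below ``fc`` passes through a complementary linear-phase
    lowpass unchanged; content above is analysed frame-by-frame (16-ms
    Hann, half overlap) into spectral peaks which are re-synthesised as
    oscillators at ``fc + (f - fc)/cr`` with the original amplitudes and
    phase continuity across frames.  ``cr = 1`` is an exact identity.
    """
    if cr < 1:
        raise ValueError("lowering ratio must be >= 1")
    if fc >= fs / 2:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    x = np.asarray(x, dtype=float)
    if cr == 1.0:
        return x.copy()

    taps = 255
    lp = sps.firwin(taps, fc, fs=fs)
    d = (taps - 1) // 2
    low = sps.fftconvolve(x, lp)[: x.size]
    delayed = np.concatenate([np.zeros(d), x])[: x.size]
    high = delayed - low

    frame = int(round(frame_ms * 1e-3 * fs))
    frame += frame % 2
    hop = frame // 2
    win = np.hanning(frame + 1)[:frame]
    nfft = 1 << int(math.ceil(math.log2(frame * 4)))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)

    out = np.zeros(x.size + frame)
    wsum = np.zeros(x.size + frame)
    tracks: dict[int, float] = {}  # coarse mapped-freq key -> phase
    thresh_rel = 10.0 ** (-60.0 / 20.0)
    peak_floor = None
    t_frame = np.arange(frame) / fs
    for start in range(0, x.size - 1, hop):
        seg = high[start : start + frame]
        if seg.size < frame:
            seg = np.pad(seg, (0, frame - seg.size))
        spec = np.fft.rfft(seg * win, nfft)
        mag = np.abs(spec)
        if peak_floor is None:
            peak_floor = max(mag.max(), 1e-9) * thresh_rel
        peaks, _ = sps.find_peaks(mag, height=max(mag.max() * 0.01, peak_floor))
        synth = np.zeros(frame)
        new_tracks: dict[int, float] = {}
        for p in peaks[np.argsort(mag[peaks])[::-1][:12]]:
            # parabolic interpolation of the peak bin
            if 0 < p < mag.size - 1:
                a, b, c = mag[p - 1], mag[p], mag[p + 1]
                denom = a - 2 * b + c
                dp = 0.5 * (a - c) / denom if denom != 0 else 0.0
            else:
                dp = 0.0
            f0 = (p + dp) * fs / nfft
            amp = 2.0 * mag[p] / win.sum()
            f_map = f0 if f0 <= fc else fc + (f0 - fc) / cr
            key = int(round(f_map / 25.0))
            phase = tracks.get(key)
            if phase is None:
                phase = float(np.angle(spec[p]))
            synth += amp * np.cos(2 * math.pi * f_map * t_frame + phase)
            new_tracks[key] = (phase + 2 * math.pi * f_map * hop / fs) % (2 * math.pi)
        tracks = new_tracks
        out[start : start + frame] += synth * win
        wsum[start : start + frame] += win
    resynth = out[: x.size] / np.maximum(wsum[: x.size], 1e-3)
    return low + resynth


def apply_delay(x: np.ndarray, fs: float, delay_ms: float = OUTPUT_DELAY_MS) -> np.ndarray:
    """Broadband output delay (integer samples nearest ``delay_ms``)."""
    n = int(round(delay_ms * 1e-3 * fs))
    if n == 0:
        return np.asarray(x, dtype=float).copy()
    return np.concatenate([np.zeros(n), np.asarray(x, dtype=float)])[: x.size + n]


def _vent_sos(fs: float, fc: float):
    hp = sps.butter(2, fc, btype="highpass", fs=fs, output="sos")
    lp = sps.butter(2, fc, btype="lowpass", fs=fs, output="sos")
    return hp, lp


def vent_mix(ha_out: np.ndarray, ear_canal_direct: np.ndarray, fs: float,
             fc: float = VENT_CUTOFF_HZ) -> np.ndarray:
    """Earmold vent: highpass the aid output, lowpass the direct leak, sum.

    The complementary 2nd-order Butterworth pair is power-complementary
    (|HP|^2 + |LP|^2 = 1 at every frequency).  ``fc = 0`` disables the vent
    and returns the hearing-aid output unchanged.
    """
    ha_out = np.asarray(ha_out, dtype=float)
    if fc <= 0:
        return ha_out.copy()
    ec = np.asarray(ear_canal_direct, dtype=float)
    n = max(ha_out.size, ec.size)
    ha_out = np.pad(ha_out, (0, n - ha_out.size))
    ec = np.pad(ec, (0, n - ec.size))
    hp, lp = _vent_sos(fs, fc)
    return sps.sosfilt(hp, ha_out) + sps.sosfilt(lp, ec)


def vent_frequency_response(fs: float, fc: float = VENT_CUTOFF_HZ,
                            freqs: np.ndarray | None = None):
    """Complex HP and LP branch responses on a frequency grid (Hz)."""
    if freqs is None:
        freqs = np.arange(1.0, fs / 2)
    hp, lp = _vent_sos(fs, fc)
    _, h_hp = sps.sosfreqz(hp, worN=freqs, fs=fs)
    _, h_lp = sps.sosfreqz(lp, worN=freqs, fs=fs)
    return freqs, h_hp, h_lp


@dataclass
class ProcessedOutput:
    """Result of one ear's hearing-aid chain."""

    ha_path: np.ndarray
    vent_path: np.ndarray
    combined: np.ndarray
    fs: float
    applied_gains: dict = field(default_factory=dict)


def _stage_plan(level: str, group: str) -> dict:
    if level not in SUPPRESSION_DB:
        raise ValueError(f"unknown processing level {level!r}")
    if group not in ("NH", "HI"):
        raise ValueError(f"unknown listener group {group!r}")
    return {
        "suppression_db": SUPPRESSION_DB[level],
        "wdrc": group == "HI" and level in ("mild", "strong"),
        "lowering": group == "HI" and level == "strong",
        "nalr": group == "HI" and level == "linear",
    }


def process_ear(
    stim: EarStimulus,
    level: str,
    group: str,
    prescription: Prescription | None = None,
    audiogram=None,
    spec: FilterbankSpec | None = None,
    delay_ms: float = OUTPUT_DELAY_MS,
    vent_fc: float = VENT_CUTOFF_HZ,
) -> tuple[ProcessedOutput, ProcessedOutput]:
    """Run the full bilateral chain; returns (left, right) outputs.

    Level semantics: NH linear = flat 0-dB pass; NH mild/strong = 6/12-dB
    suppression only; HI linear = NAL-R static gains (pass a
    ``fitting.nalr_prescription``); HI mild = 6-dB suppression + WDRC; HI
    strong = 12-dB suppression + WDRC + frequency lowering.  Every output
    passes the 10-ms delay and the vent stage; the direct ear-canal leak is
    *not* delayed, which is what makes the vent path acoustically distinct.
    ``prescription`` may be one Prescription for both ears or a
    (left, right) pair.  Left and right share no state.
    """
    plan = _stage_plan(level, group)
    fs = stim.fs
    if spec is None:
        spec = FilterbankSpec(fs=fs)
    if prescription is None:
        if plan["wdrc"] or plan["nalr"]:
            raise ValueError("an HI chain requires a prescription")
        prescription = nh_prescription()
    rx_pair = prescription if isinstance(prescription, (tuple, list)) else (prescription, prescription)

    outputs = []
    for ear in (0, 1):
        prescription = rx_pair[ear]
        x = stim.ha_mic[ear]
        log: dict = {"stages": []}
        bands = analyze(spec, x)
        if plan["suppression_db"] > 0:
            cfg = SuppressorConfig(max_attenuation=plan["suppression_db"])
            bands, g = wiener_suppress(bands, cfg, fs)
            log["stages"].append("suppress")
            log["suppressor_db"] = g
        if plan["wdrc"]:
            bands, g = wdrc(bands, prescription, fs)
            log["stages"].append("wdrc")
            log["wdrc_db"] = g
        elif plan["nalr"]:
            gains = prescription.band_gains
            bands = bands * (10.0 ** (gains[:, None] / 20.0))
            log["stages"].append("nalr")
            log["nalr_db"] = gains
        y = synthesize(bands)
        if plan["lowering"] and prescription.cr_lowering > 1.0:
            y = freq_lower(y, fs, prescription.fc_lowering, prescription.cr_lowering)
            log["stages"].append("lower")
            log["lowering"] = (prescription.fc_lowering, prescription.cr_lowering)
        y = apply_delay(y, fs, delay_ms)
        log["stages"].append("delay")
        combined = vent_mix(y, stim.ear_canal[ear], fs, vent_fc)
        log["stages"].append("vent")
        outputs.append(
            ProcessedOutput(ha_path=y, vent_path=stim.ear_canal[ear].copy(),
                            combined=combined, fs=fs, applied_gains=log)
        )
    return outputs[0], outputs[1]
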