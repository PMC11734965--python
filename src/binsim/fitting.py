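"""Audiograms and hearing-aid prescriptions.

Maps per-ear audiometric thresholds onto the simulator's per-band settings:
NAL-R linear insertion gains, a simplified compression-ratio rule standing in
for the proprietary NAL-NL2 tables, threshold-driven frequency-lowering
parameters, and the audiometric interaural-symmetry inclusion criterion.
All prescriptions are deterministic functions of the audiogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BAND_FREQUENCIES",
    "Audiogram",
    "Prescription",
    "nalr_gains",
    "wdrc_params",
    "check_symmetry",
    "lowering_params",
    "nh_prescription",
]

#: Filterbank band centres shared with the hearing-aid simulator (Hz).
BAND_FREQUENCIES = (250.0, 500.0, 1000.0, 2000.0, 4000.0, 6000.0)

# NAL-R per-frequency correction k(f) in dB (published rule constants,
# hand-checked against the rule's worked examples before integration).
_NALR_K = {250.0: -17.0, 500.0: -8.0, 1000.0: 1.0, 2000.0: -1.0,
           4000.0: -2.0, 6000.0: -2.0}

WDRC_KNEEPOINT_DB = 45.0   # input level (dB re the simulator reference)
WDRC_ANCHOR_DB = 65.0      # input level where WDRC gain matches NAL-R


@dataclass(frozen=True)
class Audiogram:
    """Per-ear pure-tone thresholds in dB HL at ascending frequencies."""

    frequencies: tuple = BAND_FREQUENCIES
    thresholds_left: tuple = (0.0,) * 6
    thresholds_right: tuple = (0.0,) * 6

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequency list must be ascending")
        for t in (self.thresholds_left, self.thresholds_right):
            if len(t) != len(self.frequencies):
                raise ValueError("one threshold per frequency is required")
            if np.any(np.asarray(t) < -10) or np.any(np.asarray(t) > 120):
                raise ValueError("thresholds must lie in [-10, 120] dB HL")

    def thresholds(self, ear: str) -> np.ndarray:
        if ear == "left":
            return np.asarray(self.thresholds_left, dtype=float)
        if ear == "right":
            return np.asarray(self.thresholds_right, dtype=float)
        raise ValueError("ear must be 'left' or 'right'")

    def at(self, ear: str, freq: float) -> float:
        """Threshold at ``freq``, interpolated linearly on log-frequency."""
        f = np.asarray(self.frequencies, dtype=float)
        t = self.thresholds(ear)
        return float(np.interp(np.log10(freq), np.log10(f), t))


@dataclass
class Prescription:
    """Per-band hearing-aid settings derived from one ear's audiogram."""

    band_gains: np.ndarray
    compression_ratios: np.ndarray
    kneepoints: np.ndarray
    attack_ms: float = 5.0
    release_ms: float = 70.0
    fc_lowering: float = 3000.0
    cr_lowering: float = 1.0
    frequencies: tuple = BAND_FREQUENCIES

    def __post_init__(self) -> None:
        self.band_gains = np.asarray(self.band_gains, dtype=float)
        self.compression_ratios = np.asarray(self.compression_ratios, dtype=float)
        self.kneepoints = np.asarray(self.kneepoints, dtype=float)
        if np.any(self.compression_ratios < 1):
            raise ValueError("compression ratios must be >= 1")
        if self.cr_lowering < 1:
            raise ValueError("cr_lowering must be >= 1")

    @property
    def is_linear(self) -> bool:
        return bool(np.all(self.compression_ratios == 1) and self.cr_lowering == 1)


def _band_thresholds(audiogram: Audiogram, ear: str) -> np.ndarray:
    for f in (500.0, 1000.0, 2000.0):
        if not (audiogram.frequencies[0] <= f <= audiogram.frequencies[-1]):
            raise ValueError("thresholds at 500/1000/2000 Hz are required")
    return np.array([audiogram.at(ear, f) for f in BAND_FREQUENCIES])


def nalr_gains(audiogram: Audiogram, ear: str) -> np.ndarray:
    """NAL-R linear insertion gains per filterbank band, clamped >= 0 dB.

    IG(f) = X + 0.31 H(f) + k(f) with X = 0.05 (H500 + H1000 + H2000),
    i.e. 0.15 times the three-frequency average.
    """
    h = _band_thresholds(audiogram, ear)
    x = 0.15 * np.mean([audiogram.at(ear, f) for f in (500.0, 1000.0, 2000.0)])
    k = np.array([_NALR_K[f] for f in BAND_FREQUENCIES])
    return np.maximum(x + 0.31 * h + k, 0.0)


def wdrc_params(
    audiogram: Audiogram,
    ear: str,
    attack_ms: float = 5.0,
    release_ms: float = 70.0,
) -> Prescription:
    """Wide dynamic-range compression settings for one ear.

    Compression ratio per band follows the simplified loss mapping
    CR = 1 + H/100 clipped to [1, 3] (an openly documented stand-in for the
    proprietary NAL-NL2 tables).  Band gains are anchored so that a 65-dB
    input receives exactly the NAL-R insertion gain in every band; the
    kneepoint is fixed at 45 dB.
    """
    h = _band_thresholds(audiogram, ear)
    cr = np.clip(1.0 + h / 100.0, 1.0, 3.0)
    nalr = nalr_gains(audiogram, ear)
    gains = nalr + (WDRC_ANCHOR_DB - WDRC_KNEEPOINT_DB) * (1.0 - 1.0 / cr)
    fc, crl = lowering_params(audiogram, ear)
    return Prescription(
        band_gains=gains,
        compression_ratios=cr,
        kneepoints=np.full(len(BAND_FREQUENCIES), WDRC_KNEEPOINT_DB),
        attack_ms=attack_ms,
        release_ms=release_ms,
        fc_lowering=fc,
        cr_lowering=crl,
    )


def nalr_prescription(audiogram: Audiogram, ear: str) -> Prescription:
    """Linear NAL-R fitting: static insertion gains, no compression."""
    n = len(BAND_FREQUENCIES)
    return Prescription(
        band_gains=nalr_gains(audiogram, ear),
        compression_ratios=np.ones(n),
        kneepoints=np.full(n, WDRC_KNEEPOINT_DB),
        fc_lowering=3000.0,
        cr_lowering=1.0,
    )


def nh_prescription() -> Prescription:
    """Flat 0-dB linear amplification (the normal-hearing fitting)."""
    n = len(BAND_FREQUENCIES)
    return Prescription(
        band_gains=np.zeros(n),
        compression_ratios=np.ones(n),
        kneepoints=np.full(n, WDRC_KNEEPOINT_DB),
        fc_lowering=3000.0,
        cr_lowering=1.0,
    )


def check_symmetry(audiogram: Audiogram) -> bool:
    """Audiometric interaural-symmetry inclusion criterion.

    Symmetric iff the interaural threshold difference is below 15 dB at
    every frequency, or below 20 dB when a difference of 15 dB or more
    occurs at exactly one test frequency.
    """
    diff = np.abs(audiogram.thresholds("left") - audiogram.thresholds("right"))
    if np.all(diff < 15):
        return True
    return bool(np.sum(diff >= 15) == 1 and np.max(diff) < 20)


def lowering_params(audiogram: Audiogram, ear: str) -> tuple[float, float]:
    """Frequency-lowering cutoff (Hz) and compression ratio for one ear.

    The audible edge ``e`` is the highest band frequency with a threshold
    of at most 60 dB HL.  The cutoff is ``e`` clipped to [1500, 3000] Hz.
    When hearing is audible out to 6 kHz no lowering is applied (ratio 1);
    otherwise the ratio maps 6 kHz to the audible edge,
    ``(6000 - fc) / (e - fc)`` clipped to [1, 3], falling back to the
    maximum ratio 3 when the edge coincides with the cutoff.
    """
    h = _band_thresholds(audiogram, ear)
    audible = [f for f, t in zip(BAND_FREQUENCIES, h) if t <= 60.0]
    edge = max(audible) if audible else BAND_FREQUENCIES[0]
    fc = float(np.clip(edge, 1500.0, 3000.0))
    if edge >= 6000.0:
        return fc, 1.0
    if edge > fc:
        return fc, float(np.clip((6000.0 - fc) / (edge - fc), 1.0, 3.0))
    return fc, 3.0
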