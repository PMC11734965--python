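"""Better-ear / binaural-unmasking prediction of spatial release from masking.

The predictor follows the standard binaural-intelligibility model family for
non-stationary maskers and normal hearing:

* **BE (better-ear glimpsing)** — target and masker ear signals are passed
  through a gammatone filterbank; per band and 24-ms frame the
  target-to-masker ratio is computed at each ear, the better ear is taken
  cell by cell, frames are averaged, and bands are combined with SII band
  importance weights.  The BE release of a condition is the difference of
  this weighted effective SNR from the reference condition's.

* **BU (binaural unmasking)** — per gammatone band, the interaural phase of
  target and masker and the masker interaural coherence rho enter the
  equalization-cancellation masking-level difference

      BMLD = max(0, 10 log10((k - cos(phi_t - phi_m)) / (k - rho)))

  with k = (1 + sigma_eps^2) * exp((2 pi f_c)^2 * sigma_del^2), using the
  classic jitter constants sigma_eps = 0.25 and sigma_del = 105 us.  The
  hand-derived check: an antiphasic target in diotic noise at 500 Hz gives
  a BMLD of about 10.7 dB.  Band BMLDs are SII-weighted and the BU release
  is again the difference from the reference.

The total release ("all cues") is BE + BU by construction, positive values
meaning a predicted speech-reception-threshold benefit in dB.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "GammatoneSpec",
    "ModelInputs",
    "SRMPrediction",
    "erb_space",
    "sii_band_importance",
    "prepare_target",
    "band_snr_matrix",
    "be_component",
    "bu_band_values",
    "bu_component",
    "bmld",
    "predict_srm",
]

SNR_CEILING_DB = 20.0
SNR_FLOOR_DB = -30.0
SIGMA_EPSILON = 0.25
SIGMA_DELTA_S = 105e-6

# ANSI-style one-third-octave SII band importance (160 Hz ... 8 kHz).
_SII_FREQS = np.array([160, 200, 250, 315, 400, 500, 630, 800, 1000, 1250,
                       1600, 2000, 2500, 3150, 4000, 5000, 6300, 8000.0])
_SII_IMPORTANCE = np.array([0.0083, 0.0095, 0.0150, 0.0289, 0.0440, 0.0578,
                            0.0653, 0.0711, 0.0818, 0.0844, 0.0882, 0.0898,
                            0.0868, 0.0844, 0.0771, 0.0527, 0.0364, 0.0185])


def erb_space(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    """Centre frequencies equally spaced on the ERB-number scale."""
    def erb_num(f):
        return 21.4 * np.log10(1.0 + 0.00437 * f)

    def inv(e):
        return (10.0 ** (e / 21.4) - 1.0) / 0.00437

    return inv(np.linspace(erb_num(f_lo), erb_num(f_hi), n))


@dataclass(frozen=True)
class GammatoneSpec:
    """Auditory filterbank and framing used by both model components."""

    n_channels: int = 30
    cf_lo: float = 80.0
    cf_hi: float = 8000.0
    frame_ms: float = 24.0

    def centers(self, fs: float) -> np.ndarray:
        hi = min(self.cf_hi, 0.45 * fs)
        cfs = erb_space(self.cf_lo, hi, self.n_channels)
        if not np.all(np.diff(cfs) > 0):
            raise ValueError("centre frequencies must be strictly increasing")
        return cfs


@dataclass
class ModelInputs:
    """Calibrated target and masker ear signals for one condition.

    ``target_lr`` is the (2, N) averaged target; ``maskers_lr`` a list of
    (2, N) masker realizations.  ``calibrate()`` scales every masker to the
    target's broadband level, i.e. the experiment's 0-dB-SNR presentation.
    """

    target_lr: np.ndarray
    maskers_lr: list
    fs: float

    def __post_init__(self) -> None:
        self.target_lr = np.atleast_2d(np.asarray(self.target_lr, dtype=float))
        self.maskers_lr = [np.atleast_2d(np.asarray(m, dtype=float)) for m in self.maskers_lr]
        if not self.maskers_lr:
            raise ValueError("at least one masker realization is required")
        n = {m.shape[1] for m in self.maskers_lr}
        if len(n) != 1:
            raise ValueError("all maskers must have equal length")

    def calibrate(self) -> "ModelInputs":
        pt = np.mean(self.target_lr**2)
        maskers = []
        for m in self.maskers_lr:
            pm = np.mean(m**2)
            maskers.append(m * math.sqrt(pt / pm) if pm > 0 else m)
        return ModelInputs(self.target_lr, maskers, self.fs)


@dataclass
class SRMPrediction:
    """Predicted spatial release in dB, split by mechanism."""

    be_only: float
    bu_only: float
    all_cues: float
    reference: str = ""
    be_se: float = float("nan")
    bu_se: float = float("nan")
    n_realizations: int = 0

    def value(self, mode: str = "all") -> float:
        return {"BE": self.be_only, "BU": self.bu_only, "all": self.all_cues}[mode]


def sii_band_importance(cfs: np.ndarray) -> np.ndarray:
    """SII band-importance weights interpolated to ``cfs``, summing to 1."""
    w = np.interp(np.log10(cfs), np.log10(_SII_FREQS), _SII_IMPORTANCE,
                  left=0.0, right=0.0)
    w = np.maximum(w, 1e-4)
    return w / w.sum()


def prepare_target(sentences: list, fs: float, discard_ms: float = 45.0) -> np.ndarray:
    """Average many sentences into the model's single target signal.

    Each sentence loses its first 45 ms, all are truncated to the shortest
    remaining duration, and the result is the sample-wise average.  Accepts
    mono arrays or (2, N) ear pairs.
    """
    if not sentences:
        raise ValueError("sentence list must not be empty")
    cut = int(round(discard_ms * 1e-3 * fs))
    trimmed = [np.atleast_2d(np.asarray(s, dtype=float))[:, cut:] for s in sentences]
    n = min(t.shape[1] for t in trimmed)
    if n <= 0:
        raise ValueError("sentences are shorter than the discard interval")
    stack = np.stack([t[:, :n] for t in trimmed])
    out = stack.mean(axis=0)
    return out[0] if out.shape[0] == 1 else out


def _gammatone_bank(x: np.ndarray, fs: float, cfs: np.ndarray) -> np.ndarray:
    out = np.empty((cfs.size, x.size))
    for i, cf in enumerate(cfs):
        b, a = sps.gammatone(cf, "iir", fs=fs)
        out[i] = sps.lfilter(b, a, x)
    return out


def _frame_energy(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    n_frames = max(1, 1 + (x.shape[-1] - frame) // hop)
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    return np.sum(x[..., idx] ** 2, axis=-1)


def band_snr_matrix(
    target_lr: np.ndarray,
    masker_lr: np.ndarray,
    spec: GammatoneSpec,
    fs: float,
):
    """Per-ear (band x frame) SNR in dB, ceiled at +20 and floored at -30.

    Frames with zero masker energy are set to the ceiling with a warning.
    """
    target_lr = np.atleast_2d(target_lr)
    masker_lr = np.atleast_2d(masker_lr)
    cfs = spec.centers(fs)
    frame = int(round(spec.frame_ms * 1e-3 * fs))
    hop = frame // 2
    out = []
    warned = False
    for ear in range(2):
        tb = _gammatone_bank(target_lr[ear], fs, cfs)
        mb = _gammatone_bank(masker_lr[ear], fs, cfs)
        et = _frame_energy(tb, frame, hop)
        em = _frame_energy(mb, frame, hop)
        zero = em <= 0
        if np.any(zero) and not warned:
            warnings.warn("masker frames with zero energy; SNR set to ceiling")
            warned = True
        with np.errstate(divide="ignore", invalid="ignore"):
            snr = 10.0 * np.log10(np.where(zero, 1.0, et / np.maximum(em, 1e-30)))
        snr[zero] = SNR_CEILING_DB
        out.append(np.clip(snr, SNR_FLOOR_DB, SNR_CEILING_DB))
    return out[0], out[1]


def be_component(snr_left: np.ndarray, snr_right: np.ndarray,
                 weights: np.ndarray) -> float:
    """Weighted better-ear effective SNR in dB for one condition.

    Cell-wise max over ears, frame average, SII-weighted band average.  The
    BE *release* of a condition is this value minus the reference
    condition's value.
    """
    if snr_left.shape != snr_right.shape:
        raise ValueError("ear SNR matrices must be aligned")
    eff = np.maximum(snr_left, snr_right).mean(axis=-1)
    return float(np.sum(weights * eff))


def bmld(cf: float, phi_target: float, phi_masker: float, rho: float) -> float:
    """Equalization-cancellation BMLD (dB) for one band, floored at 0."""
    k = (1.0 + SIGMA_EPSILON**2) * math.exp((2.0 * math.pi * cf) ** 2 * SIGMA_DELTA_S**2)
    rho = min(rho, 1.0 - 1e-6)
    val = (k - math.cos(phi_target - phi_masker)) / (k - rho)
    return max(0.0, 10.0 * math.log10(max(val, 1e-12)))


def _interaural_stats(left_bank: np.ndarray, right_bank: np.ndarray):
    """Per-band interaural phase and coherence from analytic band signals."""
    al = sps.hilbert(left_bank, axis=-1)
    ar = sps.hilbert(right_bank, axis=-1)
    cross = np.sum(al * np.conj(ar), axis=-1)
    denom = np.sqrt(np.sum(np.abs(al) ** 2, axis=-1) * np.sum(np.abs(ar) ** 2, axis=-1))
    denom = np.maximum(denom, 1e-30)
    phase = np.angle(cross)
    rho = np.abs(cross) / denom
    return phase, np.minimum(rho, 1.0 - 1e-6)


def bu_band_values(
    target_lr: np.ndarray,
    masker_lr: np.ndarray,
    spec: GammatoneSpec,
    fs: float,
) -> np.ndarray:
    """Per-band BMLD (dB) for one target/masker pair."""
    target_lr = np.atleast_2d(target_lr)
    masker_lr = np.atleast_2d(masker_lr)
    cfs = spec.centers(fs)
    tl = _gammatone_bank(target_lr[0], fs, cfs)
    tr = _gammatone_bank(target_lr[1], fs, cfs)
    ml = _gammatone_bank(masker_lr[0], fs, cfs)
    mr = _gammatone_bank(masker_lr[1], fs, cfs)
    phi_t, _ = _interaural_stats(tl, tr)
    phi_m, rho = _interaural_stats(ml, mr)
    return np.array([
        bmld(cf, pt, pm, r) for cf, pt, pm, r in zip(cfs, phi_t, phi_m, rho)
    ])


def bu_component(
    target_lr: np.ndarray,
    masker_lr: np.ndarray,
    spec: GammatoneSpec,
    fs: float,
    weights: np.ndarray | None = None,
) -> float:
    """SII-weighted binaural-unmasking advantage (dB) for one condition."""
    if weights is None:
        weights = sii_band_importance(spec.centers(fs))
    vals = bu_band_values(target_lr, masker_lr, spec, fs)
    return float(np.sum(weights * vals))


def predict_srm(
    condition: ModelInputs,
    reference: ModelInputs,
    spec: GammatoneSpec | None = None,
    mode: str = "all",
) -> SRMPrediction:
    """Predicted spatial release from masking of ``condition`` vs ``reference``.

    Per masker realization the BE effective SNR and BU advantage are
    computed and averaged across realizations for both conditions; the
    releases are the condition-minus-reference differences and
    ``all_cues = be_only + bu_only`` exactly.  When the condition *is* the
    reference the release is 0 dB in every mode.  ``mode`` selects the
    headline value returned by :meth:`SRMPrediction.value`.
    """
    if mode not in ("BE", "BU", "all"):
        raise ValueError("mode must be 'BE', 'BU' or 'all'")
    if condition.fs != reference.fs:
        raise ValueError("condition and reference sampling rates differ")
    if spec is None:
        spec = GammatoneSpec()
    fs = condition.fs
    weights = sii_band_importance(spec.centers(fs))

    def values(inputs: ModelInputs):
        # shared gammatone decompositions: the target banks are computed
        # once per condition and each masker's banks serve both components
        inputs = inputs.calibrate()
        cfs = spec.centers(fs)
        frame = int(round(spec.frame_ms * 1e-3 * fs))
        hop = frame // 2
        tl = _gammatone_bank(inputs.target_lr[0], fs, cfs)
        tr = _gammatone_bank(inputs.target_lr[1], fs, cfs)
        et = (_frame_energy(tl, frame, hop), _frame_energy(tr, frame, hop))
        phi_t, _ = _interaural_stats(tl, tr)
        be_vals, bu_vals = [], []
        for m in inputs.maskers_lr:
            ml = _gammatone_bank(m[0], fs, cfs)
            mr = _gammatone_bank(m[1], fs, cfs)
            snrs = []
            for e_t, bank in zip(et, (ml, mr)):
                em = _frame_energy(bank, frame, hop)
                nf = min(e_t.shape[1], em.shape[1])
                with np.errstate(divide="ignore", invalid="ignore"):
                    snr = 10.0 * np.log10(
                        np.where(em[:, :nf] <= 0, 1.0,
                                 e_t[:, :nf] / np.maximum(em[:, :nf], 1e-30))
                    )
                snr[em[:, :nf] <= 0] = SNR_CEILING_DB
                snrs.append(np.clip(snr, SNR_FLOOR_DB, SNR_CEILING_DB))
            be_vals.append(be_component(snrs[0], snrs[1], weights))
            phi_m, rho = _interaural_stats(ml, mr)
            bu_vals.append(float(np.sum(weights * np.array([
                bmld(cf, pt, pm, r)
                for cf, pt, pm, r in zip(cfs, phi_t, phi_m, rho)
            ]))))
        return np.array(be_vals), np.array(bu_vals)

    be_c, bu_c = values(condition)
    be_r, bu_r = values(reference)
    be = float(be_c.mean() - be_r.mean())
    bu = float(bu_c.mean() - bu_r.mean())
    n = len(be_c)
    return SRMPrediction(
        be_only=be,
        bu_only=bu,
        all_cues=be + bu,
        be_se=float(be_c.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
        bu_se=float(bu_c.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
        n_realizations=n,
    )
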