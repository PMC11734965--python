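"""WAV + JSON-sidecar I/O for scene and stimulus artifacts.

Audio is stored as float32 WAV (mono, stereo, or 4-channel) via
``scipy.io.wavfile``; structured metadata travels in a ``.json`` sidecar next
to the audio file so every artifact stays self-describing and text-adjacent.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile


def write_wav(path, fs: float, data: np.ndarray) -> Path:
    """Write float32 WAV; channels are the first axis of 2-D input."""
    path = Path(path)
    x = np.asarray(data, dtype=np.float32)
    if x.ndim == 2:
        x = x.T  # scipy expects (samples, channels)
    wavfile.write(path, int(round(fs)), x)
    return path


def read_wav(path) -> tuple[float, np.ndarray]:
    """Read WAV as float64, channels on the first axis."""
    fs, x = wavfile.read(Path(path))
    x = np.asarray(x)
    if x.dtype.kind == "i":
        x = x / float(np.iinfo(x.dtype).max)
    x = x.astype(float)
    if x.ndim == 2:
        x = x.T
    return float(fs), x


def write_sidecar(path, meta: dict) -> Path:
    path = Path(path).with_suffix(".json")
    path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=_coerce))
    return path


def read_sidecar(path) -> dict:
    return json.loads(Path(path).with_suffix(".json").read_text())


def _coerce(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
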