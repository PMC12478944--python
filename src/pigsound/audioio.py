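"""WAV input/output for mono PCM clips.

Readers normalise integer PCM to the float [-1, 1] scale the pipeline uses;
writers are the inverse up to quantisation.  Resampling is out of scope: a
file whose rate differs from the expected one is an error, never silently
converted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .preprocess import Waveform

__all__ = ["read_wav", "write_wav"]

_INT_SCALES = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def read_wav(path: str | Path, expected_rate: int | None = 8000) -> Waveform:
    """Read a mono PCM/float WAV file as a [-1, 1] float waveform.

    ``expected_rate=None`` accepts any rate; otherwise a mismatch is an
    error naming both rates (no silent resampling).
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if expected_rate is not None and rate != expected_rate:
        raise ValueError(
            f"{path}: sample rate {rate} Hz, expected {expected_rate} Hz "
            "(resampling is not performed)"
        )
    if data.dtype in _INT_SCALES:
        samples = data.astype(np.float64) / _INT_SCALES[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    return Waveform(samples=samples, rate=int(rate))


def write_wav(path: str | Path, w: Waveform, subtype: str = "float") -> None:
    """Write a waveform as 32-bit float (default) or 16-bit PCM WAV."""
    if subtype == "float":
        wavfile.write(str(path), w.rate, w.samples.astype(np.float32))
    elif subtype == "int16":
        clipped = np.clip(w.samples, -1.0, 1.0 - 2.0**-15)
        wavfile.write(str(path), w.rate, np.round(clipped * 2**15).astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV subtype {subtype!r}")
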