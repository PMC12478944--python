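"""Waveform preprocessing: activity gating, framing, and endpoint detection.

The recognition pipeline operates on short (nominally 1 s, 8 kHz) mono clips.
Before any feature is computed a clip must pass an absolute energy gate that
rejects quiet pen background; the surviving clip is denoised, then a
double-threshold voice-activity detector locates the start and end frame of
the vocalisation using short-time energy and zero-crossing rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Waveform",
    "FrameMatrix",
    "EndpointResult",
    "compute_energy",
    "activity_gate",
    "hamming_window",
    "frame_signal",
    "short_time_energy",
    "zero_crossing_rate",
    "detect_endpoints",
]

DEFAULT_RATE = 8000
DEFAULT_FRAME_LENGTH = 256  # 32 ms at 8 kHz
DEFAULT_FRAME_SHIFT = 128  # 50% overlap
DEFAULT_ENERGY_THRESHOLD = 40.0


@dataclass(frozen=True)
class Waveform:
    """Mono audio samples on the dimensionless PCM scale (nominally [-1, 1])."""

    samples: np.ndarray
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("waveform must be a non-empty 1-D sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class FrameMatrix:
    """Overlapping windowed frames of one waveform.

    ``frames[i, n] = window[n] * x[i * shift + n]`` — each row is one frame
    after multiplication by the analysis window.
    """

    frames: np.ndarray
    frame_length: int
    shift: int
    window: np.ndarray
    rate: int = DEFAULT_RATE

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 2:
            raise ValueError("frames must be a 2-D matrix")
        if frames.shape[1] != self.frame_length:
            raise ValueError("frame length inconsistent with matrix width")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "window", np.asarray(self.window, dtype=np.float64))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class EndpointResult:
    """Start/end frame of the detected vocalisation; ``valid=False`` if none found."""

    start_frame: int = 0
    end_frame: int = 0
    valid: bool = False


def compute_energy(w: Waveform) -> float:
    """Total energy of a clip, the sum of squared samples."""
    return float(np.dot(w.samples, w.samples))


def activity_gate(w: Waveform, threshold: float = DEFAULT_ENERGY_THRESHOLD) -> bool:
    """True when clip energy reaches ``threshold`` (default 40 for 1 s at 8 kHz).

    Quiet-pen background recorded without a vocalisation stays well below the
    default threshold, while coughs and screams exceed it by an order of
    magnitude, so the gate cheaply discards inactive clips.  Energy exactly
    equal to the threshold passes.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return compute_energy(w) >= threshold


def hamming_window(length: int) -> np.ndarray:
    """Hamming window ``0.54 - 0.46 cos(2 pi n / (L - 1))``, n = 0..L-1."""
    if length < 1:
        raise ValueError(f"window length must be >= 1, got {length}")
    if length == 1:
        return np.array([0.08])
    n = np.arange(length)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (length - 1))


def frame_signal(
    w: Waveform,
    frame_length: int = DEFAULT_FRAME_LENGTH,
    shift: int = DEFAULT_FRAME_SHIFT,
    window: np.ndarray | None = None,
) -> FrameMatrix:
    """Slice a waveform into overlapping frames and apply an analysis window.

    Frame ``i`` covers samples ``i*shift .. i*shift + L - 1``; a trailing
    partial frame is dropped.  ``window=None`` selects the Hamming window.
    """
    x = w.samples
    if frame_length > x.size:
        raise ValueError(
            f"signal ({x.size} samples) shorter than frame length {frame_length}"
        )
    if not 1 <= shift <= frame_length:
        raise ValueError("frame shift must satisfy 1 <= shift <= frame_length")
    if window is None:
        window = hamming_window(frame_length)
    window = np.asarray(window, dtype=np.float64)
    if window.size != frame_length:
        raise ValueError("window length must equal frame length")
    n_frames = (x.size - frame_length) // shift + 1
    idx = np.arange(frame_length)[None, :] + shift * np.arange(n_frames)[:, None]
    return FrameMatrix(
        frames=x[idx] * window[None, :],
        frame_length=frame_length,
        shift=shift,
        window=window,
        rate=w.rate,
    )


def short_time_energy(fm: FrameMatrix) -> np.ndarray:
    """Per-frame energy ``E_i = sum_n y_i(n)^2``."""
    return np.einsum("ij,ij->i", fm.frames, fm.frames)


def zero_crossing_rate(fm: FrameMatrix) -> np.ndarray:
    """Per-frame sign-change count.

    Uses the convention sgn(y) = +1 for y >= 0 and -1 otherwise, counting
    changes between adjacent samples within each frame (0 <= Z_i <= L-1).
    """
    sign = np.where(fm.frames >= 0.0, 1.0, -1.0)
    return 0.5 * np.sum(np.abs(np.diff(sign, axis=1)), axis=1)


def detect_endpoints(
    energy: np.ndarray,
    zcr: np.ndarray,
    high_energy: float,
    low_energy: float,
    zcr_thresh: float,
    min_voiced_frames: int = 3,
) -> EndpointResult:
    """Double-threshold endpoint detection over frame energy and ZCR.

    A candidate vocalisation is the earliest run of at least
    ``min_voiced_frames`` consecutive frames whose energy reaches
    ``high_energy``.  Its start is extended backward (and end forward) while
    the neighbouring frame keeps energy above ``low_energy`` or ZCR above
    ``zcr_thresh``, capturing low-energy onsets and fricative-like tails.
    """
    energy = np.asarray(energy, dtype=np.float64)
    zcr = np.asarray(zcr, dtype=np.float64)
    if energy.shape != zcr.shape or energy.ndim != 1:
        raise ValueError("energy and zcr must be 1-D vectors of equal length")
    if not high_energy >= low_energy >= 0:
        raise ValueError("thresholds must satisfy high_energy >= low_energy >= 0")

    above = energy >= high_energy
    n = energy.size
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_voiced_frames:
                start, end = i, j
                while start > 0 and (
                    energy[start - 1] > low_energy or zcr[start - 1] > zcr_thresh
                ):
                    start -= 1
                while end < n - 1 and (
                    energy[end + 1] > low_energy or zcr[end + 1] > zcr_thresh
                ):
                    end += 1
                return EndpointResult(start_frame=start, end_frame=end, valid=True)
            i = j + 1
        else:
            i += 1
    return EndpointResult(valid=False)


def default_endpoint_thresholds(
    energy: np.ndarray,
    zcr: np.ndarray,
    high_frac: float = 0.25,
    low_frac: float = 0.05,
    zcr_factor: float = 1.5,
    n_noise_frames: int = 5,
) -> tuple[float, float, float]:
    """Adaptive thresholds for :func:`detect_endpoints`.

    Energy thresholds are fractions of the maximum frame energy; the ZCR
    threshold is a multiple of the mean ZCR over the leading frames, taken
    as a background estimate.
    """
    e_max = float(np.max(energy))
    zcr_ref = float(np.mean(zcr[: max(1, n_noise_frames)]))
    return high_frac * e_max, low_frac * e_max, zcr_factor * zcr_ref
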