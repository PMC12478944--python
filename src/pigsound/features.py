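"""MFCC and first-order differential MFCC feature extraction.

Each valid frame is summarised by 12 mel-frequency cepstral coefficients
(static spectral envelope on a perceptual frequency scale) concatenated with
their first-order temporal difference (12 ΔMFCC), giving the 24-dimensional
instance vectors consumed by the SVDD classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import denoise as dn
from . import preprocess as pp

__all__ = [
    "MelFilterBank",
    "FeatureMatrix",
    "mel_from_hz",
    "hz_from_mel",
    "build_mel_filterbank",
    "mfcc",
    "delta",
    "extract_features",
    "InactiveClip",
]

LOG_FLOOR = 1e-10  # filterbank energies are clamped here before the log


class InactiveClip(Exception):
    """Raised when a clip fails the activity gate: no vocalisation to analyse."""


@dataclass(frozen=True)
class MelFilterBank:
    """Triangular filters equally spaced on the mel axis, given as FFT-bin weights."""

    weights: np.ndarray  # [M, K]
    band_edges: np.ndarray  # M + 2 FFT bin indices f(m)
    rate: int
    fft_size: int

    @property
    def n_filters(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-frame feature vectors: n_mfcc static + n_mfcc delta coefficients."""

    vectors: np.ndarray  # [f_n, 2 * n_mfcc]
    n_mfcc: int = 12

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 * self.n_mfcc:
            raise ValueError("feature matrix width must equal 2 * n_mfcc")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature matrix contains non-finite values")
        object.__setattr__(self, "vectors", v)


def mel_from_hz(f: float | np.ndarray) -> float | np.ndarray:
    """Mel scale: ``2595 * log10(1 + f / 700)``."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = 2595.0 * np.log10(1.0 + f / 700.0)
    return float(out) if out.ndim == 0 else out


def hz_from_mel(m: float | np.ndarray) -> float | np.ndarray:
    out = 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


def build_mel_filterbank(
    n_filters: int = 24,
    fft_size: int = 256,
    rate: int = 8000,
    f_low: float = 0.0,
    f_high: float | None = None,
) -> MelFilterBank:
    """Triangular mel filterbank over the one-sided FFT bins.

    The M + 2 band edges are equally spaced in mel between ``f_low`` and
    ``f_high`` (default Nyquist) and rounded down to FFT bins; filter m rises
    linearly from edge m-1 to a unit peak at edge m and falls to edge m+1.
    """
    if n_filters < 2:
        raise ValueError("need at least 2 mel filters")
    if f_high is None:
        f_high = rate / 2.0
    if not 0 <= f_low < f_high <= rate / 2.0:
        raise ValueError("band must satisfy 0 <= f_low < f_high <= rate/2")
    n_bins = fft_size // 2 + 1
    mel_edges = np.linspace(mel_from_hz(f_low), mel_from_hz(f_high), n_filters + 2)
    hz_edges = hz_from_mel(mel_edges)
    bin_edges = np.floor((fft_size + 1) * hz_edges / rate).astype(int)
    bin_edges = np.minimum(bin_edges, n_bins - 1)
    if np.any(np.diff(bin_edges[1:]) < 1):
        raise ValueError(
            "mel band too narrow for the FFT resolution: filter edges collide"
        )
    weights = np.zeros((n_filters, n_bins))
    k = np.arange(n_bins)
    for m in range(1, n_filters + 1):
        lo, mid, hi = bin_edges[m - 1], bin_edges[m], bin_edges[m + 1]
        rising = (k >= lo) & (k < mid)
        falling = (k >= mid) & (k < hi)
        weights[m - 1, rising] = (k[rising] - lo) / (mid - lo)
        weights[m - 1, falling] = (hi - k[falling]) / (hi - mid)
        weights[m - 1, mid] = 1.0
    return MelFilterBank(weights=weights, band_edges=bin_edges, rate=rate, fft_size=fft_size)


def mfcc(
    fm: pp.FrameMatrix,
    bank: MelFilterBank,
    n_coeff: int = 12,
    fft_size: int | None = None,
) -> np.ndarray:
    """Static cepstral coefficients per frame.

    Power spectrum -> mel filterbank energies -> log (clamped at a small
    floor so silent frames stay finite) -> DCT, keeping coefficients
    1..n_coeff.  The 0th coefficient (overall log energy) is discarded.
    """
    if n_coeff > bank.n_filters:
        raise ValueError("cannot keep more cepstral coefficients than mel filters")
    spec = dn.stft(fm, fft_size or bank.fft_size)
    mel_energy = spec.power @ bank.weights.T
    log_energy = np.log(np.maximum(mel_energy, LOG_FLOOR))
    return dct_cepstrum(log_energy, n_coeff)


def dct_cepstrum(log_energy: np.ndarray, n_coeff: int) -> np.ndarray:
    """Unnormalised DCT-II of each row, coefficients n = 1..n_coeff."""
    m_count = log_energy.shape[1]
    m = np.arange(m_count)
    n = np.arange(1, n_coeff + 1)
    basis = np.cos(np.pi * np.outer(n, 2 * m + 1) / (2.0 * m_count))  # [n_coeff, M]
    return log_energy @ basis.T


def delta(coeffs: np.ndarray) -> np.ndarray:
    """First-order temporal difference; the first frame's delta is zero."""
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.ndim != 2 or coeffs.shape[0] < 1:
        raise ValueError("need a [frames x coeffs] matrix with >= 1 frame")
    out = np.zeros_like(coeffs)
    out[1:] = np.diff(coeffs, axis=0)
    return out


def delta_regression(coeffs: np.ndarray, width: int = 2) -> np.ndarray:
    """Regression-style delta over +-width frames (alternative to plain difference)."""
    coeffs = np.asarray(coeffs, dtype=np.float64)
    padded = np.pad(coeffs, ((width, width), (0, 0)), mode="edge")
    # sum_t t * c[i+t] / (2 * sum_t t^2)
    denom = 2.0 * sum(t * t for t in range(1, width + 1))
    num = np.zeros_like(coeffs)
    for t in range(1, width + 1):
        num += t * (padded[width + t : width + t + coeffs.shape[0]] -
                    padded[width - t : width - t + coeffs.shape[0]])
    return num / denom


def extract_features(
    w: pp.Waveform,
    config=None,
) -> FeatureMatrix:
    """Run the full front end on one clip and return its 24-D frame vectors.

    Pipeline order: activity gate -> denoise -> endpoint detection on the
    denoised signal -> re-frame the valid segment -> 12 MFCC + 12 ΔMFCC.
    Raises :class:`InactiveClip` when the gate rejects the clip, which is a
    routine outcome for quiet background, not an error.
    """
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    p = cfg.preprocess
    if not pp.activity_gate(w, p.energy_threshold):
        raise InactiveClip(
            f"clip energy {pp.compute_energy(w):.1f} below threshold {p.energy_threshold}"
        )
    clean = dn.denoise_waveform(
        w, cfg.denoise.params(), p.frame_length, p.frame_shift, cfg.denoise.fft_size
    )
    window = pp.hamming_window(p.frame_length)
    fm = pp.frame_signal(clean, p.frame_length, p.frame_shift, window)
    energy = pp.short_time_energy(fm)
    zcr = pp.zero_crossing_rate(fm)
    high, low, zthr = pp.default_endpoint_thresholds(
        energy, zcr, p.endpoint.high_frac, p.endpoint.low_frac, p.endpoint.zcr_factor
    )
    ep = pp.detect_endpoints(energy, zcr, high, low, zthr, p.endpoint.min_frames)
    if ep.valid:
        s0 = ep.start_frame * p.frame_shift
        s1 = min(len(clean), ep.end_frame * p.frame_shift + p.frame_length)
        segment = pp.Waveform(clean.samples[s0:s1], clean.rate)
    else:
        segment = clean
    if len(segment) < p.frame_length:
        segment = clean
    seg_frames = pp.frame_signal(segment, p.frame_length, p.frame_shift, window)
    f = cfg.features
    bank = build_mel_filterbank(
        f.n_mels, cfg.denoise.fft_size or p.frame_length, w.rate, f.f_low, f.f_high
    )
    static = mfcc(seg_frames, bank, f.n_mfcc)
    d = delta_regression(static) if f.delta_mode == "regression" else delta(static)
    return FeatureMatrix(vectors=np.hstack([static, d]), n_mfcc=f.n_mfcc)
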