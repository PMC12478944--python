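"""Improved spectral subtraction with IMCRA noise tracking.

Pen recordings are short (~1 s), so there is no reliable leading noise-only
segment to profile the blower hum from.  Instead the noise power spectrum is
tracked continuously by minima-controlled recursive averaging (IMCRA): the
noisy power in each bin is recursively smoothed with a time-varying factor
that freezes the update wherever a vocalisation is probably present, and the
result is bias-compensated.  The tracked noise floor is then removed by
over-subtraction with a spectral floor (to suppress musical noise) and the
clip is resynthesised by weighted overlap-add using the noisy phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d

from .preprocess import FrameMatrix, Waveform, frame_signal, hamming_window

__all__ = [
    "SpectrumMatrix",
    "NoiseSpectrumEstimate",
    "SubtractionParams",
    "stft",
    "imcra_noise_estimate",
    "spectral_subtract",
    "reconstruct",
    "denoise_waveform",
]


@dataclass(frozen=True)
class SpectrumMatrix:
    """One-sided STFT of a frame matrix: complex spectra plus power and phase."""

    complex_spectra: np.ndarray  # [f_n, K]
    fft_size: int
    shift: int
    window: np.ndarray
    rate: int

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.complex_spectra) ** 2

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.complex_spectra)

    @property
    def n_bins(self) -> int:
        return self.complex_spectra.shape[1]


@dataclass(frozen=True)
class NoiseSpectrumEstimate:
    """IMCRA output: per frame/bin noise power and sound-presence probability."""

    lambda_hat: np.ndarray  # bias-compensated noise power [f_n, K]
    p_speech: np.ndarray  # conditional sound-presence probability [f_n, K]

    def __post_init__(self) -> None:
        if np.any(self.lambda_hat < 0):
            raise ValueError("noise power estimate must be non-negative")


@dataclass(frozen=True)
class SubtractionParams:
    """Tunables of the subtraction rule and the IMCRA recursion.

    alpha       over-subtraction factor (>= 1); how aggressively the noise
                estimate is removed.
    beta        spectral floor gain in (0, 1); residual noise level kept in
                bins that would otherwise go negative, against musical noise.
    epsilon     bias compensation on the recursively averaged noise (>= 1).
    alpha_d     base smoothing constant of the noise recursion in (0, 1).
    min_track_window   sliding-minimum length (frames) of the minima tracker.
    snr_threshold      a-posteriori ratio above which a bin is flagged active.
    p_smooth    recursive smoothing factor of the raw presence decision.
    """

    alpha: float = 2.0
    beta: float = 0.01
    epsilon: float = 1.47
    alpha_d: float = 0.85
    min_track_window: int = 40
    snr_threshold: float = 5.0
    p_smooth: float = 0.9

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError("over-subtraction factor alpha must be >= 1")
        if not 0 < self.beta < 1:
            raise ValueError("spectral floor beta must lie in (0, 1)")
        if self.epsilon < 1:
            raise ValueError("bias compensation epsilon must be >= 1")
        if not 0 < self.alpha_d < 1:
            raise ValueError("smoothing parameter alpha_d must lie in (0, 1)")


def stft(fm: FrameMatrix, fft_size: int | None = None) -> SpectrumMatrix:
    """One-sided FFT of each (already windowed) frame."""
    if fft_size is None:
        fft_size = fm.frame_length
    if fft_size < fm.frame_length:
        raise ValueError("fft_size must be >= frame length")
    if fft_size & (fft_size - 1):
        raise ValueError("fft_size must be a power of two")
    spectra = np.fft.rfft(fm.frames, n=fft_size, axis=1)
    return SpectrumMatrix(
        complex_spectra=spectra,
        fft_size=fft_size,
        shift=fm.shift,
        window=fm.window,
        rate=fm.rate,
    )


def _sound_presence_probability(power: np.ndarray, params: SubtractionParams) -> np.ndarray:
    """Per frame/bin probability that a vocalisation is present.

    Two-stage minima tracking: the noisy power is smoothed in frequency then
    in time; a causal sliding minimum of the smoothed power serves as a local
    noise floor, and bins whose smoothed power exceeds ``snr_threshold``
    times that floor are flagged active.  The binary flag is recursively
    smoothed into a soft probability.
    """
    n_frames = power.shape[0]
    # frequency smoothing (3-bin moving average), then first-order time smoothing
    s_freq = uniform_filter1d(power, size=3, axis=1, mode="nearest")
    smoothed = np.empty_like(s_freq)
    smoothed[0] = s_freq[0]
    a_s = params.p_smooth
    for l in range(1, n_frames):
        smoothed[l] = a_s * smoothed[l - 1] + (1.0 - a_s) * s_freq[l]
    # causal running minimum over the tracking window
    win = min(params.min_track_window, n_frames)
    s_min = minimum_filter1d(smoothed, size=win, axis=0, mode="nearest", origin=(win - 1) // 2)
    ratio = smoothed / np.maximum(s_min, np.finfo(np.float64).tiny)
    raw = (ratio > params.snr_threshold).astype(np.float64)
    # asymmetric smoothing: presence must engage immediately at a burst onset
    # (or the recursion would absorb the vocalisation into the noise floor)
    # but releases slowly, acting as a hangover after the burst
    p = np.empty_like(raw)
    p[0] = raw[0]
    for l in range(1, n_frames):
        p[l] = np.maximum(raw[l], a_s * p[l - 1] + (1.0 - a_s) * raw[l])
    return p


def imcra_noise_estimate(
    power: np.ndarray,
    params: SubtractionParams | None = None,
    p_speech: np.ndarray | None = None,
    n_init_frames: int = 5,
) -> NoiseSpectrumEstimate:
    """Track the noise power spectrum by minima-controlled recursive averaging.

    Per frame and bin the smoothing factor is raised toward 1 wherever sound
    is probably present, so the recursion
    ``lam(l+1) = a_hat * lam(l) + (1 - a_hat) * |Y(l)|^2`` averages the noisy
    power only over noise-dominated stretches; the result is multiplied by
    the bias-compensation factor ``epsilon``.

    ``p_speech`` may be supplied to override the built-in presence estimate
    (used by unit tests to pin the recursion's fixed points).
    """
    power = np.asarray(power, dtype=np.float64)
    if power.ndim != 2 or power.shape[0] < 2:
        raise ValueError("power must be a [frames x bins] matrix with >= 2 frames")
    if np.any(power < 0):
        raise ValueError("power spectrum entries must be non-negative")
    if params is None:
        params = SubtractionParams()
    if p_speech is None:
        p_speech = _sound_presence_probability(power, params)
    p_speech = np.broadcast_to(np.asarray(p_speech, dtype=np.float64), power.shape)

    n_frames = power.shape[0]
    lam = np.empty_like(power)
    # seed the recursion from the leading frames: the best noise proxy a 1 s
    # clip offers before any presence information accumulates
    lam_prev = power[: min(n_init_frames, n_frames)].mean(axis=0)
    a_hat = params.alpha_d + (1.0 - params.alpha_d) * p_speech
    for l in range(n_frames):
        lam_prev = a_hat[l] * lam_prev + (1.0 - a_hat[l]) * power[l]
        lam[l] = lam_prev
    return NoiseSpectrumEstimate(lambda_hat=params.epsilon * lam, p_speech=np.array(p_speech))


def spectral_subtract(
    power: np.ndarray,
    noise: NoiseSpectrumEstimate,
    params: SubtractionParams | None = None,
) -> np.ndarray:
    """Over-subtraction with spectral floor.

    Bins with enough signal get ``|Y|^2 - alpha * lam_hat``; the rest are
    clamped to the floor ``beta * lam_hat`` rather than zero, which breaks up
    the isolated tonal residues ("musical noise") of plain subtraction.
    """
    if params is None:
        params = SubtractionParams()
    power = np.asarray(power, dtype=np.float64)
    lam = noise.lambda_hat
    if power.shape != lam.shape:
        raise ValueError(
            f"power {power.shape} and noise estimate {lam.shape} shapes differ"
        )
    sub = power - params.alpha * lam
    return np.where(power >= params.alpha * lam, sub, params.beta * lam)


def reconstruct(
    clean_power: np.ndarray,
    phase: np.ndarray,
    shift: int,
    window: np.ndarray,
    n_samples: int | None = None,
    rate: int = 8000,
) -> Waveform:
    """Weighted overlap-add resynthesis from modified power and noisy phase.

    Frames are inverted individually and summed at the analysis hop; the sum
    is normalised by the accumulated analysis-window amplitude so that an
    identity filter reproduces the interior of the input exactly.
    """
    clean_power = np.asarray(clean_power, dtype=np.float64)
    phase = np.asarray(phase, dtype=np.float64)
    if clean_power.shape != phase.shape or clean_power.ndim != 2:
        raise ValueError("clean power and phase must be matching 2-D matrices")
    window = np.asarray(window, dtype=np.float64)
    n_frames, n_bins = clean_power.shape
    fft_size = 2 * (n_bins - 1)
    if window.size > fft_size:
        raise ValueError("window longer than FFT size")

    spectra = np.sqrt(np.maximum(clean_power, 0.0)) * np.exp(1j * phase)
    frames = np.fft.irfft(spectra, n=fft_size, axis=1)[:, : window.size]

    total = (n_frames - 1) * shift + window.size
    out = np.zeros(total)
    norm = np.zeros(total)
    for i in range(n_frames):
        sl = slice(i * shift, i * shift + window.size)
        out[sl] += frames[i]
        norm[sl] += window
    out /= np.maximum(norm, 1e-12)
    if n_samples is not None:
        if n_samples <= total:
            out = out[:n_samples]
        else:  # trailing partial analysis frame was dropped; keep length with silence
            out = np.concatenate([out, np.zeros(n_samples - total)])
    return Waveform(samples=out, rate=rate)


def denoise_waveform(
    w: Waveform,
    params: SubtractionParams | None = None,
    frame_length: int = 256,
    shift: int = 128,
    fft_size: int | None = None,
) -> Waveform:
    """Full chain: frame -> STFT -> IMCRA -> subtract -> overlap-add."""
    if params is None:
        params = SubtractionParams()
    fm = frame_signal(w, frame_length, shift, hamming_window(frame_length))
    spec = stft(fm, fft_size)
    noise = imcra_noise_estimate(spec.power, params)
    clean = spectral_subtract(spec.power, noise, params)
    return reconstruct(clean, spec.phase, shift, fm.window, n_samples=len(w), rate=w.rate)
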