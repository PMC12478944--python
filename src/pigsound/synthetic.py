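"""Synthetic fixtures: labelled clips and feature sets with the structure the
recogniser assumes.

Real pen recordings are not redistributable, so every stage is exercised on
generated audio instead: short band-limited noise bursts whose spectral
envelopes separate the way cough and scream spectrograms do (cough-like
energy concentrated low, scream-like high), embedded in stationary additive
background noise at a controlled SNR.  A feature-space generator (Gaussian
clusters in 24-D) supports fast classifier experiments, and a label-error
injector reproduces the tag-error contamination protocol.

None of this claims bioacoustic realism; it reproduces the statistical
premises of the method — discriminable spectra, stationary noise, bounded
burst support — so that pipeline behaviour on it is interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .preprocess import Waveform

__all__ = [
    "BurstSpec",
    "NoiseSpec",
    "COUGH_LIKE",
    "SCREAM_LIKE",
    "OTHER",
    "gen_clip",
    "gen_silence_clip",
    "gen_feature_set",
    "inject_label_errors",
]

RATE = 8000
CLIP_SECONDS = 1.0
FRAME_LENGTH = 256
FRAME_SHIFT = 128


@dataclass(frozen=True)
class BurstSpec:
    """Spectral/temporal shape of one synthetic vocalisation class."""

    class_name: str
    center_freq_range: tuple = (300.0, 800.0)  # Hz, burst carrier band centre
    bandwidth: float = 400.0  # Hz
    duration_range: tuple = (200.0, 400.0)  # ms
    attack_ms: float = 10.0
    decay_ms: float = 40.0
    rms: float = 0.3  # target RMS over the burst support
    tonal: bool = False  # pure-tone carrier instead of filtered noise

    def __post_init__(self) -> None:
        if self.center_freq_range[1] >= RATE / 2:
            raise ValueError("burst centre exceeds the Nyquist frequency")
        if self.duration_range[0] < 2 * FRAME_LENGTH / RATE * 1000:
            raise ValueError("burst shorter than two frame lengths")


@dataclass(frozen=True)
class NoiseSpec:
    """Stationary additive background: blower-like hum or broadband noise."""

    kind: str = "white"  # white | pink | fan_hum
    snr_db: float = 15.0

    def __post_init__(self) -> None:
        if self.kind not in ("white", "pink", "fan_hum"):
            raise ValueError(f"unknown noise kind {self.kind!r}")


COUGH_LIKE = BurstSpec(
    class_name="cough",
    center_freq_range=(300.0, 800.0),
    bandwidth=400.0,
    duration_range=(200.0, 400.0),
    attack_ms=8.0,
    decay_ms=40.0,
)
SCREAM_LIKE = BurstSpec(
    class_name="scream",
    center_freq_range=(1500.0, 3500.0),
    bandwidth=500.0,
    duration_range=(300.0, 600.0),
    attack_ms=20.0,
    decay_ms=60.0,
)
# distractor pool: sounds in the pen that are neither cough nor scream.
# Near-flat broadband events (gate clangs, feeder rattle) and tonal/harmonic
# events (blower squeal, voice-like phonation) — spectrally distinct from
# both band-limited burst classes.
OTHER_BROADBAND = BurstSpec(
    class_name="other",
    center_freq_range=(1500.0, 2500.0),
    bandwidth=3800.0,  # clipped to the usable band: essentially flat
    duration_range=(250.0, 500.0),
    attack_ms=15.0,
    decay_ms=50.0,
)
OTHER_TONAL = BurstSpec(
    class_name="other",
    center_freq_range=(300.0, 3200.0),
    bandwidth=100.0,
    duration_range=(250.0, 500.0),
    attack_ms=15.0,
    decay_ms=50.0,
    tonal=True,
)
OTHER = OTHER_BROADBAND
OTHER_VARIANTS = (OTHER_BROADBAND, OTHER_TONAL)

AMBIENT_RMS = 0.05  # quiet-pen background level; 1 s at this RMS stays under the gate


def _background(n: int, kind: str, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS stationary background noise of the requested colour."""
    if kind == "white":
        noise = rng.standard_normal(n)
    elif kind == "pink":
        spec = np.fft.rfft(rng.standard_normal(n))
        f = np.fft.rfftfreq(n, 1.0 / RATE)
        spec[1:] /= np.sqrt(f[1:])
        spec[0] = 0.0
        noise = np.fft.irfft(spec, n=n)
    else:  # fan_hum: harmonic stack plus a little broadband
        t = np.arange(n) / RATE
        noise = np.zeros(n)
        for h, a in ((100.0, 1.0), (200.0, 0.6), (300.0, 0.35)):
            noise += a * np.sin(2.0 * np.pi * h * t + rng.uniform(0, 2 * np.pi))
        noise += 0.3 * rng.standard_normal(n)
    return noise / np.sqrt(np.mean(noise**2))


def _burst(spec: BurstSpec, n_burst: int, rng: np.random.Generator) -> np.ndarray:
    """One enveloped, band-limited burst of unit RMS times ``spec.rms``."""
    f_c = rng.uniform(*spec.center_freq_range)
    if spec.tonal:
        carrier = np.sin(2.0 * np.pi * f_c * np.arange(n_burst) / RATE)
    else:
        lo = max(20.0, f_c - spec.bandwidth / 2)
        hi = min(RATE / 2 - 20.0, f_c + spec.bandwidth / 2)
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=RATE, output="sos")
        carrier = sps.sosfilt(sos, rng.standard_normal(n_burst + 200))[200:]
    env = np.ones(n_burst)
    n_att = min(n_burst // 2, int(spec.attack_ms * RATE / 1000))
    n_dec = min(n_burst - n_att, int(spec.decay_ms * RATE / 1000))
    if n_att:
        env[:n_att] = np.linspace(0.0, 1.0, n_att, endpoint=False)
    if n_dec:
        env[n_burst - n_dec :] = np.linspace(1.0, 0.0, n_dec)
    burst = carrier * env
    return burst * (spec.rms / np.sqrt(np.mean(burst**2)))


def gen_clip(
    spec: BurstSpec,
    noise: NoiseSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[Waveform, tuple[int, int]]:
    """One 1 s, 8 kHz clip: silence + enveloped burst + stationary noise.

    The noise floor is scaled to ``noise.snr_db`` relative to the burst RMS;
    ``snr_db=inf`` disables it.  Returns the waveform together with the true
    (start_frame, end_frame) of the burst under the default 256/128 framing,
    the ground truth used by the endpoint-detection experiments.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise is None:
        noise = NoiseSpec()
    n = int(RATE * CLIP_SECONDS)
    dur_ms = rng.uniform(*spec.duration_range)
    n_burst = int(dur_ms * RATE / 1000)
    if n_burst >= n:
        raise ValueError("burst duration exceeds the clip length")
    start = int(rng.integers(FRAME_LENGTH, n - n_burst - FRAME_LENGTH))
    x = np.zeros(n)
    x[start : start + n_burst] = _burst(spec, n_burst, rng)
    if np.isfinite(noise.snr_db):
        noise_rms = spec.rms * 10.0 ** (-noise.snr_db / 20.0)
        x = x + noise_rms * _background(n, noise.kind, rng)
    start_frame = int(round(start / FRAME_SHIFT))
    end_frame = int(round((start + n_burst - FRAME_LENGTH) / FRAME_SHIFT))
    end_frame = max(end_frame, start_frame)
    return Waveform(np.clip(x, -1.0, 1.0), RATE), (start_frame, end_frame)


def gen_silence_clip(
    seed: int | np.random.Generator = 0,
    kind: str = "white",
    rms: float = AMBIENT_RMS,
) -> Waveform:
    """Burst-free quiet-pen background; fails the default activity gate."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(RATE * CLIP_SECONDS)
    return Waveform(rms * _background(n, kind, rng), RATE)


def gen_feature_set(
    n_per_class: int,
    separation: float = 6.0,
    spread: float = 1.0,
    d: int = 24,
    n_classes: int = 2,
    eigen_decay: float = 0.7,
    class_spreads: tuple | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian class clusters in feature space for fast classifier tests.

    Class means sit ``separation`` apart along random orthogonal directions.
    Each class is a Gaussian whose per-dimension standard deviations decay
    geometrically (``spread * eigen_decay**(k/2)`` in dimension k): cepstral
    feature variance concentrates in the leading coefficients, and the
    decaying spectrum reproduces that low effective dimensionality.
    ``eigen_decay=1`` recovers the isotropic cloud.  ``class_spreads`` gives
    a per-class multiplier on ``spread`` (e.g. a broad, heterogeneous
    "other" class next to a compact target class).
    Returns (instances [n_classes*n x d], integer labels).
    """
    if n_per_class < 2:
        raise ValueError("need at least 2 points per class")
    if not 0 < eigen_decay <= 1:
        raise ValueError("eigen_decay must lie in (0, 1]")
    if class_spreads is None:
        class_spreads = (1.0,) * n_classes
    if len(class_spreads) != n_classes:
        raise ValueError("class_spreads must give one multiplier per class")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    basis, _ = np.linalg.qr(rng.standard_normal((d, n_classes)))
    # orthogonal directions scaled so every pair of class means is exactly
    # ``separation`` apart
    means = (separation / np.sqrt(2.0)) * basis.T
    scales = spread * eigen_decay ** (np.arange(d) / 2.0)
    xs, ys = [], []
    for c in range(n_classes):
        xs.append(means[c] + class_spreads[c] * scales * rng.standard_normal((n_per_class, d)))
        ys.append(np.full(n_per_class, c))
    return np.vstack(xs), np.concatenate(ys)


def inject_label_errors(
    labels: np.ndarray,
    fraction: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Flip exactly ``round(fraction * q)`` labels to a different class.

    Emulates human tagging errors in the training manifest.  Returns the
    corrupted labels and a boolean mask of the flipped positions for audit.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    labels = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = labels.size
    n_flip = int(round(fraction * q))
    classes = np.unique(labels)
    if n_flip and classes.size < 2:
        raise ValueError("cannot flip labels with fewer than two classes present")
    idx = rng.choice(q, size=n_flip, replace=False)
    corrupted = labels.copy()
    for i in idx:
        others = classes[classes != labels[i]]
        corrupted[i] = rng.choice(others)
    mask = np.zeros(q, dtype=bool)
    mask[idx] = True
    return corrupted, mask
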