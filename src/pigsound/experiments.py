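"""Reference experiments: label-noise robustness and the end-to-end benchmark.

These are the study protocols the package ships with, sized to run on one
CPU in minutes.  They are used by the test suite and the reproduction
script and are importable for interactive exploration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features as ft
from . import multisvdd as ms
from . import synthetic as syn
from .wsvdd import decide_batch, fit_wsvdd, median_sigma

__all__ = [
    "LabelNoiseResult",
    "label_noise_experiment",
    "endpoint_localization_experiment",
    "end_to_end_benchmark",
]

# Conditions of the tag-error robustness protocol: one compact target class
# (the abnormal sound being modelled) against a broad, heterogeneous pool of
# other sounds 2.5x as spread out, 200 training instances, and a test set of
# 100 target + 200 other held-out vectors.
NOISE_FRACTIONS = (0.0, 0.05, 0.10, 0.15, 0.20)
_TRAIN_N = 200
_TEST_OWN = 100
_TEST_OTHER = 200
_OTHER_SPREAD = 2.5
_SEPARATION = 6.0
_C_ROBUST = 0.08
_SIGMA_SCALE = 1.25  # on the median-pairwise-distance heuristic


@dataclass
class LabelNoiseResult:
    """Mean accuracies per contamination fraction for both model variants."""

    fractions: tuple
    weighted_accuracy: np.ndarray  # percent
    classical_accuracy: np.ndarray  # percent

    @property
    def gaps(self) -> np.ndarray:
        return self.weighted_accuracy - self.classical_accuracy


def _one_rep(rng: np.random.Generator, frac: float) -> tuple[float, float]:
    x, y = syn.gen_feature_set(
        max(_TRAIN_N + _TEST_OWN, _TEST_OWN + _TEST_OTHER),
        separation=_SEPARATION,
        class_spreads=(1.0, _OTHER_SPREAD),
        seed=rng,
    )
    x0, x1 = x[y == 0], x[y == 1]
    train = x0[:_TRAIN_N].copy()
    test_own, test_other = x0[_TRAIN_N : _TRAIN_N + _TEST_OWN], x1[:_TEST_OTHER]
    n_flip = int(round(frac * _TRAIN_N))
    # mislabeled entries: other-pool sounds tagged as the target class
    train[:n_flip] = x1[_TEST_OTHER : _TEST_OTHER + n_flip]

    center = train.mean(axis=0)
    scale = np.where(train.std(axis=0) > 1e-12, train.std(axis=0), 1.0)
    sigma = _SIGMA_SCALE * median_sigma((train - center) / scale)

    accs = []
    for weighted in (True, False):
        model = fit_wsvdd(train, C=_C_ROBUST, sigma=sigma, weighted=weighted)
        own_ok = np.sum(decide_batch(model, test_own) == 1)
        other_ok = np.sum(decide_batch(model, test_other) == -1)
        accs.append(100.0 * (own_ok + other_ok) / (_TEST_OWN + _TEST_OTHER))
    return accs[0], accs[1]


def label_noise_experiment(
    n_reps: int = 20,
    fractions=NOISE_FRACTIONS,
    seed: int = 0,
) -> LabelNoiseResult:
    """Tag-error robustness: weighted vs classical SVDD under contamination.

    For each contamination fraction, ``n_reps`` independent draws of the
    two-class feature world are made; a sphere is trained on the (partly
    mislabeled) target-class training set and scored on clean held-out
    target and other-pool points.  Returns mean accuracies per fraction.
    """
    w_acc = np.zeros(len(fractions))
    c_acc = np.zeros(len(fractions))
    for i, frac in enumerate(fractions):
        ws, cs = [], []
        for rep in range(n_reps):
            rng = np.random.default_rng(seed + 1000 * rep)
            w, c = _one_rep(rng, frac)
            ws.append(w)
            cs.append(c)
        w_acc[i], c_acc[i] = np.mean(ws), np.mean(cs)
    return LabelNoiseResult(tuple(fractions), w_acc, c_acc)


def endpoint_localization_experiment(
    n_clips: int = 100,
    seed: int = 0,
    tolerance_frames: int = 2,
    snr_range: tuple = (10.0, 20.0),
) -> tuple[int, int]:
    """Endpoint detection accuracy on synthetic bursts of known support.

    Generates ``n_clips`` clips (alternating burst classes) at SNRs drawn
    from ``snr_range``, runs the double-threshold detector on each, and
    counts clips whose detected start AND end both fall within
    ``tolerance_frames`` of the ground truth.  Returns (hits, n_clips).
    """
    from . import preprocess as pp

    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_clips):
        spec = syn.COUGH_LIKE if i % 2 == 0 else syn.SCREAM_LIKE
        snr = float(rng.uniform(*snr_range))
        w, (t0, t1) = syn.gen_clip(spec, syn.NoiseSpec(snr_db=snr), rng)
        fm = pp.frame_signal(w, window=pp.hamming_window(pp.DEFAULT_FRAME_LENGTH))
        energy = pp.short_time_energy(fm)
        zcr = pp.zero_crossing_rate(fm)
        high, low, zthr = pp.default_endpoint_thresholds(energy, zcr)
        ep = pp.detect_endpoints(energy, zcr, high, low, zthr)
        if ep.valid and abs(ep.start_frame - t0) <= tolerance_frames and abs(
            ep.end_frame - t1
        ) <= tolerance_frames:
            hits += 1
    return hits, n_clips


def end_to_end_benchmark(
    n_train: int = 100,
    n_test: int = 50,
    seed: int = 0,
    snr_db: float = 15.0,
    C: float = 0.02,
    sigma_scale: float = 0.35,
    config=None,
) -> dict:
    """Train on synthetic cough/scream clips, test on cough/scream/other.

    Runs the full audio pipeline (gate, denoise, endpoint, features) on
    every clip, trains the two weighted spheres on frame vectors, and
    recognises held-out clips by fusion + majority vote.  Returns clip-level
    accuracy and the metrics report.
    """
    rng = np.random.default_rng(seed)
    noise = syn.NoiseSpec(snr_db=snr_db)

    def clip_features(spec):
        while True:
            w, _ = syn.gen_clip(spec, noise, rng)
            try:
                return ft.extract_features(w, config).vectors
            except ft.InactiveClip:  # pragma: no cover - gate rejects ~never here
                continue

    def sphere(train):
        # kernel width: a fraction of the median heuristic — the median
        # pairwise distance covers the class's own diversity, while the
        # one-class boundary must stay tight enough to reject distractor
        # spectra it has never seen
        zn = (train - train.mean(axis=0)) / np.where(
            train.std(axis=0) > 1e-12, train.std(axis=0), 1.0
        )
        return fit_wsvdd(train, C=C, sigma=sigma_scale * median_sigma(zn))

    train_cough = np.vstack([clip_features(syn.COUGH_LIKE) for _ in range(n_train)])
    train_scream = np.vstack([clip_features(syn.SCREAM_LIKE) for _ in range(n_train)])
    mm = ms.MultiSVDDModel(model_cough=sphere(train_cough), model_scream=sphere(train_scream))

    truth, pred = [], []
    for spec, label in ((syn.COUGH_LIKE, "cough"), (syn.SCREAM_LIKE, "scream"), (syn.OTHER_VARIANTS, "other")):
        for k in range(n_test):
            one = spec[k % len(spec)] if isinstance(spec, tuple) else spec
            vectors = clip_features(one)
            vote, _ = ms.recognize_features(mm, vectors)
            truth.append(label)
            pred.append(vote)
    correct = sum(p == t for p, t in zip(pred, truth))
    report = ms.evaluate(pred, truth)
    return {
        "clip_accuracy": 100.0 * correct / len(truth),
        "report": report,
        "predictions": pred,
        "truth": truth,
    }
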