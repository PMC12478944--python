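"""Two-sphere recognition: decision fusion, voting, metrics, and PSO tuning.

One weighted SVDD is trained per abnormal-sound class (cough, scream).  A
test frame is presented to both spheres and the pair of ±1 decisions is
fused by a fixed lookup: inside exactly one sphere names the class, outside
both is "other", inside both is "unknown".  Clip-level labels come from a
majority vote over the clip's frames.  The penalty C and kernel width sigma
of each sphere can be tuned by global-best particle-swarm optimisation of
the negative mean 10-fold cross-validated recognition accuracy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from . import features as ft
from . import preprocess as pp
from .wsvdd import (
    ConfidenceVector,
    TrainingSet,
    WSVDDModel,
    confidences,
    decide_batch,
    subtractive_densities,
    train_wsvdd,
)

__all__ = [
    "MultiSVDDModel",
    "MetricsReport",
    "PSOConfig",
    "LABELS",
    "fuse",
    "majority_vote",
    "recognize_clip",
    "recognize_features",
    "evaluate",
    "cv_fitness",
    "pso_tune",
    "train_multi",
]

LABELS = ("cough", "scream", "other", "unknown")
_FUSION = {(1, -1): "cough", (-1, 1): "scream", (-1, -1): "other", (1, 1): "unknown"}
_VOTE_PRIORITY = {"cough": 0, "scream": 1, "other": 2, "unknown": 3}


@dataclass
class MultiSVDDModel:
    """One weighted-SVDD hypersphere per abnormal-sound class."""

    model_cough: WSVDDModel
    model_scream: WSVDDModel

    def __post_init__(self) -> None:
        if (
            self.model_cough.support_vectors.shape[1]
            != self.model_scream.support_vectors.shape[1]
        ):
            raise ValueError("the two spheres must share feature dimensionality")


@dataclass(frozen=True)
class MetricsReport:
    """Per-class confusion counts and the derived percentage metrics.

    ``precision``/``recall`` entries are None where the defining ratio is
    0/0 (no predicted / no true positives), never NaN.
    """

    classes: tuple
    counts: dict  # class -> dict(tp, tn, fp, fn)
    accuracy: dict  # class -> percent
    precision: dict  # class -> percent or None
    recall: dict  # class -> percent or None
    average_accuracy: float
    average_precision: float | None
    average_recall: float | None


@dataclass
class PSOConfig:
    """Swarm settings for the (C, sigma) search."""

    swarm_size: int = 60
    max_iter: int = 200
    c1: float = 1.5  # cognitive acceleration
    c2: float = 2.0  # social acceleration
    inertia: float = 1.0
    inertia_decay: bool = False
    n_folds: int = 10
    c_bounds: tuple = (0.01, 10.0)
    sigma_bounds: tuple = (0.1, 20.0)
    velocity_clamp: float = 0.2  # fraction of each bound range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 1:
            raise ValueError("swarm size must be >= 1")
        if self.c_bounds[0] <= 0 or self.sigma_bounds[0] <= 0:
            raise ValueError("search bounds must be positive")


def fuse(d1: int, d2: int) -> str:
    """Fuse the cough-sphere and scream-sphere decisions into one label."""
    if d1 not in (1, -1) or d2 not in (1, -1):
        raise ValueError(f"decisions must be +1 or -1, got ({d1}, {d2})")
    return _FUSION[(d1, d2)]


def majority_vote(frame_labels) -> str:
    """Most frequent frame label; the clip-level decision.

    "unknown" frames carry no information about which sphere fits and are
    excluded from the count unless every frame is unknown.  Ties resolve by
    the priority cough > scream > other > unknown, biased toward flagging
    abnormality.
    """
    labels = list(frame_labels)
    if not labels:
        raise ValueError("cannot vote over an empty label sequence")
    for lab in labels:
        if lab not in LABELS:
            raise ValueError(f"unexpected label {lab!r}")
    informative = [lab for lab in labels if lab != "unknown"]
    if not informative:
        return "unknown"
    tally = Counter(informative)
    best = max(tally.items(), key=lambda kv: (kv[1], -_VOTE_PRIORITY[kv[0]]))
    return best[0]


def recognize_features(mm: MultiSVDDModel, vectors: np.ndarray) -> tuple[str, list]:
    """Fused per-frame labels plus the clip vote for a feature matrix."""
    d1 = decide_batch(mm.model_cough, vectors)
    d2 = decide_batch(mm.model_scream, vectors)
    trace = [fuse(int(a), int(b)) for a, b in zip(d1, d2)]
    return majority_vote(trace), trace


def recognize_clip(mm: MultiSVDDModel, w: pp.Waveform, config=None) -> tuple[str, list]:
    """Full pipeline on one clip: features, two spheres, fusion, vote.

    Returns ``("inactive", [])`` when the activity gate rejects the clip —
    a distinct outcome from "other", which is an active but unrecognised
    sound.
    """
    try:
        fm = ft.extract_features(w, config)
    except ft.InactiveClip:
        return "inactive", []
    return recognize_features(mm, fm.vectors)


def evaluate(predictions, truth, classes=("cough", "scream", "other")) -> MetricsReport:
    """One-vs-rest confusion counts and percentage metrics per target class.

    Accuracy = (TP + TN) / all, Precision = TP / (TP + FP),
    Recall = TP / (TP + FN), each scaled to percent.
    """
    predictions = list(predictions)
    truth = list(truth)
    if len(predictions) != len(truth):
        raise ValueError("prediction and truth lists differ in length")
    if not predictions:
        raise ValueError("nothing to evaluate")
    counts, accuracy, precision, recall = {}, {}, {}, {}
    n = len(truth)
    for cls in classes:
        tp = sum(1 for p, t in zip(predictions, truth) if p == cls and t == cls)
        fp = sum(1 for p, t in zip(predictions, truth) if p == cls and t != cls)
        fn = sum(1 for p, t in zip(predictions, truth) if p != cls and t == cls)
        tn = n - tp - fp - fn
        counts[cls] = {"tp": tp, "tn": tn, "fp": fp, "fn": fn}
        accuracy[cls] = 100.0 * (tp + tn) / n
        precision[cls] = 100.0 * tp / (tp + fp) if tp + fp else None
        recall[cls] = 100.0 * tp / (tp + fn) if tp + fn else None
    defined_p = [v for v in precision.values() if v is not None]
    defined_r = [v for v in recall.values() if v is not None]
    return MetricsReport(
        classes=tuple(classes),
        counts=counts,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        average_accuracy=float(np.mean(list(accuracy.values()))),
        average_precision=float(np.mean(defined_p)) if defined_p else None,
        average_recall=float(np.mean(defined_r)) if defined_r else None,
    )


def _fold_indices(q: int, n_folds: int, groups: np.ndarray | None = None):
    """Deterministic k-fold partition; optional group-aware splitting keeps
    all frames of one clip in the same fold."""
    if groups is None:
        kf = KFold(n_splits=n_folds, shuffle=False)
        return list(kf.split(np.arange(q)))
    uniq = np.unique(groups)
    kf = KFold(n_splits=n_folds, shuffle=False)
    folds = []
    for train_g, test_g in kf.split(uniq):
        test_mask = np.isin(groups, uniq[test_g])
        folds.append((np.where(~test_mask)[0], np.where(test_mask)[0]))
    return folds


def cv_fitness(
    instances: np.ndarray,
    C: float,
    sigma: float,
    n_folds: int = 10,
    weighted: bool = True,
    groups: np.ndarray | None = None,
) -> float:
    """Negative mean held-out own-class acceptance rate under k-fold CV.

    Each fold trains a sphere on the remaining folds of the (one-class)
    training data and scores the held-out fold; a held-out point inside its
    own sphere counts as correct.  Lower is better; -1.0 is perfect.
    """
    x = np.asarray(instances, dtype=np.float64)
    if x.shape[0] < n_folds:
        raise ValueError("fewer samples than folds")
    errs = []
    for train_idx, test_idx in _fold_indices(x.shape[0], n_folds, groups):
        ts = TrainingSet(x[train_idx])
        if weighted:
            center = ts.instances.mean(axis=0)
            scale = np.where(ts.instances.std(axis=0) > 1e-12, ts.instances.std(axis=0), 1.0)
            w = confidences(subtractive_densities((ts.instances - center) / scale))
        else:
            w = ConfidenceVector.ones(ts.q)
        model = train_wsvdd(ts, w, C=C, sigma=sigma)
        inside = decide_batch(model, x[test_idx]) == 1
        errs.append(-float(np.mean(inside)))
    return float(np.mean(errs))


def pso_tune(
    instances: np.ndarray,
    cfg: PSOConfig | None = None,
    weighted: bool = True,
    groups: np.ndarray | None = None,
) -> tuple[float, float, list]:
    """Global-best PSO over (C, sigma) minimising the CV fitness.

    Standard velocity update with inertia, cognitive and social pulls;
    positions clipped to the search box, velocities clamped to a fraction of
    each range.  Fully seeded, hence bit-reproducible.  Returns the best
    (C, sigma) and the best-so-far fitness trace per iteration.
    """
    if cfg is None:
        cfg = PSOConfig()
    rng = np.random.default_rng(cfg.seed)
    lo = np.array([cfg.c_bounds[0], cfg.sigma_bounds[0]])
    hi = np.array([cfg.c_bounds[1], cfg.sigma_bounds[1]])
    span = hi - lo
    vmax = cfg.velocity_clamp * span

    pos = lo + span * rng.random((cfg.swarm_size, 2))
    vel = vmax * (2.0 * rng.random((cfg.swarm_size, 2)) - 1.0)

    def fitness(p):
        return cv_fitness(instances, p[0], p[1], cfg.n_folds, weighted, groups)

    pbest = pos.copy()
    pbest_fit = np.array([fitness(p) for p in pos])
    g = int(np.argmin(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    trace = [gbest_fit]

    for it in range(cfg.max_iter):
        w_inertia = cfg.inertia
        if cfg.inertia_decay and cfg.max_iter > 1:
            w_inertia = cfg.inertia * (1.0 - 0.5 * it / (cfg.max_iter - 1))
        r1 = rng.random((cfg.swarm_size, 2))
        r2 = rng.random((cfg.swarm_size, 2))
        vel = (
            w_inertia * vel
            + cfg.c1 * r1 * (pbest - pos)
            + cfg.c2 * r2 * (gbest - pos)
        )
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, lo, hi)
        for i in range(cfg.swarm_size):
            f = fitness(pos[i])
            if f < pbest_fit[i]:
                pbest_fit[i] = f
                pbest[i] = pos[i]
                if f < gbest_fit:
                    gbest_fit = float(f)
                    gbest = pos[i].copy()
        trace.append(gbest_fit)
    return float(gbest[0]), float(gbest[1]), trace


def train_multi(
    cough_features: np.ndarray,
    scream_features: np.ndarray,
    C: float = 1.0,
    sigma: float | None = None,
    weighted: bool = True,
) -> MultiSVDDModel:
    """Train both spheres, one per abnormal-sound class."""
    from .wsvdd import fit_wsvdd

    return MultiSVDDModel(
        model_cough=fit_wsvdd(cough_features, C=C, sigma=sigma, weighted=weighted),
        model_scream=fit_wsvdd(scream_features, C=C, sigma=sigma, weighted=weighted),
    )
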