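"""Confidence-weighted Support Vector Data Description.

Classical SVDD encloses the training class in a minimum-radius hypersphere
in RBF feature space; a single mislabeled training point can inflate that
sphere badly.  Here each training point first receives a confidence
``w_i`` in (1/2, 1] derived from its subtractive-clustering density: points
in dense regions (typical of the class) get confidence near 1, isolated
points (likely tag errors) get less.  The confidence scales the slack
penalty, so the dual box constraint becomes ``0 <= alpha_i <= C * w_i`` and
low-confidence points simply cannot buy much influence over the sphere.

The dual is the standard SVDD quadratic program

    maximize  sum_i alpha_i K(x_i, x_i) - sum_ij alpha_i alpha_j K(x_i, x_j)
    s.t.      sum_i alpha_i = 1,   0 <= alpha_i <= C * w_i

solved by a deterministic most-violating-pair SMO iteration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "TrainingSet",
    "ConfidenceVector",
    "WSVDDModel",
    "subtractive_densities",
    "confidences",
    "rbf_kernel",
    "rbf_kernel_matrix",
    "train_wsvdd",
    "fit_wsvdd",
    "decide",
    "decision_value",
    "median_sigma",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainingSet:
    """Instance matrix [q x d]; rows are per-frame feature vectors."""

    instances: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.instances, dtype=np.float64)
        if x.ndim != 2 or x.shape[0] < 2:
            raise ValueError("training set needs a [q x d] matrix with q >= 2")
        if not np.all(np.isfinite(x)):
            raise ValueError("training instances contain non-finite values")
        object.__setattr__(self, "instances", x)

    @property
    def q(self) -> int:
        return self.instances.shape[0]

    @property
    def d(self) -> int:
        return self.instances.shape[1]


@dataclass(frozen=True)
class ConfidenceVector:
    """Per-sample confidences in (0, 1], maximum 1 at the density centre."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=np.float64)
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("confidences must lie in (0, 1]")
        if not np.isclose(np.max(w), 1.0):
            raise ValueError("maximum confidence must be 1 (the density centre)")
        object.__setattr__(self, "w", w)

    @classmethod
    def ones(cls, q: int) -> "ConfidenceVector":
        return cls(np.ones(q))


@dataclass
class WSVDDModel:
    """Trained hypersphere.

    ``support_vectors`` are the training points with non-negligible dual
    coefficient, stored on the normalised scale; ``norm_stats`` holds the
    per-dimension centre/scale applied before kernel evaluation.  ``offset``
    caches the constant sum_ij alpha_i alpha_j K(x_i, x_j) appearing in the
    decision function; the sphere centre itself lives only in feature space
    and is never materialised.
    """

    support_vectors: np.ndarray
    alphas: np.ndarray
    r_squared: float
    sigma: float
    C: float
    offset: float
    norm_center: np.ndarray
    norm_scale: np.ndarray
    confidences: np.ndarray | None = None

    @property
    def n_sv(self) -> int:
        return self.support_vectors.shape[0]

    def normalize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.norm_center) / self.norm_scale

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "support_vectors": self.support_vectors.tolist(),
            "alphas": self.alphas.tolist(),
            "r_squared": self.r_squared,
            "sigma": self.sigma,
            "C": self.C,
            "offset": self.offset,
            "norm_center": self.norm_center.tolist(),
            "norm_scale": self.norm_scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "WSVDDModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        return cls(
            support_vectors=np.asarray(payload["support_vectors"]),
            alphas=np.asarray(payload["alphas"]),
            r_squared=float(payload["r_squared"]),
            sigma=float(payload["sigma"]),
            C=float(payload["C"]),
            offset=float(payload["offset"]),
            norm_center=np.asarray(payload["norm_center"]),
            norm_scale=np.asarray(payload["norm_scale"]),
        )


def subtractive_densities(instances: np.ndarray, radius_mode: str = "min_max") -> np.ndarray:
    """Subtractive-clustering density of each training point.

    The neighbouring radius is half the smallest (over candidate centres j)
    of the largest distance from j to any point; each density sums Gaussian
    affinities ``exp(-||x_i - x_j||^2 / (r_a / 2)^2)`` over the whole set,
    so 1 <= P_i <= q with the self-term contributing exactly 1.

    ``radius_mode='max_min'`` swaps the min/max nesting, an alternative
    reading of the radius rule kept for comparison.
    """
    x = np.asarray(instances, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a [q x d] matrix with q >= 2")
    dist = squareform(pdist(x))
    if radius_mode == "min_max":
        r_a = 0.5 * float(np.min(np.max(dist, axis=0)))
    elif radius_mode == "max_min":
        off_diag = dist + np.diag(np.full(x.shape[0], np.inf))
        r_a = 0.5 * float(np.max(np.min(off_diag, axis=0)))
    else:
        raise ValueError(f"unknown radius_mode {radius_mode!r}")
    if r_a <= 0.0:
        raise ValueError(
            "degenerate neighbouring radius r_a = 0: all training points coincide"
        )
    return np.sum(np.exp(-(dist**2) / (0.5 * r_a) ** 2), axis=1)


def confidences(densities: np.ndarray) -> ConfidenceVector:
    """Map densities to confidences ``w_i = 1 / (1 + ((Pmax - P_i)/Pmax)^2)``.

    The density centre gets exactly 1; an infinitely isolated point tends to
    1/2, so even certain outliers keep half the nominal penalty weight.
    """
    p = np.asarray(densities, dtype=np.float64)
    if np.any(p <= 0):
        raise ValueError("densities must be strictly positive")
    p_max = float(np.max(p))
    return ConfidenceVector(1.0 / (1.0 + ((p_max - p) / p_max) ** 2))


def rbf_kernel(a: np.ndarray, b: np.ndarray, sigma: float) -> float:
    """Gaussian kernel ``exp(-||a - b||^2 / (2 sigma^2))``."""
    if sigma <= 0:
        raise ValueError("kernel width sigma must be positive")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("kernel arguments must have equal dimension")
    diff = a - b
    return float(np.exp(-np.dot(diff, diff) / (2.0 * sigma**2)))


def rbf_kernel_matrix(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        raise ValueError("kernel width sigma must be positive")
    return np.exp(-cdist(a, b, "sqeuclidean") / (2.0 * sigma**2))


def median_sigma(instances: np.ndarray) -> float:
    """Median-pairwise-distance heuristic for the RBF width."""
    d = pdist(np.asarray(instances, dtype=np.float64))
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("all points coincide; kernel width undefined")
    return float(np.median(d))


def _solve_dual_smo(
    kernel: np.ndarray,
    upper: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Most-violating-pair SMO for the SVDD dual.

    Maximises ``sum alpha_i K_ii - alpha' K alpha`` over the simplex slice
    ``sum alpha = 1, 0 <= alpha <= upper``.  Fully deterministic: ties in the
    pair selection resolve to the lowest index via argmax/argmin.
    """
    q = kernel.shape[0]
    if np.sum(upper) < 1.0 - 1e-12:
        raise ValueError(
            "infeasible box: sum of C * w_i is below 1; increase the penalty C"
        )
    alpha = upper / np.sum(upper)
    grad = np.diag(kernel) - 2.0 * kernel @ alpha
    for _ in range(max_iter):
        can_up = alpha < upper - 1e-14
        can_dn = alpha > 1e-14
        if not can_up.any() or not can_dn.any():
            break
        gi = np.where(can_up, grad, -np.inf)
        gj = np.where(can_dn, grad, np.inf)
        i = int(np.argmax(gi))
        j = int(np.argmin(gj))
        gap = gi[i] - gj[j]
        if gap < tol:
            break
        eta = kernel[i, i] + kernel[j, j] - 2.0 * kernel[i, j]
        step = gap / (2.0 * eta) if eta > 1e-15 else np.inf
        step = min(step, upper[i] - alpha[i], alpha[j])
        alpha[i] += step
        alpha[j] -= step
        grad -= 2.0 * step * (kernel[:, i] - kernel[:, j])
    else:
        raise RuntimeError("SMO failed to converge within the iteration budget")
    return alpha


def _radius_squared(kernel: np.ndarray, alpha: np.ndarray, upper: np.ndarray, C: float) -> float:
    """Squared radius from the unbounded support vectors.

    Every alpha strictly inside its box lies exactly on the sphere; their
    radii agree up to solver tolerance and are averaged for robustness.  If
    the solution leaves no strictly interior coefficient the average runs
    over all support vectors instead.
    """
    eps = 1e-6 * C
    offset = float(alpha @ kernel @ alpha)
    interior = (alpha > eps) & (alpha < upper - eps)
    if not interior.any():
        interior = alpha > eps
    k_term = np.diag(kernel)[interior] - 2.0 * (kernel @ alpha)[interior]
    return float(np.mean(k_term) + offset)


def train_wsvdd(
    ts: TrainingSet,
    w: ConfidenceVector | None = None,
    C: float = 1.0,
    sigma: float | None = None,
    normalize: bool = True,
) -> WSVDDModel:
    """Train a (confidence-weighted) SVDD hypersphere.

    Instances are z-scored with training statistics (RBF distances are not
    comparable across raw cepstral dimensions); ``sigma=None`` selects the
    median-pairwise-distance heuristic on the normalised data.  ``w=None``
    trains the classical unweighted model.
    """
    x = ts.instances
    q = x.shape[0]
    if w is None:
        w = ConfidenceVector.ones(q)
    if w.w.shape[0] != q:
        raise ValueError("confidence vector length must match training set size")
    if C <= 0:
        raise ValueError("penalty C must be positive")

    if normalize:
        center = x.mean(axis=0)
        scale = x.std(axis=0)
        scale = np.where(scale > 1e-12, scale, 1.0)
    else:
        center = np.zeros(x.shape[1])
        scale = np.ones(x.shape[1])
    xn = (x - center) / scale

    if sigma is None:
        sigma = median_sigma(xn)
    kernel = rbf_kernel_matrix(xn, xn, sigma)
    upper = C * w.w
    alpha = _solve_dual_smo(kernel, upper)
    r2 = _radius_squared(kernel, alpha, upper, C)

    keep = alpha > 1e-6 * C
    return WSVDDModel(
        support_vectors=xn[keep],
        alphas=alpha[keep],
        r_squared=max(r2, 0.0),
        sigma=float(sigma),
        C=float(C),
        offset=float(alpha @ kernel @ alpha),
        norm_center=center,
        norm_scale=scale,
        confidences=w.w,
    )


def fit_wsvdd(
    instances: np.ndarray,
    C: float = 1.0,
    sigma: float | None = None,
    weighted: bool = True,
    radius_mode: str = "min_max",
) -> WSVDDModel:
    """Convenience front end: densities -> confidences -> train.

    Confidences are computed on the z-scored instances so the density metric
    matches the kernel metric.  ``weighted=False`` yields classical SVDD.
    """
    ts = TrainingSet(np.asarray(instances, dtype=np.float64))
    x = ts.instances
    center = x.mean(axis=0)
    scale = np.where(x.std(axis=0) > 1e-12, x.std(axis=0), 1.0)
    if weighted:
        dens = subtractive_densities((x - center) / scale, radius_mode)
        w = confidences(dens)
    else:
        w = ConfidenceVector.ones(ts.q)
    return train_wsvdd(ts, w, C=C, sigma=sigma)


def decision_value(model: WSVDDModel, z: np.ndarray) -> float:
    """Signed decision statistic: r^2 minus the kernel distance to the centre.

    Positive values lie inside the sphere; zero is exactly on the boundary.
    """
    z = np.asarray(z, dtype=np.float64)
    if z.shape != (model.support_vectors.shape[1],):
        raise ValueError(
            f"test vector has dimension {z.shape}, model expects "
            f"({model.support_vectors.shape[1]},)"
        )
    zn = model.normalize(z)
    k = rbf_kernel_matrix(zn[None, :], model.support_vectors, model.sigma)[0]
    return model.r_squared - 1.0 + 2.0 * float(model.alphas @ k) - model.offset


# points within this margin of the boundary count as inside: the tie-breaks-
# inside convention must be robust to solver-level rounding at support vectors
BOUNDARY_TOL = 1e-9


def decide(model: WSVDDModel, z: np.ndarray) -> int:
    """+1 if ``z`` falls inside or on the trained hypersphere, else -1."""
    return 1 if decision_value(model, z) >= -BOUNDARY_TOL else -1


def decide_batch(model: WSVDDModel, z: np.ndarray) -> np.ndarray:
    """Vectorised :func:`decide` over rows of ``z``."""
    z = np.asarray(z, dtype=np.float64)
    zn = (z - model.norm_center) / model.norm_scale
    k = rbf_kernel_matrix(zn, model.support_vectors, model.sigma)
    vals = model.r_squared - 1.0 + 2.0 * (k @ model.alphas) - model.offset
    return np.where(vals >= -BOUNDARY_TOL, 1, -1)
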