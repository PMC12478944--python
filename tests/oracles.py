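"""Independent brute-force oracles used to cross-check the fast paths."""

import numpy as np
from scipy.optimize import minimize


def densities_loop(x: np.ndarray, r_a: float) -> np.ndarray:
    """O(q^2) double-loop evaluation of the subtractive-clustering densities."""
    q = x.shape[0]
    out = np.zeros(q)
    for i in range(q):
        for j in range(q):
            d2 = float(np.sum((x[i] - x[j]) ** 2))
            out[i] += np.exp(-d2 / (0.5 * r_a) ** 2)
    return out


def neighbouring_radius_loop(x: np.ndarray) -> float:
    """Half the minimum over candidate centres of the maximal distance."""
    q = x.shape[0]
    maxima = []
    for j in range(q):
        maxima.append(max(float(np.linalg.norm(x[i] - x[j])) for i in range(q)))
    return 0.5 * min(maxima)


def svdd_dual_qp(kernel: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Generic convex-QP solution of the SVDD dual via SLSQP.

    minimise a' K a - a' diag(K)  s.t.  sum(a) = 1, 0 <= a_i <= upper_i.
    """
    q = kernel.shape[0]
    diag = np.diag(kernel)

    def obj(a):
        return a @ kernel @ a - a @ diag

    def grad(a):
        return 2.0 * kernel @ a - diag

    res = minimize(
        obj,
        np.minimum(np.full(q, 1.0 / q), upper),
        jac=grad,
        bounds=[(0.0, float(u)) for u in upper],
        constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0, "jac": lambda a: np.ones(q)}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    if not res.success:
        raise RuntimeError(f"QP oracle failed: {res.message}")
    return res.x


def radius_from_alpha(kernel: np.ndarray, alpha: np.ndarray, upper: np.ndarray) -> float:
    eps = 1e-8
    interior = (alpha > eps) & (alpha < upper - eps)
    if not interior.any():
        interior = alpha > eps
    k_term = np.diag(kernel)[interior] - 2.0 * (kernel @ alpha)[interior]
    return float(np.mean(k_term) + alpha @ kernel @ alpha)
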