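"""Edge features, non-negative elastic-net selection, kernel discriminant projection.

Connectivity matrices are vectorized to their upper triangle (row-major,
i < j). Discriminative edges are selected by a non-negative elastic net —
squared loss against ±1 labels with an L1 + L2 penalty and β ≥ 0, solved by
cyclic coordinate descent — and the selected features are projected to a
one-dimensional discriminant score by a Gaussian-kernel Fisher discriminant
(kernel discriminant analysis, KDA).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "vectorize_network",
    "devectorize",
    "edge_index",
    "NonNegENetModel",
    "fit_nonneg_elastic_net",
    "KDAProjection",
    "fit_kda",
    "kda_transform",
]


# ---------------------------------------------------------------- vectorization

def edge_index(n: int) -> list:
    """Upper-triangle (i, j) pairs, i < j, row-major — the fixed edge order."""
    iu, ju = np.triu_indices(n, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def vectorize_network(C) -> np.ndarray:
    """Upper-triangle edge weights of a symmetric zero-diagonal matrix."""
    values = getattr(C, "values", C)
    values = np.asarray(values, dtype=float)
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("cannot vectorize an asymmetric matrix")
    iu, ju = np.triu_indices(values.shape[0], k=1)
    return values[iu, ju]


def devectorize(v: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_network` (symmetric, zero diagonal)."""
    v = np.asarray(v, dtype=float)
    if v.size != n * (n - 1) // 2:
        raise ValueError(f"vector length {v.size} does not match n={n}")
    C = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    C[iu, ju] = v
    C[ju, iu] = v
    return C


# ---------------------------------------------------------------- elastic net

@dataclass
class NonNegENetModel:
    """Non-negative elastic net fit: β ≥ 0 minimizing ½‖y−Fβ‖² + λ1·Σβ + ½λ2‖β‖²."""

    coef: np.ndarray
    lam1: float
    lam2: float
    intercept: float = 0.0
    n_sweeps: int = 0
    converged: bool = True
    edge_pairs: list = field(default_factory=list)

    @property
    def selected_edges(self) -> np.ndarray:
        return np.flatnonzero(self.coef > 0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "coef": self.coef.tolist(),
                "lam1": self.lam1,
                "lam2": self.lam2,
                "intercept": self.intercept,
                "n_sweeps": self.n_sweeps,
                "converged": self.converged,
                "edge_pairs": [list(p) for p in self.edge_pairs],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NonNegENetModel":
        d = json.loads(text)
        return cls(
            coef=np.array(d["coef"]),
            lam1=d["lam1"],
            lam2=d["lam2"],
            intercept=d.get("intercept", 0.0),
            n_sweeps=d["n_sweeps"],
            converged=d["converged"],
            edge_pairs=[tuple(p) for p in d["edge_pairs"]],
        )


def fit_nonneg_elastic_net(F, y, lam1: float, lam2: float,
                           max_sweeps: int = 10_000, tol: float = 1e-8,
                           fit_intercept: bool = True,
                           edge_pairs=None) -> NonNegENetModel:
    """Cyclic coordinate descent with non-negative soft-threshold updates.

    Minimizes ½‖y − β₀ − Fβ‖² + λ1·Σβ + ½λ2‖β‖² over β ≥ 0, with β₀ an
    unpenalized intercept (handled by centering; without it, non-negative
    coefficients on non-negative edge weights could never fit ±1 labels).
    Gram-matrix updates make each coordinate step O(p). Converged when the
    largest coefficient change in a sweep drops below ``tol``; a warning
    reports the final gap if the sweep cap is hit. All-zero feature columns
    get coefficient 0.
    """
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam1 < 0 or lam2 < 0:
        raise ValueError("penalties must be non-negative")
    n, p = F.shape
    if len(y) != n:
        raise ValueError("label / feature row count mismatch")

    if fit_intercept:
        F_mean = F.mean(axis=0)
        y_mean = y.mean()
        F = F - F_mean
        y = y - y_mean

    G = F.T @ F
    b = F.T @ y
    denom = np.diag(G) + lam2
    beta = np.zeros(p)
    q = np.zeros(p)  # q = G @ beta, maintained incrementally
    sweep = 0
    max_delta = np.inf
    for sweep in range(1, max_sweeps + 1):
        max_delta = 0.0
        for j in range(p):
            if denom[j] <= 0:  # all-zero column with lam2 == 0
                continue
            c = b[j] - q[j] + G[j, j] * beta[j]
            new = max(0.0, (c - lam1) / denom[j])
            delta = new - beta[j]
            if delta != 0.0:
                q += delta * G[:, j]
                beta[j] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    converged = bool(max_delta < tol)
    if not converged:
        warnings.warn(
            f"elastic net did not converge in {max_sweeps} sweeps "
            f"(last max coefficient change {max_delta:.3e})",
            stacklevel=2,
        )
    intercept = float(y_mean - F_mean @ beta) if fit_intercept else 0.0
    return NonNegENetModel(beta, lam1, lam2, intercept=intercept,
                           n_sweeps=sweep, converged=converged,
                           edge_pairs=list(edge_pairs) if edge_pairs is not None else [])


# ---------------------------------------------------------------- KDA

@dataclass
class KDAProjection:
    """Gaussian-kernel Fisher discriminant: one direction for two classes.

    Kernel K(a,b) = exp(−γ‖a−b‖²). The dual coefficients α maximize the
    kernelized Fisher ratio (αᵀMα)/(αᵀ(N+εI)α); for two classes the leading
    generalized eigenvector is α ∝ (N+εI)⁻¹(m₊ − m₋), with m_c the class
    means of kernel columns. Sign is fixed so patients score higher on
    average than controls in training.
    """

    alpha: np.ndarray
    gamma: float
    epsilon: float
    X_train: np.ndarray
    classes: tuple = (1, -1)


def _median_heuristic_gamma(F: np.ndarray) -> float:
    d2 = pdist(F, metric="sqeuclidean")
    if d2.size == 0:
        return 1.0
    med = np.median(d2)
    return 1.0 / med if med > 0 else 1.0


def fit_kda(F, labels, gamma: float | None = None,
            epsilon: float | None = None) -> KDAProjection:
    """Fit the kernel Fisher discriminant on training features.

    ``gamma`` defaults to the median heuristic (1 / median pairwise squared
    distance); ``epsilon`` to 1e-3·trace(N)/n_train. Labels are ±1 with
    patient = +1.
    """
    F = np.asarray(F, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("KDA requires exactly two classes in training data")
    if gamma is None:
        gamma = _median_heuristic_gamma(F)
    if gamma <= 0:
        raise ValueError("gamma must be positive")

    n = F.shape[0]
    K = np.exp(-gamma * cdist(F, F, metric="sqeuclidean"))
    cls_hi, cls_lo = max(classes.tolist()), min(classes.tolist())
    pos = np.flatnonzero(y == cls_hi)
    neg = np.flatnonzero(y == cls_lo)
    m_pos = K[:, pos].mean(axis=1)
    m_neg = K[:, neg].mean(axis=1)

    N = np.zeros((n, n))
    for idx in (pos, neg):
        Kc = K[:, idx]
        nc = len(idx)
        center = np.eye(nc) - np.ones((nc, nc)) / nc
        N += Kc @ center @ Kc.T
    if epsilon is None:
        epsilon = 1e-3 * np.trace(N) / n
        if epsilon <= 0:
            epsilon = 1e-6
    try:
        alpha = np.linalg.solve(N + epsilon * np.eye(n), m_pos - m_neg)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"within-class kernel system singular despite epsilon={epsilon:g}; "
            "try a larger epsilon"
        ) from exc
    norm = np.linalg.norm(alpha)
    if norm > 0:
        alpha = alpha / norm
    model = KDAProjection(alpha, gamma, epsilon, F.copy(),
                          classes=(cls_hi, cls_lo))
    scores = kda_transform(model, F)
    if scores[pos].mean() < scores[neg].mean():
        model.alpha = -model.alpha
    return model


def kda_transform(model: KDAProjection, F) -> np.ndarray:
    """Project samples to their scalar discriminant score."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    K = np.exp(-model.gamma * cdist(F, model.X_train, metric="sqeuclidean"))
    return K @ model.alpha
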