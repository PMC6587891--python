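"""First-order (Pearson), second-order (triplet), and hybrid connectivity networks.

The second-order network encodes ordinal neighbor structure. For a center
region ``i`` with time series ``x_i``, and squared-Euclidean distances
``dist(·,·)`` between region time series, the relative distance of region
``v`` with respect to neighbor ``u`` is

    S^i_{uv} = dist(x_i, x_v) − dist(x_i, x_u)

(an antisymmetric matrix in u, v). Summing over the k nearest neighbors
``N_i`` of region i gives the aggregate relative distance

    dist'(x_i, x_v) = Σ_{u ∈ N_i} S^i_{uv} = k·dist(x_i, x_v) − Σ_{u ∈ N_i} dist(x_i, x_u)

Edges are then assigned only from a center to its own neighbors — the
negated relative distances, min-max rescaled to [0, 1] over all computed
entries of the subject's matrix (larger relative distance ⇒ weaker
connectivity), zero elsewhere — and the result is symmetrized as
(C + Cᵀ)/2. The hybrid network is the convex combination
μ·C¹ + (1−μ)·C² of the Pearson network C¹ and the second-order network C².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ConnectivityMatrix",
    "NeighborSets",
    "pairwise_sq_euclidean",
    "knn_neighbors",
    "triplet_relative_sums",
    "second_order_network",
    "pearson_network",
    "hybrid_network",
    "threshold_network",
]

KINDS = ("first_order", "second_order", "hybrid")


@dataclass
class ConnectivityMatrix:
    """Symmetric zero-diagonal n×n edge-weight matrix with provenance.

    ``kind`` records how it was built; ``params`` holds k / mu / threshold
    as applicable. Second-order entries lie in [0, 1], first-order
    off-diagonals in [−1, 1], hybrid entries in [−μ, 1].
    """

    values: np.ndarray
    kind: str = "first_order"
    params: dict = field(default_factory=dict)
    region_labels: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("connectivity matrix must be square")
        if self.kind not in KINDS:
            raise ValueError(f"unknown network kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if self.region_labels is None:
            self.region_labels = [f"R{i + 1}" for i in range(n)]
        elif len(self.region_labels) != n:
            raise ValueError("region_labels length mismatch")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class NeighborSets:
    """Per-region ordered k-nearest-neighbor index lists.

    ``indices[i]`` holds the k regions nearest to i (excluding i), ordered
    by (distance, index); ties broken toward the smaller region index.
    """

    indices: np.ndarray  # n x k int array
    k: int

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        n = self.indices.shape[0]
        if self.indices.shape != (n, self.k):
            raise ValueError("neighbor index array must be n × k")
        for i in range(n):
            if i in self.indices[i]:
                raise ValueError(f"region {i} appears in its own neighbor set")


def pairwise_sq_euclidean(X) -> np.ndarray:
    """Squared Euclidean distance D[i,j] = Σ_t (X[i,t] − X[j,t])² between region rows."""
    values = getattr(X, "values", X)
    values = np.asarray(values, dtype=float)
    D = squareform(pdist(values, metric="sqeuclidean"))
    np.fill_diagonal(D, 0.0)
    return D


def knn_neighbors(D: np.ndarray, k: int) -> NeighborSets:
    """k nearest regions per row of the distance matrix, deterministic ties.

    Sorted by (distance, index) so equal distances resolve to the smaller
    region index.
    """
    n = D.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    idx = np.empty((n, k), dtype=int)
    col = np.arange(n)
    for i in range(n):
        order = np.lexsort((col, D[i]))
        order = order[order != i]
        idx[i] = order[:k]
    return NeighborSets(idx, k)


def triplet_relative_sums(D: np.ndarray, N: NeighborSets, i: int) -> np.ndarray:
    """Aggregate relative distance dist'(x_i, x_v) for every region v.

    Equals k·D[i,v] − Σ_{u∈N_i} D[i,u]: the sum over the neighbor set of the
    antisymmetric relative-distance entries S^i_{uv}.
    """
    neigh_sum = D[i, N.indices[i]].sum()
    return N.k * D[i] - neigh_sum


def second_order_network(X, k: int, region_labels=None) -> ConnectivityMatrix:
    """Triplet-based second-order network of one subject.

    Entries are assigned from each center i to its k nearest neighbors only:
    the negated aggregate relative distances, min-max normalized to [0, 1]
    over all computed entries of this subject's matrix; entries to
    non-neighbors are 0. The matrix is then symmetrized as (C + Cᵀ)/2 and
    the diagonal forced to 0. If every computed value is identical the
    normalization is degenerate — there is no ordinal information — and all
    computed entries are set to 0 with a warning.
    """
    values = getattr(X, "values", X)
    if region_labels is None:
        region_labels = getattr(X, "region_labels", None)
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    D = pairwise_sq_euclidean(values)
    N = knn_neighbors(D, k)

    raw = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        rel = triplet_relative_sums(D, N, i)
        raw[i, N.indices[i]] = -rel[N.indices[i]]
        mask[i, N.indices[i]] = True

    computed = raw[mask]
    lo, hi = computed.min(), computed.max()
    C = np.zeros((n, n))
    if hi - lo == 0:
        warnings.warn(
            "degenerate second-order normalization: all computed relative "
            "distances are equal; network set to zero",
            stacklevel=2,
        )
    else:
        C[mask] = (computed - lo) / (hi - lo)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 0.0)
    return ConnectivityMatrix(C, kind="second_order", params={"k": k},
                              region_labels=region_labels)


def pearson_network(X, region_labels=None) -> ConnectivityMatrix:
    """First-order network: Pearson correlation between region time series, zero diagonal."""
    values = getattr(X, "values", X)
    if region_labels is None:
        region_labels = getattr(X, "region_labels", None)
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        names = (
            [region_labels[b] for b in bad]
            if region_labels is not None
            else [f"R{b + 1}" for b in bad]
        )
        raise ValueError(f"constant time series (zero variance) in region(s): {names}")
    C = np.corrcoef(values)
    C = (C + C.T) / 2.0  # remove asymmetric rounding
    np.fill_diagonal(C, 0.0)
    return ConnectivityMatrix(C, kind="first_order", params={},
                              region_labels=region_labels)


def hybrid_network(C1: ConnectivityMatrix, C2: ConnectivityMatrix, mu: float) -> ConnectivityMatrix:
    """Convex fusion μ·C1 + (1−μ)·C2 of a first- and a second-order network."""
    if C1.kind != "first_order" or C2.kind != "second_order":
        raise ValueError("hybrid_network expects (first_order, second_order) inputs")
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu must be in [0, 1], got {mu}")
    if C1.values.shape != C2.values.shape:
        raise ValueError("shape mismatch between first- and second-order networks")
    if C1.region_labels != C2.region_labels:
        raise ValueError("region label mismatch between networks")
    values = mu * C1.values + (1.0 - mu) * C2.values
    params = {"mu": mu}
    if "k" in C2.params:
        params["k"] = C2.params["k"]
    return ConnectivityMatrix(values, kind="hybrid", params=params,
                              region_labels=C1.region_labels)


def threshold_network(C: ConnectivityMatrix, t: float) -> ConnectivityMatrix:
    """Zero out entries with |weight| < t (absolute value: first-order edges can be negative)."""
    if t < 0:
        raise ValueError("threshold must be non-negative")
    values = np.where(np.abs(C.values) < t, 0.0, C.values)
    params = dict(C.params)
    params["threshold"] = t
    return ConnectivityMatrix(values, kind=C.kind, params=params,
                              region_labels=C.region_labels)
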