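"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — explicit loops, full enumeration,
generic optimizers — and shares no code with hyconn's implementation paths.
"""

import numpy as np


def literal_second_order(X, k):
    """Triplet-based second-order network by literal enumeration.

    Double-loop squared distances; neighbor sets by full sort on
    (distance, index); aggregate relative distance as an explicit sum of
    relative-distance terms over the neighbor set; global min-max over the
    computed entries; explicit symmetrization.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    D = [[sum((X[i][t] - X[j][t]) ** 2 for t in range(m)) for j in range(n)]
         for i in range(n)]
    N = []
    for i in range(n):
        order = sorted((j for j in range(n) if j != i), key=lambda j: (D[i][j], j))
        N.append(order[:k])
    raw = {}
    for i in range(n):
        for j in N[i]:
            dp = 0.0
            for u in N[i]:
                s_uv = D[i][j] - D[i][u]  # relative distance of j w.r.t. neighbor u
                dp += s_uv
            raw[(i, j)] = -dp
    vals = list(raw.values())
    lo, hi = min(vals), max(vals)
    C = np.zeros((n, n))
    if hi > lo:
        for (i, j), v in raw.items():
            C[i, j] = (v - lo) / (hi - lo)
    C = (C + C.T) / 2.0
    for i in range(n):
        C[i, i] = 0.0
    return C


def pairs_auc(scores, labels, positive="patient"):
    """All-pairs concordance AUC with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def projected_gradient_enet(F, y, lam1, lam2, n_iter=200_000, tol=1e-12):
    """Projected gradient descent for the non-negative elastic net (no intercept)."""
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    p = F.shape[1]
    L = np.linalg.norm(F.T @ F, 2) + lam2 + 1e-12
    beta = np.zeros(p)
    for _ in range(n_iter):
        grad = -F.T @ (y - F @ beta) + lam1 + lam2 * beta
        new = np.maximum(0.0, beta - grad / L)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def enet_objective(F, y, beta, lam1, lam2):
    r = y - F @ beta
    return 0.5 * r @ r + lam1 * beta.sum() + 0.5 * lam2 * beta @ beta


def kda_direction_dense(F, labels, gamma, epsilon):
    """Leading generalized eigenvector of (M, N+εI) via scipy's dense solver."""
    from scipy.linalg import eigh
    from scipy.spatial.distance import cdist

    F = np.asarray(F, dtype=float)
    y = np.asarray(labels)
    K = np.exp(-gamma * cdist(F, F, metric="sqeuclidean"))
    n = len(y)
    classes = sorted(set(y.tolist()))
    m = {}
    N = np.zeros((n, n))
    for c in classes:
        idx = np.flatnonzero(y == c)
        m[c] = K[:, idx].mean(axis=1)
        Kc = K[:, idx]
        nc = len(idx)
        N += Kc @ (np.eye(nc) - np.ones((nc, nc)) / nc) @ Kc.T
    d = m[classes[1]] - m[classes[0]]
    M = np.outer(d, d)
    w, V = eigh(M, N + epsilon * np.eye(n))
    return V[:, -1]


def graph_metrics_oracle(A):
    """Degree/density/clustering/paths/efficiency/centralities via igraph + scipy.

    Assumes a connected graph. Returns a dict keyed like GraphMetricsRow.
    """
    import igraph
    from scipy.sparse.csgraph import shortest_path

    A = np.asarray(A, dtype=int)
    n = A.shape[0]
    g = igraph.Graph.Adjacency((A > 0).tolist(), mode="undirected")
    deg = np.array(g.degree(), dtype=float)
    sp = shortest_path(A, method="D", unweighted=True)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / sp
    inv[~np.isfinite(inv)] = 0.0

    # local efficiency: mean over nodes of global efficiency of the neighbor subgraph
    loc = []
    for i in range(n):
        nb = np.flatnonzero(A[i])
        if len(nb) < 2:
            loc.append(0.0)
            continue
        sub = A[np.ix_(nb, nb)]
        sps = shortest_path(sub, method="D", unweighted=True)
        offs = ~np.eye(len(nb), dtype=bool)
        with np.errstate(divide="ignore"):
            invs = 1.0 / sps
        invs[~np.isfinite(invs)] = 0.0
        loc.append(invs[offs].mean())

    mean_dist = sp.sum(axis=1) / (n - 1)
    diameter = sp.max()
    clust = g.transitivity_local_undirected(mode="zero")
    norm_pairs = (n - 1) * (n - 2) / 2.0
    node_bc = np.array(g.betweenness()) / norm_pairs
    edge_bc = np.array(g.edge_betweenness()) / (n * (n - 1) / 2.0)
    return {
        "average_degree": deg.mean(),
        "density": g.density(),
        "clustering_coefficient": float(np.mean(clust)),
        "characteristic_path_length": sp[off].mean(),
        "global_efficiency": inv[off].mean(),
        "local_efficiency": float(np.mean(loc)),
        "closeness_centrality": float(np.mean(1.0 / mean_dist)),
        "node_betweenness_centrality": float(node_bc.mean()),
        "edge_betweenness_centrality": float(edge_bc.mean()),
        "radiality": float(np.mean(diameter + 1.0 - mean_dist)),
        "assortativity": g.assortativity_degree(directed=False),
    }
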