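"""Independent brute-force oracles used by the test suite.

Deliberately written without networkx (scipy.sparse.csgraph for distances,
plain counting for everything else) so every graph metric is checked through
a second, independent route.  Small-n only.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.sparse.csgraph import shortest_path


def adjacency(nodes: list, edges: list[tuple]) -> np.ndarray:
    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v in edges:
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1.0
    return A


def path_counts(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest-path distances and path counts.

    ``sigma[s, t]`` counts distinct shortest s-t paths, by dynamic
    programming over nodes ordered by distance from s.
    """
    n = A.shape[0]
    D = shortest_path(A, method="D", unweighted=True)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(D[s])
        for t in order:
            if t == s or np.isinf(D[s, t]):
                continue
            preds = [u for u in range(n) if A[u, t] and D[s, u] == D[s, t] - 1]
            sigma[s, t] = sum(sigma[s, u] for u in preds)
    return D, sigma


def brute_node_betweenness(A: np.ndarray) -> np.ndarray:
    """Raw betweenness: fractional count of shortest paths through each node,
    over unordered pairs of distinct other nodes."""
    n = A.shape[0]
    D, sigma = path_counts(A)
    bt = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if np.isinf(D[s, t]) or sigma[s, t] == 0:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            if D[s, v] + D[v, t] == D[s, t]:
                bt[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bt


def brute_edge_betweenness(A: np.ndarray) -> dict[frozenset, float]:
    """Raw edge betweenness over unordered pairs (endpoints included)."""
    n = A.shape[0]
    D, sigma = path_counts(A)
    out: dict[frozenset, float] = {}
    edges = [(u, v) for u in range(n) for v in range(u + 1, n) if A[u, v]]
    for u, v in edges:
        total = 0.0
        for s, t in itertools.combinations(range(n), 2):
            if np.isinf(D[s, t]) or sigma[s, t] == 0:
                continue
            # paths using the edge in either direction
            for a, b in ((u, v), (v, u)):
                if D[s, a] + 1 + D[b, t] == D[s, t]:
                    total += sigma[s, a] * sigma[b, t] / sigma[s, t]
        out[frozenset((u, v))] = total
    return out


def brute_distance_metrics(A: np.ndarray) -> tuple[int, float]:
    """(diameter, characteristic path length) over connected pairs."""
    D = shortest_path(A, method="D", unweighted=True)
    n = A.shape[0]
    ds = [D[s, t] for s, t in itertools.combinations(range(n), 2) if np.isfinite(D[s, t])]
    if not ds:
        raise ValueError("no connected pairs")
    return int(max(ds)), float(np.mean(ds))


def brute_clustering(A: np.ndarray) -> tuple[float, float]:
    """(transitivity, average local clustering with degree<2 nodes as 0)."""
    n = A.shape[0]
    deg = A.sum(axis=1)
    triangles = np.trace(A @ A @ A) / 6.0
    triples = sum(d * (d - 1) / 2.0 for d in deg)
    transitivity = 3.0 * triangles / triples if triples else 0.0
    local = []
    for v in range(n):
        nbrs = np.flatnonzero(A[v])
        k = len(nbrs)
        if k < 2:
            local.append(0.0)
            continue
        links = A[np.ix_(nbrs, nbrs)].sum() / 2.0
        local.append(2.0 * links / (k * (k - 1)))
    avg = float(np.mean(local)) if n else 0.0
    return float(transitivity), avg


def brute_modularity(A: np.ndarray, communities: list[set]) -> float:
    """Newman Q of a partition, from the adjacency matrix directly."""
    m = A.sum() / 2.0
    if m == 0:
        return 0.0
    deg = A.sum(axis=1)
    q = 0.0
    for c in communities:
        c = sorted(c)
        l_c = A[np.ix_(c, c)].sum() / 2.0
        d_c = deg[c].sum()
        q += l_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def set_partitions(items: list):
    """Yield all partitions of ``items`` (Bell-number many; keep n small)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def best_modularity(A: np.ndarray) -> float:
    """Exhaustive maximum modularity over all partitions (n <= ~8)."""
    n = A.shape[0]
    best = -np.inf
    for part in set_partitions(list(range(n))):
        q = brute_modularity(A, [set(c) for c in part])
        best = max(best, q)
    return best


def random_graph(rng: np.random.Generator, n_max: int = 25, p_edge: float | None = None):
    """A random simple graph as (nodes, edges); at least one edge."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.1, 0.7)) if p_edge is None else p_edge
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    if not edges:
        i, j = rng.choice(n, size=2, replace=False)
        edges = [(nodes[min(i, j)], nodes[max(i, j)])]
    return nodes, edges


# ---------------------------------------------------------------------------
# Dense penalized-likelihood maximizer (graphical-lasso oracle)
# ---------------------------------------------------------------------------

def dense_glasso_oracle(R: np.ndarray, lam: float, penalize_diagonal: bool = True,
                        eps: float = 1e-10) -> np.ndarray:
    """Maximize ``log det T - tr(R T) - lam*||T||_1`` by smoothed L-BFGS.

    Parametrizes T through its Cholesky factor (log-diagonal) and replaces
    |x| with sqrt(x^2 + eps^2), solving a warm-started continuation over
    decreasing eps; the final eps is far below the test tolerance.
    """
    from scipy.optimize import minimize

    p = R.shape[0]
    tril = np.tril_indices(p)

    def unpack(x):
        L = np.zeros((p, p))
        L[tril] = x
        d = np.diag(L).copy()
        L[np.diag_indices(p)] = np.exp(d)
        return L

    def negobj(x):
        L = unpack(x)
        T = L @ L.T
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        pen = np.sqrt(T**2 + eps**2)
        if not penalize_diagonal:
            pen = pen - np.diag(np.diag(pen))
        return -(logdet - np.trace(R @ T) - lam * pen.sum()
                 + (lam * p * eps if penalize_diagonal else 0.0))

    def solve(eps_val, x):
        nonlocal eps
        eps = eps_val
        return minimize(negobj, x, method="L-BFGS-B",
                        options={"maxiter": 50000, "ftol": 1e-16, "gtol": 1e-14})

    best = None
    for scale in (0.0, 0.1):
        x = np.zeros(p * (p + 1) // 2)
        x += scale * np.random.default_rng(0).standard_normal(x.size)
        res = None
        for eps_val in (1e-3, 1e-5, 1e-8, 1e-10):  # smoothing continuation
            res = solve(eps_val, x)
            x = res.x
        if best is None or res.fun < best.fun:
            best = res
    L = unpack(best.x)
    return L @ L.T
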