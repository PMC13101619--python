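"""Structural metrics of a care-activity network.

All metrics are computed on the binarized (unweighted) graph; the signed
partial-correlation weights are carried only for export and display.  The
conventions follow the standard definitions for undirected graphs:

* node degree — number of incident edges;
* node/edge betweenness — Brandes-style raw accumulation over unordered pairs
  of distinct endpoints, with fractional counting over tied shortest paths
  (endpoints excluded for node betweenness; a normalized variant divides by
  the number of unordered pairs of other nodes);
* diameter / characteristic path length — over *connected* unordered pairs
  only, so a disconnected network still has well-defined distances;
* transitivity — 3 x triangles / connected triples; average clustering —
  mean of local clustering coefficients, nodes of degree < 2 contributing 0
  by default;
* modularity — Newman's Q of a deterministic greedy agglomerative partition
  (lexicographic tie-breaking on community labels, hence seedless and
  reproducible).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CareNetError
from .inference import CareNetwork


def _as_graph(g) -> nx.Graph:
    if isinstance(g, CareNetwork):
        return g.graph
    if isinstance(g, nx.Graph):
        return g
    raise TypeError(f"expected CareNetwork or networkx.Graph, got {type(g)!r}")


# ---------------------------------------------------------------------------
# Combinatorics helpers
# ---------------------------------------------------------------------------

def max_edges(n_nodes: int) -> int:
    """Maximum number of edges of an undirected simple graph: n(n-1)/2."""
    if n_nodes < 0:
        raise ValueError("node count must be nonnegative")
    return n_nodes * (n_nodes - 1) // 2


def density(n_nodes: int, n_edges: int) -> float:
    """Fraction of possible edges present: m / (n(n-1)/2)."""
    possible = max_edges(n_nodes)
    if possible == 0:
        return 0.0
    return n_edges / possible


# ---------------------------------------------------------------------------
# Centralities
# ---------------------------------------------------------------------------

def degree_centrality(g) -> dict[str, int]:
    """Integer degree per node on the binarized graph."""
    graph = _as_graph(g)
    return {n: int(d) for n, d in graph.degree()}


def betweenness(g, *, normalized: bool = False) -> tuple[dict, dict]:
    """Node and edge betweenness by shortest-path counting.

    Raw (unnormalized) accumulation over unordered pairs by default; the
    normalized variant rescales by the count of unordered pairs.  Returns
    ``(node_betweenness, edge_betweenness)`` with edges keyed by frozenset.
    """
    graph = _as_graph(g)
    node_bt = nx.betweenness_centrality(graph, normalized=normalized)
    edge_bt = nx.edge_betweenness_centrality(graph, normalized=normalized)
    return (
        {n: float(v) for n, v in node_bt.items()},
        {frozenset(e): float(v) for e, v in edge_bt.items()},
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMetrics:
    diameter: int
    characteristic_path_length: float
    #: fraction of connected unordered pairs at each shortest-path distance
    distance_distribution: dict[int, float]
    n_connected_pairs: int


def distance_metrics(g) -> DistanceMetrics:
    """Diameter, characteristic path length and the shortest-path-length
    distribution, over connected unordered node pairs only."""
    graph = _as_graph(g)
    if graph.number_of_edges() == 0:
        raise CareNetError("distances undefined: the network has no edges")
    counts: dict[int, int] = {}
    for source, lengths in nx.all_pairs_shortest_path_length(graph):
        for target, d in lengths.items():
            if source < target:  # each unordered pair once
                counts[d] = counts.get(d, 0) + 1
    n_pairs = sum(counts.values())
    total = sum(d * c for d, c in counts.items())
    return DistanceMetrics(
        diameter=max(counts),
        characteristic_path_length=total / n_pairs,
        distance_distribution={d: c / n_pairs for d, c in sorted(counts.items())},
        n_connected_pairs=n_pairs,
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def clustering_metrics(g, *, include_low_degree: bool = True) -> tuple[float, float]:
    """``(transitivity, average_clustering)`` of the binarized graph.

    ``include_low_degree`` counts nodes of degree < 2 as having local
    clustering 0 in the average (the default); when False they are excluded.
    """
    graph = _as_graph(g)
    transitivity = nx.transitivity(graph)
    if graph.number_of_nodes() == 0:
        return 0.0, 0.0
    average = nx.average_clustering(graph, count_zeros=include_low_degree)
    return float(transitivity), float(average)


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------

def modularity_score(g, communities) -> float:
    """Newman modularity ``Q = sum_c (L_c / m - (D_c / 2m)^2)`` of a partition.

    ``L_c`` is the number of intra-community edges, ``D_c`` the total degree
    of community ``c`` and ``m`` the number of edges.  Every node must belong
    to exactly one community.
    """
    graph = _as_graph(g)
    communities = [set(c) for c in communities]
    seen: set = set()
    for c in communities:
        if c & seen:
            raise ValueError("communities overlap")
        seen |= c
    if seen != set(graph.nodes):
        raise ValueError("communities must cover every node exactly once")
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for c in communities:
        l_c = sum(1 for u, v in graph.edges(c) if u in c and v in c)
        d_c = sum(d for _, d in graph.degree(c))
        q += l_c / m - (d_c / (2.0 * m)) ** 2
    return q


def modularity_partition(g) -> tuple[list[set], float]:
    """Deterministic greedy agglomerative modularity maximization.

    Starts from singleton communities and repeatedly merges the connected
    pair of communities with the largest positive modularity gain; ties are
    broken lexicographically on the communities' smallest node labels.  Being
    greedy, the result is a (reproducible) heuristic, not a global optimum.
    Returns ``(communities, Q)``.
    """
    graph = _as_graph(g)
    nodes = sorted(graph.nodes)
    m = graph.number_of_edges()
    if m == 0:
        return [{n} for n in nodes], 0.0

    comms: dict[str, set] = {n: {n} for n in nodes}  # rep label -> members
    deg_sum: dict[str, int] = {n: graph.degree(n) for n in nodes}
    links: dict[frozenset, int] = {}  # unordered rep pair -> edges between
    for u, v in graph.edges:
        if u != v:
            key = frozenset((u, v))
            links[key] = links.get(key, 0) + 1

    two_m = 2.0 * m
    while True:
        best_gain = 0.0
        best_pair: tuple[str, str] | None = None
        for key, l_uv in links.items():
            a, b = sorted(key)
            gain = l_uv / m - 2.0 * (deg_sum[a] / two_m) * (deg_sum[b] / two_m)
            if gain > best_gain + 1e-12 or (
                best_pair is not None
                and abs(gain - best_gain) <= 1e-12
                and (a, b) < best_pair
            ):
                if gain > 1e-12:
                    best_gain = gain
                    best_pair = (a, b)
        if best_pair is None:
            break
        a, b = best_pair  # a < b lexicographically; a absorbs b
        comms[a] |= comms.pop(b)
        deg_sum[a] += deg_sum.pop(b)
        merged: dict[frozenset, int] = {}
        for key, cnt in links.items():
            if key == frozenset((a, b)):
                continue
            new_key = frozenset(a if r == b else r for r in key)
            if len(new_key) == 1:
                continue
            merged[new_key] = merged.get(new_key, 0) + cnt
        links = merged

    partition = sorted(comms.values(), key=lambda c: min(c))
    return partition, modularity_score(graph, partition)


# ---------------------------------------------------------------------------
# Summary report
# ---------------------------------------------------------------------------

def _quartile_summary(values) -> dict[str, float]:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return {"median": float("nan"), "q25": float("nan"), "q75": float("nan"),
                "min": float("nan"), "max": float("nan")}
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return {"median": float(med), "q25": float(q25), "q75": float(q75),
            "min": float(arr.min()), "max": float(arr.max())}


@dataclass
class NetworkMetricsReport:
    """Full structural characterization of a care network.

    Scalar fields are kept at full precision; :meth:`to_dict` optionally
    rounds for display.
    """

    n_nodes: int
    n_edges: int
    density: float
    diameter: int
    characteristic_path_length: float
    global_clustering: float
    average_clustering: float
    modularity: float
    communities: list[list[str]]
    node_degree: dict[str, float]
    node_betweenness: dict[str, float]
    edge_betweenness: dict[str, float]
    distance_distribution: dict[int, float]
    per_node: pd.DataFrame = field(repr=False, default=None)
    per_edge: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self, round_digits: int | None = 2) -> dict:
        def _r(x):
            if round_digits is None or not isinstance(x, float):
                return x
            return round(x, round_digits)

        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": _r(self.density),
            "diameter": self.diameter,
            "characteristic_path_length": _r(self.characteristic_path_length),
            "global_clustering": _r(self.global_clustering),
            "average_clustering": _r(self.average_clustering),
            "modularity": _r(self.modularity),
            "n_communities": len(self.communities),
            "communities": self.communities,
            "node_degree": {k: _r(v) for k, v in self.node_degree.items()},
            "node_betweenness": {k: _r(v) for k, v in self.node_betweenness.items()},
            "edge_betweenness": {k: _r(v) for k, v in self.edge_betweenness.items()},
            "distance_distribution": {
                str(k): _r(v) for k, v in self.distance_distribution.items()
            },
        }

    def to_json(self, path: str | Path, round_digits: int | None = 2) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(round_digits), indent=2))
        return path


def summarize(g, *, normalized_betweenness: bool = False,
              include_low_degree: bool = True) -> NetworkMetricsReport:
    """Compute every structural metric and the quartile summaries."""
    graph = _as_graph(g)
    degrees = degree_centrality(graph)
    node_bt, edge_bt = betweenness(graph, normalized=normalized_betweenness)
    dist = distance_metrics(graph)
    transitivity, avg_clust = clustering_metrics(
        graph, include_low_degree=include_low_degree
    )
    communities, q = modularity_partition(graph)

    per_node = pd.DataFrame(
        {
            "activity": list(degrees),
            "degree": [degrees[n] for n in degrees],
            "betweenness": [node_bt[n] for n in degrees],
        }
    ).set_index("activity").sort_index()
    per_edge = pd.DataFrame(
        [
            {
                "source": u,
                "target": v,
                "weight": data.get("weight", float("nan")),
                "betweenness": edge_bt[frozenset((u, v))],
            }
            for u, v, data in sorted(graph.edges(data=True))
        ],
        columns=["source", "target", "weight", "betweenness"],
    )

    return NetworkMetricsReport(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        density=density(graph.number_of_nodes(), graph.number_of_edges()),
        diameter=dist.diameter,
        characteristic_path_length=dist.characteristic_path_length,
        global_clustering=transitivity,
        average_clustering=avg_clust,
        modularity=q,
        communities=[sorted(c) for c in communities],
        node_degree=_quartile_summary(degrees.values()),
        node_betweenness=_quartile_summary(node_bt.values()),
        edge_betweenness=_quartile_summary(edge_bt.values()),
        distance_distribution=dist.distance_distribution,
        per_node=per_node,
        per_edge=per_edge,
    )
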