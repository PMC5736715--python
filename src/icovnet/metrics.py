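"""Weighted undirected graph metrics.

Conventions follow the standard connectivity-analysis toolbox definitions:

* clustering: Onnela geometric-mean triangle intensity for weights in [0, 1];
* path length: shortest paths over the connection-length matrix (1/weight),
  characteristic path length as the mean over reachable off-diagonal pairs;
* small-worldness: observed clustering and path length normalized by their
  means over degree-preserving rewired null networks, sigma = gamma/lambda;
* modularity: weighted Newman Q, averaged over randomized-order Louvain runs;
* betweenness: Brandes accounting on connection lengths, each unordered node
  pair counted once, shortest-path multiplicities split fractionally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra

from .network import WeightedNetwork

__all__ = [
    "GlobalMetrics",
    "clustering_coefficients",
    "to_connection_length",
    "shortest_path_lengths",
    "characteristic_path_length",
    "rewire_degree_preserving",
    "normalized_small_world",
    "modularity_q",
    "node_betweenness",
    "edge_betweenness",
]

log = logging.getLogger("icovnet")


@dataclass(frozen=True)
class GlobalMetrics:
    """Global characteristics of one thresholded network."""

    gamma: float  # normalized clustering coefficient
    lambda_: float  # normalized characteristic path length
    sigma: float  # small-worldness gamma/lambda
    q: float  # modularity, mean over heuristic runs
    n_connected: int  # nodes with degree >= 1


def clustering_coefficients(net: WeightedNetwork) -> np.ndarray:
    """Per-node weighted clustering (geometric-mean triangle intensity).

    C_i = sum_{j,h} (w_ij w_ih w_jh)^(1/3) / (k_i (k_i - 1)) for binary
    degree k_i >= 2, else 0. Requires weights in [0, 1].
    """
    w = net.weights
    if np.any(w > 1):
        raise ValueError("clustering variant assumes weights <= 1")
    cbrt = np.cbrt(w)
    cycles = np.diag(cbrt @ cbrt @ cbrt)  # ordered (j, h) pairs
    k = (w > 0).sum(axis=0)
    c = np.zeros(net.n_nodes)
    mask = k >= 2
    c[mask] = cycles[mask] / (k[mask] * (k[mask] - 1))
    return c


def to_connection_length(net: WeightedNetwork) -> np.ndarray:
    """Elementwise 1/weight; absent pairs become infinite, diagonal 0."""
    w = net.weights
    lengths = np.full_like(w, np.inf)
    present = w > 0
    lengths[present] = 1.0 / w[present]
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_path_lengths(lengths: np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path distances (Dijkstra).

    ``lengths`` is a connection-length matrix: finite positive entries are
    edges, infinite entries absent pairs. Unreachable pairs stay infinite.
    """
    graph = np.where(np.isfinite(lengths), lengths, 0.0)
    np.fill_diagonal(graph, 0.0)
    return dijkstra(graph, directed=False)


def characteristic_path_length(distances: np.ndarray) -> float:
    """Mean finite off-diagonal distance; infinite pairs are excluded.

    Raises ``ValueError`` on a fully disconnected input (no finite
    off-diagonal distance). Exclusion of unreachable pairs is logged by the
    caller pipeline whenever any exist.
    """
    n = distances.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(distances)
    if not finite.any():
        raise ValueError("characteristic path length undefined: no connected pair")
    return float(distances[finite].mean())


def _n_infinite_pairs(distances: np.ndarray) -> int:
    n = distances.shape[0]
    off = ~np.eye(n, dtype=bool)
    return int(np.isinf(distances[off]).sum()) // 2


def rewire_degree_preserving(
    net: WeightedNetwork,
    swaps_per_edge: int = 10,
    rng: np.random.Generator | None = None,
) -> WeightedNetwork:
    """Degree-preserving randomization by repeated double-edge swaps.

    Attempts ``swaps_per_edge * n_edges`` swaps (a-b, c-d) -> (a-d, c-b),
    rejecting any that would create a self-loop or multi-edge. The binary
    degree sequence is preserved exactly; weights travel with the swapped
    edges so the weight multiset is preserved too. Graphs admitting no valid
    swap (e.g. a triangle) come back unchanged.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n = net.n_nodes
    iu, ju = np.triu_indices(n, 1)
    mask = net.weights[iu, ju] > 0
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    weights = net.weights[iu, ju][mask].tolist()
    m = len(edges)
    if m < 2:
        log.warning("rewire: fewer than 2 edges, returning an unchanged copy")
        return WeightedNetwork(net.weights.copy(), list(net.node_names), net.sparsity_k)
    present = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        present[a, b] = present[b, a] = True
    attempts = swaps_per_edge * m
    picks = rng.integers(0, m, size=(attempts, 2))
    flips = rng.random(attempts) < 0.5
    swapped = 0
    for (e1, e2), flip in zip(picks, flips):
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        # candidate new edges a-d and c-b
        if a == d or c == b:
            continue
        if len({a, b, c, d}) < 4:
            continue
        if present[a, d] or present[c, b]:
            continue
        present[a, b] = present[b, a] = False
        present[c, d] = present[d, c] = False
        present[a, d] = present[d, a] = True
        present[c, b] = present[b, c] = True
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
        swapped += 1
    if swapped == 0:
        log.warning("rewire: no valid swap found, returning an unchanged copy")
    out = np.zeros_like(net.weights)
    for (a, b), w in zip(edges, weights):
        out[a, b] = out[b, a] = w
    return WeightedNetwork(out, list(net.node_names), net.sparsity_k)


def normalized_small_world(
    net: WeightedNetwork,
    n_null: int = 100,
    swaps_per_edge: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) against degree-preserving rewired nulls.

    gamma = observed mean clustering / mean over nulls of mean clustering;
    lambda = observed characteristic path length / mean null value;
    sigma = gamma / lambda. A graph that is a fixed point of rewiring (e.g.
    the complete graph) yields (1, 1, 1) for any ``n_null``.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    obs_c = float(clustering_coefficients(net).mean())
    obs_l = characteristic_path_length(shortest_path_lengths(to_connection_length(net)))
    null_c = np.empty(n_null)
    null_l = np.empty(n_null)
    for i in range(n_null):
        null = rewire_degree_preserving(net, swaps_per_edge, rng)
        null_c[i] = clustering_coefficients(null).mean()
        null_l[i] = characteristic_path_length(
            shortest_path_lengths(to_connection_length(null))
        )
    mean_c, mean_l = float(null_c.mean()), float(null_l.mean())
    if mean_c == 0:
        raise ValueError("degenerate null model: mean null clustering is zero")
    if mean_l == 0:
        raise ValueError("degenerate null model: mean null path length is zero")
    gamma = obs_c / mean_c
    lam = obs_l / mean_l
    return gamma, lam, gamma / lam


def _to_nx(weights: np.ndarray, attr: str = "weight") -> nx.Graph:
    n = weights.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, 1)
    mask = np.isfinite(weights[iu, ju]) & (weights[iu, ju] > 0)
    g.add_weighted_edges_from(
        zip(iu[mask].tolist(), ju[mask].tolist(), weights[iu, ju][mask].tolist()),
        weight=attr,
    )
    return g


def modularity_q(
    net: WeightedNetwork,
    n_runs: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[float, list[set[int]]]:
    """Mean weighted-Newman Q over randomized Louvain runs, and best partition.

    The Louvain heuristic is stochastic in its node visiting order; Q is the
    mean over ``n_runs`` independent runs, and the returned partition is the
    best one found. Raises on an edgeless network.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if net.n_edges == 0:
        raise ValueError("modularity undefined for an edgeless network")
    rng = rng if rng is not None else np.random.default_rng()
    g = _to_nx(net.weights)
    qs = np.empty(n_runs)
    best_q, best_part = -np.inf, None
    for i in range(n_runs):
        seed = int(rng.integers(0, 2**31 - 1))
        part = nx.community.louvain_communities(g, weight="weight", seed=seed)
        q = nx.community.modularity(g, part, weight="weight")
        qs[i] = q
        if q > best_q:
            best_q, best_part = q, part
    return float(qs.mean()), [set(c) for c in best_part]


def _length_graph(lengths: np.ndarray) -> nx.Graph:
    masked = np.where(np.isfinite(lengths), lengths, 0.0)
    np.fill_diagonal(masked, 0.0)
    return _to_nx(masked, attr="length")


def node_betweenness(lengths: np.ndarray) -> np.ndarray:
    """Weighted node betweenness over the connection-length matrix.

    For each node, the multiplicity-split count of shortest paths between
    other node pairs passing through it; endpoints excluded, each unordered
    pair counted once (a 5-star's center scores (n-1)(n-2)/2 = 6).
    """
    g = _length_graph(lengths)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(lengths.shape[0])])


def edge_betweenness(lengths: np.ndarray) -> np.ndarray:
    """Weighted edge betweenness, returned as a symmetric matrix.

    Entry (i, j) is the multiplicity-split count of node-pair shortest paths
    traversing edge i-j (the endpoints' own pair counts toward the edge);
    absent pairs are 0.
    """
    g = _length_graph(lengths)
    ebc = nx.edge_betweenness_centrality(g, weight="length", normalized=False)
    n = lengths.shape[0]
    out = np.zeros((n, n))
    for (i, j), v in ebc.items():
        out[i, j] = out[j, i] = v
    return out
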