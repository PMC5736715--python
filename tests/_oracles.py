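"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths (and libraries) the package uses:
Floyd-Warshall for all-pairs distances, exhaustive simple-path enumeration
for betweenness, exhaustive set-partition search for modularity, and the
classic rank-difference formula for Spearman.
"""

import itertools
import math

import numpy as np

TOL = 1e-9


def floyd_warshall(lengths):
    """All-pairs shortest distances by triple-loop relaxation."""
    d = np.array(lengths, dtype=float)
    n = d.shape[0]
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def all_shortest_paths(lengths, s, t, tol=1e-12):
    """Every shortest simple path s->t by exhaustive DFS enumeration."""
    n = lengths.shape[0]
    adj = [
        [j for j in range(n) if j != i and math.isfinite(lengths[i, j])]
        for i in range(n)
    ]
    best = [math.inf]
    paths: list[list[int]] = []

    def dfs(node, dist, path, visited):
        if dist > best[0] + tol:
            return
        if node == t:
            if dist < best[0] - tol:
                best[0] = dist
                paths.clear()
            paths.append(list(path))
            return
        for nb in adj[node]:
            if nb not in visited:
                visited.add(nb)
                path.append(nb)
                dfs(nb, dist + lengths[node, nb], path, visited)
                path.pop()
                visited.remove(nb)

    dfs(s, 0.0, [s], {s})
    return best[0], paths


def brute_force_betweenness(lengths):
    """(node betweenness, edge betweenness matrix) by path enumeration.

    Each unordered reachable pair contributes 1 split equally over its
    shortest paths; internal nodes collect node credit, every edge on a path
    collects edge credit (so a direct edge earns its endpoints' own pair).
    """
    n = lengths.shape[0]
    node_bw = np.zeros(n)
    edge_bw = np.zeros((n, n))
    for s in range(n):
        for t in range(s + 1, n):
            dist, paths = all_shortest_paths(lengths, s, t)
            if not math.isfinite(dist) or not paths:
                continue
            share = 1.0 / len(paths)
            for path in paths:
                for v in path[1:-1]:
                    node_bw[v] += share
                for a, b in zip(path, path[1:]):
                    edge_bw[a, b] += share
                    edge_bw[b, a] += share
    return node_bw, edge_bw


def set_partitions(items):
    """All partitions of a list into nonempty blocks."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i, block in enumerate(partition):
            yield partition[:i] + [block + [first]] + partition[i + 1:]
        yield partition + [[first]]


def weighted_modularity(weights, partition):
    """Newman weighted Q of a given node partition."""
    w = np.asarray(weights, dtype=float)
    two_m = w.sum()
    strength = w.sum(axis=0)
    q = 0.0
    for block in partition:
        idx = np.array(sorted(block))
        q += w[np.ix_(idx, idx)].sum() / two_m
        q -= (strength[idx].sum() / two_m) ** 2
    return q


def exhaustive_max_modularity(weights):
    """(max Q, best partition) over every partition (feasible for n <= 8)."""
    n = weights.shape[0]
    best_q, best_p = -np.inf, None
    for partition in set_partitions(range(n)):
        q = weighted_modularity(weights, partition)
        if q > best_q:
            best_q, best_p = q, [set(b) for b in partition]
    return best_q, best_p


def spearman_rank_formula(x, y):
    """Spearman rho as Pearson correlation of tie-averaged ranks."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def random_weighted_graph(n, rng, p=0.5):
    """Random symmetric weight matrix in (0, 1], ensuring >= 1 edge."""
    while True:
        mask = rng.random((n, n)) < p
        mask = np.triu(mask, 1)
        if mask.sum() >= 1:
            break
    w = np.zeros((n, n))
    w[mask] = rng.uniform(0.05, 1.0, size=int(mask.sum()))
    return w + w.T
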