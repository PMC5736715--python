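"""Per-participant covariance-proximity networks.

A participant's 18 scores are group-standardized, sign-flipped so positive
z means a better condition, and every variable pair (i, j) is joined by an
edge of weight exp(-(z_i - z_j)^2): variables whose standardized scores sit
close together within that person are strongly connected. Proportional
thresholding then keeps the top fraction K of the 153 possible edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import CohortTable
from .variables import VariableSpec, registry_names

__all__ = [
    "ZMatrix",
    "WeightedNetwork",
    "zscore_cohort",
    "covariance_edge_weight",
    "build_participant_network",
    "threshold_proportional",
]

log = logging.getLogger("icovnet")


@dataclass
class ZMatrix:
    """Signed z-scores for a cohort, plus the group statistics used.

    ``values[t, i]`` is participant t's z-score on variable i after the
    sign-convention flip (positive = better). ``plain()`` recovers the
    unflipped z-scores used for e.g. the depression-anxiety difference.
    """

    values: np.ndarray  # participants x variables, signed
    group_means: np.ndarray
    group_sds: np.ndarray
    directions: np.ndarray  # +1/-1 per variable
    names: list[str]

    def plain(self) -> np.ndarray:
        """Unflipped z-scores (raw - mean) / sd."""
        return self.values * self.directions


def zscore_cohort(cohort: CohortTable, registry: list[VariableSpec] | None = None) -> ZMatrix:
    """Group-wise z-scoring with the better-condition sign convention.

    Each column is standardized by the cohort's own mean and sample SD
    (ddof=1), then multiplied by the variable's ``better_direction`` so that
    every positive signed z indicates a better condition. The group
    statistics are a property of the analyzed cohort, not an external norm.
    """
    registry = registry if registry is not None else cohort.registry
    raw = cohort.values
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=1)
    directions = np.array([s.better_direction for s in registry], dtype=float)
    signed = (raw - means) / sds * directions
    return ZMatrix(signed, means, sds, directions, registry_names(registry))


def covariance_edge_weight(zi, zj):
    """Proximity kernel exp(-(zi - zj)^2); 1 at equality, ->0 as z diverge.

    Symmetric, translation-invariant and invariant under joint negation;
    accepts scalars or arrays.
    """
    zi = np.asarray(zi, dtype=float)
    zj = np.asarray(zj, dtype=float)
    out = np.exp(-((zi - zj) ** 2))
    return out if out.ndim else float(out)


@dataclass
class WeightedNetwork:
    """One participant's symmetric weighted network.

    ``weights`` is an n x n symmetric matrix with zero diagonal, entries in
    (0, 1] where an edge is present and exactly 0 where absent.
    ``sparsity_k`` is the retained fraction of the n(n-1)/2 possible edges
    (1.0 for the unthresholded network).
    """

    weights: np.ndarray
    node_names: list[str]
    sparsity_k: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.array_equal(w, w.T):
            raise ValueError("weights must be exactly symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_possible_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def degrees(self) -> np.ndarray:
        """Binary degree per node."""
        return (self.weights > 0).sum(axis=0)

    def n_connected(self) -> int:
        """Nodes with at least one edge."""
        return int((self.degrees() >= 1).sum())

    def edge_list(self) -> list[tuple[int, int, float]]:
        iu, ju = np.triu_indices(self.n_nodes, 1)
        mask = self.weights[iu, ju] > 0
        return [
            (int(i), int(j), float(self.weights[i, j]))
            for i, j in zip(iu[mask], ju[mask])
        ]


def build_participant_network(
    z_row: Sequence[float], node_names: Sequence[str] | None = None
) -> WeightedNetwork:
    """All-pairs proximity network from one participant's signed z-scores."""
    z = np.asarray(z_row, dtype=float)
    if z.ndim != 1:
        raise ValueError("z_row must be one participant's score vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("z_row contains non-finite values")
    w = covariance_edge_weight(z[:, None], z[None, :])
    np.fill_diagonal(w, 0.0)
    w = np.minimum(w, w.T)  # guard symmetry against fp asymmetry (none expected)
    names = list(node_names) if node_names is not None else [f"v{i}" for i in range(z.size)]
    return WeightedNetwork(w, names, sparsity_k=1.0)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def threshold_proportional(net: WeightedNetwork, k: float) -> WeightedNetwork:
    """Keep the round(K * n(n-1)/2) strongest edges, zero the rest.

    Half-away-from-zero rounding of the retained count (e.g. 31 edges at
    K=0.20 for 18 nodes). Boundary ties in weight are broken by stable
    lexicographic (i, j) order and logged; with continuous z-scores exact
    ties essentially never occur. Surviving weights are unchanged.
    """
    if not 0 < k <= 1:
        raise ValueError(f"sparsity K must lie in (0, 1], got {k}")
    n = net.n_nodes
    m = net.n_possible_edges
    keep = _round_half_away(k * m)
    iu, ju = np.triu_indices(n, 1)
    w = net.weights[iu, ju]
    order = np.lexsort((ju, iu, -w))  # weight desc, then (i, j) asc
    kept = order[:keep]
    if keep < m and w[order[keep - 1]] == w[order[keep]] and keep > 0:
        log.warning(
            "threshold_proportional: weight tie at the K=%.2f retention "
            "boundary broken by lexicographic edge order", k,
        )
    out = np.zeros_like(net.weights)
    out[iu[kept], ju[kept]] = w[kept]
    out = out + out.T
    return WeightedNetwork(out, list(net.node_names), sparsity_k=float(k))
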