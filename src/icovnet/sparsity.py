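"""Sparsity scan and data-driven selection of the optimal K range.

For every participant and every K on the grid, the thresholded network is
scored on three criteria: small-world organization (sigma > 1), modular
organization (Q > 0.3) and connectedness (more than 15 of the 18 nodes with
at least one edge). The optimal range is the set of K values at which all
three hold simultaneously in more than a prevalence threshold (default 95%)
of participants.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import GlobalMetrics, modularity_q, normalized_small_world
from .network import WeightedNetwork, threshold_proportional

__all__ = [
    "SparsityProfile",
    "compute_global_metrics",
    "evaluate_criteria",
    "scan_sparsity",
    "select_optimal_range",
]

log = logging.getLogger("icovnet")

Q_THRESHOLD = 0.3
MIN_CONNECTED = 15  # criterion is strictly more than 15 of 18 nodes


def compute_global_metrics(
    net: WeightedNetwork,
    n_null: int,
    n_modularity_runs: int,
    swaps_per_edge: int,
    rng: np.random.Generator,
) -> GlobalMetrics:
    """All four global characteristics of one thresholded network."""
    gamma, lam, sigma = normalized_small_world(net, n_null, swaps_per_edge, rng)
    q, _ = modularity_q(net, n_modularity_runs, rng)
    return GlobalMetrics(gamma, lam, sigma, q, net.n_connected())


def evaluate_criteria(metrics: GlobalMetrics) -> tuple[bool, bool, bool]:
    """(small-world, modular, connected) flags — all strict inequalities."""
    return (
        metrics.sigma > 1.0,
        metrics.q > Q_THRESHOLD,
        metrics.n_connected > MIN_CONNECTED,
    )


@dataclass
class SparsityProfile:
    """Per participant x K global metrics and criterion flags."""

    table: pd.DataFrame  # columns: participant, k, gamma, lambda, sigma, q,
    # n_connected, small_world, modular, connected, all_criteria

    def satisfaction_by_k(self) -> pd.DataFrame:
        """Fraction of participants satisfying each criterion per K."""
        cols = ["small_world", "modular", "connected", "all_criteria"]
        return self.table.groupby("k")[cols].mean()


def scan_sparsity(
    networks: dict[str, WeightedNetwork],
    k_grid: tuple[float, ...],
    n_null: int,
    n_modularity_runs: int,
    swaps_per_edge: int,
    seed_seq: np.random.SeedSequence,
) -> SparsityProfile:
    """Threshold every participant's network at every K and score it.

    ``networks`` maps participant id to the unthresholded network. The child
    seed for each (participant, K) cell is keyed by the participant id and
    the K index, so results do not depend on iteration or row order.
    """
    rows = []
    for pid, net in networks.items():
        pid_key = zlib.crc32(str(pid).encode())
        for ki, k in enumerate(k_grid):
            cell = np.random.SeedSequence(
                entropy=seed_seq.entropy,
                spawn_key=tuple(seed_seq.spawn_key) + (pid_key, ki),
            )
            rng = np.random.default_rng(cell)
            thresholded = threshold_proportional(net, k)
            m = compute_global_metrics(
                thresholded, n_null, n_modularity_runs, swaps_per_edge, rng
            )
            sw, mod, conn = evaluate_criteria(m)
            rows.append(
                dict(
                    participant=pid, k=k, gamma=m.gamma, lambda_=m.lambda_,
                    sigma=m.sigma, q=m.q, n_connected=m.n_connected,
                    small_world=sw, modular=mod, connected=conn,
                    all_criteria=sw and mod and conn,
                )
            )
    return SparsityProfile(pd.DataFrame(rows))


def select_optimal_range(
    profile: SparsityProfile, prevalence: float = 0.95
) -> list[float]:
    """K values where all three criteria hold in > ``prevalence`` of participants.

    Strict comparison: with 90 participants and the default 0.95, at least 86
    must satisfy all criteria. An empty selection is reported with a warning,
    not an error; a non-contiguous selection is logged and kept whole.
    """
    frac = profile.satisfaction_by_k()["all_criteria"]
    selected = [float(k) for k, f in frac.items() if f > prevalence]
    if not selected:
        log.warning(
            "no sparsity K reached joint-criterion prevalence > %.2f", prevalence
        )
    else:
        ks = sorted(frac.index)
        span = [k for k in ks if selected[0] <= k <= selected[-1]]
        if len(span) != len(selected):
            log.warning("selected sparsity range is non-contiguous: %s", selected)
    return selected
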