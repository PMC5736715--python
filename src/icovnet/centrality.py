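"""Rank-transformed centralities and their correlation with symptom severity.

Betweenness values are rank-transformed within participant (tie-averaged,
rank 1 = highest betweenness, i.e. most central), averaged over the selected
sparsity range, and correlated with symptom severity by Spearman's rho.
Edge-level analysis additionally extracts the "influential" edge set — pairs
in a participant's top 20% of edge ranks in more than 45% of participants —
and correlates each influential edge's rank with the depression-anxiety
difference z(BDI) - z(BAI) (plain z-scores, no sign convention applied),
with Bonferroni correction over the influential edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable
from .metrics import edge_betweenness, node_betweenness, to_connection_length
from .network import WeightedNetwork, zscore_cohort

__all__ = [
    "CorrelationResult",
    "InfluentialEdgeSet",
    "rank_descending",
    "average_ranks_over_k",
    "spearman",
    "compute_node_ranks",
    "compute_edge_ranks",
    "node_symptom_correlations",
    "influential_edges",
    "edge_dynamic_correlation",
]

log = logging.getLogger("icovnet")

SYMPTOM_VARIABLES = ("BDI", "BAI")


def rank_descending(values: np.ndarray) -> np.ndarray:
    """Tie-averaged ranks with rank 1 = largest value.

    A low rank therefore means high centrality. Raises on non-finite input.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("rank_descending requires finite values")
    return stats.rankdata(-values, method="average")


def average_ranks_over_k(
    ranks_by_k: dict[float, np.ndarray], selected_k: list[float]
) -> np.ndarray:
    """Arithmetic mean of rank vectors over the selected sparsity values."""
    missing = [k for k in selected_k if k not in ranks_by_k]
    if missing:
        raise ValueError(f"ranks missing for selected K values: {missing}")
    return np.mean([ranks_by_k[k] for k in selected_k], axis=0)


@dataclass(frozen=True)
class CorrelationResult:
    """One Spearman correlation with its significance flag."""

    name: str
    rho: float
    p: float
    n: int
    alpha: float
    significant: bool


def spearman(x: np.ndarray, y: np.ndarray, name: str = "", alpha: float = 0.05) -> CorrelationResult:
    """Spearman's rho with tie-averaged ranks and two-sided t-approximation p.

    Raises ``ValueError`` for fewer than 4 pairs or a constant input vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman requires two equal-length vectors")
    if x.size < 4:
        raise ValueError("spearman requires at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"spearman undefined for constant input ({name or 'unnamed'})")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(name, float(rho), float(p), int(x.size), alpha, bool(p < alpha))


def _betweenness_tables(
    networks_by_k: dict[str, dict[float, WeightedNetwork]],
    node_names: list[str],
    kind: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared driver for node- and edge-level rank tables.

    Returns (long table with per-K betweenness and ranks, wide table of mean
    ranks: participants x nodes or participants x pairs).
    """
    n = len(node_names)
    if kind == "edge":
        iu, ju = np.triu_indices(n, 1)
        labels = [f"{node_names[i]}--{node_names[j]}" for i, j in zip(iu, ju)]
    else:
        labels = list(node_names)
    rows = []
    mean_rows = {}
    for pid, by_k in networks_by_k.items():
        ranks_by_k: dict[float, np.ndarray] = {}
        for k, net in by_k.items():
            lengths = to_connection_length(net)
            if kind == "edge":
                values = edge_betweenness(lengths)[iu, ju]
            else:
                values = node_betweenness(lengths)
            ranks = rank_descending(values)
            ranks_by_k[k] = ranks
            rows.extend(
                dict(participant=pid, k=k, name=lab,
                     betweenness=float(v), rank=float(r))
                for lab, v, r in zip(labels, values, ranks)
            )
        mean_rows[pid] = average_ranks_over_k(ranks_by_k, list(by_k))
    long = pd.DataFrame(rows)
    mean_rank = pd.DataFrame.from_dict(mean_rows, orient="index", columns=labels)
    mean_rank.index.name = "participant"
    long_mean = mean_rank.stack().rename("mean_rank").reset_index()
    long_mean.columns = ["participant", "name", "mean_rank"]
    long = long.merge(long_mean, on=["participant", "name"], how="left")
    return long, mean_rank


def compute_node_ranks(
    networks_by_k: dict[str, dict[float, WeightedNetwork]], node_names: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node betweenness, per-K ranks and mean ranks over the selected range.

    ``networks_by_k`` maps participant id -> {K: thresholded network}.
    Rank 1 = most central node for that participant at that K.
    """
    return _betweenness_tables(networks_by_k, node_names, "node")


def compute_edge_ranks(
    networks_by_k: dict[str, dict[float, WeightedNetwork]], node_names: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge betweenness ranks over the full universe of node pairs.

    Pairs absent from a thresholded network have betweenness 0 and thus
    share the worst tie-averaged ranks, so every participant ranks the same
    153 pairs and "top 20%" is well defined across participants.
    """
    return _betweenness_tables(networks_by_k, node_names, "edge")


def node_symptom_correlations(
    mean_node_ranks: pd.DataFrame,
    cohort: CohortTable,
    alpha: float = 0.01,
) -> tuple[list[CorrelationResult], list[str]]:
    """Spearman of each node's mean rank against each raw symptom total.

    Severity enters as the raw BDI/BAI totals. Under the rank convention
    (1 = most central), a positive rho means higher severity goes with
    *lower* centrality of that node. Constant rank columns are skipped with
    a warning rather than an error. Returns (results, warnings).
    """
    results, warnings = [], []
    ranks = mean_node_ranks.loc[cohort.participant_ids]
    for symptom in SYMPTOM_VARIABLES:
        severity = cohort.column(symptom)
        for node in ranks.columns:
            label = f"{node} vs {symptom}"
            try:
                results.append(
                    spearman(severity, ranks[node].to_numpy(), label, alpha)
                )
            except ValueError as err:
                warnings.append(f"skipped {label}: {err}")
                log.warning("skipped correlation %s: %s", label, err)
    return results, warnings


@dataclass
class InfluentialEdgeSet:
    """Edges in a participant's top fraction of edge ranks in more than a
    prevalence fraction of participants."""

    edges: list[str]  # "A--B" labels
    prevalence: dict[str, float]  # fraction of participants per retained edge
    top_fraction: float
    prevalence_threshold: float

    def to_json_dict(self) -> dict:
        return {
            "edges": self.edges,
            "prevalence": self.prevalence,
            "top_fraction": self.top_fraction,
            "prevalence_threshold": self.prevalence_threshold,
            "rank_convention": "rank 1 = highest edge betweenness",
        }


def influential_edges(
    mean_edge_ranks: pd.DataFrame,
    top_fraction: float = 0.20,
    prevalence: float = 0.45,
) -> InfluentialEdgeSet:
    """Prevalence-selected set of each participant's best-ranked edges.

    Per participant the best ``round(top_fraction * n_pairs)`` pairs by mean
    rank are marked (boundary ties broken by stable column order); pairs
    marked in strictly more than ``prevalence`` of participants are
    retained, with their prevalence fractions.
    """
    n_pairs = mean_edge_ranks.shape[1]
    n_top = int(np.floor(top_fraction * n_pairs + 0.5))
    counts = np.zeros(n_pairs)
    ranks = mean_edge_ranks.to_numpy()
    for row in ranks:
        order = np.lexsort((np.arange(n_pairs), row))  # rank asc, stable
        counts[order[:n_top]] += 1
    frac = counts / len(mean_edge_ranks)
    keep = frac > prevalence
    labels = list(mean_edge_ranks.columns)
    edges = [lab for lab, k in zip(labels, keep) if k]
    prev = {lab: float(f) for lab, f, k in zip(labels, frac, keep) if k}
    return InfluentialEdgeSet(edges, prev, top_fraction, prevalence)


def symptom_difference_z(cohort: CohortTable) -> np.ndarray:
    """Plain z(BDI) - z(BAI): group-standardized totals, no sign flip."""
    zmat = zscore_cohort(cohort)
    plain = zmat.plain()
    names = zmat.names
    return plain[:, names.index("BDI")] - plain[:, names.index("BAI")]


def edge_dynamic_correlation(
    edge_set: InfluentialEdgeSet,
    mean_edge_ranks: pd.DataFrame,
    cohort: CohortTable,
    family_alpha: float = 0.05,
) -> tuple[list[CorrelationResult], list[str]]:
    """Correlate each influential edge's mean rank with z(BDI) - z(BAI).

    Bonferroni: per-edge alpha = ``family_alpha`` / number of influential
    edges. A positive rho means a larger depression-minus-anxiety z
    difference goes with a numerically larger rank (less influential edge);
    negative rho means relatively more anxiety strengthens the edge's
    shortcut role. Degenerate inputs (identical BDI/BAI z-profiles) are
    skipped with a warning.
    """
    results, warnings = [], []
    if not edge_set.edges:
        return results, ["no influential edges; dynamic analysis skipped"]
    alpha = family_alpha / len(edge_set.edges)
    diff = symptom_difference_z(cohort)
    ranks = mean_edge_ranks.loc[cohort.participant_ids]
    if np.ptp(diff) == 0:
        msg = "z(BDI) - z(BAI) is constant; dynamic analysis skipped"
        log.warning(msg)
        return results, [msg]
    for edge in edge_set.edges:
        label = f"{edge} vs z(BDI)-z(BAI)"
        try:
            results.append(spearman(diff, ranks[edge].to_numpy(), label, alpha))
        except ValueError as err:
            warnings.append(f"skipped {label}: {err}")
            log.warning("skipped correlation %s: %s", label, err)
    return results, warnings


def correlations_frame(
    node_results: list[CorrelationResult],
    edge_results: list[CorrelationResult],
) -> pd.DataFrame:
    """Combined long-format correlation table for serialization."""
    rows = [dict(level="node", **asdict(r)) for r in node_results]
    rows += [dict(level="edge", **asdict(r)) for r in edge_results]
    cols = ["level", "name", "rho", "p", "n", "alpha", "significant"]
    return pd.DataFrame(rows, columns=cols)
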