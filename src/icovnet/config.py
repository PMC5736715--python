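"""Run configuration: sparsity grid, null-model counts, thresholds, seeding.

All randomized stages draw child seeds deterministically from one master
seed via ``numpy.random.SeedSequence``, so a run is exactly reproducible
from its config alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = ["RunConfig", "default_k_grid"]


def default_k_grid() -> tuple[float, ...]:
    """Sparsity fractions K = 0.10, 0.11, ..., 0.30."""
    return tuple(np.round(np.arange(0.10, 0.301, 0.01), 2).tolist())


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run.

    Parameters
    ----------
    k_grid:
        Sparsity fractions scanned for the optimal range.
    k_selected:
        Optional explicit K range; when given the scan stage is skipped and
        centralities are computed at exactly these sparsities.
    n_null:
        Degree-preserving rewired null networks per participant network used
        to normalize clustering and path length (publication scale 10000;
        100 is adequate for smoke-scale work).
    n_modularity_runs:
        Randomized-order Louvain repetitions averaged into Q
        (publication scale 500).
    swaps_per_edge:
        Rewiring passes per edge when generating each null network.
    prevalence_threshold:
        Fraction of participants that must satisfy all three global criteria
        for a K to enter the optimal range (strict >).
    edge_top_fraction, edge_prevalence:
        Per-participant top fraction of edge ranks, and across-participant
        prevalence (strict >), defining the influential edge set.
    alpha_node:
        Significance level for node-level symptom correlations.
    seed:
        Master seed for all stochastic stages.
    """

    k_grid: tuple[float, ...] = field(default_factory=default_k_grid)
    k_selected: tuple[float, ...] | None = None
    n_null: int = 10_000
    n_modularity_runs: int = 500
    swaps_per_edge: int = 10
    prevalence_threshold: float = 0.95
    edge_top_fraction: float = 0.20
    edge_prevalence: float = 0.45
    alpha_node: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.k_grid = tuple(float(k) for k in self.k_grid)
        if self.k_selected is not None:
            self.k_selected = tuple(float(k) for k in self.k_selected)
        for name in ("prevalence_threshold", "edge_top_fraction", "edge_prevalence",
                     "alpha_node"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        ks = self.k_grid
        if any(not 0 < k <= 1 for k in ks):
            raise ValueError("k_grid entries must lie in (0, 1]")
        if any(a >= b for a, b in zip(ks, ks[1:])):
            raise ValueError("k_grid must be strictly increasing")
        for name in ("n_null", "n_modularity_runs", "swaps_per_edge"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def test_scale(cls, **overrides) -> "RunConfig":
        """Config with reduced null/modularity counts for fast runs."""
        overrides.setdefault("n_null", 100)
        overrides.setdefault("n_modularity_runs", 100)
        return cls(**overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_grid"] = list(self.k_grid)
        d["k_selected"] = list(self.k_selected) if self.k_selected else None
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    def child_seed(self, stage: str) -> np.random.SeedSequence:
        """Deterministic per-stage seed derived from the master seed."""
        digest = sum(ord(c) * 131 ** i for i, c in enumerate(stage)) % (2**32)
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(digest,))
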