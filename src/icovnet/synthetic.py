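"""Synthetic cohort generator with plantable network structure.

Real study data of this kind (90 students' clinical questionnaires and
neurocognitive test scores) are rarely deposited, so the generator draws
cohorts from a multivariate normal whose marginals reproduce the published
per-measure means/SDs and whose correlation matrix has block compound
symmetry: the 11 clinical measures form one correlated block, the 7
neurocognitive measures another, with weaker cross-block correlation.

On top of that, :func:`plant_bridge` installs a known ground truth for the
centrality-severity analysis: one target variable's position in each
participant's z-profile is moved between "bridging" (midpoint of the widest
gap among the other variables' z-scores, where it shortcuts between
clusters) and "peripheral" (beyond the most extreme other score) as a
logistic function of the participant's symptom z-score. Higher symptom
severity pushes the target to the periphery, lowering its betweenness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import CohortTable
from .network import zscore_cohort
from .variables import VariableSpec, default_registry, registry_names

__all__ = ["SimConfig", "PlantSpec", "generate_cohort", "plant_bridge", "TABLE_MARGINALS"]

log = logging.getLogger("icovnet")

# Published per-measure marginal (mean, SD) for the 90-student cohort.
TABLE_MARGINALS: dict[str, tuple[float, float]] = {
    "BDI": (24.6, 10.8),
    "BAI": (16.8, 11.1),
    "MMPI_1_Hs": (55.8, 11.4),
    "MMPI_2_D": (66.4, 11.8),
    "MMPI_3_Hy": (57.6, 10.5),
    "MMPI_4_Pd": (56.2, 11.7),
    "MMPI_6_Pa": (55.6, 10.9),
    "MMPI_7_Pt": (63.4, 12.6),
    "MMPI_8_Sc": (58.3, 11.2),
    "MMPI_9_Ma": (46.9, 9.0),
    "MMPI_0_Si": (62.5, 12.6),
    "CPT_omission": (1.7, 4.6),
    "CPT_commission": (14.3, 7.5),
    "TMT_A": (21.2, 5.7),
    "TMT_B": (48.6, 13.1),
    "WCST_PE": (6.6, 5.3),
    "DS_forward": (11.7, 2.2),
    "DS_backward": (9.6, 3.1),
}


@dataclass
class PlantSpec:
    """Ground-truth coupling between a symptom score and one variable's
    bridging position.

    ``strength`` (beta >= 0) is the logistic slope mapping the coupling
    variable's plain z-score to bridging propensity
    b = logistic(-beta * z): higher symptom severity -> lower b -> more
    peripheral target placement.
    """

    target_variable: str = "WCST_PE"
    coupling_variable: str = "BDI"
    strength: float = 3.0

    def __post_init__(self) -> None:
        if self.target_variable == self.coupling_variable:
            raise ValueError("plant target and coupling variables must differ")
        if self.strength < 0:
            raise ValueError("plant strength must be >= 0")


@dataclass
class SimConfig:
    """Synthetic cohort parameters.

    Defaults emulate the published cohort: n=90, published marginal
    means/SDs, and block compound-symmetry correlation (0.4 within the 11
    clinical measures, 0.2 within the 7 neurocognitive measures, 0.1 across
    blocks). The implied correlation matrix is validated positive definite.
    """

    n_participants: int = 90
    means: dict[str, float] = field(
        default_factory=lambda: {k: v[0] for k, v in TABLE_MARGINALS.items()}
    )
    sds: dict[str, float] = field(
        default_factory=lambda: {k: v[1] for k, v in TABLE_MARGINALS.items()}
    )
    clinical_block_r: float = 0.4
    cognitive_block_r: float = 0.2
    cross_block_r: float = 0.1
    plant: PlantSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if any(s <= 0 for s in self.sds.values()):
            raise ValueError("all marginal SDs must be > 0")
        # fail fast on an impossible correlation request
        self.correlation_matrix(default_registry())

    def correlation_matrix(self, registry: list[VariableSpec]) -> np.ndarray:
        names = registry_names(registry)
        clinical = np.array([s.domain == "clinical" for s in registry])
        corr = np.full((len(names), len(names)), self.cross_block_r)
        for block in (clinical, ~clinical):
            idx = np.ix_(block, block)
            corr[idx] = self.clinical_block_r if block is clinical else self.cognitive_block_r
        np.fill_diagonal(corr, 1.0)
        if np.linalg.eigvalsh(corr).min() <= 1e-10:
            raise ValueError("requested block correlations are not positive definite")
        return corr

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "plant" in raw and raw["plant"] is not None:
            raw["plant"] = PlantSpec(**raw["plant"])
        return cls(**raw)


def generate_cohort(
    cfg: SimConfig, registry: list[VariableSpec] | None = None
) -> CohortTable:
    """Draw a cohort from the configured multivariate normal.

    Deterministic given ``cfg.seed``. Marginals are Gaussian even for
    count-like measures (the analysis consumes only z-scores, so only
    mean/SD/correlation matter); values are not clamped to be non-negative.
    Note the plant, if any, is applied separately via :func:`plant_bridge`.
    """
    registry = registry if registry is not None else default_registry()
    names = registry_names(registry)
    missing = [n for n in names if n not in cfg.means or n not in cfg.sds]
    if missing:
        raise ValueError(f"marginals missing for variables: {missing}")
    corr = cfg.correlation_matrix(registry)
    sds = np.array([cfg.sds[n] for n in names])
    means = np.array([cfg.means[n] for n in names])
    cov = corr * np.outer(sds, sds)
    rng = np.random.default_rng(cfg.seed)
    values = rng.multivariate_normal(means, cov, size=cfg.n_participants,
                                     method="cholesky")
    ids = [f"p{i + 1:03d}" for i in range(cfg.n_participants)]
    frame = pd.DataFrame(values, index=pd.Index(ids, name="participant_id"),
                         columns=names)
    return CohortTable(frame, registry)


def _largest_gap_midpoint(sorted_vals: np.ndarray) -> float:
    gaps = np.diff(sorted_vals)
    i = int(np.argmax(gaps))  # first widest gap on ties
    return float((sorted_vals[i] + sorted_vals[i + 1]) / 2.0)


def bridge_placement(others: np.ndarray, b: float) -> float:
    """Signed-z position of the target given the other 17 signed z-scores.

    ``b = 1`` puts the target at the midpoint of the widest gap (maximal
    bridging); ``b = 0`` puts it one unit beyond the maximum (peripheral);
    intermediate propensities interpolate linearly.
    """
    vals = np.sort(np.asarray(others, dtype=float))
    peripheral = float(vals[-1]) + 1.0
    return (1.0 - b) * peripheral + b * _largest_gap_midpoint(vals)


def plant_bridge(
    cohort: CohortTable, plant: PlantSpec, seed: int | None = None
) -> tuple[CohortTable, np.ndarray]:
    """Overwrite the target variable to encode known bridging structure.

    Per participant, bridging propensity ``b = logistic(-beta * z_c)`` with
    ``z_c`` the plain (unflipped) z of the coupling variable. In the signed-z
    space where the network kernel operates, the target is placed at
    ``(1 - b) * peripheral + b * mid_gap`` where ``peripheral`` is 1 beyond
    the maximum of the other 17 signed z-scores and ``mid_gap`` is the
    midpoint of the widest gap among them. The raw score is recovered
    through the variable's sign convention and the cohort's pre-plant
    column mean/SD; all other columns are untouched.

    Returns the planted cohort and the per-participant propensities ``b``.
    The placement is fully deterministic; ``seed`` is accepted for interface
    symmetry with the generator and unused.
    """
    names = registry_names(cohort.registry)
    for var in (plant.target_variable, plant.coupling_variable):
        if var not in names:
            raise ValueError(f"plant variable {var!r} not in cohort registry")
    t_idx = names.index(plant.target_variable)
    zmat = zscore_cohort(cohort)
    z_coupling = zmat.plain()[:, names.index(plant.coupling_variable)]
    b = 1.0 / (1.0 + np.exp(plant.strength * z_coupling))
    signed = zmat.values
    others = np.delete(signed, t_idx, axis=1)
    target_signed = np.array(
        [bridge_placement(others[t], b[t]) for t in range(cohort.n_participants)]
    )
    direction = cohort.registry[t_idx].better_direction
    mean_t, sd_t = zmat.group_means[t_idx], zmat.group_sds[t_idx]
    raw = mean_t + sd_t * (target_signed * direction)
    data = cohort.data.copy()
    data[plant.target_variable] = raw
    return CohortTable(data, cohort.registry), b
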