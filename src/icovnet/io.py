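"""Cohort table I/O and result serialization.

Cohorts are CSV files with a ``participant_id`` column and one numeric
column per registry variable; results are written as plain CSV/JSON tables
that round-trip numerically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .variables import VariableSpec, registry_names, validate_registry

__all__ = ["CohortTable", "ResultBundle", "load_cohort", "write_results"]

log = logging.getLogger("icovnet")

ID_COLUMN = "participant_id"


@dataclass
class CohortTable:
    """Raw participants x variables scores, columns in registry order."""

    data: pd.DataFrame  # index: participant ids, columns: registry names
    registry: list[VariableSpec]

    def __post_init__(self) -> None:
        validate_registry(self.registry)
        names = registry_names(self.registry)
        if list(self.data.columns) != names:
            missing = sorted(set(names) - set(self.data.columns))
            if missing:
                raise ValueError(f"cohort is missing columns: {missing}")
            self.data = self.data.loc[:, names]
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate participant ids: {dupes}")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing values in columns: {bad}")
        values = self.data.to_numpy(dtype=float)
        sds = values.std(axis=0, ddof=1) if len(self.data) > 1 else np.ones(values.shape[1])
        zero_var = [n for n, s in zip(names, sds) if not s > 0]
        if zero_var:
            raise ValueError(
                f"zero-variance columns (cannot be z-scored): {zero_var}"
            )

    @property
    def participant_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_participants(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


def load_cohort(path: str | Path, registry: list[VariableSpec]) -> CohortTable:
    """Read and validate a cohort CSV.

    The file must contain a ``participant_id`` column plus one numeric
    column per registry variable; extra columns are ignored, column order is
    normalized to registry order. Raises ``ValueError`` naming the offending
    column/id for missing columns, non-numeric cells, duplicate ids and
    zero-variance columns.
    """
    frame = pd.read_csv(path)
    if ID_COLUMN not in frame.columns:
        raise ValueError(f"cohort file {path} has no {ID_COLUMN!r} column")
    frame = frame.set_index(ID_COLUMN)
    names = registry_names(registry)
    missing = [n for n in names if n not in frame.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns: {missing}")
    frame = frame.loc[:, names]
    for name in names:
        col = pd.to_numeric(frame[name], errors="coerce")
        bad = frame.index[col.isna() & frame[name].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value in column {name!r} at participant(s) {list(bad)}"
            )
        frame[name] = col
    return CohortTable(frame, registry)


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.data.rename_axis(ID_COLUMN).to_csv(path)
    return path


@dataclass
class ResultBundle:
    """All tabular outputs of one pipeline run."""

    global_metrics: pd.DataFrame
    node_centrality: pd.DataFrame
    edge_centrality: pd.DataFrame
    influential_edges: dict[str, Any]
    correlations: pd.DataFrame
    run_record: dict[str, Any] = field(default_factory=dict)


_CSV_MEMBERS = ("global_metrics", "node_centrality", "edge_centrality", "correlations")


def write_results(results: ResultBundle, out_dir: str | Path) -> list[Path]:
    """Write the five result tables to ``out_dir``; returns written paths.

    CSV values round-trip through ``float_format='%.17g'`` so reloading
    reproduces them bit-exactly; the influential edge set is JSON.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for member in _CSV_MEMBERS:
        path = out_dir / f"{member}.csv"
        getattr(results, member).to_csv(path, index=False, float_format="%.17g")
        written.append(path)
    path = out_dir / "influential_edges.json"
    path.write_text(json.dumps(results.influential_edges, indent=2))
    written.append(path)
    log.info("wrote %d result files to %s", len(written), out_dir)
    return written


def read_results(out_dir: str | Path) -> ResultBundle:
    """Reload a results directory written by :func:`write_results`."""
    out_dir = Path(out_dir)
    tables = {m: pd.read_csv(out_dir / f"{m}.csv") for m in _CSV_MEMBERS}
    edges = json.loads((out_dir / "influential_edges.json").read_text())
    record_path = out_dir / "run_record.json"
    record = json.loads(record_path.read_text()) if record_path.exists() else {}
    return ResultBundle(influential_edges=edges, run_record=record, **tables)
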