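"""Replica-pooled coordination counts and per-ligand occupancy tables.

Per-frame quantities are first averaged within each replica; means and
standard errors are then taken *across* replicas (sample sd with n-1).  A
single replica reports its dispersion as undefined (None), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .shells import ShellAssignment


def _sem(values: np.ndarray) -> float | None:
    if len(values) < 2:
        return None
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


@dataclass(frozen=True)
class CoordinationSummary:
    """Mean +/- SEM (across replicas) of shell population counts."""

    per_replica: pd.DataFrame  # one row per replica, columns <kind>_<shell>
    mean: dict[str, float]
    sem: dict[str, float | None]
    n_replicas: int


_COUNT_COLUMNS = (
    "protein_first",
    "protein_second",
    "protein_total",
    "water_first",
    "water_second",
    "water_total",
)


def coordination_counts(assignments: Sequence[ShellAssignment]) -> CoordinationSummary:
    """Replica-averaged coordination numbers in first, second and total shells."""
    if not assignments:
        raise ValueError("at least one replica assignment required")
    rows = []
    for a in assignments:
        rows.append(
            {
                "replica": a.trajectory.replica,
                "protein_first": float(a.first_protein.sum(axis=1).mean()),
                "protein_second": float(a.second_protein.sum(axis=1).mean()),
                "protein_total": float(a.total_protein().sum(axis=1).mean()),
                "water_first": float(a.first_water.sum(axis=1).mean()),
                "water_second": float(a.second_water.sum(axis=1).mean()),
                "water_total": float(a.total_water().sum(axis=1).mean()),
            }
        )
    df = pd.DataFrame(rows).set_index("replica")
    mean = {c: float(df[c].mean()) for c in _COUNT_COLUMNS}
    sem = {c: _sem(df[c].to_numpy()) for c in _COUNT_COLUMNS}
    return CoordinationSummary(per_replica=df, mean=mean, sem=sem, n_replicas=len(df))


@dataclass(frozen=True)
class OccupancyTable:
    """Per-ligand occupancy percentages, per replica and pooled."""

    per_replica: pd.DataFrame  # MultiIndex (replica, ligand): first_pct, total_pct
    pooled: pd.DataFrame       # index ligand: first_mean/sem, total_mean/sem
    n_replicas: int

    def to_csv(self, path) -> None:
        self.pooled.to_csv(path)


def occupancy_table(assignments: Sequence[ShellAssignment]) -> OccupancyTable:
    """Percent of frames each protein ligand spends in the first / total shell."""
    if not assignments:
        raise ValueError("at least one replica assignment required")
    ligands = [a.id for a in assignments[0].trajectory.atoms if a.role == "protein_ligand"]
    if not ligands:
        raise ValueError("no protein_ligand atoms to tabulate")
    rows = []
    for a in assignments:
        if a.n_frames == 0:
            raise ValueError(f"replica {a.trajectory.replica}: zero retained frames")
        lig_idx = a.ligand_indices()
        ids = [a.trajectory.atoms[i].id for i in lig_idx]
        if ids != ligands:
            raise ValueError("replicas disagree on the protein ligand atoms")
        first = 100.0 * a.first_protein[:, lig_idx].mean(axis=0)
        total = 100.0 * a.total_protein()[:, lig_idx].mean(axis=0)
        for lig, f, t in zip(ligands, first, total):
            rows.append(
                {
                    "replica": a.trajectory.replica,
                    "ligand": lig,
                    "first_pct": float(f),
                    "total_pct": float(t),
                }
            )
    per_replica = pd.DataFrame(rows).set_index(["replica", "ligand"])
    pooled_rows = []
    for lig in ligands:
        sub = per_replica.xs(lig, level="ligand")
        pooled_rows.append(
            {
                "ligand": lig,
                "first_mean": float(sub["first_pct"].mean()),
                "first_sem": _sem(sub["first_pct"].to_numpy()),
                "total_mean": float(sub["total_pct"].mean()),
                "total_sem": _sem(sub["total_pct"].to_numpy()),
            }
        )
    pooled = pd.DataFrame(pooled_rows).set_index("ligand")
    return OccupancyTable(per_replica=per_replica, pooled=pooled, n_replicas=len(assignments))
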