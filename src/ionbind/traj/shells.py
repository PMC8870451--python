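"""Coordination-shell assignment around the ion.

Rules (distances to the ion):
  * first-shell protein ligand:   d <= first_shell_protein (2.8 Å)
  * first-shell water oxygen:     d <= first_shell_water (3.0 Å)
  * second-shell water oxygen:    first_shell_water < d <= second_shell (6 Å)
  * second-shell protein ligand:  first_shell_protein < d <= second_shell AND
    at least one first-shell water within ``bridge_water`` (3 Å) of that
    protein atom in the same frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AnalysisParams, Trajectory, TrajectoryError, ion_distances


@dataclass(frozen=True)
class ShellAssignment:
    """Per-frame boolean membership masks, shape (n_frames, n_atoms)."""

    trajectory: Trajectory
    first_protein: np.ndarray
    first_water: np.ndarray
    second_protein: np.ndarray
    second_water: np.ndarray

    def __post_init__(self) -> None:
        shape = (self.trajectory.n_frames, self.trajectory.n_atoms)
        for name in ("first_protein", "first_water", "second_protein", "second_water"):
            arr = getattr(self, name)
            if arr.shape != shape or arr.dtype != bool:
                raise ValueError(f"{name} must be a bool mask of shape {shape}")
        if np.any(self.first_protein & self.second_protein) or np.any(
            self.first_water & self.second_water
        ):
            raise ValueError("first and second shells must be disjoint")

    @property
    def n_frames(self) -> int:
        return self.trajectory.n_frames

    def total_protein(self) -> np.ndarray:
        return self.first_protein | self.second_protein

    def total_water(self) -> np.ndarray:
        return self.first_water | self.second_water

    def ligand_indices(self) -> np.ndarray:
        return self.trajectory.indices_with_role("protein_ligand")


def assign_shells(traj: Trajectory, params: AnalysisParams | None = None) -> ShellAssignment:
    """Assign every protein ligand and water oxygen to a coordination shell."""
    params = params if params is not None else AnalysisParams()
    prot = traj.indices_with_role("protein_ligand")
    wat = traj.indices_with_role("water_oxygen")
    if len(prot) == 0 and len(wat) == 0:
        raise TrajectoryError(
            "no atoms with role 'protein_ligand' or 'water_oxygen'; roles missing?"
        )
    d = ion_distances(traj)  # raises if the ion is absent
    n_frames, n_atoms = d.shape

    first_protein = np.zeros((n_frames, n_atoms), dtype=bool)
    first_water = np.zeros((n_frames, n_atoms), dtype=bool)
    second_protein = np.zeros((n_frames, n_atoms), dtype=bool)
    second_water = np.zeros((n_frames, n_atoms), dtype=bool)

    if len(wat):
        dw = d[:, wat]
        first_water[:, wat] = dw <= params.first_shell_water
        second_water[:, wat] = (dw > params.first_shell_water) & (dw <= params.second_shell)

    if len(prot):
        dp = d[:, prot]
        first_protein[:, prot] = dp <= params.first_shell_protein
        candidate = (dp > params.first_shell_protein) & (dp <= params.second_shell)
        if np.any(candidate) and len(wat):
            # bridging: candidate protein atom within bridge_water of a
            # first-shell water in the same frame
            pw = np.linalg.norm(
                traj.coords[:, prot, None, :] - traj.coords[:, None, wat, :], axis=3
            )  # (frames, n_prot, n_wat)
            fw = first_water[:, wat]  # (frames, n_wat)
            bridged = np.any((pw <= params.bridge_water) & fw[:, None, :], axis=2)
            second_protein[:, prot] = candidate & bridged

    return ShellAssignment(
        trajectory=traj,
        first_protein=first_protein,
        first_water=first_water,
        second_protein=second_protein,
        second_water=second_water,
    )
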