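"""Trajectory container and analysis parameters.

A :class:`Trajectory` is a stack of coordinate frames over a fixed atom table.
Atoms carry a functional ``role`` used by the shell / H-bond analyses instead
of force-field typing: the ion itself, electronegative protein ligands, water
oxygens, H-bond donors/hydrogens/acceptors, or ``other``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

ROLES = ("ion", "protein_ligand", "water_oxygen", "donor", "hydrogen", "acceptor", "other")


@dataclass(frozen=True)
class Atom:
    """Static per-atom metadata."""

    id: str
    name: str
    role: str
    resname: str = "UNK"
    resid: int = 1

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"atom {self.id!r}: unknown role {self.role!r}; expected one of {ROLES}")


class TrajectoryError(ValueError):
    """Malformed trajectory (shape, ordering or role defects)."""


@dataclass(frozen=True)
class Trajectory:
    atoms: tuple[Atom, ...]
    coords: np.ndarray  # (n_frames, n_atoms, 3), Å
    times: np.ndarray   # (n_frames,), ns
    replica: str = "0"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise TrajectoryError(f"coords must be (frames, atoms, 3), got {coords.shape}")
        if coords.shape[1] != len(self.atoms):
            raise TrajectoryError(
                f"{len(self.atoms)} atoms declared but frames carry {coords.shape[1]}"
            )
        if len(times) != coords.shape[0]:
            raise TrajectoryError("one timestamp per frame required")
        if len(times) == 0:
            raise TrajectoryError("trajectory has no frames")
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise TrajectoryError("times must be strictly increasing")
        ids = [a.id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise TrajectoryError("atom ids must be unique")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "times", times)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index_of(self, atom_id: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.id == atom_id:
                return i
        raise KeyError(f"no atom with id {atom_id!r}")

    def indices_with_role(self, role: str) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.role == role], dtype=int)

    def ion_index(self) -> int:
        ions = self.indices_with_role("ion")
        if len(ions) == 0:
            raise TrajectoryError("trajectory has no atom with role 'ion'")
        if len(ions) > 1:
            raise TrajectoryError(f"trajectory has {len(ions)} ion atoms; exactly one expected")
        return int(ions[0])

    def with_replica(self, replica: str) -> "Trajectory":
        return replace(self, replica=replica)


@dataclass(frozen=True)
class AnalysisParams:
    """Geometric cutoffs for coordination-shell, H-bond and rotamer analyses."""

    first_shell_protein: float = 2.8  # Å
    first_shell_water: float = 3.0    # Å
    second_shell: float = 6.0         # Å
    bridge_water: float = 3.0         # Å, water-to-protein-atom bridging distance
    hbond_dist: float = 3.5           # Å, donor-acceptor
    hbond_angle_dev: float = 30.0     # deg, deviation of D-H...A from linearity
    rotamer_filter_window: float = 50.0  # ns

    def __post_init__(self) -> None:
        if not (0 < self.first_shell_protein < self.second_shell):
            raise ValueError("require 0 < first_shell_protein < second_shell")
        if not (0 < self.first_shell_water <= self.second_shell):
            raise ValueError("require 0 < first_shell_water <= second_shell")
        if not (0.0 < self.hbond_angle_dev < 90.0):
            raise ValueError("hbond_angle_dev must be in (0, 90) degrees")
        if self.hbond_dist <= 0 or self.bridge_water <= 0:
            raise ValueError("distance cutoffs must be positive")


def check_whole(traj: Trajectory, max_extent: float = 200.0) -> None:
    """Reject frames whose bounding box implies broken (unwrapped) molecules."""
    spans = traj.coords.max(axis=1) - traj.coords.min(axis=1)  # (frames, 3)
    bad = np.nonzero(np.any(spans > max_extent, axis=1))[0]
    if len(bad):
        raise TrajectoryError(
            f"frame {int(bad[0])}: atom spread {spans[bad[0]].max():.1f} Å exceeds "
            f"{max_extent} Å; coordinates look unwrapped/broken"
        )


def ion_distances(traj: Trajectory) -> np.ndarray:
    """Distance of every atom to the ion, per frame: shape (n_frames, n_atoms)."""
    ion = traj.ion_index()
    delta = traj.coords - traj.coords[:, ion : ion + 1, :]
    return np.linalg.norm(delta, axis=2)
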