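"""Ion RMSD after rigid-body superposition of an alignment selection.

Each frame is least-squares superposed (Kabsch) onto the reference using the
alignment atoms, and the displacement of the transformed ion from its
reference position is reported.  By default the reference is frame 0 and the
alignment selection is all protein-ligand atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Trajectory, TrajectoryError


def kabsch_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centered ``moving`` onto centered ``target``."""
    H = moving.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


@dataclass(frozen=True)
class IonRmsdResult:
    deviations: np.ndarray  # per frame, Å
    mean: float
    sd: float
    times: np.ndarray


def ion_rmsd(
    traj: Trajectory,
    reference: np.ndarray | None = None,
    align_indices: np.ndarray | None = None,
) -> IonRmsdResult:
    """Per-frame deviation of the ion from its reference position.

    ``reference`` is a full coordinate set (n_atoms, 3); frame 0 by default.
    ``align_indices`` selects the atoms used for superposition; defaults to
    all protein-ligand atoms.  Fewer than three alignment atoms leave the
    superposition underdetermined and are rejected.
    """
    ion = traj.ion_index()
    if align_indices is None:
        align_indices = traj.indices_with_role("protein_ligand")
    align_indices = np.asarray(align_indices, dtype=int)
    if len(align_indices) < 3:
        raise TrajectoryError(
            f"superposition needs >= 3 alignment atoms, got {len(align_indices)}"
        )
    ref = traj.coords[0] if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != (traj.n_atoms, 3):
        raise TrajectoryError(f"reference must be ({traj.n_atoms}, 3), got {ref.shape}")

    ref_sel = ref[align_indices]
    ref_centroid = ref_sel.mean(axis=0)
    ref_ion = ref[ion]

    deviations = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        sel = traj.coords[f, align_indices]
        centroid = sel.mean(axis=0)
        R = kabsch_rotation(sel - centroid, ref_sel - ref_centroid)
        ion_aligned = R @ (traj.coords[f, ion] - centroid) + ref_centroid
        deviations[f] = np.linalg.norm(ion_aligned - ref_ion)

    return IonRmsdResult(
        deviations=deviations,
        mean=float(deviations.mean()),
        sd=float(deviations.std(ddof=1)) if traj.n_frames > 1 else 0.0,
        times=traj.times,
    )
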