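"""Side-chain dihedral angles and rotamer-state classification.

Bin edges (the three chi1 wells at 180, +60 and -60 degrees):
  trans: |chi1| > 120;  g+: chi1 in (0, 120];  g-: chi1 in (-120, 0].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import Trajectory, TrajectoryError

TRANS, G_PLUS, G_MINUS = "trans", "g+", "g-"
ROTAMER_STATES = (TRANS, G_PLUS, G_MINUS)

#: cross products below this norm mean colinear atoms -> undefined dihedral
_COLINEAR_TOL = 1e-8


def dihedral_angles(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Signed dihedral (deg, in (-180, 180]) for stacked frames; IUPAC sign.

    Returns ``(angles, defined)`` where ``defined`` is False for frames with
    colinear atoms (angle undefined, reported as NaN).
    """
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    defined = (np.linalg.norm(n1, axis=-1) > _COLINEAR_TOL) & (
        np.linalg.norm(n2, axis=-1) > _COLINEAR_TOL
    )
    b1n = b1 / np.maximum(np.linalg.norm(b1, axis=-1, keepdims=True), 1e-300)
    m1 = np.cross(n1, b1n)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    # sign flipped so the result follows the IUPAC convention (clockwise
    # positive looking from p1 towards p2)
    ang = np.degrees(np.arctan2(-y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    ang = np.where(defined, ang, np.nan)
    return ang, defined


def classify_chi1(angles: np.ndarray) -> np.ndarray:
    """Map chi1 angles (deg) to rotamer labels; NaN maps to ''."""
    labels = np.full(angles.shape, "", dtype=object)
    with np.errstate(invalid="ignore"):
        labels[np.abs(angles) > 120.0] = TRANS
        labels[(angles > 0.0) & (angles <= 120.0)] = G_PLUS
        labels[(angles > -120.0) & (angles <= 0.0)] = G_MINUS
    return labels


@dataclass(frozen=True)
class ChiSeries:
    times: np.ndarray
    chi1: np.ndarray           # deg, NaN where undefined
    labels: np.ndarray         # rotamer labels, '' where undefined
    defined: np.ndarray        # bool mask
    chi2: np.ndarray | None = None

    def fractions(self) -> dict[str, float]:
        """Histogram fractions over the defined frames (sum to 1)."""
        n = int(self.defined.sum())
        if n == 0:
            raise ValueError("no defined frames to histogram")
        return {
            s: float(np.sum(self.labels[self.defined] == s)) / n for s in ROTAMER_STATES
        }

    def n_undefined(self) -> int:
        return int((~self.defined).sum())


def classify_rotamer(
    traj: Trajectory,
    chi1_atoms: Sequence[str],
    chi2_atoms: Sequence[str] | None = None,
) -> ChiSeries:
    """Chi1 (and optional chi2) series for the named atom quadruple(s).

    Frames with colinear atoms are flagged as undefined, not dropped.
    """
    if len(chi1_atoms) != 4:
        raise TrajectoryError(f"chi1 needs 4 atom ids, got {len(chi1_atoms)}")
    idx = [traj.index_of(a) for a in chi1_atoms]
    pts = [traj.coords[:, i, :] for i in idx]
    chi1, defined = dihedral_angles(*pts)

    chi2 = None
    if chi2_atoms is not None:
        if len(chi2_atoms) != 4:
            raise TrajectoryError(f"chi2 needs 4 atom ids, got {len(chi2_atoms)}")
        idx2 = [traj.index_of(a) for a in chi2_atoms]
        chi2, defined2 = dihedral_angles(*(traj.coords[:, i, :] for i in idx2))
        defined = defined & defined2

    return ChiSeries(
        times=traj.times,
        chi1=chi1,
        labels=classify_chi1(chi1),
        defined=defined,
        chi2=chi2,
    )
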