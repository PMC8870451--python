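"""Charge systems and Poisson-Boltzmann parameters.

A :class:`ChargeSystem` is the solver-facing view of a molecule: positions,
partial charges and radii, read from / written to PQR-style text.  Defaults in
:class:`PBParams` follow the Gaussian smooth-dielectric protocol (eps_in 8,
sigma 0.7, 0.15 M, 1.8 grid points per Å, solute filling 70% of the box edge).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ..constants import DEFAULT_TEMPERATURE


@dataclass(frozen=True)
class ChargeAtom:
    """One atom: position (Å), partial charge (e), radius (Å)."""

    name: str
    position: tuple[float, float, float]
    charge: float
    radius: float
    resname: str = "UNK"
    resid: int = 1
    titratable: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"atom {self.name!r}: radius must be > 0, got {self.radius}")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates {self.position}")


@dataclass(frozen=True)
class ChargeSystem:
    """Collection of charged atoms, optionally flagging one as the ion."""

    atoms: tuple[ChargeAtom, ...]
    ion_index: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("ChargeSystem must contain at least one atom")
        if self.ion_index is not None and not (0 <= self.ion_index < len(self.atoms)):
            raise ValueError(f"ion_index {self.ion_index} out of range")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def extent(self) -> float:
        """Maximal axis-aligned solute dimension including atom radii (Å)."""
        pos, rad = self.positions, self.radii
        spans = (pos + rad[:, None]).max(axis=0) - (pos - rad[:, None]).min(axis=0)
        return float(spans.max())

    def translated(self, shift: Sequence[float]) -> "ChargeSystem":
        s = np.asarray(shift, dtype=float)
        atoms = tuple(
            dataclasses.replace(a, position=tuple(np.asarray(a.position) + s))
            for a in self.atoms
        )
        return dataclasses.replace(self, atoms=atoms)

    @staticmethod
    def from_arrays(
        positions: np.ndarray,
        charges: np.ndarray,
        radii: np.ndarray,
        names: Iterable[str] | None = None,
        **kwargs,
    ) -> "ChargeSystem":
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = len(positions)
        names = list(names) if names is not None else [f"A{i}" for i in range(n)]
        atoms = tuple(
            ChargeAtom(names[i], tuple(positions[i]), float(charges[i]), float(radii[i]))
            for i in range(n)
        )
        return ChargeSystem(atoms=atoms, **kwargs)


@dataclass(frozen=True)
class PBParams:
    """Finite-difference PB settings (Gaussian smooth dielectric)."""

    eps_in: float = 8.0
    eps_out: float = 80.0
    sigma: float = 0.7
    ionic_strength: float = 0.15  # mol/L
    scale: float = 1.8  # grid points per Å
    fill_ratio: float = 0.7  # solute extent / box edge
    grid_points: int | None = None  # per-axis node count; overrides fill_ratio
    temperature: float = DEFAULT_TEMPERATURE
    kappa_exclusion_density: float = 0.1  # no screening where solute density > this
    dielectric_model: str = "gaussian"  # "gaussian" (smooth) or "sharp" (two-dielectric)
    tolerance: float = 1e-6
    max_iterations: int = 20000

    def __post_init__(self) -> None:
        if self.dielectric_model not in ("gaussian", "sharp"):
            raise ValueError(
                f"dielectric_model must be 'gaussian' or 'sharp', got {self.dielectric_model!r}"
            )
        if not (1.0 <= self.eps_in <= self.eps_out):
            raise ValueError(f"require 1 <= eps_in <= eps_out, got {self.eps_in}, {self.eps_out}")
        if not (0.0 < self.sigma <= 1.0):
            raise ValueError(f"sigma must be in (0, 1], got {self.sigma}")
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if not (0.0 < self.fill_ratio < 1.0):
            raise ValueError(f"fill_ratio must be in (0, 1), got {self.fill_ratio}")
        if self.grid_points is not None and self.grid_points < 5:
            raise ValueError("grid_points must be >= 5")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")

    @property
    def spacing(self) -> float:
        return 1.0 / self.scale


# ---------------------------------------------------------------------------
# PQR I/O (whitespace dialect, as emitted by pdb2pqr and friends)
# ---------------------------------------------------------------------------

def read_pqr(path: str | Path) -> ChargeSystem:
    """Read a whitespace-separated PQR file into a :class:`ChargeSystem`."""
    atoms: list[ChargeAtom] = []
    for line in Path(path).read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        parts = line.split()
        # ATOM serial name resname [chain] resid x y z q r
        if len(parts) == 11:
            parts = parts[:4] + parts[5:]
        if len(parts) != 10:
            raise ValueError(f"unparseable PQR line: {line!r}")
        _, _, name, resname, resid, x, y, z, q, r = parts
        atoms.append(
            ChargeAtom(
                name=name,
                position=(float(x), float(y), float(z)),
                charge=float(q),
                radius=float(r),
                resname=resname,
                resid=int(resid),
            )
        )
    if not atoms:
        raise ValueError(f"no ATOM/HETATM records in {path}")
    return ChargeSystem(atoms=tuple(atoms))


def write_pqr(system: ChargeSystem, path: str | Path) -> None:
    lines = []
    for i, a in enumerate(system.atoms, start=1):
        x, y, z = a.position
        lines.append(
            f"ATOM  {i:5d} {a.name:<4s} {a.resname:<4s} {a.resid:4d}    "
            f"{x:10.4f}{y:10.4f}{z:10.4f} {a.charge:8.4f} {a.radius:7.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def merge_systems(*systems: ChargeSystem, label: str = "") -> ChargeSystem:
    """Concatenate systems atom-for-atom (used to form complex = receptor + ion)."""
    atoms: tuple[ChargeAtom, ...] = ()
    for s in systems:
        atoms = atoms + s.atoms
    return ChargeSystem(atoms=atoms, label=label)
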