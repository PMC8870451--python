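"""Binding and solvation energetics via grid-energy differences.

The electrostatic component of the ion binding free energy is the difference
of three PB runs -- complex, receptor alone, ion alone -- all performed on the
*identical* lattice so that the lattice self-energies cancel:

    dG_bind = E_grid(complex) - E_grid(receptor) - E_grid(ion)
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .energy import grid_energy
from .grids import GridGeometry, build_grids, grid_occupancy, plan_geometry
from .model import ChargeSystem, PBParams
from .solver import solve_lpb

#: solute may occupy at most this fraction of the box edge before a warning
OCCUPANCY_WARN_FRACTION = 0.70


class SystemMismatchError(ValueError):
    """Complex does not decompose atom-for-atom into receptor + ion."""


def _check_decomposition(
    complex_: ChargeSystem, receptor: ChargeSystem, ion: ChargeSystem, tol: float = 1e-6
) -> None:
    if len(complex_) != len(receptor) + len(ion):
        raise SystemMismatchError(
            f"complex has {len(complex_)} atoms, receptor+ion have "
            f"{len(receptor) + len(ion)}"
        )
    merged_pos = np.vstack([receptor.positions, ion.positions])
    merged_q = np.concatenate([receptor.charges, ion.charges])
    merged_r = np.concatenate([receptor.radii, ion.radii])
    if (
        not np.allclose(complex_.positions, merged_pos, atol=tol)
        or not np.allclose(complex_.charges, merged_q, atol=tol)
        or not np.allclose(complex_.radii, merged_r, atol=tol)
    ):
        raise SystemMismatchError(
            "receptor + ion must reproduce the complex coordinates, charges and "
            "radii exactly (same-position-in-the-box requirement)"
        )


def binding_energy(
    complex_: ChargeSystem,
    receptor: ChargeSystem,
    ion: ChargeSystem,
    params: PBParams,
    geometry: GridGeometry | None = None,
) -> float:
    """Three-run grid-energy-difference binding energy in kT.

    The complex defines the lattice; the receptor-only and ion-only runs reuse
    it verbatim.  Raises :class:`SystemMismatchError` unless the complex is
    exactly receptor followed by ion.
    """
    _check_decomposition(complex_, receptor, ion)
    geom = geometry if geometry is not None else plan_geometry(complex_, params)
    occ = grid_occupancy(complex_, geom)
    if occ >= OCCUPANCY_WARN_FRACTION:
        warnings.warn(
            f"solute occupies {100 * occ:.0f}% of the box edge "
            f"(>= {100 * OCCUPANCY_WARN_FRACTION:.0f}%); enlarge the grid",
            stacklevel=2,
        )
    energies = {}
    for key, system in (("complex", complex_), ("receptor", receptor), ("ion", ion)):
        grid = build_grids(system, params, geometry=geom)
        energies[key] = grid_energy(solve_lpb(grid), grid)
    return energies["complex"] - energies["receptor"] - energies["ion"]


def solvation_energy(
    system: ChargeSystem, params: PBParams, geometry: GridGeometry | None = None
) -> float:
    """Reaction-field (solvation) energy in kT.

    Difference of two identical-lattice runs: solvent dielectric ``eps_out``
    minus a homogeneous reference with ``eps_out == eps_in``; self-energies
    cancel, leaving the Born-type solvation term.
    """
    geom = geometry if geometry is not None else plan_geometry(system, params)
    grid = build_grids(system, params, geometry=geom)
    e_solv = grid_energy(solve_lpb(grid), grid)
    ref_params = dataclasses.replace(params, eps_out=params.eps_in, ionic_strength=0.0)
    ref_grid = build_grids(system, ref_params, geometry=geom)
    e_ref = grid_energy(solve_lpb(ref_grid), ref_grid)
    return e_solv - e_ref


@dataclass(frozen=True)
class BindingEnergyReport:
    """Boxplot summary of per-snapshot binding energies plus the coordination fit."""

    energies: tuple[float, ...]           # all snapshots pooled (kT)
    per_trajectory_mean: tuple[float, ...]
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float
    mean: float
    r_squared: float | None               # mean dG vs mean first-shell coordination
    slope: float | None
    intercept: float | None

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles out of order")


def _least_squares_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(np.clip(r2, 0.0, 1.0)), float(slope), float(intercept)


def aggregate_binding(
    per_trajectory_energies: Sequence[Sequence[float]],
    coordination_means: Sequence[float] | None = None,
    grid_occupancies: Sequence[float] | None = None,
) -> BindingEnergyReport:
    """Pool per-snapshot binding energies into a boxplot-style report.

    ``coordination_means`` (one mean first-shell protein coordination per
    trajectory) enables the least-squares R^2 between per-trajectory mean
    binding energy and coordination; with fewer than two trajectories the
    correlation is reported as ``None``, never fabricated.
    """
    if not per_trajectory_energies or any(len(t) == 0 for t in per_trajectory_energies):
        raise ValueError("every trajectory must contribute at least one snapshot")
    if grid_occupancies is not None:
        for i, occ in enumerate(grid_occupancies):
            if occ >= OCCUPANCY_WARN_FRACTION:
                warnings.warn(
                    f"trajectory {i}: solute grid occupancy {100 * occ:.0f}% >= "
                    f"{100 * OCCUPANCY_WARN_FRACTION:.0f}%",
                    stacklevel=2,
                )
    pooled = np.concatenate([np.asarray(t, dtype=float) for t in per_trajectory_energies])
    traj_means = np.array([float(np.mean(t)) for t in per_trajectory_energies])

    r2 = slope = intercept = None
    if coordination_means is not None:
        coord = np.asarray(coordination_means, dtype=float)
        if len(coord) != len(traj_means):
            raise ValueError("one coordination mean per trajectory required")
        if len(coord) >= 2 and np.ptp(coord) > 0:
            r2, slope, intercept = _least_squares_r2(coord, traj_means)

    q1, med, q3 = np.percentile(pooled, [25, 50, 75])
    return BindingEnergyReport(
        energies=tuple(float(v) for v in pooled),
        per_trajectory_mean=tuple(float(v) for v in traj_means),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        minimum=float(pooled.min()),
        maximum=float(pooled.max()),
        mean=float(pooled.mean()),
        r_squared=r2,
        slope=slope,
        intercept=intercept,
    )
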