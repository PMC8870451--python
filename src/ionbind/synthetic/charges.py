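"""Toy charge systems with closed-form electrostatics for solver oracles."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ..constants import DEFAULT_TEMPERATURE, coulomb_kt
from ..pb.model import ChargeSystem

KINDS = ("point", "born", "dipole", "two_body")


@dataclass(frozen=True)
class SyntheticChargeSystem:
    """A charge system plus its closed-form reference where one exists."""

    kind: str
    system: ChargeSystem
    reference_energy: float | None            # kT (solvation for born, interaction for two_body)
    reference_potential: Callable[[np.ndarray], np.ndarray] | None  # kT/e at points (Å)


def gen_charge_system(
    kind: str,
    q: float = 1.0,
    radius: float = 2.0,
    eps_in: float = 2.0,
    eps_out: float = 80.0,
    separation: float = 5.0,
    q2: float = -1.0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> SyntheticChargeSystem:
    """Build a point / born / dipole / two_body oracle system.

    * ``point``: single charge; reference potential is Coulomb in a
      homogeneous ``eps_out`` medium (zero everywhere for q = 0).
    * ``born``: single ion of radius ``radius``; reference energy is the Born
      solvation energy -(q^2 C / 2 radius)(1/eps_in - 1/eps_out) in kT.
    * ``dipole``: +q/-q pair ``separation`` apart; reference potential is the
      two-center Coulomb sum in homogeneous ``eps_out``.
    * ``two_body``: charges q and q2 ``separation`` apart; reference energy is
      the Coulomb interaction q*q2*C/(eps_out*separation).
    """
    C = coulomb_kt(temperature)
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if kind == "point":
        system = ChargeSystem.from_arrays([[0.0, 0.0, 0.0]], [q], [radius], label="point")

        def phi(points: np.ndarray) -> np.ndarray:
            r = np.linalg.norm(np.atleast_2d(points), axis=1)
            return C * q / (eps_out * r)

        return SyntheticChargeSystem("point", system, None, phi if q != 0 else (lambda p: np.zeros(len(np.atleast_2d(p)))))
    if kind == "born":
        system = ChargeSystem.from_arrays([[0.0, 0.0, 0.0]], [q], [radius], label="born")
        energy = -(q * q * C / (2.0 * radius)) * (1.0 / eps_in - 1.0 / eps_out)
        return SyntheticChargeSystem("born", system, energy, None)
    if kind == "dipole":
        half = separation / 2.0
        system = ChargeSystem.from_arrays(
            [[-half, 0.0, 0.0], [half, 0.0, 0.0]], [q, -q], [radius, radius], label="dipole"
        )

        def phi_dipole(points: np.ndarray) -> np.ndarray:
            pts = np.atleast_2d(points)
            r1 = np.linalg.norm(pts - np.array([-half, 0.0, 0.0]), axis=1)
            r2 = np.linalg.norm(pts - np.array([half, 0.0, 0.0]), axis=1)
            return C * q / eps_out * (1.0 / r1 - 1.0 / r2)

        return SyntheticChargeSystem("dipole", system, None, phi_dipole)
    if kind == "two_body":
        if separation <= 0:
            raise ValueError("separation must be > 0")
        system = ChargeSystem.from_arrays(
            [[0.0, 0.0, 0.0], [separation, 0.0, 0.0]], [q, q2], [radius, radius], label="two_body"
        )
        energy = q * q2 * C / (eps_out * separation)
        return SyntheticChargeSystem("two_body", system, energy, None)
    raise ValueError(f"unknown charge-system kind {kind!r}; expected one of {KINDS}")
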