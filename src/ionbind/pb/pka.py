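"""Single-site pKa shifts from continuum electrostatics.

The shift of a titratable site relative to its model compound is

    pKa = pKa_model + ddG / (ln(10) kT)

with ddG the deprotonation free-energy difference (protein minus model
compound), each obtained as an identical-lattice grid-energy difference
between the deprotonated and protonated charge states.  Destabilization of
the deprotonated (anionic) form of an acid raises its pKa; site-site
titration coupling is out of scope (single-site approximation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .energy import grid_energy
from .grids import build_grids, plan_geometry
from .model import ChargeSystem, PBParams
from .solver import solve_lpb

LN10 = math.log(10.0)

#: model-compound pKa values for common titratable side chains
MODEL_PKA = {
    "ASP": 4.0,
    "GLU": 4.4,
    "HIS": 6.3,
    "CYS": 8.3,
    "TYR": 9.6,
    "LYS": 10.4,
    "ARG": 12.0,
}


@dataclass(frozen=True)
class SiteStates:
    """Protonated/deprotonated charge systems for one environment (one frame)."""

    protonated: ChargeSystem
    deprotonated: ChargeSystem

    def __post_init__(self) -> None:
        if len(self.protonated) != len(self.deprotonated):
            raise ValueError(
                "protonated and deprotonated states must have the same atoms"
            )


@dataclass(frozen=True)
class PkaResult:
    residue: str
    model_pka: float
    per_frame_shift: tuple[float, ...]  # pK units
    per_frame_pka: tuple[float, ...]
    mean: float
    sd: float

    @property
    def n_frames(self) -> int:
        return len(self.per_frame_pka)


def _titrating_position(states: SiteStates) -> np.ndarray:
    """Position of the (first) atom whose charge differs between the states."""
    dq = states.deprotonated.charges - states.protonated.charges
    changed = np.nonzero(np.abs(dq) > 1e-12)[0]
    idx = int(changed[0]) if len(changed) else 0
    return states.deprotonated.positions[idx]


def _deprotonation_energy(states: SiteStates, params: PBParams) -> float:
    """G(deprotonated) - G(protonated), identical lattice (kT).

    The grid is centered on the titrating atom so that its lattice
    self-energy sits at the same sub-grid offset in the protein and the
    model-compound runs and cancels in the double difference.
    """
    geom = plan_geometry(states.deprotonated, params, center=_titrating_position(states))
    grid_d = build_grids(states.deprotonated, params, geometry=geom)
    grid_p = build_grids(states.protonated, params, geometry=geom)
    return grid_energy(solve_lpb(grid_d), grid_d) - grid_energy(solve_lpb(grid_p), grid_p)


def pka_from_shifts(
    residue: str, model_pka: float, ddg_kt: Sequence[float]
) -> PkaResult:
    """Assemble a :class:`PkaResult` from precomputed per-frame ddG values (kT)."""
    shifts = tuple(float(d) / LN10 for d in ddg_kt)
    pkas = tuple(model_pka + s for s in shifts)
    arr = np.asarray(pkas)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return PkaResult(
        residue=residue,
        model_pka=model_pka,
        per_frame_shift=shifts,
        per_frame_pka=pkas,
        mean=float(arr.mean()),
        sd=sd,
    )


def pka(
    residue: str,
    protein_frames: Sequence[SiteStates],
    model_compound: SiteStates,
    params: PBParams,
    model_pka: float | None = None,
) -> PkaResult:
    """Single-site pKa of ``residue`` over trajectory frames (the protocol uses 7).

    ``protein_frames`` supplies protonated/deprotonated systems of the site in
    its protein environment for each frame; ``model_compound`` is the isolated
    reference in pure solvent.  ``model_pka`` defaults to the tabulated value
    for the residue name.
    """
    if model_pka is None:
        try:
            model_pka = MODEL_PKA[residue.upper()[:3]]
        except KeyError:
            raise ValueError(
                f"no model pKa tabulated for {residue!r}; pass model_pka explicitly"
            ) from None
    if not protein_frames:
        raise ValueError("at least one protein frame is required")
    dg_model = _deprotonation_energy(model_compound, params)
    ddg = [
        _deprotonation_energy(frame, params) - dg_model for frame in protein_frames
    ]
    return pka_from_shifts(residue, model_pka, ddg)
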