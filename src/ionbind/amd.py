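"""Dual-boost accelerated-MD parameterization.

Thresholds are the window averages of the classical-MD dihedral and total
potential energies ("soft" protocol); the acceleration factors are

    alpha_dihed = lambda * E_dihed_avg / 5
    alpha_pot   = lambda * N

with N the number of atoms in the system.  The boost applied below a
threshold E is dV = (E - V)^2 / (alpha + E - V), zero at and above E.
Reweighting of accelerated trajectories is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EnergySeries:
    """Per-frame dihedral and total potential energies (kcal/mol) vs time (ns)."""

    times: np.ndarray
    dihedral: np.ndarray
    potential: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.dihedral, dtype=float)
        p = np.asarray(self.potential, dtype=float)
        if not (len(t) == len(d) == len(p)):
            raise ValueError("times, dihedral and potential must have equal length")
        if len(t) == 0:
            raise ValueError("energy series is empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "dihedral", d)
        object.__setattr__(self, "potential", p)

    def __len__(self) -> int:
        return len(self.times)

    @staticmethod
    def from_csv(path: str | Path) -> "EnergySeries":
        df = pd.read_csv(path)
        required = {"time", "dihedral", "potential"}
        if not required.issubset(df.columns):
            raise ValueError(f"CSV must have columns {sorted(required)}, got {list(df.columns)}")
        return EnergySeries(
            df["time"].to_numpy(), df["dihedral"].to_numpy(), df["potential"].to_numpy()
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time": self.times, "dihedral": self.dihedral, "potential": self.potential}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class BoostParams:
    e_dihed_avg: float  # kcal/mol
    e_pot_avg: float    # kcal/mol
    alpha_dihed: float  # kcal/mol
    alpha_pot: float    # kcal/mol
    lambda_factor: float
    n_atoms: int

    def __post_init__(self) -> None:
        if self.alpha_dihed < 0 or self.alpha_pot < 0:
            raise ValueError("acceleration factors must be >= 0")
        if not (0.0 < self.lambda_factor <= 1.0):
            raise ValueError(f"lambda must be in (0, 1], got {self.lambda_factor}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    def to_namd_snippet(self) -> str:
        """Key/value block in the style of an MD engine's aMD configuration."""
        return "\n".join(
            [
                "accelMD            on",
                "accelMDdual        on",
                f"accelMDE           {self.e_dihed_avg:.4f}",
                f"accelMDalpha       {self.alpha_dihed:.4f}",
                f"accelMDTE          {self.e_pot_avg:.4f}",
                f"accelMDTalpha      {self.alpha_pot:.4f}",
            ]
        )


def boost_params(
    series: EnergySeries,
    window: tuple[float, float] = (20.0, 120.0),
    lambda_factor: float = 0.3,
    n_atoms: int = 1,
) -> BoostParams:
    """Compute dual-boost thresholds and acceleration factors.

    ``window`` is the (start, end) time interval in ns over which the
    classical-MD averages are taken (inclusive on both ends).
    """
    if n_atoms < 1:
        raise ValueError(f"n_atoms must be >= 1, got {n_atoms}")
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty window {window}")
    mask = (series.times >= lo) & (series.times <= hi)
    if not np.any(mask):
        raise ValueError(
            f"window {window} ns selects no frames from series spanning "
            f"[{series.times[0]}, {series.times[-1]}] ns"
        )
    e_dihed = float(series.dihedral[mask].mean())
    e_pot = float(series.potential[mask].mean())
    return BoostParams(
        e_dihed_avg=e_dihed,
        e_pot_avg=e_pot,
        alpha_dihed=lambda_factor * e_dihed / 5.0,
        alpha_pot=lambda_factor * n_atoms,
        lambda_factor=lambda_factor,
        n_atoms=n_atoms,
    )


def apply_boost(v, e_threshold: float, alpha: float):
    """Boost energy dV for potential value(s) ``v`` below threshold ``e_threshold``.

    dV = (E - V)^2 / (alpha + E - V) for V < E, else 0.  The boosted value
    V + dV never exceeds E, and dV is continuous (and zero) at V = E.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    v_arr = np.asarray(v, dtype=float)
    gap = e_threshold - v_arr
    dv = np.where(gap > 0, gap * gap / (alpha + np.abs(gap)), 0.0)
    if np.isscalar(v) or v_arr.ndim == 0:
        return float(dv)
    return dv
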