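"""Finite-difference solution of the linearized Poisson-Boltzmann equation.

Discretizes ``div(eps grad(phi)) - eps_out*kappa^2*phi = -4*pi*C*rho`` on the
7-point stencil with harmonic-mean face dielectrics, Debye-Hueckel monopole
boundary values, and a Jacobi-preconditioned conjugate-gradient solve.
Potentials are in kT/e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix, diags
from scipy.sparse.linalg import cg

from ..constants import coulomb_kt
from .grids import DielectricGrid, GridGeometry
from .model import PBParams


class ConvergenceError(RuntimeError):
    """CG failed to reach the requested residual within max_iterations."""


@dataclass(frozen=True)
class PotentialGrid:
    geometry: GridGeometry
    values: np.ndarray  # kT/e, shape == geometry.shape
    residual: float     # relative residual achieved by the solver

    def at(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the potential at Cartesian points (Å)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        geom = self.geometry
        frac = (points - np.asarray(geom.origin)) / geom.spacing
        if np.any(frac < 0) or np.any(frac > np.asarray(geom.shape) - 1):
            raise ValueError("interpolation point outside grid")
        base = np.minimum(np.floor(frac).astype(int), np.asarray(geom.shape) - 2)
        t = frac - base
        out = np.zeros(len(points))
        for di in (0, 1):
            wi = np.where(di == 0, 1 - t[:, 0], t[:, 0])
            for dj in (0, 1):
                wj = np.where(dj == 0, 1 - t[:, 1], t[:, 1])
                for dk in (0, 1):
                    wk = np.where(dk == 0, 1 - t[:, 2], t[:, 2])
                    out += (
                        wi * wj * wk
                        * self.values[base[:, 0] + di, base[:, 1] + dj, base[:, 2] + dk]
                    )
        return out


def debye_boundary(
    grid: DielectricGrid, coords: np.ndarray
) -> np.ndarray:
    """Sum of screened-monopole potentials of all charges at ``coords`` (kT/e)."""
    p = grid.params
    C = coulomb_kt(p.temperature)
    mk2 = float(np.max(grid.kappa2))
    kappa = math.sqrt(mk2 / p.eps_out) if mk2 > 0 else 0.0
    out = np.zeros(len(coords))
    for q, pos in zip(grid.system.charges, grid.system.positions):
        if q == 0.0:
            continue
        r = np.linalg.norm(coords - pos, axis=1)
        r = np.maximum(r, 1e-6)
        out += C * q * np.exp(-kappa * r) / (p.eps_out * r)
    return out


def _face_harmonic(e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    return 2.0 * e1 * e2 / (e1 + e2)


def solve_lpb(grid: DielectricGrid, params: PBParams | None = None) -> PotentialGrid:
    """Solve the linearized PB equation on ``grid``.

    Returns the potential on the full lattice (boundary faces carry the
    Debye-Hueckel values).  Raises :class:`ConvergenceError` when CG does not
    reach ``params.tolerance`` relative residual.
    """
    p = params if params is not None else grid.params
    geom = grid.geometry
    nx, ny, nz = geom.shape
    h = geom.spacing
    C = coulomb_kt(p.temperature)

    eps = grid.eps
    # face dielectrics along each axis
    fx = _face_harmonic(eps[:-1, :, :], eps[1:, :, :])
    fy = _face_harmonic(eps[:, :-1, :], eps[:, 1:, :])
    fz = _face_harmonic(eps[:, :, :-1], eps[:, :, 1:])

    # boundary values on all six faces
    u = np.zeros((nx, ny, nz), dtype=float)
    bmask = np.zeros((nx, ny, nz), dtype=bool)
    bmask[0, :, :] = bmask[-1, :, :] = True
    bmask[:, 0, :] = bmask[:, -1, :] = True
    bmask[:, :, 0] = bmask[:, :, -1] = True
    if np.any(grid.system.charges != 0.0):
        ii, jj, kk = np.nonzero(bmask)
        ax, ay, az = geom.axes()
        coords = np.column_stack([ax[ii], ay[jj], az[kk]])
        u[bmask] = debye_boundary(grid, coords)

    interior = ~bmask
    idx = -np.ones((nx, ny, nz), dtype=np.int64)
    n_int = int(interior.sum())
    idx[interior] = np.arange(n_int)

    diag = np.zeros((nx, ny, nz), dtype=float)
    rhs = np.zeros((nx, ny, nz), dtype=float)
    rhs[interior] = 4.0 * math.pi * C * grid.charge[interior] / h  # (q/h^3)*h^2

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def couple(face: np.ndarray, shift: tuple[int, int, int]) -> None:
        # face[p] couples node A = p and node B = p + shift
        si, sj, sk = shift
        sl_a = (slice(0, nx - si), slice(0, ny - sj), slice(0, nz - sk))
        sl_b = (slice(si, nx), slice(sj, ny), slice(sk, nz))
        diag[sl_a] += face
        diag[sl_b] += face
        int_a = interior[sl_a]
        int_b = interior[sl_b]
        idx_a = idx[sl_a]
        idx_b = idx[sl_b]
        both = int_a & int_b
        ra, cb, f = idx_a[both], idx_b[both], face[both]
        rows.append(ra)
        cols.append(cb)
        vals.append(-f)
        rows.append(cb)
        cols.append(ra)
        vals.append(-f)
        # one endpoint on the Dirichlet boundary: lift eps_f * u_b into the RHS
        a_only = int_a & ~int_b
        rhs[sl_a][a_only] += face[a_only] * u[sl_b][a_only]
        b_only = int_b & ~int_a
        rhs[sl_b][b_only] += face[b_only] * u[sl_a][b_only]

    couple(fx, (1, 0, 0))
    couple(fy, (0, 1, 0))
    couple(fz, (0, 0, 1))

    diag += h * h * grid.kappa2

    d_int = diag[interior]
    A = csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_int, n_int),
    )
    A = A + diags(d_int)
    b_int = rhs[interior]

    bnorm = float(np.linalg.norm(b_int))
    if bnorm == 0.0:
        sol = np.zeros(n_int)
        res = 0.0
    else:
        M = diags(1.0 / d_int)
        sol, info = cg(A, b_int, rtol=p.tolerance, atol=0.0, maxiter=p.max_iterations, M=M)
        res = float(np.linalg.norm(b_int - A @ sol)) / bnorm
        if info != 0:
            raise ConvergenceError(
                f"PB solve did not converge in {p.max_iterations} iterations "
                f"(relative residual {res:.3e})"
            )
    u[interior] = sol
    return PotentialGrid(geometry=geom, values=u, residual=res)


def write_dx(potential: PotentialGrid, path: str | Path) -> None:
    """Export the potential as an OpenDX scalar field (text)."""
    geom = potential.geometry
    nx, ny, nz = geom.shape
    h = geom.spacing
    n = nx * ny * nz
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {geom.origin[0]:.6f} {geom.origin[1]:.6f} {geom.origin[2]:.6f}",
        f"delta {h:.6f} 0.0 0.0",
        f"delta 0.0 {h:.6f} 0.0",
        f"delta 0.0 0.0 {h:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {n} data follows",
    ]
    flat = potential.values.reshape(-1)
    for i in range(0, n, 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    Path(path).write_text("\n".join(lines) + "\n")
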