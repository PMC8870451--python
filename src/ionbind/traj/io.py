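"""Trajectory serialization.

Topology+frames go to multi-model PDB; atom roles are encoded as a numeric
code in the occupancy column and documented in a sidecar JSON written next to
the PDB (`<stem>.roles.json`).  A plain whitespace XYZ-per-frame dialect is
also supported:

    n_atoms
    time <ns>
    <id> <x> <y> <z>      (one line per atom; metadata from a sidecar JSON)

Coordinates survive a round trip to the fixed precision of the format
(3 decimal places for PDB, 6 for XYZ).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import ROLES, Atom, Trajectory, TrajectoryError

_ROLE_CODE = {role: float(i) for i, role in enumerate(ROLES)}
_CODE_ROLE = {i: role for i, role in enumerate(ROLES)}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".roles.json")


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB; roles go to the occupancy column + sidecar JSON."""
    path = Path(path)
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for i, atom in enumerate(traj.atoms):
            x, y, z = traj.coords[f, i]
            code = _ROLE_CODE[atom.role]
            name = atom.name[:4]
            lines.append(
                f"ATOM  {i + 1:5d} {name:<4s} {atom.resname[:3]:<3s} A{atom.resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{code:6.2f}{0.0:6.2f}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "role_codes": {role: int(code) for role, code in _ROLE_CODE.items()},
        "replica": traj.replica,
        "times_ns": [float(t) for t in traj.times],
        "atoms": [
            {"id": a.id, "name": a.name, "role": a.role, "resname": a.resname, "resid": a.resid}
            for a in traj.atoms
        ],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1) + "\n")


def read_pdb(path: str | Path) -> Trajectory:
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise TrajectoryError(f"missing role sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    atoms = tuple(
        Atom(id=a["id"], name=a["name"], role=a["role"], resname=a["resname"], resid=a["resid"])
        for a in sidecar["atoms"]
    )
    frames: list[list[list[float]]] = []
    current: list[list[float]] | None = None
    for line in path.read_text().splitlines():
        if line.startswith("MODEL"):
            current = []
        elif line.startswith("ENDMDL"):
            if current is None:
                raise TrajectoryError("ENDMDL without MODEL")
            frames.append(current)
            current = None
        elif line.startswith(("ATOM", "HETATM")) and current is not None:
            current.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    if not frames:
        raise TrajectoryError(f"no MODEL frames in {path}")
    coords = np.asarray(frames, dtype=float)
    return Trajectory(
        atoms=atoms,
        coords=coords,
        times=np.asarray(sidecar["times_ns"], dtype=float),
        replica=str(sidecar.get("replica", "0")),
    )


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(str(traj.n_atoms))
        lines.append(f"time {traj.times[f]:.6f}")
        for i, atom in enumerate(traj.atoms):
            x, y, z = traj.coords[f, i]
            lines.append(f"{atom.id} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "replica": traj.replica,
        "atoms": [
            {"id": a.id, "name": a.name, "role": a.role, "resname": a.resname, "resid": a.resid}
            for a in traj.atoms
        ],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1) + "\n")


def read_xyz(path: str | Path) -> Trajectory:
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise TrajectoryError(f"missing role sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    atoms = tuple(
        Atom(id=a["id"], name=a["name"], role=a["role"], resname=a["resname"], resid=a["resid"])
        for a in sidecar["atoms"]
    )
    lines = path.read_text().splitlines()
    frames, times = [], []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        times.append(float(lines[i + 1].split()[1]))
        block = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            block.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(block)
        i += 2 + n
    return Trajectory(
        atoms=atoms,
        coords=np.asarray(frames, dtype=float),
        times=np.asarray(times, dtype=float),
        replica=str(sidecar.get("replica", "0")),
    )


def write_table_csv(df, path: str | Path, metadata: dict) -> None:
    """CSV with a JSON metadata header line (prefixed '#')."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#" + json.dumps(metadata, sort_keys=True) + "\n")
        df.to_csv(fh)


def read_table_metadata(path: str | Path) -> dict:
    with Path(path).open() as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError(f"{path} has no JSON metadata header")
    return json.loads(first[1:])
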