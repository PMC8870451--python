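"""Synthetic ion-site trajectories with planted, exactly recoverable truth.

Each ligand follows a per-frame membership schedule (first / second / none).
First-shell frames place the ligand at its nominal distance (validated to sit
at least 3*noise_sd inside the 2.8 Å cutoff); second-shell frames place it in
(2.8, 6] Å and put a dedicated bridging water on the ion-ligand axis within
3 Å of both; 'none' frames park it beyond both cutoffs.  Chi1 rotamer states
and H-bond on/off events are planted on dedicated atom groups far from the
ion.  Per-coordinate Gaussian noise is truncated at sqrt(3)*noise_sd so no
atom moves more than 3*noise_sd and planted memberships can never flip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ..traj.model import Atom, Trajectory

FIRST, SECOND, NONE = "first", "second", "none"
_SHELL_STATES = (FIRST, SECOND, NONE)

_CHI_TARGET = {"trans": 180.0, "g+": 60.0, "g-": -60.0}

#: chi1 quadruple planted in every generated trajectory
CHI_ATOM_IDS = ("CHI_N", "CHI_CA", "CHI_CB", "CHI_CG")


@dataclass(frozen=True)
class LigandSpec:
    """One protein electronegative ligand atom around the ion."""

    label: str
    nominal_distance: float = 2.5   # Å, used for first-shell frames
    second_distance: float = 4.5    # Å, used for second-shell frames
    none_distance: float = 8.0      # Å, used for out-of-shell frames
    role: str = "protein_ligand"


@dataclass(frozen=True)
class SiteTrajectorySpec:
    n_frames: int
    ligands: tuple[LigandSpec, ...]
    shell_schedule: Mapping[str, Sequence[str]]  # ligand label -> per-frame state
    frame_interval: float = 1.0  # ns
    ion_start: tuple[float, float, float] = (0.0, 0.0, 0.0)
    water_count: int = 0         # spectator waters beyond both shells
    chi_schedule: Sequence[str] | None = None
    hbond_schedule: Mapping[str, Sequence[bool]] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        labels = [lig.label for lig in self.ligands]
        if len(set(labels)) != len(labels):
            raise ValueError("ligand labels must be unique")
        if set(self.shell_schedule) != set(labels):
            raise ValueError("shell_schedule must cover exactly the declared ligands")


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-ligand occupancies, per-frame counts, rotamers and H-bonds."""

    first_occupancy: dict[str, float]   # fraction of frames in first shell
    total_occupancy: dict[str, float]   # first or second
    protein_first_counts: np.ndarray    # per frame
    protein_second_counts: np.ndarray
    water_first_counts: np.ndarray
    water_second_counts: np.ndarray
    chi_labels: tuple[str, ...] | None
    hbond_occupancy: dict[str, float]

    def __post_init__(self) -> None:
        for d in (self.first_occupancy, self.total_occupancy, self.hbond_occupancy):
            for k, v in d.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"occupancy fraction out of [0,1] for {k}: {v}")


def _validate_distances(spec: SiteTrajectorySpec, cutoffs) -> None:
    n = spec.noise_sd
    first_cut, water_cut, second_cut, bridge_cut = cutoffs
    for lig in spec.ligands:
        schedule = spec.shell_schedule[lig.label]
        if len(schedule) != spec.n_frames:
            raise ValueError(
                f"ligand {lig.label!r}: schedule has {len(schedule)} entries for "
                f"{spec.n_frames} frames"
            )
        for f, state in enumerate(schedule):
            if state not in _SHELL_STATES:
                raise ValueError(f"ligand {lig.label!r} frame {f}: unknown state {state!r}")
            if state == FIRST and lig.nominal_distance > first_cut - 3 * n:
                raise ValueError(
                    f"ligand {lig.label!r} frame {f}: first-shell distance "
                    f"{lig.nominal_distance} Å cannot stay under the {first_cut} Å "
                    f"cutoff with noise_sd {n}"
                )
            if state == SECOND:
                lo = first_cut + 3 * n
                hi = min(second_cut - 3 * n, 2 * bridge_cut - 9 * n)
                if not (lo < lig.second_distance <= hi):
                    raise ValueError(
                        f"ligand {lig.label!r} frame {f}: second-shell distance "
                        f"{lig.second_distance} Å must lie in ({lo:.2f}, {hi:.2f}] Å "
                        f"to admit a bridging water at noise_sd {n}"
                    )
            if state == NONE and lig.none_distance <= second_cut + 3 * n:
                raise ValueError(
                    f"ligand {lig.label!r} frame {f}: out-of-shell distance "
                    f"{lig.none_distance} Å is inside the {second_cut} Å cutoff"
                )
    if spec.chi_schedule is not None:
        if len(spec.chi_schedule) != spec.n_frames:
            raise ValueError("chi_schedule length must equal n_frames")
        for f, state in enumerate(spec.chi_schedule):
            if state not in _CHI_TARGET:
                raise ValueError(f"chi_schedule frame {f}: unknown state {state!r}")
    for pair, series in spec.hbond_schedule.items():
        if len(series) != spec.n_frames:
            raise ValueError(f"hbond pair {pair!r}: schedule length must equal n_frames")
    if spec.hbond_schedule and spec.noise_sd > 0.05:
        raise ValueError(
            "noise_sd > 0.05 Å could flip planted H-bond geometry; lower it"
        )


def _sphere_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (golden-spiral points)."""
    k = np.arange(n) + 0.5
    phi = math.pi * (1 + math.sqrt(5)) * k
    cos_t = 1 - 2 * k / n
    sin_t = np.sqrt(1 - cos_t**2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def gen_site_trajectory(spec: SiteTrajectorySpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a trajectory whose shell/rotamer/H-bond analysis equals the truth.

    Deterministic given ``spec.seed``.  Cutoffs assumed by the construction are
    the analysis defaults (2.8 / 3.0 / 6.0 / 3.0 Å, 3.5 Å / 30 deg).
    """
    cutoffs = (2.8, 3.0, 6.0, 3.0)
    _validate_distances(spec, cutoffs)
    rng = np.random.default_rng(spec.seed)
    n_frames = spec.n_frames
    noise = spec.noise_sd
    ion0 = np.asarray(spec.ion_start, dtype=float)

    atoms: list[Atom] = [Atom(id="NA", name="NA", role="ion", resname="SOD")]
    blocks: list[np.ndarray] = [np.tile(ion0, (n_frames, 1, 1))]

    n_lig = len(spec.ligands)
    dirs = _sphere_directions(max(n_lig + spec.water_count, 1))

    # ligand + dedicated bridge-water placement
    water_first = np.zeros(n_frames, dtype=int)
    bridge_park = 8.0  # Å, bridge water parking distance when unused
    for li, lig in enumerate(spec.ligands):
        schedule = spec.shell_schedule[lig.label]
        u = dirs[li]
        dist = np.empty(n_frames)
        wdist = np.full(n_frames, bridge_park)
        for f, state in enumerate(schedule):
            if state == FIRST:
                dist[f] = lig.nominal_distance
            elif state == SECOND:
                dist[f] = lig.second_distance
                # on-axis bridge: within 3 Å of the ion and of the ligand atom
                lo = lig.second_distance - (cutoffs[3] - 6 * noise)
                hi = cutoffs[1] - 3 * noise
                wdist[f] = 0.5 * (max(lo, 0.5) + hi)
                water_first[f] += 1
            else:
                dist[f] = lig.none_distance
        atoms.append(Atom(id=lig.label, name="O", role=lig.role, resname="LIG", resid=li + 1))
        blocks.append(ion0 + dist[:, None, None] * u[None, None, :])
        atoms.append(
            Atom(id=f"WB{li}", name="OH2", role="water_oxygen", resname="TIP3", resid=100 + li)
        )
        blocks.append(ion0 + wdist[:, None, None] * u[None, None, :])

    # spectator waters parked beyond the second shell
    for wi in range(spec.water_count):
        u = dirs[n_lig + wi]
        d = 7.5 + 0.25 * (wi % 8)
        atoms.append(
            Atom(id=f"WS{wi}", name="OH2", role="water_oxygen", resname="TIP3", resid=200 + wi)
        )
        blocks.append(np.tile(ion0 + d * u, (n_frames, 1, 1)))

    # chi1 quadruple, far from the ion
    if spec.chi_schedule is not None:
        base = ion0 + np.array([0.0, 0.0, 30.0])
        p0 = base + np.array([-0.5, 1.4, 0.0])
        p1 = base
        p2 = base + np.array([1.5, 0.0, 0.0])
        quad = np.empty((n_frames, 4, 3))
        for f, state in enumerate(spec.chi_schedule):
            theta = math.radians(_CHI_TARGET[state])  # construction yields chi = theta
            p3 = p2 + np.array([0.5, 1.4 * math.cos(theta), 1.4 * math.sin(theta)])
            quad[f] = [p0, p1, p2, p3]
        for k, aid in enumerate(CHI_ATOM_IDS):
            atoms.append(Atom(id=aid, name=aid.split("_")[1], role="other", resname="CHI"))
            blocks.append(quad[:, k : k + 1, :])

    # H-bond triples, one isolated group per pair
    hb_names: dict[str, tuple[str, str, str]] = {}
    for gi, (pair, series) in enumerate(sorted(spec.hbond_schedule.items())):
        base = ion0 + np.array([0.0, 30.0 + 6.0 * gi, 0.0])
        dname, hname, aname = f"D_{pair}", f"H_{pair}", f"A_{pair}"
        hb_names[pair] = (dname, hname, aname)
        d_xyz = np.tile(base, (n_frames, 1, 1))
        h_xyz = np.tile(base + np.array([1.0, 0.0, 0.0]), (n_frames, 1, 1))
        a_xyz = np.empty((n_frames, 1, 3))
        for f, on in enumerate(series):
            a_xyz[f, 0] = base + np.array([2.9 if on else 5.0, 0.0, 0.0])
        atoms.append(Atom(id=dname, name="N", role="donor", resname="HBD", resid=300 + gi))
        atoms.append(Atom(id=hname, name="H", role="hydrogen", resname="HBD", resid=300 + gi))
        atoms.append(Atom(id=aname, name="O", role="acceptor", resname="HBA", resid=300 + gi))
        blocks.extend([d_xyz, h_xyz, a_xyz])

    coords = np.concatenate(blocks, axis=1)

    if noise > 0:
        # truncated per-coordinate Gaussian: |shift| <= 3*noise_sd per atom
        cap = math.sqrt(3.0) * noise
        jitter = rng.normal(0.0, noise, size=coords.shape)
        jitter = np.clip(jitter, -cap, cap)
        jitter[:, 0, :] = 0.0  # the ion itself stays planted
        coords = coords + jitter

    times = spec.frame_interval * np.arange(n_frames, dtype=float)
    traj = Trajectory(atoms=tuple(atoms), coords=coords, times=times)

    first_occ, total_occ = {}, {}
    prot_first = np.zeros(n_frames, dtype=int)
    prot_second = np.zeros(n_frames, dtype=int)
    for lig in spec.ligands:
        schedule = list(spec.shell_schedule[lig.label])
        states = np.array(schedule)
        first_occ[lig.label] = float(np.mean(states == FIRST))
        total_occ[lig.label] = float(np.mean((states == FIRST) | (states == SECOND)))
        prot_first += states == FIRST
        prot_second += states == SECOND

    truth = GroundTruth(
        first_occupancy=first_occ,
        total_occupancy=total_occ,
        protein_first_counts=prot_first,
        protein_second_counts=prot_second,
        water_first_counts=water_first,
        water_second_counts=np.zeros(n_frames, dtype=int),
        chi_labels=tuple(spec.chi_schedule) if spec.chi_schedule is not None else None,
        hbond_occupancy={
            pair: float(np.mean(np.asarray(series, dtype=bool)))
            for pair, series in spec.hbond_schedule.items()
        },
    )
    return traj, truth


def hbond_atom_ids(pair: str) -> tuple[str, str, str]:
    """(donor, hydrogen, acceptor) atom ids used for a planted H-bond pair."""
    return (f"D_{pair}", f"H_{pair}", f"A_{pair}")
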