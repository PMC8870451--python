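"""H-bond occupancy with the rotamer-based replica filter.

A frame counts an H-bond for a (donor, hydrogen, acceptor) triple iff the
donor-acceptor distance is <= 3.5 Å AND the D-H...A angle deviates from
linearity (180 deg) by <= 30 deg.

When a rotamer label series is supplied per replica, replicas whose filtered
side chain switches to the outward state (g- by default) before the filter
window (50 ns) are excluded entirely; for the remaining replicas only frames
with a non-outward (inward) label enter the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import AnalysisParams, Trajectory, TrajectoryError
from .rotamers import G_MINUS, ChiSeries


@dataclass(frozen=True)
class HBondPair:
    donor: str
    hydrogen: str | None
    acceptor: str

    def __post_init__(self) -> None:
        if self.hydrogen is None:
            raise TrajectoryError(
                f"H-bond pair {self.donor}->{self.acceptor} lacks a hydrogen atom"
            )

    @property
    def label(self) -> str:
        return f"{self.donor}->{self.acceptor}"


def _as_pair(pair) -> HBondPair:
    if isinstance(pair, HBondPair):
        return pair
    if len(pair) == 3:
        return HBondPair(*pair)
    if len(pair) == 2:
        return HBondPair(pair[0], None, pair[1])
    raise TrajectoryError(f"H-bond pair must be (donor, hydrogen, acceptor), got {pair!r}")


def hbond_frame_mask(
    traj: Trajectory, pair: HBondPair, params: AnalysisParams
) -> np.ndarray:
    """Boolean per-frame H-bond presence for one triple."""
    d = traj.coords[:, traj.index_of(pair.donor), :]
    h = traj.coords[:, traj.index_of(pair.hydrogen), :]
    a = traj.coords[:, traj.index_of(pair.acceptor), :]
    da = np.linalg.norm(d - a, axis=1)
    v1 = d - h
    v2 = a - h
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    cosang = np.sum(v1 * v2, axis=1) / np.maximum(n1 * n2, 1e-300)
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    deviation = 180.0 - angle
    return (da <= params.hbond_dist) & (deviation <= params.hbond_angle_dev)


@dataclass(frozen=True)
class HBondTable:
    per_replica: pd.DataFrame   # MultiIndex (replica, pair): occupancy_pct, n_retained
    pooled: pd.DataFrame        # index pair: mean_pct, sem_pct
    excluded_replicas: tuple[str, ...]
    retained_masks: dict[str, np.ndarray]  # replica -> retained-frame mask


def _sem(values: np.ndarray) -> float | None:
    if len(values) < 2:
        return None
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def hbond_occupancy(
    trajectories: Sequence[Trajectory] | Trajectory,
    pairs: Sequence,
    params: AnalysisParams | None = None,
    filter_on: Sequence[ChiSeries] | None = None,
    outward_label: str = G_MINUS,
) -> HBondTable:
    """Occupancy table of H-bond triples across replicas.

    ``filter_on`` supplies one rotamer label series per replica (frame-aligned
    with its trajectory): replicas that go outward before
    ``params.rotamer_filter_window`` ns are dropped; for the rest only
    inward-labelled frames are retained as denominator.
    """
    params = params if params is not None else AnalysisParams()
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise TrajectoryError("at least one replica trajectory required")
    pair_objs = [_as_pair(p) for p in pairs]
    if not pair_objs:
        raise TrajectoryError("at least one H-bond pair required")
    if filter_on is not None and len(filter_on) != len(trajectories):
        raise TrajectoryError("one rotamer series per replica required")

    rows = []
    excluded: list[str] = []
    retained_masks: dict[str, np.ndarray] = {}
    for r, traj in enumerate(trajectories):
        retained = np.ones(traj.n_frames, dtype=bool)
        if filter_on is not None:
            series = filter_on[r]
            if len(series.labels) != traj.n_frames:
                raise TrajectoryError(
                    f"replica {traj.replica}: rotamer series has {len(series.labels)} "
                    f"frames, trajectory has {traj.n_frames}"
                )
            outward = series.labels == outward_label
            early = outward & (traj.times < params.rotamer_filter_window)
            if np.any(early):
                excluded.append(traj.replica)
                continue
            retained = ~outward & series.defined
        if not np.any(retained):
            raise TrajectoryError(f"replica {traj.replica}: zero retained frames")
        retained_masks[traj.replica] = retained
        for pair in pair_objs:
            mask = hbond_frame_mask(traj, pair, params)
            occ = 100.0 * float(mask[retained].mean())
            rows.append(
                {
                    "replica": traj.replica,
                    "pair": pair.label,
                    "occupancy_pct": occ,
                    "n_retained": int(retained.sum()),
                }
            )

    if not rows:
        raise TrajectoryError("all replicas were removed by the rotamer filter")
    per_replica = pd.DataFrame(rows).set_index(["replica", "pair"])
    pooled_rows = []
    for pair in pair_objs:
        sub = per_replica.xs(pair.label, level="pair")["occupancy_pct"].to_numpy()
        pooled_rows.append(
            {"pair": pair.label, "mean_pct": float(np.mean(sub)), "sem_pct": _sem(sub)}
        )
    pooled = pd.DataFrame(pooled_rows).set_index("pair")
    return HBondTable(
        per_replica=per_replica,
        pooled=pooled,
        excluded_replicas=tuple(excluded),
        retained_masks=retained_masks,
    )
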