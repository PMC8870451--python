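"""Greedy identity clustering with deterministic representative selection.

Sequences are visited in order of decreasing ungapped length (ties broken by
id); each joins the first existing cluster whose *representative* it matches
at or above the identity threshold, otherwise it founds a new cluster and
becomes its representative.  This makes the manual "longest termini
privileged" representative choice deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .identity import IdentityMatrix
from .model import AlignedSequenceSet


@dataclass(frozen=True)
class Cluster:
    representative: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class ClusterSet:
    clusters: tuple[Cluster, ...]
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def representative_ids(self) -> tuple[str, ...]:
        return tuple(c.representative for c in self.clusters)

    def membership(self) -> dict[str, str]:
        """sequence id -> representative id"""
        return {m: c.representative for c in self.clusters for m in c.members}


def greedy_cluster(
    aln: AlignedSequenceSet, idmat: IdentityMatrix, threshold: float = 0.90
) -> ClusterSet:
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if tuple(idmat.ids) != tuple(aln.ids):
        raise ValueError("identity matrix ids do not match the alignment")
    order = sorted(aln.ids, key=lambda sid: (-aln.ungapped_length(sid), sid))
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for sid in order:
        placed = False
        for rep in reps:
            ident = idmat.identity(sid, rep)
            if not np.isnan(ident) and ident >= threshold:
                members[rep].append(sid)
                placed = True
                break
        if not placed:
            reps.append(sid)
            members[sid] = [sid]
    clusters = tuple(Cluster(representative=r, members=tuple(members[r])) for r in reps)
    return ClusterSet(clusters=clusters, threshold=threshold)


def write_clusters_tsv(clusters: ClusterSet, path) -> None:
    lines = ["member\trepresentative"]
    for c in clusters.clusters:
        for m in c.members:
            lines.append(f"{m}\t{c.representative}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
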