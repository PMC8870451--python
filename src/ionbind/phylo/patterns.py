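"""Structure-anchored position patterns (Ballesteros-style labels).

Anchors name residue indices *in a reference sequence* (0-based, over its
ungapped residues); these are mapped through the alignment to columns, and
per-sequence residues, per-clade consensus and logo-style frequency vectors
are reported for each labelled position.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .model import GAP, AlignedSequenceSet


@dataclass(frozen=True)
class PositionPatternTable:
    labels: tuple[str, ...]                       # e.g. "2.50", "3.35", "7.46"
    columns: dict[str, int]                       # label -> alignment column
    residues: pd.DataFrame                        # index sequence id, columns labels
    frequencies: dict[str, dict[str, float]]      # label -> residue -> fraction
    clade_consensus: pd.DataFrame | None          # index clade, columns labels

    def to_csv(self, path) -> None:
        self.residues.to_csv(path)


def _reference_column_map(reference_row: str) -> dict[int, int]:
    """ungapped residue index -> alignment column for the reference sequence"""
    mapping: dict[int, int] = {}
    res = 0
    for col, c in enumerate(reference_row):
        if c != GAP:
            mapping[res] = col
            res += 1
    return mapping


def position_patterns(
    aln: AlignedSequenceSet,
    reference_id: str,
    anchors: Mapping[str, int],
    expected_residues: Mapping[str, str] | None = None,
) -> PositionPatternTable:
    """Map labelled reference positions to columns and tabulate residues.

    ``anchors`` maps label -> residue index in the reference (0-based over its
    ungapped sequence).  ``expected_residues`` optionally asserts the
    reference residue at each anchor; a mismatch is an error, as is an anchor
    mapping to a gap (impossible by construction) or out of range.
    """
    if reference_id not in aln.ids:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    ref = aln.sequence(reference_id)
    res_to_col = _reference_column_map(ref)
    n_res = len(res_to_col)

    columns: dict[str, int] = {}
    for label, res_idx in anchors.items():
        if not (0 <= res_idx < n_res):
            raise ValueError(
                f"anchor {label}: residue index {res_idx} outside reference "
                f"length {n_res}"
            )
        col = res_to_col[res_idx]
        if expected_residues is not None and label in expected_residues:
            actual = ref[col]
            if actual != expected_residues[label]:
                raise ValueError(
                    f"anchor {label}: reference residue {actual!r} at index "
                    f"{res_idx} does not match declared {expected_residues[label]!r}"
                )
        columns[label] = col

    labels = tuple(anchors)
    rows = {
        sid: {label: aln.sequence(sid)[col] for label, col in columns.items()}
        for sid in aln.ids
    }
    residues = pd.DataFrame.from_dict(rows, orient="index")[list(labels)]

    frequencies: dict[str, dict[str, float]] = {}
    for label, col in columns.items():
        counted = Counter(s[col] for s in aln.sequences if s[col] != GAP)
        total = sum(counted.values())
        frequencies[label] = (
            {res: c / total for res, c in sorted(counted.items())} if total else {}
        )

    clade_consensus = None
    if aln.taxa is not None:
        clades = sorted(set(aln.taxa))
        data = {}
        for clade in clades:
            members = [i for i, t in enumerate(aln.taxa) if t == clade]
            row = {}
            for label, col in columns.items():
                counted = Counter(
                    aln.sequences[i][col] for i in members if aln.sequences[i][col] != GAP
                )
                row[label] = counted.most_common(1)[0][0] if counted else GAP
            data[clade] = row
        clade_consensus = pd.DataFrame.from_dict(data, orient="index")[list(labels)]

    return PositionPatternTable(
        labels=labels,
        columns=columns,
        residues=residues,
        frequencies=frequencies,
        clade_consensus=clade_consensus,
    )
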