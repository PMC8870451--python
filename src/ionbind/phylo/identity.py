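"""Pairwise sequence identity and its cumulative distribution.

Identity convention (recorded in outputs): matches divided by the number of
columns where *neither* sequence carries a gap.  A pair with no comparable
columns has undefined identity and is flagged, not silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GAP, AlignedSequenceSet

DENOMINATOR_CONVENTION = "columns ungapped in both sequences"


@dataclass(frozen=True)
class IdentityMatrix:
    ids: tuple[str, ...]
    values: np.ndarray          # symmetric, unit diagonal; NaN where undefined
    undefined_pairs: tuple[tuple[str, str], ...]
    denominator: str = DENOMINATOR_CONVENTION

    def identity(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def distances(self, correction: str = "none") -> np.ndarray:
        """Distance matrix d = 1 - identity, or Poisson-corrected -ln(identity)."""
        if np.any(np.isnan(self.values)):
            raise ValueError("identity undefined for some pair; cannot build distances")
        if correction == "none":
            return 1.0 - self.values
        if correction == "poisson":
            return -np.log(np.maximum(self.values, 1e-10))
        raise ValueError(f"unknown correction {correction!r}")


def pairwise_identity(aln: AlignedSequenceSet) -> IdentityMatrix:
    """All-pairs identity fractions under the gap-excluded convention."""
    if aln.n_sequences < 2:
        raise ValueError("need at least two sequences")
    seqs = np.array([list(s) for s in aln.sequences])
    gaps = seqs == GAP
    n = aln.n_sequences
    values = np.eye(n)
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ~gaps[i] & ~gaps[j]
            denom = int(comparable.sum())
            if denom == 0:
                values[i, j] = values[j, i] = np.nan
                undefined.append((aln.ids[i], aln.ids[j]))
                continue
            matches = int(np.sum(seqs[i][comparable] == seqs[j][comparable]))
            values[i, j] = values[j, i] = matches / denom
    return IdentityMatrix(ids=aln.ids, values=values, undefined_pairs=tuple(undefined))


def identity_cdf(idmat: IdentityMatrix) -> pd.DataFrame:
    """Empirical CDF over all unordered (defined) pairs: columns identity, cdf."""
    n = len(idmat.ids)
    iu = np.triu_indices(n, k=1)
    vals = idmat.values[iu]
    vals = np.sort(vals[~np.isnan(vals)])
    if len(vals) == 0:
        raise ValueError("no defined pairs")
    cdf = np.arange(1, len(vals) + 1) / len(vals)
    return pd.DataFrame({"identity": vals, "cdf": cdf})
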