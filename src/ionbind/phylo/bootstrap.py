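"""Bootstrap supports for NJ trees by column resampling.

Each replicate resamples alignment columns with replacement (replicate r uses
the r-th child of a single seed sequence, so runs are reproducible and
replicas independent), rebuilds the identity-derived distance matrix and NJ
tree, and counts how often each internal bipartition of the original tree
reappears.
"""

from __future__ import annotations

import numpy as np

from .identity import pairwise_identity
from .model import AlignedSequenceSet
from .nj import nj_tree
from .tree import Tree


def _resampled(aln: AlignedSequenceSet, columns: np.ndarray) -> AlignedSequenceSet:
    seqs = tuple("".join(s[c] for c in columns) for s in aln.sequences)
    return AlignedSequenceSet(ids=aln.ids, sequences=seqs, taxa=aln.taxa)


def _nj_from_alignment(aln: AlignedSequenceSet, correction: str) -> Tree:
    idmat = pairwise_identity(aln)
    return nj_tree(idmat.distances(correction=correction), list(aln.ids))


def bootstrap_support(
    aln: AlignedSequenceSet,
    tree: Tree | None = None,
    n_reps: int = 500,
    seed: int = 0,
    correction: str = "none",
) -> tuple[Tree, dict[frozenset[str], float]]:
    """Per-edge bootstrap support (%) for the NJ tree of ``aln``.

    Returns the tree (built here when not supplied) with supports annotated on
    its internal nodes, plus the support of every internal bipartition.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if tree is None:
        tree = _nj_from_alignment(aln, correction)
    reference = tree.bipartitions()
    counts = {split: 0 for split in reference}

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    n_cols = aln.n_columns
    for r in range(n_reps):
        rng = np.random.default_rng(children[r])
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_tree = _nj_from_alignment(_resampled(aln, cols), correction)
        rep_splits = rep_tree.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    supports = {split: 100.0 * c / n_reps for split, c in counts.items()}
    # annotate internal nodes
    all_leaves = frozenset(tree.leaf_names())
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(node.leaf_names())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canonical = min(side, other, key=lambda s: (len(s), sorted(s)))
        node.support = supports.get(canonical)
    return tree, supports
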