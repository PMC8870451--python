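"""Evolve aligned sequence families along a known guide tree.

Substitutions follow a Jukes-Cantor-style uniform replacement over the 20
amino acids: on a branch of length t (substitutions/site) each site is hit
with probability 1 - exp(-t) and then redrawn uniformly (so the expected
per-branch retention is exp(-t) + (1 - exp(-t))/20).  No indels are
introduced, so leaves stay aligned to the root.  Specific columns can be
overridden at named tree nodes and are inherited by the whole subtree, which
plants exact clade-defining patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ..phylo.model import AMINO_ACIDS, AlignedSequenceSet
from ..phylo.tree import Tree, TreeNode


@dataclass(frozen=True)
class SequenceEvolutionSpec:
    guide_tree: Tree
    root_sequence: str
    seed: int = 0
    marked_columns: Mapping[str, int] = field(default_factory=dict)  # label -> column
    #: node name -> {column index -> residue}; applied at that node, inherited below
    clade_overrides: Mapping[str, Mapping[int, str]] = field(default_factory=dict)
    taxa: Mapping[str, str] | None = None  # leaf name -> clade label

    def __post_init__(self) -> None:
        leaves = self.guide_tree.leaf_names()
        if not leaves:
            raise ValueError("guide tree has no leaves")
        if len(set(leaves)) != len(leaves):
            raise ValueError("guide tree leaf names must be unique")
        if not self.root_sequence:
            raise ValueError("root sequence is empty")
        bad = set(self.root_sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"root sequence has non-residue characters {sorted(bad)}")
        L = len(self.root_sequence)
        for label, col in self.marked_columns.items():
            if not (0 <= col < L):
                raise ValueError(f"marked column {label}={col} outside sequence length {L}")
        for node, cols in self.clade_overrides.items():
            for col, res in cols.items():
                if not (0 <= col < L):
                    raise ValueError(f"override at {node!r}: column {col} out of range")
                if res not in AMINO_ACIDS:
                    raise ValueError(f"override at {node!r}: {res!r} is not a residue")
        for node in self.guide_tree.root.walk():
            if node.length is not None and node.length < 0:
                raise ValueError("branch lengths must be >= 0")


def expected_pairwise_identity(t_total: float) -> float:
    """Expected identity of two sequences separated by total path length t."""
    retain = math.exp(-t_total)
    # either no change on the path, or both ended on the same uniform residue
    return retain + (1.0 - retain) / len(AMINO_ACIDS)


def gen_sequence_family(spec: SequenceEvolutionSpec) -> tuple[AlignedSequenceSet, Tree]:
    """Evolve the root sequence down the guide tree; returns leaves + true tree.

    Deterministic given the seed; leaf order follows the tree's depth-first
    leaf order.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    lookup = {a: i for i, a in enumerate(alphabet)}
    root = np.array([lookup[c] for c in spec.root_sequence], dtype=int)
    L = len(root)

    leaf_seqs: dict[str, str] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        seq = seq.copy()
        t = node.length or 0.0
        if t > 0:
            hit = rng.random(L) < (1.0 - math.exp(-t))
            n_hit = int(hit.sum())
            if n_hit:
                seq[hit] = rng.integers(0, len(alphabet), size=n_hit)
        if node.name is not None and node.name in spec.clade_overrides:
            for col, res in spec.clade_overrides[node.name].items():
                seq[col] = lookup[res]
        if node.is_leaf:
            leaf_seqs[node.name] = "".join(alphabet[seq])
        else:
            for child in node.children:
                descend(child, seq)

    descend(spec.guide_tree.root, root)

    ids = tuple(spec.guide_tree.leaf_names())
    taxa = None
    if spec.taxa is not None:
        taxa = tuple(spec.taxa.get(i, "") for i in ids)
    aln = AlignedSequenceSet(
        ids=ids, sequences=tuple(leaf_seqs[i] for i in ids), taxa=taxa
    )
    return aln, spec.guide_tree
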