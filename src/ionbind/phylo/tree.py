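"""Minimal phylogenetic tree: nodes, Newick round trip, bipartitions.

Branch supports (bootstrap %) are stored on internal nodes and serialized as
internal node labels, the convention most tree viewers expect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass
class TreeNode:
    name: str | None = None
    length: float | None = None   # branch length above this node
    support: float | None = None  # bootstrap %, internal nodes only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]


@dataclass
class Tree:
    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the canonical (lexicographically smaller)
        side of the leaf-set bipartition; invariant to rooting."""
        all_leaves = frozenset(self.leaf_names())
        splits: set[frozenset[str]] = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            canonical = min(side, other, key=lambda s: (len(s), sorted(s)))
            splits.add(canonical)
        return splits

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.root.walk() if n is not self.root)

    def to_newick(self, support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner})"
                if support and node.support is not None:
                    label += f"{node.support:g}"
                elif node.name:
                    label += node.name
            if node.length is not None:
                label += f":{node.length:g}"
            return label

        return fmt(self.root) + ";"


def parse_newick(text: str) -> Tree:
    """Parse a Newick string (labels, branch lengths, internal labels)."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    raise ValueError("unbalanced parentheses in Newick")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        token = s[start:pos]
        if token:
            if ":" in token:
                raise ValueError("malformed token")
            node.name = token or None
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            node.length = float(s[start:pos])
        if node.children and node.name is not None:
            # internal label: interpret numeric labels as bootstrap support
            try:
                node.support = float(node.name)
                node.name = None
            except ValueError:
                pass
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in Newick at {pos}: {s[pos:]!r}")
    return Tree(root=root)
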