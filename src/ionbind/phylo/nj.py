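"""Neighbor-joining (Saitou-Nei) tree construction.

Exact on additive distance matrices: topology and branch lengths are
recovered to machine precision.  Ties in the Q criterion break to the
lowest-index pair, making the construction deterministic.  The result is the
conventional unrooted tree serialized with a trifurcating root (a plain
bifurcation for two taxa, where the two child branches sum to the input
distance).
"""

from __future__ import annotations

import warnings

import numpy as np

from .tree import Tree, TreeNode


def nj_tree(distances: np.ndarray, labels) -> Tree:
    """Neighbor-joining tree from a symmetric distance matrix."""
    D = np.array(distances, dtype=float)
    labels = list(labels)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError(f"distance matrix {D.shape} does not match {n} labels")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        warnings.warn("two taxa: returning the single-edge (degenerate) tree", stacklevel=2)
        half = D[0, 1] / 2.0
        return Tree(
            TreeNode(children=[TreeNode(name=labels[0], length=half),
                               TreeNode(name=labels[1], length=half)])
        )

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie-break: flat argmin scans rows in order
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        new = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining ones
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.empty((m - 1, m - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = du[keep]
        D_new[:-1, -1] = du[keep]
        D_new[-1, -1] = 0.0
        D = D_new
        nodes = [nodes[k] for k in keep] + [new]

    # resolve the final three nodes as a star (unrooted trifurcation)
    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length = max(la, 0.0)
    b.length = max(lb, 0.0)
    c.length = max(lc, 0.0)
    return Tree(TreeNode(children=[a, b, c]))


def tree_distance_matrix(tree: Tree) -> tuple[np.ndarray, list[str]]:
    """Patristic (path-length) distances between all leaves of a tree."""
    leaves = tree.root.leaves()
    names = [l.name for l in leaves]
    # parent map + depth from root
    parent: dict[int, TreeNode] = {}
    for node in tree.root.walk():
        for c in node.children:
            parent[id(c)] = node

    def path_to_root(node: TreeNode) -> list[TreeNode]:
        path = [node]
        while id(path[-1]) in parent:
            path.append(parent[id(path[-1])])
        return path

    n = len(leaves)
    D = np.zeros((n, n))
    paths = [path_to_root(l) for l in leaves]
    for i in range(n):
        for j in range(i + 1, n):
            pi = {id(x) for x in paths[i]}
            # find the lowest common ancestor
            lca = next(x for x in paths[j] if id(x) in pi)
            d = 0.0
            for x in paths[i]:
                if x is lca:
                    break
                d += x.length or 0.0
            for x in paths[j]:
                if x is lca:
                    break
                d += x.length or 0.0
            D[i, j] = D[j, i] = d
    return D, names
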