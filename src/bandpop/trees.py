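"""Neighbour-joining and UPGMA trees with column-bootstrap supports.

Trees are :class:`skbio.TreeNode`.  The NJ agglomeration is written out
explicitly so that tie-breaking is deterministic (smallest pair index)
and negative branch-length estimates are truncated to zero and flagged -
both conventions the downstream reports rely on.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .io import BandMatrix
from .distances import jaccard_distance

__all__ = ["nj_tree", "upgma_tree", "upgma_clusters", "bootstrap_support", "bipartitions"]


def _set_length(node: TreeNode, length: float, flagged: list[str]) -> None:
    if length < 0:
        flagged.append(node.name or "<internal>")
        length = 0.0
    node.length = float(length)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining with the standard Q-criterion.

    On an additive matrix the generating topology and branch lengths are
    recovered exactly.  Ties in Q are broken by the lowest (i, j) index
    pair, so output is deterministic.  Negative branch-length estimates
    are truncated to 0 and reported via a warning.  With fewer than 3
    taxa a degenerate two-leaf tree is returned with a warning.
    """
    labels = list(dm.ids)
    d = dm.data.astype(float).copy()
    n = len(labels)
    nodes: list[TreeNode] = [TreeNode(name=str(l)) for l in labels]
    flagged: list[str] = []

    if n < 2:
        raise ValueError("need >= 2 taxa")
    if n == 2:
        warnings.warn("fewer than 3 taxa: returning a degenerate tree", stacklevel=2)
        root = TreeNode()
        for node in nodes:
            _set_length(node, d[0, 1] / 2.0, flagged)
            root.append(node)
        return root

    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin of the flattened array scans rows
        # first, giving the smallest (i, j) among minima
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        ni, nj = nodes[active[i]], nodes[active[j]]
        _set_length(ni, li, flagged)
        _set_length(nj, lj, flagged)
        parent.append(ni)
        parent.append(nj)

        # distances from the new node to the remaining taxa
        rest = [a for k, a in enumerate(active) if k not in (i, j)]
        new_d = 0.5 * (d[active[i], rest] + d[active[j], rest] - dij)
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[new_idx, rest] = new_d
        d[rest, new_idx] = new_d
        nodes.append(parent)
        active = rest + [new_idx]

    a, b = active
    root = TreeNode()
    half = d[a, b] / 2.0
    _set_length(nodes[a], half, flagged)
    _set_length(nodes[b], half, flagged)
    root.append(nodes[a])
    root.append(nodes[b])
    if flagged:
        warnings.warn(
            f"{len(flagged)} negative NJ branch length(s) truncated to 0",
            stacklevel=2)
    return root


def upgma_tree(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) dendrogram; ultrametric input is recovered
    exactly, with tip-to-tip path lengths equal to the input distances."""
    labels = list(dm.ids)
    if len(labels) < 2:
        raise ValueError("need >= 2 items")
    z = hierarchy.linkage(squareform(dm.data, checks=False), method="average")
    nodes: dict[int, tuple[TreeNode, float]] = {
        i: (TreeNode(name=l), 0.0) for i, l in enumerate(labels)
    }
    n = len(labels)
    for k, (a, b, height, _) in enumerate(z):
        parent = TreeNode()
        h = height / 2.0  # tips sit at depth (merge height)/2
        for idx in (int(a), int(b)):
            child, child_h = nodes.pop(idx)
            child.length = h - child_h
            parent.append(child)
        nodes[n + k] = (parent, h)
    root, _ = nodes.popitem()[1]
    root.length = None
    return root


def upgma_clusters(dm: DistanceMatrix, height: float) -> dict[str, int]:
    """Flat grouping from cutting the UPGMA dendrogram at a merge height."""
    z = hierarchy.linkage(squareform(dm.data, checks=False), method="average")
    flat = hierarchy.fcluster(z, t=height, criterion="distance")
    return {l: int(c) for l, c in zip(dm.ids, flat)}


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of a tree, each canonicalized as the side
    not containing the lexicographically smallest tip."""
    tips = sorted(t.name for t in tree.tips())
    anchor = tips[0]
    full = set(tips)
    parts: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if anchor in side:
            side = full - side
        if 2 <= len(side) <= len(full) - 2:
            parts.add(frozenset(side))
    return parts


def bootstrap_support(
    bm: BandMatrix,
    tree_builder=nj_tree,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    distance=jaccard_distance,
) -> TreeNode:
    """Resample band columns with replacement, rebuild the tree and
    annotate the point-estimate tree's internal nodes with percent
    bipartition support (``node.support``, also set as the node name)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    point = tree_builder(distance(bm))

    counts: dict[frozenset, int] = {}
    L = bm.n_bands
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep_bm = BandMatrix(
            list(bm.genotype_ids),
            [f"{bm.band_ids[c]}.{k}" for k, c in enumerate(cols)],
            bm.scores[:, cols].copy(),
        )
        rep_tree = tree_builder(distance(rep_bm))
        for part in bipartitions(rep_tree):
            counts[part] = counts.get(part, 0) + 1

    tips = sorted(t.name for t in point.tips())
    anchor, full = tips[0], set(tips)
    for node in point.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if anchor in side:
            side = full - side
        support = 100.0 * counts.get(frozenset(side), 0) / n_reps
        node.support = support
        node.name = f"{support:g}"
    return point
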