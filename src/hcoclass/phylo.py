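"""Neighbor-joining trees from similarity-derived distances.

Percent similarities convert linearly to distances, d = (100 − sim)/100
(no multiple-substitution correction — the tree serves as a clustering
consistency check, not a branch-length estimate).  Neighbor joining is the
classical Saitou–Nei agglomeration with a deterministic tie-break and a
documented treatment of negative branch lengths: the negative length is
clamped to zero and the deficit moved onto the sibling branch, preserving
the joined pair's distance sum.

An optional bootstrap annotates split frequencies by column-resampling a
user-supplied fixed multiple alignment, rebuilding an NJ tree from
p-distances per replicate.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .alignment import SimilarityMatrix


def to_distances(simmatrix: SimilarityMatrix) -> DistanceMatrix:
    """Distance matrix d = (100 − sim)/100 with a zero diagonal."""
    d = (100.0 - simmatrix.sim) / 100.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # guard against float asymmetry
    return DistanceMatrix(d, ids=simmatrix.ids)


def _min_leaf(node: TreeNode) -> str:
    if node.is_tip():
        return node.name
    return min(tip.name for tip in node.tips())


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Classical neighbor joining; unrooted tree as a trifurcating root.

    Q-matrix ties are broken by the lexicographically smallest pair of
    representative leaf names.  Negative branch lengths are clamped to 0
    with the deficit absorbed by the sibling branch (final trifurcation:
    plain clamping).
    """
    ids = list(dist.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.array(dist.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]
    reps: list[str] = list(ids)

    while len(nodes) > 3:
        n = len(nodes)
        row_sums = d.sum(axis=1)
        q = (n - 2) * d - row_sums[:, None] - row_sums[None, :]
        # floats make q[i,j] and q[j,i] differ in the last bit; use the
        # upper triangle only
        q[np.tril_indices(n)] = np.inf
        q_min = q.min()
        candidates = list(zip(*np.nonzero(q == q_min)))
        i, j = min(candidates, key=lambda p: tuple(sorted((reps[p[0]], reps[p[1]]))))

        dij = d[i, j]
        li = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2 * (n - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        elif lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        left, right = nodes[i], nodes[j]
        left.length, right.length = float(li), float(lj)
        parent = TreeNode(children=[left, right])

        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        d_next = np.zeros((n - 1, n - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = new_row[keep]
        d_next[:-1, -1] = new_row[keep]
        d = d_next
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    # Final trifurcation: three-point branch lengths.
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lengths = (
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    )
    for node, length in zip(nodes, lengths):
        node.length = float(max(length, 0.0))
    return TreeNode(children=nodes)


# ---------------------------------------------------------------------------
# Bootstrap over a fixed alignment


def _bipartitions(tree: TreeNode, all_tips: frozenset[str]) -> set[frozenset[str]]:
    """Canonical nontrivial bipartitions (smaller side; tie -> sorted min)."""
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        below = frozenset(tip.name for tip in node.tips())
        if len(below) < 2 or len(all_tips - below) < 2:
            continue
        other = all_tips - below
        if len(below) < len(other) or (len(below) == len(other)
                                       and sorted(below) < sorted(other)):
            splits.add(below)
        else:
            splits.add(frozenset(other))
    return splits


def p_distance_matrix(alignment: Mapping[str, str],
                      columns: np.ndarray | None = None) -> DistanceMatrix:
    """Pairwise mismatch fractions over (optionally resampled) columns.

    Gapped positions are excluded per pair; a pair with no comparable
    column gets distance 1.
    """
    ids = list(alignment)
    rows = [alignment[i] for i in ids]
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("alignment rows must have equal length")
    arr = np.array([list(r) for r in rows])
    if columns is not None:
        arr = arr[:, columns]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != "-") & (arr[j] != "-")
            total = int(ok.sum())
            d[i, j] = d[j, i] = (
                float((arr[i][ok] != arr[j][ok]).sum() / total) if total else 1.0
            )
    return DistanceMatrix(d, ids=ids)


def bootstrap_support(alignment: Mapping[str, str] | None, n_reps: int = 100,
                      seed: int = 0) -> TreeNode:
    """NJ tree from a fixed alignment, internal nodes annotated with the
    fraction of column-resampling replicates containing their split.

    ``alignment`` maps ids to equal-length aligned rows (gap ``-``).  It
    must be supplied — this package does not build multiple alignments.
    """
    if not alignment:
        raise ValueError(
            "bootstrap_support requires a fixed multiple alignment; supply "
            "one (e.g. built with an external aligner)"
        )
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    reference = neighbor_joining(p_distance_matrix(alignment))
    all_tips = frozenset(alignment)
    length = len(next(iter(alignment.values())))
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        columns = rng.integers(length, size=length)
        replicate = neighbor_joining(p_distance_matrix(alignment, columns))
        for split in _bipartitions(replicate, all_tips):
            counts[split] = counts.get(split, 0) + 1
    for node in reference.non_tips(include_self=False):
        below = frozenset(tip.name for tip in node.tips())
        other = all_tips - below
        if len(below) < 2 or len(other) < 2:
            continue
        canonical = below if (len(below) < len(other) or (
            len(below) == len(other) and sorted(below) < sorted(other))) else frozenset(other)
        support = counts.get(canonical, 0) / n_reps
        node.support = support
        node.name = f"{support:g}"
    return reference
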