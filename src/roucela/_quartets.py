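"""Shared quartet-resolution machinery for leaf-labelled gene trees.

Unrooted quartet topologies are read off a (possibly multifurcating) rooted
tree from pairwise MRCA depths: for leaves ``a, b, c, d``, the resolution is
``ab|cd`` iff the MRCA of one of the pairs is strictly deeper than both
cross-pair MRCAs involving one of its members (MRCAs of pairs sharing a
leaf all lie on that leaf's root path, so their depths are comparable).
Polytomies simply fail the strict inequality and the quartet is reported
unresolved.  The result is invariant to the root position.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mrca_depth_table", "resolve_quartet"]


def mrca_depth_table(tree) -> tuple[dict[str, int], np.ndarray]:
    """Leaf-label index and pairwise MRCA-depth matrix for a dendropy tree.

    ``D[i, j]`` is the topological depth (root = 0) of the MRCA of leaves
    ``i`` and ``j``.  Computed in one postorder pass: at each internal node,
    every cross-child leaf pair has its MRCA at that node.
    """
    labels: dict[str, int] = {}
    for leaf in tree.leaf_node_iter():
        labels[leaf.taxon.label] = len(labels)
    n = len(labels)
    D = np.zeros((n, n), dtype=np.int32)

    depth = {}
    for nd in tree.preorder_node_iter():
        depth[id(nd)] = 0 if nd.parent_node is None else depth[id(nd.parent_node)] + 1

    leafsets: dict[int, list[int]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            leafsets[id(nd)] = [labels[nd.taxon.label]]
            continue
        groups = [leafsets.pop(id(c)) for c in nd.child_nodes()]
        d = depth[id(nd)]
        merged: list[int] = []
        for g in groups:
            for i in merged:
                for j in g:
                    D[i, j] = d
                    D[j, i] = d
            merged.extend(g)
        leafsets[id(nd)] = merged
    return labels, D


def resolve_quartet(D: np.ndarray, i: int, j: int, k: int, l: int) -> int | None:
    """Resolution of the quartet ``(i, j, k, l)``.

    Returns 0 for ``ij|kl``, 1 for ``ik|jl``, 2 for ``il|jk``, or ``None``
    when the induced quartet is unresolved.
    """
    dij = D[i, j]; dik = D[i, k]; dil = D[i, l]
    dkl = D[k, l]; djl = D[j, l]; djk = D[j, k]
    if (dij > dik and dij > dil) or (dkl > dik and dkl > djk):
        return 0
    if (dik > dij and dik > dil) or (djl > dij and djl > djk):
        return 1
    if (dil > dij and dil > dik) or (djk > dij and djk > djl):
        return 2
    return None
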