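import itertools

import dendropy
import numpy as np
import pytest

import roucela as rc


@pytest.fixture(scope="session")
def default_net():
    return rc.default_roucela_network(0.5, 1.0)


@pytest.fixture(scope="session")
def lineage_map_2x():
    """Lineage map for two samples per lineage of the default network."""
    net = rc.default_roucela_network(0.5, 1.0)
    cfg = rc.SimulationConfig(n_genes=1, samples_per_lineage=2, seed=0)
    samples = rc.sample_names(net, cfg)
    return rc.LineageMap({s: lin for lin, ss in samples.items() for s in ss})


@pytest.fixture(scope="session")
def hypothesis_spec():
    return rc.HypothesisSpec("erinus8x", "erinus4x", "creutzburgii",
                             "rhodensis")


def random_binary_tree(labels, rng):
    """Random rooted binary tree over ``labels`` with unit branch lengths,
    as a dendropy tree (independent of the package's simulators)."""
    nodes = [f"{lab}" for lab in labels]
    subtrees = [f"{lab}:1" for lab in labels]
    while len(subtrees) > 1:
        i = int(rng.integers(len(subtrees)))
        a = subtrees.pop(i)
        j = int(rng.integers(len(subtrees)))
        b = subtrees.pop(j)
        subtrees.append(f"({a},{b}):1")
    newick = subtrees[0].rsplit(":", 1)[0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)


def leaf_distances(tree):
    """Pairwise leaf-to-leaf path lengths by explicit traversal -- an
    independent oracle route (no MRCA logic shared with the package)."""
    dists = {}
    for leaf in tree.leaf_node_iter():
        # distance from this leaf to every node, walking up the tree
        up = {}
        node, d = leaf, 0.0
        while node is not None:
            up[id(node)] = d
            d += node.edge.length or 0.0
            node = node.parent_node
        for other in tree.leaf_node_iter():
            if other.taxon.label <= leaf.taxon.label:
                continue
            node, d2 = other, 0.0
            while id(node) not in up:
                d2 += node.edge.length or 0.0
                node = node.parent_node
            dists[(leaf.taxon.label, other.taxon.label)] = d2 + up[id(node)]
    return dists


def quartet_topology_oracle(tree, four_labels):
    """Four-point-condition quartet resolution from leaf distances.

    Returns 0 (12|34), 1 (13|24), 2 (14|23) for the sorted labels, or None
    on a tie (unresolved).
    """
    a, b, c, d = sorted(four_labels)
    dist = leaf_distances(tree)

    def dd(x, y):
        return dist[(x, y)] if (x, y) in dist else dist[(y, x)]

    sums = [dd(a, b) + dd(c, d), dd(a, c) + dd(b, d), dd(a, d) + dd(b, c)]
    best = min(sums)
    if sums.count(best) > 1:
        return None
    return sums.index(best)
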