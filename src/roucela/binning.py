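"""Support-aware binning of gene trees into competing topology classes.

Given a hybridization hypothesis (hybrid lineage H, candidate parents P1
and P2, outgroup O), each gene tree is classified twice:

* *strict*: after restricting the tree to samples of H, P1, P2 and O and
  rooting on the outgroup, the tree is T1 if the H and P1 samples are each
  monophyletic and sister to one another, T2 likewise with P2, otherwise
  OTHER;
* *relaxed*: branches with bootstrap support below a threshold (default
  80) are collapsed first, then every (h, p1, p2, o) one-sample-per-lineage
  quartet votes for its resolution; the majority between hp1|p2o and
  hp2|p1o decides T1 vs T2, ties and all-unresolved trees stay UNASSIGNED.

The strict rule mirrors reciprocal-monophyly-plus-sisterhood binning of
well-resolved trees; the relaxed rule is a reproducible surrogate for the
judgement that a poorly supported tree "approximates" one of the two
topologies once weak branches are discounted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._quartets import mrca_depth_table, resolve_quartet

__all__ = [
    "BinningError",
    "LineageMap",
    "HypothesisSpec",
    "BinCounts",
    "read_gene_trees",
    "support_of",
    "collapse_low_support",
    "classify_strict",
    "classify_relaxed",
    "bin_gene_trees",
]

T1, T2, OTHER, UNASSIGNED = "T1", "T2", "OTHER", "UNASSIGNED"

ROLES = {"hybrid", "parent1", "parent2", "outgroup", "other"}


class BinningError(ValueError):
    pass


@dataclass
class LineageMap:
    """sample_id -> lineage_id assignment, with optional lineage roles."""

    assignments: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        bad = {r for r in self.roles.values()} - ROLES
        if bad:
            raise BinningError(f"unknown lineage roles: {sorted(bad)}")

    def lineage_of(self, sample: str) -> str:
        try:
            return self.assignments[sample]
        except KeyError:
            raise BinningError(f"sample {sample!r} has no lineage assignment")

    def samples_of(self, lineage: str) -> list[str]:
        return sorted(s for s, l in self.assignments.items() if l == lineage)

    @property
    def lineages(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    @classmethod
    def from_tsv(cls, path) -> "LineageMap":
        df = pd.read_csv(path, sep="\t")
        for col in ("sample_id", "lineage"):
            if col not in df.columns:
                raise BinningError(f"lineage map {path} lacks column {col!r}")
        return cls(dict(zip(df["sample_id"], df["lineage"])))


@dataclass(frozen=True)
class HypothesisSpec:
    """One hybridization hypothesis: which lineage is the putative hybrid,
    its two candidate parents, and the outgroup used for rooting."""

    hybrid: str
    parent1: str
    parent2: str
    outgroup: str
    support_threshold: float = 80.0

    def __post_init__(self):
        ids = (self.hybrid, self.parent1, self.parent2, self.outgroup)
        if len(set(ids)) != 4:
            raise BinningError(f"hypothesis lineages must be distinct: {ids}")
        if not 0.0 <= self.support_threshold <= 100.0:
            raise BinningError("support_threshold must lie in [0, 100], got "
                               f"{self.support_threshold}")

    @property
    def lineages(self) -> tuple[str, str, str, str]:
        return (self.hybrid, self.parent1, self.parent2, self.outgroup)


@dataclass
class BinCounts:
    """Per-tree topology tallies (strict and relaxed) over a tree set."""

    n_t1: int = 0
    n_t2: int = 0
    n_other: int = 0
    n_t1_relaxed: int = 0
    n_t2_relaxed: int = 0
    n_unassigned: int = 0

    @property
    def n_trees(self) -> int:
        return self.n_t1 + self.n_t2 + self.n_other

    def frequencies(self) -> dict[str, float]:
        n = self.n_trees
        if n == 0:
            raise BinningError("no trees binned")
        return {
            "strict_T1": self.n_t1 / n,
            "strict_T2": self.n_t2 / n,
            "strict_OTHER": self.n_other / n,
            "relaxed_T1": self.n_t1_relaxed / n,
            "relaxed_T2": self.n_t2_relaxed / n,
            "relaxed_UNASSIGNED": self.n_unassigned / n,
        }

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "strict": {"T1": self.n_t1, "T2": self.n_t2, "OTHER": self.n_other},
            "relaxed": {"T1": self.n_t1_relaxed, "T2": self.n_t2_relaxed,
                        "UNASSIGNED": self.n_unassigned},
            "frequencies": self.frequencies(),
        }


# ---------------------------------------------------------------------------
# Reading and support handling
# ---------------------------------------------------------------------------

def read_gene_trees(path) -> list[dendropy.Tree]:
    """Read newick gene trees (one or more per file); internal node labels
    are kept verbatim and interpreted as bootstrap supports where numeric."""
    try:
        trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                      suppress_internal_node_taxa=True,
                                      preserve_underscores=True)
    except Exception as exc:
        raise BinningError(f"failed to parse newick file {path}: {exc}") from exc
    return list(trees)


def support_of(node) -> float | None:
    """Bootstrap support of the edge above ``node`` (its label), if numeric."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except (TypeError, ValueError):
        return None


def collapse_low_support(tree: dendropy.Tree, threshold: float
                         ) -> dendropy.Tree:
    """Contract every internal edge whose support is present and below
    ``threshold``; returns a new tree (children of a contracted node are
    reattached to its parent, keeping their own edge lengths).  Edges with
    no support annotation are kept."""
    if not 0.0 <= threshold <= 100.0:
        raise BinningError(f"threshold must lie in [0, 100], got {threshold}")
    out = tree.clone(depth=1)
    doomed = []
    for nd in out.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        sup = support_of(nd)
        if sup is not None and sup < threshold:
            doomed.append(nd)
    for nd in doomed:
        parent = nd.parent_node
        for child in nd.child_nodes():
            nd.remove_child(child)
            parent.add_child(child)
        parent.remove_child(nd)
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _samples_in_tree(tree, lineages, lmap) -> dict[str, list[str]]:
    present: dict[str, list[str]] = {lin: [] for lin in lineages}
    for leaf in tree.leaf_node_iter():
        lin = lmap.assignments.get(leaf.taxon.label)
        if lin in present:
            present[lin].append(leaf.taxon.label)
    for lin, samples in present.items():
        if not samples:
            raise BinningError(f"lineage {lin!r} has no samples in tree")
    return present


def _is_clade(tree, labels: set[str]) -> bool:
    mrca = tree.mrca(taxon_labels=labels)
    below = {lf.taxon.label for lf in mrca.leaf_iter()}
    return below == labels


def classify_strict(tree: dendropy.Tree, hyp: HypothesisSpec,
                    lmap: LineageMap, details: dict | None = None) -> str:
    """Strict topology class of one gene tree: T1, T2, or OTHER."""
    present = _samples_in_tree(tree, hyp.lineages, lmap)
    keep = sorted(s for samples in present.values() for s in samples)
    sub = tree.extract_tree_with_taxa_labels(labels=keep)
    sub.is_rooted = True

    o_labels = set(present[hyp.outgroup])
    mrca_o = sub.mrca(taxon_labels=o_labels)
    rerooted_on_outgroup = True
    if mrca_o is not sub.seed_node:
        if mrca_o.edge.length is None:
            mrca_o.edge.length = 1.0
        sub.reroot_at_edge(mrca_o.edge, update_bipartitions=False)
    else:
        # outgroup not a clade under the read rooting: root on the edge
        # above the ingroup's common ancestor instead (equivalent split
        # when the outgroup is monophyletic in the unrooted sense)
        in_labels = set(keep) - o_labels
        mrca_in = sub.mrca(taxon_labels=in_labels)
        if mrca_in is not sub.seed_node:
            if mrca_in.edge.length is None:
                mrca_in.edge.length = 1.0
            sub.reroot_at_edge(mrca_in.edge, update_bipartitions=False)
        else:
            rerooted_on_outgroup = False
    outgroup_mono = _is_clade(sub, o_labels)

    h = set(present[hyp.hybrid])
    p1 = set(present[hyp.parent1])
    p2 = set(present[hyp.parent2])
    call = OTHER
    if _is_clade(sub, h):
        if _is_clade(sub, p1) and _is_clade(sub, h | p1):
            call = T1
        elif _is_clade(sub, p2) and _is_clade(sub, h | p2):
            call = T2
    if details is not None:
        details["outgroup_monophyletic"] = outgroup_mono
        details["rerooted_on_outgroup"] = rerooted_on_outgroup
    return call


def classify_relaxed(tree: dendropy.Tree, hyp: HypothesisSpec,
                     lmap: LineageMap, seed: int = 0,
                     max_quartets: int = 500,
                     details: dict | None = None) -> str:
    """Support-relaxed topology class: T1, T2, or UNASSIGNED.

    Collapses branches below ``hyp.support_threshold``, then lets every
    (h, p1, p2, o) individual quartet vote; strict majority between the two
    competing resolutions decides, ties stay UNASSIGNED.  At most
    ``max_quartets`` quartets are drawn (seeded) when the full enumeration
    is larger.
    """
    present = _samples_in_tree(tree, hyp.lineages, lmap)
    collapsed = collapse_low_support(tree, hyp.support_threshold)
    labels, D = mrca_depth_table(collapsed)
    groups = [[labels[s] for s in present[lin]] for lin in hyp.lineages]

    total = 1
    for g in groups:
        total *= len(g)
    if total <= max_quartets:
        combos = itertools.product(*groups)
    else:
        rng = np.random.default_rng(seed)
        combos = ((g[rng.integers(len(g))] for g in groups)
                  for _ in range(max_quartets))

    # slot order for (h, p1, p2, o): 0 -> h,p1|p2,o (T1); 1 -> h,p2|p1,o
    # (T2); 2 -> h,o|p1,p2
    tally = [0, 0, 0]
    n_unresolved = 0
    for combo in combos:
        ih, ip1, ip2, io = combo
        slot = resolve_quartet(D, ih, ip1, ip2, io)
        if slot is None:
            n_unresolved += 1
        else:
            tally[slot] += 1
    if details is not None:
        details["quartets_T1"] = tally[0]
        details["quartets_T2"] = tally[1]
        details["quartets_HO"] = tally[2]
        details["quartets_unresolved"] = n_unresolved
    if tally[0] > tally[1]:
        return T1
    if tally[1] > tally[0]:
        return T2
    return UNASSIGNED


def bin_gene_trees(trees: list[dendropy.Tree], hyp: HypothesisSpec,
                   lmap: LineageMap, seed: int = 0,
                   max_quartets: int = 500
                   ) -> tuple[BinCounts, pd.DataFrame]:
    """Classify every tree; returns counts plus a per-tree audit table
    (tree index, strict and relaxed calls, quartet tallies, rooting flags)."""
    if not trees:
        raise BinningError("no gene trees to bin")
    counts = BinCounts()
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(len(trees)) % (2 ** 31)
    for i, tree in enumerate(trees):
        det: dict = {}
        try:
            s_call = classify_strict(tree, hyp, lmap, details=det)
            r_call = classify_relaxed(tree, hyp, lmap, seed=int(seeds[i]),
                                      max_quartets=max_quartets, details=det)
        except BinningError as exc:
            raise BinningError(f"tree {i}: {exc}") from exc
        counts.n_t1 += s_call == T1
        counts.n_t2 += s_call == T2
        counts.n_other += s_call == OTHER
        counts.n_t1_relaxed += r_call == T1
        counts.n_t2_relaxed += r_call == T2
        counts.n_unassigned += r_call == UNASSIGNED
        rows.append({
            "tree_index": i,
            "strict": s_call,
            "relaxed": r_call,
            "quartets_T1": det.get("quartets_T1", 0),
            "quartets_T2": det.get("quartets_T2", 0),
            "quartets_HO": det.get("quartets_HO", 0),
            "quartets_unresolved": det.get("quartets_unresolved", 0),
            "outgroup_monophyletic": det.get("outgroup_monophyletic"),
            "rerooted_on_outgroup": det.get("rerooted_on_outgroup"),
        })
    return counts, pd.DataFrame(rows)
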