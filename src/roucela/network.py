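"""Level-1 phylogenetic networks with a single hybrid node.

A species network here is a rooted tree plus at most one reticulation: a
hybrid node with two parent edges carrying inheritance probabilities
``1 - gamma`` and ``gamma``.  Branch lengths are in coalescent units (the
time scale on which *k* lineages coalesce at rate ``k(k-1)/2``), so they
control the amount of incomplete lineage sorting.  Removing either hybrid
parent edge yields an ordinary rooted species tree (a *displayed tree*);
each locus of the hybrid lineage is assumed to trace exactly one of the two
displayed trees, the second with probability ``gamma``.

The module also provides the closed-form expected quartet concordance
factors on such a network: for a quartet whose internal path has length
``t`` coalescent units on a displayed tree, the displayed resolution has
probability ``1 - (2/3) e^{-t}`` and each alternative ``(1/3) e^{-t}``;
when the hybrid is involved the two displayed-tree triples are mixed with
weights ``(1 - gamma, gamma)``.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "NetworkError",
    "SpeciesNetwork",
    "default_roucela_network",
    "DEFAULT_LINEAGES",
]


class NetworkError(ValueError):
    """Raised for structurally invalid networks or parameters."""


# ---------------------------------------------------------------------------
# Internal graph structure
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "child_edges", "parent_edges")

    def __init__(self, label: str | None = None):
        self.label = label
        self.child_edges: list[_Edge] = []
        self.parent_edges: list[_Edge] = []

    @property
    def is_leaf(self) -> bool:
        return not self.child_edges

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"_Node({self.label!r})"


class _Edge:
    __slots__ = ("parent", "child", "length", "gamma", "eid")

    def __init__(self, parent: _Node, child: _Node, length: float,
                 gamma: float | None = None, eid: str | None = None):
        self.parent = parent
        self.child = child
        self.length = float(length)
        self.gamma = gamma      # inheritance probability; None on tree edges
        self.eid = eid          # identifier for free internal branch lengths


@dataclass
class DisplayedTree:
    """One of the (at most two) trees displayed by the network.

    ``children[node]`` maps a node id to ``(child_id, segments)`` pairs where
    ``segments`` is a list of ``(eid, length)`` for the original network
    edges merged into that displayed-tree edge (degree-two nodes created by
    dropping a hybrid edge are suppressed).
    """

    weight: float
    root: int
    labels: dict[int, str]                       # leaf id -> tip label
    children: dict[int, list[tuple[int, list[tuple[str | None, float]]]]]
    parent: dict[int, tuple[int, list[tuple[str | None, float]]]]
    depth: dict[int, int]                        # topological depth from root

    def leaf_of(self, label: str) -> int:
        for nid, lab in self.labels.items():
            if lab == label:
                return nid
        raise NetworkError(f"unknown lineage {label!r}")

    def node_ages(self, lengths: dict[str, float] | None = None) -> dict[int, float]:
        """Height of each node above the deepest tip, using edge lengths
        (optionally overriding free internal lengths via ``lengths``)."""
        dist = {self.root: 0.0}
        order = [self.root]
        i = 0
        while i < len(order):
            nid = order[i]
            i += 1
            for cid, segs in self.children.get(nid, []):
                d = sum((lengths[e] if (lengths and e in lengths) else ln)
                        for e, ln in segs)
                dist[cid] = dist[nid] + d
                order.append(cid)
        height = max(dist[n] for n in self.labels)
        return {n: height - d for n, d in dist.items()}

    # -- quartet machinery ---------------------------------------------------

    def _ancestors(self, nid: int) -> list[int]:
        path = [nid]
        while path[-1] in self.parent:
            path.append(self.parent[path[-1]][0])
        return path

    def _mrca(self, a: int, b: int) -> int:
        anc = set(self._ancestors(a))
        n = b
        while n not in anc:
            n = self.parent[n][0]
        return n

    def _segments_up(self, nid: int, anc: int) -> list[tuple[str | None, float]]:
        segs: list[tuple[str | None, float]] = []
        n = nid
        while n != anc:
            up, s = self.parent[n]
            segs.extend(s)
            n = up
        return segs

    def quartet_path(self, labels4: Sequence[str]
                     ) -> tuple[int, list[tuple[str | None, float]]]:
        """Resolve the quartet induced by four tip labels.

        Returns ``(slot, segments)`` where slot indexes the unrooted
        resolution in canonical order (0: 12|34, 1: 13|24, 2: 14|23 with
        respect to the label order given) and ``segments`` are the network
        edges on the internal path of the induced quartet.
        """
        a, b, c, d = (self.leaf_of(l) for l in labels4)
        dep = self.depth
        m = {}
        for x, y in itertools.combinations((a, b, c, d), 2):
            m[frozenset((x, y))] = self._mrca(x, y)

        def md(x, y):
            return dep[m[frozenset((x, y))]]

        pairings = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
        slot = None
        for s, ((p, q), (r, t)) in enumerate(pairings):
            if md(p, q) > max(md(p, r), md(p, t)) or \
               md(r, t) > max(md(r, p), md(r, q)):
                slot = s
                break
        if slot is None:
            raise NetworkError("displayed tree does not resolve quartet "
                               f"{labels4} (zero-length or polytomy)")
        (p, q), (r, t) = pairings[slot]
        u = m[frozenset((p, q))]
        v = m[frozenset((r, t))]
        anc_u = set(self._ancestors(u))
        anc_v = set(self._ancestors(v))
        if u in anc_v:          # u is an ancestor of v -> swap roles
            u, v = v, u
            (p, q), (r, t) = (r, t), (p, q)
            anc_u, anc_v = anc_v, anc_u
        if v in anc_u:
            # caterpillar: the (r, t) side Steiner point is the deeper of the
            # two cross ancestors, not v itself
            w1 = self._mrca(u, r)
            w2 = self._mrca(u, t)
            w = w1 if dep[w1] > dep[w2] else w2
            return slot, self._segments_up(u, w)
        w = self._mrca(u, v)
        return slot, self._segments_up(u, w) + self._segments_up(v, w)


# ---------------------------------------------------------------------------
# The public network class
# ---------------------------------------------------------------------------

class SpeciesNetwork:
    """A rooted species tree with at most one hybrid node.

    Construct via :func:`default_roucela_network`, :meth:`from_enewick`, or
    the lower-level :meth:`build` helper.  Tips are lineages; multiple
    sampled individuals per lineage are handled downstream.
    """

    def __init__(self, root: _Node):
        self._root = root
        self._validate()
        self._assign_eids()
        self._displayed: list[DisplayedTree] | None = None

    # -- construction --------------------------------------------------------

    @classmethod
    def build(cls, newick_backbone: str, hybrid: str | None = None,
              parents: tuple[str, str] | None = None,
              gamma: float = 0.5,
              attach_below: float = 0.5,
              hybrid_edge_length: float = 0.5) -> "SpeciesNetwork":
        """Build a network from a plain newick backbone plus a hybrid tip.

        The hybrid tip ``hybrid`` is attached onto the *terminal* edges of
        the two ``parents`` tips, ``attach_below`` coalescent units below
        each parent tip's parent node, via hybrid edges of length
        ``hybrid_edge_length`` with inheritance weights
        ``(1 - gamma, gamma)`` for ``(parents[0], parents[1])``.
        """
        if not 0.0 <= gamma <= 1.0:
            raise NetworkError(f"gamma must lie in [0, 1], got {gamma}")
        root = _parse_enewick(newick_backbone)[0]
        net_tmp = object.__new__(cls)
        net_tmp._root = root
        if hybrid is None:
            return cls(root)
        hyb = _Node(hybrid)
        for w, parent_tip in zip((1.0 - gamma, gamma), parents):
            tip = _find_tip(root, parent_tip)
            (edge,) = tip.parent_edges
            if edge.length < attach_below:
                raise NetworkError(
                    f"terminal edge of {parent_tip!r} (length {edge.length}) "
                    f"is shorter than the attachment depth {attach_below}")
            mid = _Node(None)
            upper = _Edge(edge.parent, mid, edge.length - attach_below)
            lower = _Edge(mid, tip, attach_below)
            edge.parent.child_edges[edge.parent.child_edges.index(edge)] = upper
            mid.parent_edges.append(upper)
            mid.child_edges.append(lower)
            tip.parent_edges[0] = lower
            hedge = _Edge(mid, hyb, hybrid_edge_length, gamma=w)
            mid.child_edges.append(hedge)
            hyb.parent_edges.append(hedge)
        return cls(root)

    @classmethod
    def from_enewick(cls, text: str) -> "SpeciesNetwork":
        """Parse an extended newick string (``#H`` hybrid-node notation,
        ``:length:support:gamma`` edge annotations as written by network
        inference tools)."""
        root, _ = _parse_enewick(text), None
        return cls(root[0])

    # -- validation ----------------------------------------------------------

    def _iter_nodes(self) -> list[_Node]:
        seen: list[_Node] = []
        seen_ids = set()
        stack = [self._root]
        while stack:
            n = stack.pop()
            if id(n) in seen_ids:
                continue
            seen_ids.add(id(n))
            seen.append(n)
            for e in n.child_edges:
                stack.append(e.child)
        return seen

    def _validate(self):
        nodes = self._iter_nodes()
        tips = [n for n in nodes if n.is_leaf]
        labels = [n.label for n in tips]
        if len(set(labels)) != len(labels):
            raise NetworkError(f"tip labels are not unique: {sorted(labels)}")
        hybrids = [n for n in nodes if len(n.parent_edges) == 2]
        if any(len(n.parent_edges) > 2 for n in nodes):
            raise NetworkError("a hybrid node may have exactly two parents")
        if len(hybrids) > 1:
            raise NetworkError("at most one hybrid node is supported (level-1, "
                               "single reticulation)")
        for n in nodes:
            for e in n.child_edges:
                if e.length < 0:
                    raise NetworkError(f"negative edge length {e.length}")
        self._hybrid = hybrids[0] if hybrids else None
        if self._hybrid is not None:
            g1, g2 = (e.gamma for e in self._hybrid.parent_edges)
            if g1 is None and g2 is None:
                g1 = g2 = 0.5
            elif g1 is None:
                g1 = 1.0 - g2
            elif g2 is None:
                g2 = 1.0 - g1
            if not (0 <= g1 <= 1 and 0 <= g2 <= 1 and abs(g1 + g2 - 1) < 1e-9):
                raise NetworkError(
                    f"hybrid inheritance probabilities ({g1}, {g2}) must lie "
                    "in [0, 1] and sum to 1")
            self._hybrid.parent_edges[0].gamma = g1
            self._hybrid.parent_edges[1].gamma = g2

    def _assign_eids(self):
        # internal edges (child is not a tip) get stable ids named by the
        # tip set reachable below them; these are the free branch-length
        # parameters during network fitting
        for n in self._iter_nodes():
            for e in n.child_edges:
                if not e.child.is_leaf:
                    below = sorted(_tips_below(e.child))
                    e.eid = "+".join(below)

    # -- basic properties ----------------------------------------------------

    @property
    def gamma(self) -> float:
        """Inheritance probability on the second hybrid parent edge
        (0 for a plain tree)."""
        if self._hybrid is None:
            return 0.0
        return self._hybrid.parent_edges[1].gamma

    @property
    def hybrid_lineage(self) -> str | None:
        return self._hybrid.label if self._hybrid is not None else None

    @property
    def tip_labels(self) -> list[str]:
        return sorted(n.label for n in self._iter_nodes() if n.is_leaf)

    @property
    def n_hybrid(self) -> int:
        return 0 if self._hybrid is None else 1

    def internal_edge_ids(self) -> list[str]:
        out = []
        for n in self._iter_nodes():
            for e in n.child_edges:
                if e.eid is not None:
                    out.append(e.eid)
        return sorted(set(out))

    def edge_lengths(self) -> dict[str, float]:
        out = {}
        for n in self._iter_nodes():
            for e in n.child_edges:
                if e.eid is not None:
                    out[e.eid] = e.length
        return out

    # -- parameter substitution ---------------------------------------------

    def with_params(self, gamma: float | None = None,
                    lengths: dict[str, float] | None = None
                    ) -> "SpeciesNetwork":
        """Return a copy with updated inheritance probability and/or
        internal branch lengths (keyed by edge id)."""
        clone = self.copy()
        if gamma is not None:
            if not 0.0 <= gamma <= 1.0:
                raise NetworkError(f"gamma must lie in [0, 1], got {gamma}")
            if clone._hybrid is None:
                raise NetworkError("cannot set gamma on a network without a "
                                   "hybrid node")
            clone._hybrid.parent_edges[0].gamma = 1.0 - gamma
            clone._hybrid.parent_edges[1].gamma = gamma
        if lengths:
            for n in clone._iter_nodes():
                for e in n.child_edges:
                    if e.eid in lengths:
                        if lengths[e.eid] < 0:
                            raise NetworkError("negative branch length")
                        e.length = float(lengths[e.eid])
        clone._displayed = None
        return clone

    def copy(self) -> "SpeciesNetwork":
        mapping: dict[int, _Node] = {}

        def rec(n: _Node) -> _Node:
            if id(n) in mapping:
                return mapping[id(n)]
            nn = _Node(n.label)
            mapping[id(n)] = nn
            for e in n.child_edges:
                cc = rec(e.child)
                ne = _Edge(nn, cc, e.length, e.gamma, e.eid)
                nn.child_edges.append(ne)
                cc.parent_edges.append(ne)
            return nn

        return SpeciesNetwork(rec(self._root))

    # -- displayed trees -----------------------------------------------------

    def displayed_trees(self) -> list[DisplayedTree]:
        """The trees displayed by the network with their weights.

        A plain tree displays itself with weight 1; a one-hybrid network
        displays two trees with weights ``(1 - gamma, gamma)``.
        """
        if self._displayed is None:
            if self._hybrid is None:
                self._displayed = [self._extract(None)]
            else:
                self._displayed = [self._extract(keep)
                                   for keep in self._hybrid.parent_edges]
        return self._displayed

    def _extract(self, keep_edge: _Edge | None) -> DisplayedTree:
        labels: dict[int, str] = {}
        children: dict[int, list] = {}
        parent: dict[int, tuple] = {}
        depth: dict[int, int] = {}
        counter = itertools.count()

        def rec(n: _Node, nid: int, d: int):
            depth[nid] = d
            kept = []
            for e in n.child_edges:
                if e.gamma is not None and e is not keep_edge \
                        and e.child is self._hybrid:
                    continue
                kept.append(e)
            if not kept:
                labels[nid] = n.label
                return
            # suppress degree-2 chains, concatenating edge segments
            entries = []
            for e in kept:
                segs = [(e.eid, e.length)]
                ch = e.child
                while True:
                    sub = [se for se in ch.child_edges
                           if not (se.gamma is not None and se is not keep_edge
                                   and se.child is self._hybrid)]
                    if len(sub) == 1 and not ch.is_leaf:
                        segs.append((sub[0].eid, sub[0].length))
                        ch = sub[0].child
                    else:
                        break
                cid = next(counter)
                entries.append((ch, cid, segs))
            children[nid] = [(cid, segs) for _, cid, segs in entries]
            for ch, cid, segs in entries:
                parent[cid] = (nid, segs)
                rec(ch, cid, d + 1)

        root_id = next(counter)
        rec(self._root, root_id, 0)
        weight = 1.0 if keep_edge is None else keep_edge.gamma
        return DisplayedTree(weight=weight, root=root_id, labels=labels,
                             children=children, parent=parent, depth=depth)

    # -- expected quartet concordance factors --------------------------------

    def expected_quartet_cf(self, quartet: Sequence[str]
                            ) -> tuple[float, float, float]:
        """Expected concordance factors of the three resolutions of a
        4-lineage set, in canonical slot order (12|34, 13|24, 14|23 with
        respect to the order given)."""
        if len(set(quartet)) != 4:
            raise NetworkError("quartet must contain four distinct lineages")
        tips = set(self.tip_labels)
        for q in quartet:
            if q not in tips:
                raise NetworkError(f"unknown lineage {q!r}")
        cf = [0.0, 0.0, 0.0]
        for dt in self.displayed_trees():
            slot, segs = dt.quartet_path(quartet)
            t = sum(ln for _, ln in segs)
            e = math.exp(-t)
            for s in range(3):
                cf[s] += dt.weight * (e / 3.0)
            cf[slot] += dt.weight * (1.0 - e)
        return tuple(cf)

    # -- serialisation -------------------------------------------------------

    def to_enewick(self) -> str:
        """Write the network in extended newick (hybrid node tagged ``#H1``
        with ``:length::gamma`` annotations on its parent edges)."""
        written: set[int] = set()

        def rec(n: _Node) -> str:
            if n is self._hybrid:
                tag = f"{n.label}#H1"
                if id(n) in written:
                    return tag
                written.add(id(n))
                return tag
            if n.is_leaf:
                return n.label
            parts = []
            for e in n.child_edges:
                s = rec(e.child)
                if e.gamma is not None:
                    parts.append(f"{s}:{_fmt(e.length)}::{_fmt(e.gamma)}")
                else:
                    parts.append(f"{s}:{_fmt(e.length)}")
            return "(" + ",".join(parts) + ")"

        return rec(self._root) + ";"

    def __repr__(self):  # pragma: no cover
        return (f"SpeciesNetwork(tips={self.tip_labels}, "
                f"hybrid={self.hybrid_lineage!r}, gamma={self.gamma:.3f})")


def _fmt(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _tips_below(n: _Node) -> set[str]:
    out = set()
    stack = [n]
    while stack:
        m = stack.pop()
        if m.is_leaf:
            out.add(m.label)
        for e in m.child_edges:
            stack.append(e.child)
    return out


def _find_tip(root: _Node, label: str) -> _Node:
    stack = [root]
    while stack:
        n = stack.pop()
        if n.is_leaf and n.label == label:
            return n
        for e in n.child_edges:
            stack.append(e.child)
    raise NetworkError(f"tip {label!r} not found in backbone")


# ---------------------------------------------------------------------------
# Extended newick parsing
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*([(),;]|[^(),;:\s]+|:[^(),;:]*)")


def _parse_enewick(text: str) -> list[_Node]:
    """Parse (extended) newick into a root node; ``#H`` tags merge the two
    occurrences of a hybrid node."""
    pos = 0
    n = len(text)
    hybrids: dict[str, _Node] = {}

    def error(msg):
        raise NetworkError(f"newick parse error at position {pos}: {msg}")

    def peek():
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1
        return text[pos] if pos < n else ""

    def read_label():
        nonlocal pos
        start = pos
        while pos < n and text[pos] not in "(),;:":
            pos += 1
        return text[start:pos].strip()

    def read_annotations():
        # :length[:support[:gamma]]
        nonlocal pos
        vals = []
        while peek() == ":":
            pos += 1
            start = pos
            while pos < n and text[pos] not in "(),;:":
                pos += 1
            tok = text[start:pos].strip()
            vals.append(float(tok) if tok else None)
        return vals

    def node():
        nonlocal pos
        children = []
        if peek() == "(":
            pos += 1
            while True:
                children.append(subtree())
                ch = peek()
                if ch == ",":
                    pos += 1
                    continue
                if ch == ")":
                    pos += 1
                    break
                error("expected ',' or ')'")
        label = read_label()
        vals = read_annotations()
        return children, label, vals

    def subtree():
        children, label, vals = node()
        length = vals[0] if len(vals) >= 1 and vals[0] is not None else 1.0
        gamma = vals[2] if len(vals) >= 3 else None
        if "#" in label:
            name, tag = label.split("#", 1)
            if tag in hybrids:
                nd = hybrids[tag]
                if name and nd.label is None:
                    nd.label = name
            else:
                nd = _Node(name or None)
                hybrids[tag] = nd
        else:
            nd = _Node(label or None)
        for ce, clen, cgam in children:
            edge = _Edge(nd, ce, clen, gamma=cgam)
            nd.child_edges.append(edge)
            ce.parent_edges.append(edge)
        return nd, length, gamma

    children, label, vals = node()
    root = _Node(label or None)
    for ce, clen, cgam in children:
        edge = _Edge(root, ce, clen, gamma=cgam)
        root.child_edges.append(edge)
        ce.parent_edges.append(edge)
    if peek() == ";":
        pos += 1
    if not children and (label and "#" not in label):
        # bare leaf "a;" -- degenerate but harmless
        pass
    for tag, nd in hybrids.items():
        if len(nd.parent_edges) != 2:
            raise NetworkError(
                f"hybrid node #{tag} must occur exactly twice (has "
                f"{len(nd.parent_edges)} parents)")
    return [root]


# ---------------------------------------------------------------------------
# The default study network
# ---------------------------------------------------------------------------

DEFAULT_LINEAGES = ["rhodensis", "drabifolia", "erinus4x", "simulans",
                    "creutzburgii", "erinus8x"]

#: gamma is the creutzburgii-side inheritance probability of the octoploid.
DEFAULT_GAMMA = 0.534


def default_roucela_network(gamma: float = DEFAULT_GAMMA,
                            scale: float = 1.0) -> SpeciesNetwork:
    """The six-lineage candidate network for the *Roucela* complex.

    Backbone ``(rhodensis,((drabifolia,erinus4x),(simulans,creutzburgii)))``
    with the octoploid ``erinus8x`` as a hybrid tip attached symmetrically
    onto the terminal edges of tetraploid ``erinus4x`` (weight ``1 - gamma``)
    and ``creutzburgii`` (weight ``gamma``).  All internal edges have length
    ``scale`` coalescent units and the hybrid attachment points sit
    ``scale/2`` below the parental tips' parent nodes, so the two hybrid
    attachment edges are symmetric.
    """
    if not 0.0 <= gamma <= 1.0:
        raise NetworkError(f"gamma must lie in [0, 1], got {gamma}")
    if scale <= 0:
        raise NetworkError(f"scale must be positive, got {scale}")
    s = scale
    backbone = (
        f"(rhodensis:{_fmt(3 * s)},"
        f"((drabifolia:{_fmt(s)},erinus4x:{_fmt(s)}):{_fmt(s)},"
        f"(simulans:{_fmt(s)},creutzburgii:{_fmt(s)}):{_fmt(s)}):{_fmt(s)});"
    )
    return SpeciesNetwork.build(
        backbone,
        hybrid="erinus8x",
        parents=("erinus4x", "creutzburgii"),
        gamma=gamma,
        attach_below=s / 2.0,
        hybrid_edge_length=s / 2.0,
    )
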