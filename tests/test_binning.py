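import itertools

import dendropy
import numpy as np
import pytest

import roucela as rc
from roucela.binning import BinningError, T1, T2, OTHER, UNASSIGNED
from roucela._quartets import mrca_depth_table, resolve_quartet
from conftest import random_binary_tree, quartet_topology_oracle


def tree_of(newick):
    return dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)


def splits(tree):
    """Set of non-trivial leaf-label splits (unrooted clades)."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in nd.leaf_iter())
        if 1 < len(below) < len(all_leaves) - 1:
            out.add(frozenset({below, all_leaves - below}))
    return out


@pytest.fixture
def simple_map():
    return rc.LineageMap({
        "h1": "H", "h2": "H", "p1a": "P1", "p1b": "P1",
        "p2a": "P2", "o1": "O", "o2": "O",
    })


@pytest.fixture
def simple_hyp():
    return rc.HypothesisSpec("H", "P1", "P2", "O")


class TestReadWrite:
    def test_supports_parsed(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((a,b)95,(c,d)80);\n")
        trees = rc.read_gene_trees(p)
        assert len(trees) == 1
        sups = sorted(rc.support_of(nd)
                      for nd in trees[0].preorder_node_iter()
                      if not nd.is_leaf() and nd.parent_node is not None)
        assert sups == [80.0, 95.0]

    def test_multi_tree_file_count(self, tmp_path):
        p = tmp_path / "many.nwk"
        p.write_text("((a:1,b:1):1,c:2);\n" * 130)
        assert len(rc.read_gene_trees(p)) == 130

    def test_round_trip_preserves_supports(self, tmp_path):
        net = rc.default_roucela_network(0.5, 1.0)
        cfg = rc.SimulationConfig(n_genes=5, samples_per_lineage=2, seed=2)
        trees = rc.attach_support(rc.simulate_gene_trees(net, cfg), cfg)
        p = tmp_path / "rt.nwk"
        rc.write_gene_trees(trees, p)
        again = rc.read_gene_trees(p)
        assert [rc.tree_to_newick(t) for t in again] == \
            [rc.tree_to_newick(t) for t in trees]

    def test_malformed_newick_reports_file(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((a,b);;)")
        with pytest.raises(BinningError, match="bad.nwk"):
            rc.read_gene_trees(p)


class TestCollapse:
    def test_high_support_untouched(self):
        tr = tree_of("((a,b)100,(c,d)100);")
        out = rc.collapse_low_support(tr, 80)
        assert splits(out) == splits(tr)

    def test_all_low_support_gives_star(self):
        tr = tree_of("((a,b)10,(c,d)10);")
        out = rc.collapse_low_support(tr, 80)
        assert splits(out) == set()

    def test_manual_contraction_example(self):
        tr = tree_of("(((a,b)50,c)90,(d,e)85);")
        out = rc.collapse_low_support(tr, 80)
        assert splits(out) == splits(tree_of("((a,b,c)90,(d,e)85);"))

    def test_unsupported_edges_kept(self):
        tr = tree_of("(((a,b),c)90,(d,e)85);")
        out = rc.collapse_low_support(tr, 80)
        assert splits(out) == splits(tr)

    def test_collapse_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tr = random_binary_tree([f"x{i}" for i in range(8)], rng)
            for nd in tr.preorder_node_iter():
                if not nd.is_leaf() and nd.parent_node is not None:
                    nd.label = str(int(rng.integers(0, 101)))
            lo = splits(rc.collapse_low_support(tr, 50))
            hi = splits(rc.collapse_low_support(tr, 90))
            assert hi <= lo


class TestStrict:
    def test_t1(self, simple_map, simple_hyp):
        tr = tree_of("(((h1,h2),(p1a,p1b)),(p2a,(o1,o2)));")
        assert rc.classify_strict(tr, simple_hyp, simple_map) == T1

    def test_t2(self, simple_map, simple_hyp):
        tr = tree_of("((((h1,h2),p2a),(p1a,p1b)),(o1,o2));")
        assert rc.classify_strict(tr, simple_hyp, simple_map) == T2

    def test_paraphyletic_hybrid_is_other(self, simple_map, simple_hyp):
        tr = tree_of("(((p1a,h1),(p1b,h2)),(p2a,(o1,o2)));")
        assert rc.classify_strict(tr, simple_hyp, simple_map) == OTHER

    def test_missing_lineage_named(self, simple_hyp):
        lmap = rc.LineageMap({"h1": "H", "p1a": "P1", "o1": "O"})
        tr = tree_of("((h1,p1a),o1);")
        with pytest.raises(BinningError, match="P2"):
            rc.classify_strict(tr, simple_hyp, lmap)

    def test_relabeling_within_lineage_invariant(self, simple_hyp):
        """Swapping sample names within a lineage cannot change the call."""
        lmap = rc.LineageMap({"h1": "H", "h2": "H", "p1a": "P1",
                              "p1b": "P1", "p2a": "P2", "o1": "O",
                              "o2": "O"})
        tr1 = tree_of("(((h1,h2),(p1a,p1b)),(p2a,(o1,o2)));")
        tr2 = tree_of("(((h2,h1),(p1b,p1a)),(p2a,(o2,o1)));")
        assert rc.classify_strict(tr1, simple_hyp, lmap) == \
            rc.classify_strict(tr2, simple_hyp, lmap)

    def test_extra_lineages_pruned(self, simple_hyp):
        lmap = rc.LineageMap({"h1": "H", "p1a": "P1", "p2a": "P2",
                              "o1": "O", "z1": "Z"})
        tr = tree_of("(((h1,z1),p1a),(p2a,o1));")
        # after pruning z1, h1 and p1a are sisters
        assert rc.classify_strict(tr, simple_hyp, lmap) == T1


class TestRelaxed:
    def test_refines_strict_on_resolved_tree(self, simple_map, simple_hyp):
        tr = tree_of("(((h1,h2)99,(p1a,p1b)99)99,(p2a,(o1,o2)99)99);")
        assert rc.classify_strict(tr, simple_hyp, simple_map) == T1
        assert rc.classify_relaxed(tr, simple_hyp, simple_map) == T1

    def test_star_tree_unassigned(self, simple_map, simple_hyp):
        tr = tree_of("(h1,h2,p1a,p1b,p2a,o1,o2);")
        assert rc.classify_relaxed(tr, simple_hyp, simple_map) == UNASSIGNED

    def test_quartet_majority(self, simple_hyp):
        """Two quartets voting hp1|p2o against one voting hp2|p1o -> T1."""
        lmap = rc.LineageMap({"h1": "H", "h2": "H", "p1a": "P1",
                              "p2a": "P2", "o1": "O"})
        # h1 and h2 sit on opposite sides: (h1,p1a) cherry vs (h2,p2a) cherry
        tr = tree_of("(((h1,p1a)99,(h2,p2a)99)99,o1);")
        det = {}
        call = rc.classify_relaxed(tr, simple_hyp, lmap, details=det)
        assert det["quartets_T1"] == 1 and det["quartets_T2"] == 1
        assert call == UNASSIGNED  # exact tie stays unassigned

    def test_low_support_conflict_discounted(self, simple_map, simple_hyp):
        """A strictly-OTHER tree whose conflicting edge is weak becomes T1
        after collapsing."""
        tr = tree_of("((((h1,p1b)40,h2)95,p1a)95,(p2a,(o1,o2)95)95);")
        assert rc.classify_strict(tr, simple_hyp, simple_map) == OTHER
        assert rc.classify_relaxed(tr, simple_hyp, simple_map) == T1

    def test_agrees_with_fourpoint_oracle_on_random_trees(self):
        """The MRCA-depth quartet rule matches an independent four-point
        distance oracle for every 4-subset of 100 random 12-leaf trees."""
        rng = np.random.default_rng(41)
        labels = [f"s{i:02d}" for i in range(12)]
        for _ in range(100):
            tr = random_binary_tree(labels, rng)
            idx, D = mrca_depth_table(tr)
            for quad in itertools.combinations(sorted(labels), 4):
                got = resolve_quartet(D, *(idx[l] for l in quad))
                assert got == quartet_topology_oracle(tr, quad)


class TestBinCounts:
    def test_identical_t1_trees(self, simple_map, simple_hyp):
        trees = [tree_of("(((h1,h2)99,(p1a,p1b)99)99,(p2a,(o1,o2)99)99);")
                 for _ in range(10)]
        counts, audit = rc.bin_gene_trees(trees, simple_hyp, simple_map)
        f = counts.frequencies()
        assert (f["strict_T1"], f["strict_T2"], f["strict_OTHER"]) == \
            (1.0, 0.0, 0.0)
        assert len(audit) == 10

    def test_counts_conserved(self, lineage_map_2x, hypothesis_spec):
        net = rc.default_roucela_network(0.4, 1.0)
        cfg = rc.SimulationConfig(n_genes=50, samples_per_lineage=2, seed=10)
        trees = rc.attach_support(rc.simulate_gene_trees(net, cfg), cfg)
        counts, _ = rc.bin_gene_trees(trees, hypothesis_spec, lineage_map_2x)
        assert counts.n_t1 + counts.n_t2 + counts.n_other == 50
        assert (counts.n_t1_relaxed + counts.n_t2_relaxed
                + counts.n_unassigned) == 50
        assert sum(counts.frequencies()[k]
                   for k in ("strict_T1", "strict_T2", "strict_OTHER")) == \
            pytest.approx(1.0)
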