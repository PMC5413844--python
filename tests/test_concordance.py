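import itertools
import math

import dendropy
import numpy as np
import pytest

import roucela as rc
from conftest import random_binary_tree, quartet_topology_oracle


def tree_of(newick):
    return dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)


class TestCladeCF:
    def test_simple_fraction(self):
        concordant = [tree_of("(((a,b),c),d);") for _ in range(3)]
        discordant = [tree_of("(((a,c),b),d);") for _ in range(7)]
        res = rc.clade_cf(concordant + discordant, {"a", "b"})
        assert res.cf == pytest.approx(0.3)
        assert res.n_trees == 10

    def test_whole_tree_clade_uninformative(self):
        trees = [tree_of("((a,b),c);")]
        with pytest.raises(ValueError, match="uninformative"):
            rc.clade_cf(trees, {"a", "b", "c"})

    def test_empty_clade_rejected(self):
        with pytest.raises(ValueError):
            rc.clade_cf([tree_of("((a,b),c);")], set())

    def test_matches_monophyly_scan_oracle(self):
        """CF over random trees equals an independent per-tree scan that
        checks whether some node's leaf set is exactly the clade."""
        rng = np.random.default_rng(47)
        labels = [f"s{i}" for i in range(8)]
        trees = [random_binary_tree(labels, rng) for _ in range(50)]
        clade = {"s0", "s1", "s2"}
        res = rc.clade_cf(trees, clade)
        hits = 0
        for tr in trees:
            node_sets = [frozenset(l.taxon.label for l in nd.leaf_iter())
                         for nd in tr.preorder_node_iter()]
            hits += frozenset(clade) in node_sets
        assert res.cf == pytest.approx(hits / 50)


class TestQuartetCFTable:
    def test_identical_trees_give_unit_cf(self, lineage_map_2x):
        net = rc.default_roucela_network(0.0, 10.0)
        cfg = rc.SimulationConfig(n_genes=1, samples_per_lineage=2, seed=1)
        tree = rc.simulate_gene_trees(net, cfg)[0]
        trees = [tree] * 20
        tab = rc.quartet_cf_table(trees, lineage_map_2x,
                                  lineage_map_2x.lineages, seed=0)
        assert len(tab) == math.comb(6, 4)
        cfs = tab[["cf12_34", "cf13_24", "cf14_23"]].to_numpy()
        assert np.allclose(cfs.max(axis=1), 1.0)
        assert np.allclose(cfs.sum(axis=1), 1.0)

    def test_triples_normalized(self, lineage_map_2x):
        net = rc.default_roucela_network(0.5, 0.5)
        cfg = rc.SimulationConfig(n_genes=60, samples_per_lineage=2, seed=2)
        trees = rc.simulate_gene_trees(net, cfg)
        tab = rc.quartet_cf_table(trees, lineage_map_2x,
                                  lineage_map_2x.lineages, seed=0)
        sums = tab[["cf12_34", "cf13_24", "cf14_23"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_absent_lineage_named(self, lineage_map_2x):
        trees = [tree_of("((erinus8x_1,erinus4x_1),rhodensis_1);")]
        with pytest.raises(Exception, match="creutzburgii"):
            rc.quartet_cf_table(trees, lineage_map_2x,
                                lineage_map_2x.lineages, seed=0)

    def test_matches_exhaustive_per_gene_counting(self):
        """CF table over random resolved trees equals brute-force quartet
        counting via the independent four-point oracle."""
        rng = np.random.default_rng(53)
        lineages = [f"L{i}" for i in range(6)]
        lmap = rc.LineageMap({f"L{i}_1": f"L{i}" for i in range(6)})
        labels = sorted(lmap.assignments)
        trees = [random_binary_tree(labels, rng) for _ in range(200)]
        tab = rc.quartet_cf_table(trees, lmap, lineages, seed=0)
        for row in tab.itertuples(index=False):
            quad = tuple(sorted(f"{l}_1" for l in
                                (row.l1, row.l2, row.l3, row.l4)))
            votes = [0, 0, 0]
            for tr in trees:
                slot = quartet_topology_oracle(tr, quad)
                if slot is not None:
                    votes[slot] += 1
            n = sum(votes)
            assert row.n_eff == n
            assert (row.cf12_34, row.cf13_24, row.cf14_23) == \
                pytest.approx(tuple(v / n for v in votes))

    def test_simulated_cf_matches_closed_form(self):
        """4-tip species tree with internal path t=1: the major observed CF
        approaches 1-(2/3)e^{-1}."""
        net = rc.SpeciesNetwork.build("((a:2,b:2):0.5,(c:2,d:2):0.5);")
        n = 8000
        cfg = rc.SimulationConfig(n_genes=n, samples_per_lineage=1, seed=19)
        trees = rc.simulate_gene_trees(net, cfg)
        lmap = rc.LineageMap({f"{l}_1": l for l in "abcd"})
        tab = rc.quartet_cf_table(trees, lmap, list("abcd"), seed=0)
        p = 1 - (2 / 3) * math.exp(-1)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(tab.iloc[0]["cf12_34"] - p) < 3 * se


class TestPseudolik:
    def test_single_quartet_arithmetic(self):
        import pandas as pd
        net = rc.SpeciesNetwork.build("((a:2,b:2):0.5,(c:2,d:2):0.5);")
        tab = pd.DataFrame([("a", "b", "c", "d", 1.0, 0.0, 0.0, 100)],
                           columns=rc.concordance.CF_COLUMNS)
        val = rc.network_pseudolik(net, tab)
        assert val == pytest.approx(100 * math.log(0.7547470392), abs=1e-4)
        assert val == pytest.approx(-28.14, abs=0.01)

    def test_linearity_in_n_eff(self, default_net):
        tab = rc.expected_cf_table(default_net, n_eff=50)
        doubled = tab.copy()
        doubled["n_eff"] = 100
        assert rc.network_pseudolik(default_net, doubled) == \
            pytest.approx(2 * rc.network_pseudolik(default_net, tab))

    def test_truth_maximizes_gibbs(self, default_net):
        """When observed CFs equal the expectation, any parameter change
        scores lower (Gibbs inequality)."""
        tab = rc.expected_cf_table(default_net, n_eff=100)
        best = rc.network_pseudolik(default_net, tab)
        for g in (0.1, 0.9):
            assert rc.network_pseudolik(default_net.with_params(gamma=g),
                                        tab) < best
        shrunk = default_net.with_params(
            lengths={e: 0.3 for e in default_net.internal_edge_ids()})
        assert rc.network_pseudolik(shrunk, tab) < best


class TestFit:
    def test_self_consistency_recovers_gamma(self):
        truth = rc.default_roucela_network(0.3, 1.0)
        tab = rc.expected_cf_table(truth, n_eff=100)
        fit = rc.fit_network(tab, rc.default_roucela_network(0.5, 1.0),
                             seed=5)
        assert abs(fit.gamma_hat - 0.3) < 1e-3

    def test_boundary_gamma_zero(self):
        truth = rc.default_roucela_network(0.0, 1.0)
        tab = rc.expected_cf_table(truth, n_eff=100)
        fit = rc.fit_network(tab, rc.default_roucela_network(0.5, 1.0),
                             seed=5)
        assert fit.gamma_hat < 0.02

    def test_nesting_fixed_gamma_reproduces_tree_fit(self, default_net):
        tab = rc.expected_cf_table(default_net, n_eff=100)
        a = rc.fit_network(tab, default_net, fix_gamma=0.0, seed=7)
        b = rc.fit_network(tab, default_net, fix_gamma=0.0, seed=7)
        assert a.loglik == b.loglik
        assert a.gamma_fixed and a.gamma_hat == 0.0

    def test_parameter_recovery_from_simulation(self):
        """gamma and the attachment-path lengths are recovered from CFs of
        10,000 simulated genes within +/-0.05."""
        gamma = 0.3
        net = rc.default_roucela_network(gamma, 1.0)
        cfg = rc.SimulationConfig(n_genes=10000, samples_per_lineage=2,
                                  seed=61)
        trees = rc.simulate_gene_trees(net, cfg)
        lmap = rc.LineageMap({s: l for l, ss in
                              rc.sample_names(net, cfg).items() for s in ss})
        tab = rc.quartet_cf_table(trees, lmap, lmap.lineages, seed=1)
        fit = rc.fit_network(tab, rc.default_roucela_network(0.5, 1.0),
                             seed=3)
        assert abs(fit.gamma_hat - gamma) <= 0.05

    def test_empty_table_rejected(self, default_net):
        import pandas as pd
        with pytest.raises(ValueError):
            rc.fit_network(pd.DataFrame(columns=rc.concordance.CF_COLUMNS),
                           default_net)


class TestCompareModels:
    def test_tree_data_gives_no_hybrid_support(self):
        """Data generated without any hybrid contribution (gamma=0): the
        free fit gains essentially nothing over the gamma=0 fit and the
        hybrid edge is not supported."""
        truth = rc.default_roucela_network(0.0, 1.0)
        tab = rc.expected_cf_table(truth, n_eff=200)
        cand = rc.default_roucela_network(0.5, 1.0)
        h1 = rc.fit_network(tab, cand, seed=1)
        t0 = rc.fit_network(tab, cand, fix_gamma=0.0, seed=1)
        rep = rc.compare_models(t0, h1, margin=0.5)
        assert abs(rep["delta_pseudolik"]) < 1e-6
        assert h1.gamma_hat < 0.02
        assert rep["verdict"] == "no support for a hybrid edge"

    def test_hybrid_data_supported(self):
        net = rc.default_roucela_network(0.5, 0.5)
        cfg = rc.SimulationConfig(n_genes=2000, samples_per_lineage=1,
                                  seed=67)
        trees = rc.simulate_gene_trees(net, cfg)
        lmap = rc.LineageMap({f"{l}_1": l for l in rc.DEFAULT_LINEAGES})
        tab = rc.quartet_cf_table(trees, lmap, lmap.lineages, seed=2)
        cand = rc.default_roucela_network(0.5, 1.0)
        h1 = rc.fit_network(tab, cand, seed=3)
        t0 = rc.fit_network(tab, cand, fix_gamma=0.0, seed=3)
        rep = rc.compare_models(t0, h1)
        assert rep["delta_pseudolik"] > 0
        assert rep["verdict"] == "hybrid edge supported"

    def test_mismatched_tables_rejected(self, default_net):
        tab1 = rc.expected_cf_table(default_net, n_eff=100)
        tab2 = rc.expected_cf_table(default_net, n_eff=50)
        f1 = rc.fit_network(tab1, default_net, seed=1)
        f2 = rc.fit_network(tab2, default_net, fix_gamma=0.0, seed=1)
        with pytest.raises(ValueError):
            rc.compare_models(f2, f1)
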