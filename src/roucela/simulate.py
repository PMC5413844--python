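"""Synthetic data with the statistical structure the analysis assumes.

Gene trees are drawn from a one-hybrid species network under the network
multispecies coalescent: each locus first chooses the hybrid lineage's
parental path (Bernoulli with the inheritance probability ``gamma``) and
then coalesces on the resulting displayed tree.  Within a species-tree
branch of length ``t`` coalescent units, ``k`` lineages merge at rate
``k(k-1)/2``; at the root the process runs to a single ancestor.  All
branch lengths are therefore in coalescent units (2N-generation units).

The module also attaches noisy bootstrap-like supports to internal edges,
evolves optional Jukes-Cantor alignments, and draws bract morphometrics for
two indistinguishable cytotypes plus one long-toothed relative -- enough to
exercise every downstream stage without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .network import SpeciesNetwork, NetworkError, default_roucela_network
from .morphology import BractRecord

__all__ = [
    "SimulationConfig",
    "BractLineageParams",
    "DEFAULT_BRACT_PARAMS",
    "simulate_gene_trees",
    "attach_support",
    "simulate_alignment",
    "simulate_bracts",
    "simulate_assembly_summaries",
    "tree_to_newick",
    "write_gene_trees",
    "write_lineage_map",
    "write_fasta",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic generator.

    samples_per_lineage may be a single count applied to every lineage or a
    per-lineage mapping.  ``support_lambda`` is the branch-length scale of
    the support model: an internal edge of length ``l`` receives a support
    drawn from ``Binomial(B, 1 - exp(-l/lambda))`` rescaled to [0, 100], so
    short (ILS-prone) edges get low, noisy support.  ``subst_scale``
    converts coalescent units to expected substitutions/site for optional
    alignments.
    """

    n_genes: int = 130
    samples_per_lineage: int | dict[str, int] = 2
    seed: int = 0
    support_lambda: float = 0.2
    support_replicates: int = 100
    subst_scale: float = 0.01
    n_sites: int = 500

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        counts = (self.samples_per_lineage.values()
                  if isinstance(self.samples_per_lineage, dict)
                  else [self.samples_per_lineage])
        if any(c < 1 for c in counts):
            raise ValueError("samples_per_lineage counts must be >= 1")
        if self.support_lambda <= 0:
            raise ValueError("support_lambda must be > 0")

    def n_samples(self, lineage: str) -> int:
        if isinstance(self.samples_per_lineage, dict):
            return self.samples_per_lineage[lineage]
        return self.samples_per_lineage


def sample_names(network: SpeciesNetwork, config: SimulationConfig
                 ) -> dict[str, list[str]]:
    """Deterministic per-lineage sample ids, e.g. ``erinus8x_1``."""
    return {lin: [f"{lin}_{i + 1}" for i in range(config.n_samples(lin))]
            for lin in network.tip_labels}


# ---------------------------------------------------------------------------
# Gene-tree simulation (network multispecies coalescent)
# ---------------------------------------------------------------------------

def simulate_gene_trees(network: SpeciesNetwork, config: SimulationConfig
                        ) -> list[dendropy.Tree]:
    """Draw ``config.n_genes`` gene trees from the network MSC.

    Per gene: the hybrid's parental path is chosen with probability
    ``gamma`` (second displayed tree), then lineages of all sampled
    individuals coalesce on that displayed tree.  Trees are rooted, with
    coalescent-unit branch lengths, reproducible under ``config.seed``.
    """
    if not isinstance(network, SpeciesNetwork):
        raise NetworkError("simulate_gene_trees requires a SpeciesNetwork")
    rng = np.random.default_rng(config.seed)
    samples = sample_names(network, config)

    displayed = network.displayed_trees()
    prepared = []
    for dt in displayed:
        ages = dt.node_ages()
        prepared.append((dt, ages))
    gamma = network.gamma if len(displayed) == 2 else 0.0

    tns = dendropy.TaxonNamespace()
    taxa = {name: tns.new_taxon(label=name)
            for lin in sorted(samples) for name in samples[lin]}

    trees = []
    for _ in range(config.n_genes):
        use_second = len(displayed) == 2 and rng.random() < gamma
        dt, ages = prepared[1] if use_second else prepared[0]
        root_lin = _coalesce_on_tree(dt, ages, samples, rng)
        trees.append(_lineage_to_dendropy(root_lin, tns, taxa))
    return trees


def _coalesce_on_tree(dt, ages, samples, rng):
    """Run the MSC on a displayed tree; returns a nested (height, payload)
    lineage structure for the single root ancestor."""

    def coalesce(pool, t0, t1):
        t = t0
        while len(pool) > 1:
            k = len(pool)
            t += rng.exponential(2.0 / (k * (k - 1)))
            if t >= t1:
                break
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            a, b = pool[i], pool[j]
            pool.pop(max(i, j))
            pool.pop(min(i, j))
            pool.append((t, (a, b)))
        return pool

    def rec(nid):
        kids = dt.children.get(nid)
        if not kids:
            label = dt.labels[nid]
            pool = [(ages[nid], name) for name in samples[label]]
        else:
            pool = []
            for cid, _segs in kids:
                pool.extend(rec(cid))
        if nid == dt.root:
            return coalesce(pool, ages[nid], math.inf)
        return coalesce(pool, ages[nid], ages[dt.parent[nid][0]])

    result = rec(dt.root)
    assert len(result) == 1
    return result[0]


def _lineage_to_dendropy(root_lin, tns, taxa) -> dendropy.Tree:
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True

    def build(lin, parent_node, parent_height):
        height, payload = lin
        node = dendropy.Node()
        if parent_node is None:
            tree.seed_node = node
        else:
            parent_node.add_child(node)
            node.edge.length = parent_height - height
        if isinstance(payload, str):
            node.taxon = taxa[payload]
        else:
            for child in payload:
                build(child, node, height)
        return node

    build(root_lin, None, None)
    return tree


# ---------------------------------------------------------------------------
# Bootstrap-like supports
# ---------------------------------------------------------------------------

def attach_support(trees: list[dendropy.Tree], config: SimulationConfig
                   ) -> list[dendropy.Tree]:
    """Attach supports to internal edges, in place; returns the list.

    Support for an internal edge of length ``l`` is drawn from
    ``Binomial(B, 1 - exp(-l / lambda))`` and rescaled to [0, 100]; it is
    stored as the child node's label (the common newick dialect).
    """
    rng = np.random.default_rng(config.seed + 1)
    lam = config.support_lambda
    B = config.support_replicates
    for idx, tree in enumerate(trees):
        for nd in tree.preorder_node_iter():
            if nd.is_leaf() or nd.parent_node is None:
                continue
            if nd.edge.length is None:
                raise ValueError(
                    f"tree {idx}: internal edge without branch length; "
                    "supports require branch lengths")
            p = 1.0 - math.exp(-nd.edge.length / lam)
            nd.label = str(round(100.0 * rng.binomial(B, p) / B))
    return trees


# ---------------------------------------------------------------------------
# Jukes-Cantor alignments
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_alignment(tree: dendropy.Tree, config: SimulationConfig,
                       rng: np.random.Generator | None = None
                       ) -> dict[str, str]:
    """Evolve ``n_sites`` independent sites under Jukes-Cantor along the
    tree, with branch lengths rescaled by ``subst_scale`` (coalescent units
    to substitutions/site).  Returns ``{leaf label: sequence}``."""
    if config.n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {config.n_sites}")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    L = config.n_sites
    s = config.subst_scale
    seqs: dict[str, str] = {}

    def evolve(parent_states, nd):
        if nd.edge.length is None or nd.parent_node is None:
            states = parent_states
        else:
            d = nd.edge.length * s
            # JC probability a site differs from its parent state
            p_diff = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
            states = parent_states.copy()
            hit = rng.random(L) < p_diff
            n_hit = int(hit.sum())
            if n_hit:
                # jump to one of the three other bases, uniformly
                shift = rng.integers(1, 4, size=n_hit)
                states[hit] = (states[hit] + shift) % 4
        if nd.is_leaf():
            seqs[nd.taxon.label] = _BASES[states].tobytes().decode("ascii")
        else:
            for child in nd.child_nodes():
                evolve(states, child)

    root_states = rng.integers(0, 4, size=L)
    evolve(root_states, tree.seed_node)
    return seqs


# ---------------------------------------------------------------------------
# Bract morphometrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BractLineageParams:
    """Per-lineage generative parameters for bract morphometrics (mm)."""
    ratio_mean: float      # mean tooth/bract ratio
    ratio_sd: float
    bract_mean: float = 8.0
    bract_sd: float = 2.0
    n: int = 100


#: The two cytotypes share the corrected-tooth distribution (they are
#: morphologically cryptic); the long-toothed relative is well separated.
#: Default sample sizes follow the herbarium survey (22 / 123 / 129).
DEFAULT_BRACT_PARAMS: dict[str, BractLineageParams] = {
    "creutzburgii": BractLineageParams(ratio_mean=0.36, ratio_sd=0.07, n=22),
    "erinus_4x": BractLineageParams(ratio_mean=0.12, ratio_sd=0.03, n=123),
    "erinus_8x": BractLineageParams(ratio_mean=0.12, ratio_sd=0.03, n=129),
}


def simulate_bracts(n_per_lineage: int | dict[str, int] | None = None,
                    params: dict[str, BractLineageParams] | None = None,
                    seed: int = 0) -> list[BractRecord]:
    """Draw bract/tooth measurements for the three lineages.

    Bract lengths are truncated normal (positive); tooth length is bract
    length times a noisy per-lineage ratio, truncated to ``(0, bract)``.
    """
    params = dict(params or DEFAULT_BRACT_PARAMS)
    if n_per_lineage is not None:
        if isinstance(n_per_lineage, int):
            n_map = {lin: n_per_lineage for lin in params}
        else:
            n_map = dict(n_per_lineage)
        for lin, n in n_map.items():
            if n < 1:
                raise ValueError(f"n_per_lineage must be >= 1 for {lin!r}, "
                                 f"got {n}")
            params[lin] = replace(params[lin], n=n)
    rng = np.random.default_rng(seed)
    records: list[BractRecord] = []
    for lin in sorted(params):
        p = params[lin]
        if p.n < 1:
            raise ValueError(f"sample size must be >= 1 for {lin!r}")
        bract = np.clip(rng.normal(p.bract_mean, p.bract_sd, size=p.n),
                        0.5, None)
        ratio = np.clip(rng.normal(p.ratio_mean, p.ratio_sd, size=p.n),
                        1e-3, 0.999)
        tooth = bract * ratio
        area = 0.35 * bract ** 2   # crude geometric stand-in, stored only
        for i in range(p.n):
            records.append(BractRecord(
                specimen_id=f"{lin}_sp{i + 1}",
                lineage=lin,
                bract_length=float(bract[i]),
                bract_tooth_length=float(tooth[i]),
                bract_area=float(area[i]),
            ))
    return records


# ---------------------------------------------------------------------------
# Synthetic locus-assembly summaries (for the QC stage)
# ---------------------------------------------------------------------------

def simulate_assembly_summaries(loci: list[str], taxa: list[str],
                                seed: int = 0,
                                paralog_rate: float = 0.03,
                                missing_rate: float = 0.02):
    """Per-locus contig summaries: mostly one near-full-length contig per
    taxon, with occasional second long contigs (paralog-like) and missing
    taxa.  Returns a pandas DataFrame (locus_id, taxon_id, contig_id,
    fraction)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for locus in loci:
        for taxon in taxa:
            u = rng.random()
            if u < missing_rate:
                continue
            frac = float(np.clip(rng.normal(1.0, 0.12), 0.3, 1.4))
            rows.append((locus, taxon, "c1", round(frac, 4)))
            if u > 1.0 - paralog_rate:
                frac2 = float(np.clip(rng.normal(0.95, 0.1), 0.76, 1.3))
                rows.append((locus, taxon, "c2", round(frac2, 4)))
    return pd.DataFrame(rows, columns=["locus_id", "taxon_id", "contig_id",
                                       "fraction"])


# ---------------------------------------------------------------------------
# Deterministic writers
# ---------------------------------------------------------------------------

def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Byte-stable newick with branch lengths and internal-node labels
    (supports)."""

    def rec(nd):
        if nd.is_leaf():
            body = nd.taxon.label
        else:
            body = "(" + ",".join(rec(c) for c in nd.child_nodes()) + ")"
            if nd.label is not None:
                body += str(nd.label)
        if nd.edge.length is not None and nd.parent_node is not None:
            body += ":" + _fmt_len(nd.edge.length)
        return body

    return rec(tree.seed_node) + ";"


def write_gene_trees(trees: list[dendropy.Tree], path) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree_to_newick(tree) + "\n")


def write_lineage_map(samples: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlineage\n")
        for lin in sorted(samples):
            for name in samples[lin]:
                fh.write(f"{name}\t{lin}\n")


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n{seqs[name]}\n")
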