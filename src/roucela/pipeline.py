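"""End-to-end orchestration: simulate -> qc -> bin -> cf -> fit -> morph.

One YAML-serialisable configuration drives all stages; every source of
randomness derives from a single root seed (split deterministically per
stage), so a rerun with the same configuration reproduces every output
byte for byte.  Each stage writes its own artifacts into the output
directory and the final ``report.json`` aggregates the numbers downstream
consumers need, together with provenance (seed, thresholds, version).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .binning import HypothesisSpec, LineageMap, bin_gene_trees, read_gene_trees
from .concordance import (clade_cf, compare_models, fit_network,
                          quartet_cf_table, CF_COLUMNS)
from .morphology import lineage_comparison, read_bract_tsv, write_report
from .network import SpeciesNetwork, default_roucela_network, DEFAULT_GAMMA
from .qc import completeness_filter, flag_paralogs, presence_matrix, read_assembly_tsv
from .simulate import (SimulationConfig, attach_support, sample_names,
                       simulate_assembly_summaries, simulate_bracts,
                       simulate_gene_trees, write_gene_trees,
                       write_lineage_map)

__all__ = ["PipelineConfig", "run_all"]

log = logging.getLogger("roucela")

DEFAULT_STAGES = ("simulate", "qc", "bin", "cf", "fit", "morph")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    outdir: str = "roucela_out"
    seed: int = 0
    stages: tuple[str, ...] = DEFAULT_STAGES

    # synthetic generation
    n_genes: int = 130
    samples_per_lineage: int = 2
    gamma: float = DEFAULT_GAMMA
    scale: float = 1.0

    # external inputs (used when the simulate stage is disabled)
    trees_path: str | None = None
    map_path: str | None = None
    qc_path: str | None = None
    morph_path: str | None = None
    network_enewick: str | None = None

    # hypothesis & thresholds
    hybrid: str = "erinus8x"
    parent1: str = "erinus4x"
    parent2: str = "creutzburgii"
    outgroup: str = "rhodensis"
    support_threshold: float = 80.0
    min_fraction: float = 0.75
    max_quartets: int = 500
    n_restarts: int = 10

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(
            len(DEFAULT_STAGES)) % (2 ** 31)
        return {s: int(v) for s, v in zip(DEFAULT_STAGES, state)}


def run_all(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the aggregated report
    (also written to ``<outdir>/report.json``).

    A stage failure is logged with the stage name and the stages that
    depend on its outputs are skipped; the report records the error.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    report: dict = {
        "provenance": {
            "package": "roucela",
            "version": __version__,
            "seed": config.seed,
            "support_threshold": config.support_threshold,
            "min_fraction": config.min_fraction,
            "gamma_simulated": config.gamma if "simulate" in config.stages else None,
            "stages": list(config.stages),
        },
        "errors": {},
    }
    hyp = HypothesisSpec(config.hybrid, config.parent1, config.parent2,
                         config.outgroup, config.support_threshold)

    trees = None
    lmap = None
    qc_table_path = config.qc_path
    morph_path = config.morph_path
    failed = set()

    def guard(stage, needs=()):
        if stage not in config.stages:
            return False
        broken = [n for n in needs if n in failed]
        if broken:
            log.error("[%s] skipped: upstream stage(s) failed: %s",
                      stage, broken)
            failed.add(stage)
            report["errors"][stage] = f"skipped (upstream failed: {broken})"
            return False
        return True

    # -- simulate ------------------------------------------------------------
    if guard("simulate"):
        try:
            log.info("[simulate] %d genes, gamma=%.3f, scale=%.2f",
                     config.n_genes, config.gamma, config.scale)
            network = default_roucela_network(config.gamma, config.scale)
            sim = SimulationConfig(n_genes=config.n_genes,
                                   samples_per_lineage=config.samples_per_lineage,
                                   seed=seeds["simulate"])
            trees = simulate_gene_trees(network, sim)
            attach_support(trees, sim)
            samples = sample_names(network, sim)
            write_gene_trees(trees, out / "gene_trees.nwk")
            write_lineage_map(samples, out / "lineages.tsv")
            lmap = LineageMap({s: lin for lin, ss in samples.items()
                               for s in ss})
            loci = [f"locus{i + 1:04d}" for i in range(config.n_genes)]
            taxa = sorted(s for ss in samples.values() for s in ss)
            asm = simulate_assembly_summaries(loci, taxa,
                                              seed=seeds["simulate"] + 1)
            asm.to_csv(out / "assemblies.tsv", sep="\t", index=False)
            qc_table_path = out / "assemblies.tsv"
            bracts = simulate_bracts(seed=seeds["simulate"] + 2)
            from .morphology import records_to_frame
            records_to_frame(bracts).to_csv(out / "bracts.tsv", sep="\t",
                                            index=False)
            morph_path = out / "bracts.tsv"
            report["simulate"] = {"n_genes": len(trees),
                                  "n_samples": len(lmap.assignments)}
        except Exception as exc:
            log.exception("[simulate] failed")
            failed.add("simulate")
            report["errors"]["simulate"] = str(exc)

    if trees is None and config.trees_path and "simulate" not in failed:
        trees = read_gene_trees(config.trees_path)
    if lmap is None and config.map_path:
        lmap = LineageMap.from_tsv(config.map_path)

    # -- qc ------------------------------------------------------------------
    kept_loci = None
    if guard("qc", needs=("simulate",) if "simulate" in config.stages else ()):
        try:
            asm = read_assembly_tsv(qc_table_path)
            flags = flag_paralogs(asm, config.min_fraction)
            matrix = presence_matrix(asm, flags)
            kept_loci = completeness_filter(matrix, list(matrix.columns))
            pd_flags = sorted(flags)
            with open(out / "qc_flags.tsv", "w") as fh:
                fh.write("locus_id\ttaxon_id\n")
                for locus, taxon in pd_flags:
                    fh.write(f"{locus}\t{taxon}\n")
            (out / "kept_loci.txt").write_text(
                "".join(f"{l}\n" for l in kept_loci))
            report["qc"] = {"n_loci": int(matrix.shape[0]),
                            "n_taxa": int(matrix.shape[1]),
                            "n_paralog_flags": len(flags),
                            "n_kept_loci": len(kept_loci)}
            log.info("[qc] %d/%d loci kept, %d paralog flags",
                     len(kept_loci), matrix.shape[0], len(flags))
        except Exception as exc:
            log.exception("[qc] failed")
            failed.add("qc")
            report["errors"]["qc"] = str(exc)

    # restrict trees to QC-passing loci (simulated locus i <-> tree i)
    binned_trees = trees
    if (trees is not None and kept_loci is not None
            and "simulate" in config.stages):
        idx = {f"locus{i + 1:04d}": i for i in range(len(trees))}
        binned_trees = [trees[idx[l]] for l in kept_loci if l in idx]

    # -- bin -----------------------------------------------------------------
    if guard("bin"):
        try:
            if binned_trees is None or lmap is None:
                raise ValueError("bin stage needs gene trees and a lineage map")
            counts, audit = bin_gene_trees(binned_trees, hyp, lmap,
                                           seed=seeds["bin"],
                                           max_quartets=config.max_quartets)
            audit.to_csv(out / "per_tree_bins.tsv", sep="\t", index=False)
            report["bin"] = counts.to_dict()
            write_report(counts.to_dict(), out / "bin_summary.json")
            log.info("[bin] strict T1/T2/OTHER = %d/%d/%d",
                     counts.n_t1, counts.n_t2, counts.n_other)
        except Exception as exc:
            log.exception("[bin] failed")
            failed.add("bin")
            report["errors"]["bin"] = str(exc)

    # -- cf ------------------------------------------------------------------
    cf_table = None
    if guard("cf"):
        try:
            if binned_trees is None or lmap is None:
                raise ValueError("cf stage needs gene trees and a lineage map")
            cf_table = quartet_cf_table(binned_trees, lmap, lmap.lineages,
                                        seed=seeds["cf"],
                                        max_quartets=config.max_quartets)
            cf_table.to_csv(out / "quartet_cf.tsv", sep="\t", index=False)
            clades = {
                "octoploid_creutzburgii": (lmap.samples_of(hyp.hybrid)
                                           + lmap.samples_of(hyp.parent2)),
                "tetraploid_drabifolia": (lmap.samples_of(hyp.parent1)
                                          + lmap.samples_of("drabifolia")),
            }
            clade_cfs = {}
            for name, members in clades.items():
                if members:
                    try:
                        res = clade_cf(binned_trees, members)
                        clade_cfs[name] = {"cf": res.cf,
                                           "n_trees": res.n_trees}
                    except ValueError as exc:
                        clade_cfs[name] = {"error": str(exc)}
            report["cf"] = {"n_quartets": len(cf_table),
                            "clade_cf": clade_cfs}
            log.info("[cf] %d quartets", len(cf_table))
        except Exception as exc:
            log.exception("[cf] failed")
            failed.add("cf")
            report["errors"]["cf"] = str(exc)

    # -- fit -----------------------------------------------------------------
    if guard("fit", needs=("cf",)):
        try:
            if config.network_enewick:
                candidate = SpeciesNetwork.from_enewick(config.network_enewick)
            else:
                candidate = default_roucela_network(0.5, config.scale)
            fit_h1 = fit_network(cf_table, candidate,
                                 n_restarts=config.n_restarts,
                                 seed=seeds["fit"])
            fit_tree = fit_network(cf_table, candidate, fix_gamma=0.0,
                                   n_restarts=config.n_restarts,
                                   seed=seeds["fit"])
            comparison = compare_models(fit_tree, fit_h1)
            report["fit"] = {"h1": fit_h1.to_dict(),
                             "tree": fit_tree.to_dict(),
                             "comparison": comparison}
            write_report(report["fit"], out / "fit.json")
            log.info("[fit] gamma_hat=%.3f delta=%.2f", fit_h1.gamma_hat,
                     comparison["delta_pseudolik"])
        except Exception as exc:
            log.exception("[fit] failed")
            failed.add("fit")
            report["errors"]["fit"] = str(exc)

    # -- morph ---------------------------------------------------------------
    if guard("morph"):
        try:
            if morph_path is None:
                raise ValueError("morph stage needs a bract table")
            records = read_bract_tsv(morph_path)
            morph = lineage_comparison(records)
            write_report(morph, out / "morph_report.json")
            report["morphology"] = morph
            log.info("[morph] %d lineages compared", len(morph["lineages"]))
        except Exception as exc:
            log.exception("[morph] failed")
            failed.add("morph")
            report["errors"]["morph"] = str(exc)

    report["failed_stages"] = sorted(failed)
    write_report(report, out / "report.json")
    return report
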