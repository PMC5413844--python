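"""Locus-level quality filters for target-enrichment assemblies.

Two filters, applied in sequence, reduce a set of per-locus assembly
summaries to a complete (no-missing-data) locus x taxon matrix:

* paralog flagging -- a taxon that assembles two or more contigs each
  covering at least ``min_fraction`` of the bait length at a locus is
  flagged as a potential paralog there and loses the locus (all copies
  removed for that taxon);
* completeness -- only loci recovered (and unflagged) for every required
  taxon are kept.

Contig fractions may exceed 1 because assembled contigs can extend beyond
the bait into flanking (intronic) sequence; the threshold is one-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "QCError",
    "LocusAssembly",
    "flag_paralogs",
    "presence_matrix",
    "completeness_filter",
    "read_assembly_tsv",
]

ASSEMBLY_COLUMNS = ["locus_id", "taxon_id", "contig_id", "fraction"]


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class LocusAssembly:
    """One assembled contig for one taxon at one locus; ``fraction`` is the
    contig length divided by the bait length (may exceed 1)."""
    locus_id: str
    taxon_id: str
    contig_id: str
    fraction: float


def _as_frame(assemblies) -> pd.DataFrame:
    if isinstance(assemblies, pd.DataFrame):
        df = assemblies.loc[:, ASSEMBLY_COLUMNS].copy()
    else:
        df = pd.DataFrame(
            [(a.locus_id, a.taxon_id, a.contig_id, a.fraction)
             for a in assemblies],
            columns=ASSEMBLY_COLUMNS)
    bad = df[df["fraction"] < 0]
    if len(bad):
        r = bad.iloc[0]
        raise QCError(
            f"negative bait-length fraction {r.fraction} for locus "
            f"{r.locus_id!r}, taxon {r.taxon_id!r}, contig {r.contig_id!r}")
    dup = df.duplicated(subset=["locus_id", "taxon_id", "contig_id"])
    if dup.any():
        r = df[dup].iloc[0]
        raise QCError(f"duplicate record (locus {r.locus_id!r}, taxon "
                      f"{r.taxon_id!r}, contig {r.contig_id!r})")
    return df


def read_assembly_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ASSEMBLY_COLUMNS if c not in df.columns]
    if missing:
        raise QCError(f"assembly table {path} lacks columns {missing}")
    return df


def flag_paralogs(assemblies, min_fraction: float = 0.75
                  ) -> set[tuple[str, str]]:
    """(locus, taxon) pairs with >= 2 contigs each covering at least
    ``min_fraction`` of the bait length."""
    if not 0.0 < min_fraction <= 1.0:
        raise QCError(f"min_fraction must lie in (0, 1], got {min_fraction}")
    df = _as_frame(assemblies)
    long_hits = df[df["fraction"] >= min_fraction]
    counts = long_hits.groupby(["locus_id", "taxon_id"]).size()
    return set(counts[counts >= 2].index)


def presence_matrix(assemblies, flags: set[tuple[str, str]] | None = None,
                    loci: list[str] | None = None,
                    taxa: list[str] | None = None) -> pd.DataFrame:
    """Boolean loci x taxa matrix: sequence recovered and not
    paralog-flagged.  Row/column order follows first appearance unless
    given explicitly."""
    df = _as_frame(assemblies)
    if loci is None:
        loci = list(dict.fromkeys(df["locus_id"]))
    if taxa is None:
        taxa = list(dict.fromkeys(df["taxon_id"]))
    mat = pd.DataFrame(False, index=pd.Index(loci, name="locus_id"),
                       columns=pd.Index(taxa, name="taxon_id"))
    for locus, taxon in df[["locus_id", "taxon_id"]].drop_duplicates().itertuples(index=False):
        if locus in mat.index and taxon in mat.columns:
            mat.at[locus, taxon] = True
    for locus, taxon in (flags or ()):
        if locus in mat.index and taxon in mat.columns:
            mat.at[locus, taxon] = False
    return mat


def completeness_filter(matrix: pd.DataFrame,
                        required_taxa: list[str]) -> list[str]:
    """Loci present for every required taxon, in matrix row order."""
    unknown = [t for t in required_taxa if t not in matrix.columns]
    if unknown:
        raise QCError(f"unknown taxa in completeness filter: {unknown}")
    if not required_taxa:
        return list(matrix.index)
    keep = matrix.loc[:, list(required_taxa)].all(axis=1)
    return list(matrix.index[keep])
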