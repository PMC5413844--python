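"""Bract-tooth morphometrics behind the cryptic-lineage comparison.

Bract tooth length varies with plant and bract age, so raw tooth lengths
are corrected by dividing by the length of the whole bract; the resulting
dimensionless ratio is the diagnostic character.  The comparison report
gives per-lineage summaries of the corrected ratio, per-lineage
least-squares regressions of tooth on bract length, and two pairwise
contrasts -- tetraploid vs octoploid (the cryptic pair) and the
long-toothed relative vs the pooled cytotypes -- each with a standardized
mean difference (Cohen's d) and a rank-sum test.  The rank-sum test is
distribution-free and reported as descriptive support only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MorphologyError",
    "BractRecord",
    "corrected_tooth",
    "lineage_comparison",
    "read_bract_tsv",
    "records_to_frame",
    "cohen_d",
]

CRYPTIC_PAIR = ("erinus_4x", "erinus_8x")
LONG_TOOTHED = "creutzburgii"


class MorphologyError(ValueError):
    pass


@dataclass(frozen=True)
class BractRecord:
    """One measured bract: lengths in mm, optional area in mm^2."""

    specimen_id: str
    lineage: str
    bract_length: float
    bract_tooth_length: float
    bract_area: float | None = None

    def __post_init__(self):
        if self.bract_length <= 0:
            raise MorphologyError(
                f"specimen {self.specimen_id!r}: bract length must be "
                f"positive, got {self.bract_length}")
        if not 0 <= self.bract_tooth_length <= self.bract_length:
            raise MorphologyError(
                f"specimen {self.specimen_id!r}: tooth length "
                f"{self.bract_tooth_length} outside [0, bract length "
                f"{self.bract_length}]")


def corrected_tooth(record: BractRecord) -> float:
    """Tooth length divided by bract length (in [0, 1])."""
    return record.bract_tooth_length / record.bract_length


def cohen_d(x, y) -> float:
    """Standardized mean difference with pooled (n-1) standard deviation;
    0 when both groups are constant and equal."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    pooled_var = (((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                  / (nx + ny - 2))
    diff = x.mean() - y.mean()
    if pooled_var == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return float(diff / math.sqrt(pooled_var))


def records_to_frame(records: list[BractRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "specimen_id": [r.specimen_id for r in records],
        "lineage": [r.lineage for r in records],
        "bract_length_mm": [r.bract_length for r in records],
        "tooth_length_mm": [r.bract_tooth_length for r in records],
        "bract_area_mm2": [r.bract_area for r in records],
        "corrected_tooth": [corrected_tooth(r) for r in records],
    })


def read_bract_tsv(path) -> list[BractRecord]:
    df = pd.read_csv(path, sep="\t")
    for col in ("specimen_id", "lineage", "bract_length_mm",
                "tooth_length_mm"):
        if col not in df.columns:
            raise MorphologyError(f"bract table {path} lacks column {col!r}")
    has_area = "bract_area_mm2" in df.columns
    return [BractRecord(
        specimen_id=str(r.specimen_id), lineage=str(r.lineage),
        bract_length=float(r.bract_length_mm),
        bract_tooth_length=float(r.tooth_length_mm),
        bract_area=float(r.bract_area_mm2) if has_area
        and not pd.isna(r.bract_area_mm2) else None)
        for r in df.itertuples(index=False)]


def _pair_stats(x, y) -> dict:
    d = cohen_d(x, y)
    if np.ptp(x) == 0 and np.ptp(y) == 0 and np.mean(x) == np.mean(y):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return {"cohen_d": d, "rank_sum_p": p, "n1": len(x), "n2": len(y)}


def lineage_comparison(records: list[BractRecord],
                       min_n: int = 2) -> dict:
    """Summary statistics and pairwise contrasts of the corrected tooth
    ratio.  Lineages with fewer than ``min_n`` records are excluded (listed
    in the report)."""
    if not records:
        raise MorphologyError("no bract records")
    df = records_to_frame(records)
    counts = df["lineage"].value_counts()
    excluded = sorted(counts[counts < min_n].index)
    df = df[~df["lineage"].isin(excluded)]

    per_lineage = {}
    for lin, grp in df.groupby("lineage"):
        ratios = grp["corrected_tooth"].to_numpy()
        entry = {
            "n": int(len(grp)),
            "mean_corrected_tooth": float(ratios.mean()),
            "sd_corrected_tooth": float(ratios.std(ddof=1)),
        }
        bract = grp["bract_length_mm"].to_numpy()
        tooth = grp["tooth_length_mm"].to_numpy()
        if np.ptp(bract) > 0:
            reg = stats.linregress(bract, tooth)
            entry["tooth_vs_bract"] = {
                "slope": float(reg.slope),
                "intercept": float(reg.intercept),
                "r": float(reg.rvalue),
            }
        else:
            entry["tooth_vs_bract"] = None
            entry["regression_flag"] = "bract lengths constant; slope undefined"
        per_lineage[lin] = entry

    comparisons = {}
    a, b = CRYPTIC_PAIR
    have = set(per_lineage)
    if a in have and b in have:
        comparisons["erinus_4x_vs_8x"] = _pair_stats(
            df.loc[df["lineage"] == a, "corrected_tooth"],
            df.loc[df["lineage"] == b, "corrected_tooth"])
    erinus = df[df["lineage"].isin(CRYPTIC_PAIR)]
    if LONG_TOOTHED in have and len(erinus) >= 2:
        comparisons["creutzburgii_vs_erinus"] = _pair_stats(
            df.loc[df["lineage"] == LONG_TOOTHED, "corrected_tooth"],
            erinus["corrected_tooth"])

    return {
        "lineages": per_lineage,
        "comparisons": comparisons,
        "excluded_lineages": excluded,
    }


def write_report(report: dict, path) -> None:
    """Deterministic JSON (sorted keys, stable float repr)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
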