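"""SNP QC filtering and per-marker diversity statistics.

Allele frequencies use non-missing calls only.  For a biallelic marker with
allele frequencies p and q = 1 - p:

    gene diversity D = 1 - p^2 - q^2
    PIC (Botstein)   = 1 - p^2 - q^2 - 2 p^2 q^2

Filter thresholds are strict: a marker is removed iff missing rate > 0.10,
major-allele frequency > 0.95, or observed heterozygosity > 0.20 (defaults;
monomorphic markers automatically fail the MAF rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from heterokit.io import GenotypeMatrix


@dataclass(frozen=True)
class FilterThresholds:
    missing: float = 0.10
    maf_major: float = 0.95
    het: float = 0.20


@dataclass
class FilterReport:
    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_removed_het: int
    n_retained: int
    thresholds: FilterThresholds

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_missing": self.n_removed_missing,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_het": self.n_removed_het,
            "n_retained": self.n_retained,
            "thresholds": {
                "missing": self.thresholds.missing,
                "maf_major": self.thresholds.maf_major,
                "het": self.thresholds.het,
            },
        }


def marker_stats(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker MAF, gene diversity, PIC, observed het and missing rate.

    Returns a DataFrame indexed like ``geno.markers`` with columns
    ``marker_id, maf_major, gene_diversity, pic, het_obs, missing_rate,
    defined``; all-missing markers are flagged ``defined=False`` with NaN
    statistics.
    """
    calls = geno.calls
    miss = geno.missing_mask()
    n_called = (~miss).sum(axis=0).astype(float)
    missing_rate = miss.mean(axis=0)

    dose = np.where(miss, 0, calls).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = dose / (2.0 * n_called)
        het_obs = np.where(miss, False, calls == 1).sum(axis=0) / n_called
    maf_major = np.maximum(p_alt, 1.0 - p_alt)
    p, q = p_alt, 1.0 - p_alt
    gene_div = 1.0 - p**2 - q**2
    pic = gene_div - 2.0 * p**2 * q**2
    defined = n_called > 0

    stats = pd.DataFrame(
        {
            "marker_id": geno.marker_ids,
            "maf_major": maf_major,
            "gene_diversity": gene_div,
            "pic": pic,
            "het_obs": het_obs,
            "missing_rate": missing_rate,
            "defined": defined,
        }
    )
    stats.loc[~defined, ["maf_major", "gene_diversity", "pic", "het_obs"]] = np.nan
    return stats


def filter_markers(
    geno: GenotypeMatrix,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove markers failing any QC rule (strict > comparisons).

    Removal attribution follows the order missing -> MAF -> heterozygosity
    (each marker charged to the first failing rule); the removal set itself
    is the OR of the three conditions and order-independent.  All-missing
    markers are charged to the missing rule.  Marker order is preserved.
    """
    stats = marker_stats(geno)
    fail_missing = (stats["missing_rate"] > thresholds.missing) | ~stats["defined"]
    fail_maf = stats["maf_major"] > thresholds.maf_major
    fail_het = stats["het_obs"] > thresholds.het

    removed_missing = fail_missing
    removed_maf = fail_maf & ~removed_missing
    removed_het = fail_het & ~removed_missing & ~removed_maf
    keep = ~(fail_missing | fail_maf.fillna(False) | fail_het.fillna(False))

    report = FilterReport(
        n_input=geno.n_markers,
        n_removed_missing=int(removed_missing.sum()),
        n_removed_maf=int(removed_maf.sum()),
        n_removed_het=int(removed_het.sum()),
        n_retained=int(keep.sum()),
        thresholds=thresholds,
    )
    return geno.subset_markers(keep.to_numpy()), report


def summarize_diversity(stats: pd.DataFrame) -> pd.DataFrame:
    """min/max/mean of the four marker statistics over defined markers."""
    usable = stats.loc[stats["defined"]]
    if usable.empty:
        raise ValueError("no defined markers to summarize")
    cols = ["maf_major", "gene_diversity", "pic", "het_obs"]
    return pd.DataFrame(
        {
            "statistic": cols,
            "min": [usable[c].min() for c in cols],
            "max": [usable[c].max() for c in cols],
            "mean": [usable[c].mean() for c in cols],
        }
    )
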