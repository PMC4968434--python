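"""Per-SNP pairwise F_st between population clusters and empirical outliers.

Three estimators are available per SNP: "wright" (heterozygosity ratio
(H_T - H_S)/H_T with sample-size-weighted frequencies, the default),
"hudson" (Hudson/Slatkin/Maddison 1992 with the Bhatia 2013 sample-size
correction) and "wc" (Weir & Cockerham 1984 theta for haploid allele
samples).  Sites monomorphic in the pooled pair are undefined (NaN) and
excluded from outlier calling.  Outliers are called against an empirical
genome background at a nearest-rank percentile threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HaplotypeMatrix, PopulationPanel, VariantSite

ESTIMATORS = ("wright", "hudson", "wc")


def daf(H: HaplotypeMatrix, chrom_idx) -> np.ndarray:
    """Per-site derived-allele frequency among the given chromosomes."""
    if H.coding != "ancestral/derived":
        raise ValueError("DAF requires ancestral/derived coding; polarize first")
    chrom_idx = np.asarray(chrom_idx, dtype=np.intp)
    if chrom_idx.size == 0:
        raise ValueError("empty group")
    return H.data[:, chrom_idx].mean(axis=1)


def fst_from_frequencies(pA, nA: int, pB, nB: int, estimator: str = "wright") -> np.ndarray:
    """Vectorized per-SNP F_st from group allele frequencies and sizes.

    Returns NaN where the pooled sample is monomorphic.
    """
    pA = np.atleast_1d(np.asarray(pA, dtype=float))
    pB = np.atleast_1d(np.asarray(pB, dtype=float))
    pbar = (nA * pA + nB * pB) / (nA + nB)
    poly = (pbar > 0) & (pbar < 1)
    out = np.full(pA.shape, np.nan)
    if estimator == "wright":
        hS = (nA * 2 * pA * (1 - pA) + nB * 2 * pB * (1 - pB)) / (nA + nB)
        hT = 2 * pbar * (1 - pbar)
        np.divide(hT - hS, hT, out=out, where=poly)
    elif estimator == "hudson":
        num = (pA - pB) ** 2 - pA * (1 - pA) / (nA - 1) - pB * (1 - pB) / (nB - 1)
        den = pA * (1 - pB) + pB * (1 - pA)
        np.divide(num, den, out=out, where=poly & (den > 0))
    elif estimator == "wc":
        # Weir & Cockerham 1984, r = 2 haploid allele samples
        r = 2.0
        nbar = (nA + nB) / r
        nc = (nA + nB - (nA**2 + nB**2) / (nA + nB)) / (r - 1)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1) * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
        np.divide(a, a + b, out=out, where=poly & (a + b != 0))
    else:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    return out


def fst_per_site(
    H: HaplotypeMatrix, groupA_idx, groupB_idx, estimator: str = "wright"
) -> np.ndarray:
    """Per-site F_st between two chromosome index sets."""
    groupA_idx = np.asarray(groupA_idx, dtype=np.intp)
    groupB_idx = np.asarray(groupB_idx, dtype=np.intp)
    if groupA_idx.size == 0 or groupB_idx.size == 0:
        raise ValueError("both groups must be nonempty")
    pA = H.data[:, groupA_idx].mean(axis=1)
    pB = H.data[:, groupB_idx].mean(axis=1)
    return fst_from_frequencies(pA, groupA_idx.size, pB, groupB_idx.size, estimator)


def nearest_rank_percentile(values, percentile: float) -> float:
    """Nearest-rank (ceiling) percentile: the smallest value such that at
    least ``percentile`` percent of the data are <= it."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty background")
    rank = max(1, math.ceil(percentile / 100.0 * v.size))
    return float(v[rank - 1])


@dataclass
class FstRecord:
    site: VariantSite
    pair: tuple
    fst: float
    daf_A: float
    daf_B: float
    percentile_rank: float = float("nan")
    outlier: bool = False


def scan_pair(
    H: HaplotypeMatrix,
    panel: PopulationPanel,
    clusterA: str,
    clusterB: str,
    estimator: str = "wright",
) -> list[FstRecord]:
    """Per-SNP F_st records (with DAFs) for one cluster pair."""
    iA = H.chromosomes_of(panel.samples_in_cluster(clusterA))
    iB = H.chromosomes_of(panel.samples_in_cluster(clusterB))
    fst = fst_per_site(H, iA, iB, estimator=estimator)
    dA, dB = daf(H, iA), daf(H, iB)
    return [
        FstRecord(site=s, pair=(clusterA, clusterB), fst=float(f), daf_A=float(a), daf_B=float(b))
        for s, f, a, b in zip(H.sites, fst, dA, dB)
        if not np.isnan(f)
    ]


def empirical_outliers(
    gene_records: list[FstRecord], background, percentile: float = 99.0
) -> list[FstRecord]:
    """Flag gene SNPs at or above the background's nearest-rank percentile.

    ``percentile_rank`` records, for every gene SNP, the percent of
    background values less than or equal to it.
    """
    bg = np.sort(np.asarray(background, dtype=float))
    bg = bg[~np.isnan(bg)]
    if bg.size == 0:
        raise ValueError("empty background distribution")
    if bg.size < 100.0 / (100.0 - percentile):
        raise ValueError(
            f"background of {bg.size} values has no mass beyond the "
            f"{percentile}th percentile"
        )
    threshold = nearest_rank_percentile(bg, percentile)
    for rec in gene_records:
        rec.percentile_rank = 100.0 * np.searchsorted(bg, rec.fst, side="right") / bg.size
        rec.outlier = rec.fst >= threshold
    return gene_records


def records_to_frame(records: list[FstRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": [r.site.id for r in records],
            "chrom": [r.site.chrom for r in records],
            "pos": [r.site.pos for r in records],
            "pair": ["%s-%s" % r.pair for r in records],
            "fst": [r.fst for r in records],
            "daf_A": [r.daf_A for r in records],
            "daf_B": [r.daf_B for r in records],
            "percentile_rank": [r.percentile_rank for r in records],
            "outlier": [r.outlier for r in records],
        }
    )
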