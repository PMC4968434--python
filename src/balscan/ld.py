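"""Pairwise linkage disequilibrium, sliding-window pruning, high-LD sets.

Two r-squared flavours: the genotypic one (squared Pearson correlation of
allele dosages, what PLINK's --indep-pairwise uses) and the haplotypic
one (D^2 over the product of allele-frequency variances, from phased
haplotype counts).  Pruning follows the classic 50-SNP window / 10-SNP
step / r2 > 0.1 recipe with an explicit removal rule: of a violating
pair, drop the lower-MAF SNP, ties broken by larger coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import MISSING_DOSAGE, GenotypeMatrix, HaplotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LdPruneConfig:
    window_snps: int = 50
    step_snps: int = 10
    r2_threshold: float = 0.1

    def __post_init__(self):
        if self.step_snps > self.window_snps:
            raise ValueError("step must be <= window")
        if not 0.0 < self.r2_threshold < 1.0:
            raise ValueError("r2_threshold must be in (0,1)")


def r2_genotypic(g1, g2) -> float | None:
    """Squared Pearson correlation of dosage vectors, pairwise-complete.

    None (undefined) when either vector has zero variance or fewer than
    two complete pairs remain.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING_DOSAGE) & (g2 != MISSING_DOSAGE)
    g1, g2 = g1[ok], g2[ok]
    if g1.size < 2:
        return None
    v1 = g1 - g1.mean()
    v2 = g2 - g2.mean()
    d1, d2 = (v1**2).sum(), (v2**2).sum()
    if d1 == 0 or d2 == 0:
        return None
    return float((v1 @ v2) ** 2 / (d1 * d2))


def r2_haplotypic(H: HaplotypeMatrix, site_i: int, site_j: int) -> float | None:
    """r2 = D^2 / (p_i(1-p_i) p_j(1-p_j)) from phased haplotype counts."""
    xi = H.data[site_i].astype(float)
    xj = H.data[site_j].astype(float)
    pi, pj = xi.mean(), xj.mean()
    if pi in (0.0, 1.0) or pj in (0.0, 1.0):
        return None
    pij = (xi * xj).mean()
    D = pij - pi * pj
    return float(D * D / (pi * (1 - pi) * pj * (1 - pj)))


def _dosage_r2_matrix(X: np.ndarray) -> np.ndarray:
    """All-pairs genotypic r2 for a (snps x individuals) dosage block.

    Assumes no missing values (the pruning path mean-imputes first).
    Zero-variance SNPs yield r2 = 0 against everything (logged upstream).
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc**2).sum(axis=1))
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc @ Xc.T / denom, 0.0)
    return r**2


def ld_prune(G: GenotypeMatrix, cfg: LdPruneConfig = LdPruneConfig()) -> list[str]:
    """Sliding-window LD pruning; returns the surviving SNP ids in order.

    Within each window of ``window_snps`` currently-kept SNPs, while any
    kept pair exceeds the threshold the lower-MAF SNP of the worst pair
    is removed; the window then advances by ``step_snps``.  Missing
    dosages are mean-imputed for the correlation only; undefined r2
    (monomorphic SNP) is treated as 0.
    """
    X = G.data.T.astype(float)  # snps x individuals
    X[X == MISSING_DOSAGE] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=1)
    col_mean = np.nan_to_num(col_mean)
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[0]]
    n_snps = X.shape[0]
    maf = np.minimum(X.mean(axis=1) / 2.0, 1 - X.mean(axis=1) / 2.0)
    pos = np.array([s.pos for s in G.sites])
    keep = np.ones(n_snps, dtype=bool)
    start = 0
    while True:
        window = np.flatnonzero(keep)[start : start + cfg.window_snps]
        if window.size >= 2:
            r2 = _dosage_r2_matrix(X[window])
            np.fill_diagonal(r2, 0.0)
            while True:
                ii, jj = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[ii, jj] <= cfg.r2_threshold:
                    break
                a, b = window[ii], window[jj]
                # drop lower MAF; ties -> larger coordinate
                if (maf[a], -pos[a]) < (maf[b], -pos[b]):
                    drop, di = a, ii
                else:
                    drop, di = b, jj
                keep[drop] = False
                r2[di, :] = 0.0
                r2[:, di] = 0.0
        if start + cfg.window_snps >= keep.sum():
            break
        start += cfg.step_snps
    return [G.sites[i].id for i in np.flatnonzero(keep)]


@dataclass
class HighLdSet:
    anchors: list[str]
    members: list[str]
    r2_matrix: np.ndarray  # member x member
    span_bp: int
    n_non_members: int
    threshold: float


def high_ld_set(
    H: HaplotypeMatrix,
    anchors: list[str],
    threshold: float = 0.95,
    method: str = "genotypic",
) -> HighLdSet:
    """SNPs in r2 > threshold with at least one anchor SNP.

    Reports the member-by-member r2 matrix, the genomic span of the
    member set, and how many scanned SNPs stayed outside it.
    """
    ids = [s.id for s in H.sites]
    missing = [a for a in anchors if a not in ids]
    if missing:
        raise ValueError(f"anchors not in matrix: {missing}")
    if method == "genotypic":
        from .io import to_genotypes

        X = to_genotypes(H).data.T.astype(float)
        r2_full = _dosage_r2_matrix(X)
    elif method == "haplotypic":
        X = H.data.astype(float)
        r2_full = _dosage_r2_matrix(X)  # same algebra: D^2-normalized == squared corr
    else:
        raise ValueError(f"unknown method {method!r}")
    anchor_idx = [ids.index(a) for a in anchors]
    is_member = np.zeros(len(ids), dtype=bool)
    is_member[anchor_idx] = True
    for ai in anchor_idx:
        is_member |= r2_full[ai] > threshold
    member_idx = np.flatnonzero(is_member)
    positions = H.positions[member_idx]
    return HighLdSet(
        anchors=list(anchors),
        members=[ids[i] for i in member_idx],
        r2_matrix=r2_full[np.ix_(member_idx, member_idx)],
        span_bp=int(positions.max() - positions.min()) if member_idx.size else 0,
        n_non_members=int(len(ids) - member_idx.size),
        threshold=threshold,
    )
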