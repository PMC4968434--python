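"""Haplotype-frequency inference from unphased genotypes.

Excoffier-Slatkin EM under Hardy-Weinberg: the E-step distributes each
ambiguous multi-heterozygote genotype over its compatible haplotype
pairs in proportion to the current pair probabilities, the M-step
re-estimates frequencies from the expected counts.  Random restarts
guard against local optima; the log-likelihood is non-decreasing within
a run.  Intended for small sets of tightly linked SNPs (<= 32 sites,
around ten distinct haplotypes) — the regime of a high-LD block.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import MISSING_DOSAGE, GenotypeMatrix, PopulationPanel

log = logging.getLogger(__name__)

MAX_SITES = 32


def _dosages(G) -> tuple[np.ndarray, list]:
    if isinstance(G, GenotypeMatrix):
        return G.data.astype(np.int64), list(G.sample_ids)
    arr = np.asarray(G, dtype=np.int64)
    return arr, [f"ind{i}" for i in range(arr.shape[0])]


def _compatible_pairs(geno: np.ndarray) -> list[tuple[int, int]]:
    """All unordered haplotype-code pairs consistent with one genotype row."""
    L = geno.size
    base = 0
    het = []
    for i in range(L):
        if geno[i] == 2:
            base |= 1 << i
        elif geno[i] == 1:
            het.append(i)
    if not het:
        return [(base, base)]
    pairs = []
    first = het[0]
    rest = het[1:]
    # fix the first het site on haplotype 1 to halve the enumeration
    for bits in itertools.product((0, 1), repeat=len(rest)):
        h1 = base | (1 << first)
        h2 = base
        for site, b in zip(rest, bits):
            if b:
                h1 |= 1 << site
            else:
                h2 |= 1 << site
        pairs.append((min(h1, h2), max(h1, h2)))
    return pairs


def _row_masks(geno: np.ndarray) -> tuple[int, int]:
    """(homozygous-derived mask, heterozygous mask) of a genotype row."""
    hom2 = het = 0
    for i, g in enumerate(geno):
        if g == 2:
            hom2 |= 1 << i
        elif g == 1:
            het |= 1 << i
    return hom2, het


def _pair_lists(X: np.ndarray, max_het_full: int) -> list[list[tuple[int, int]]]:
    """Compatible haplotype pairs per individual, with partial enumeration.

    Rows with at most ``max_het_full`` heterozygous sites are enumerated
    fully.  Beyond that 2^(h-1) explodes, so pairs are generated from the
    candidate haplotype pool those rows establish: each compatible
    candidate determines its partner uniquely (at heterozygous sites the
    partner is the complement), the standard partial-enumeration EM for
    tight-LD blocks.  A row no candidate resolves falls back to the
    single all-reference/all-alternate split of its heterozygous sites.
    """
    het_counts = [(int((row == 1).sum())) for row in X]
    pair_lists: list[list[tuple[int, int]] | None] = [None] * len(X)
    pool: set[int] = set()
    for idx, row in enumerate(X):
        if het_counts[idx] <= max_het_full:
            pairs = _compatible_pairs(row)
            pair_lists[idx] = pairs
            pool.update(h for p in pairs for h in p)
    for idx, row in enumerate(X):
        if pair_lists[idx] is not None:
            continue
        hom2, het = _row_masks(row)
        fixed = hom2 | het
        pairs = set()
        for h1 in pool:
            if (h1 & ~fixed) == 0 and (hom2 & ~h1) == 0:
                h2 = hom2 | (het & ~h1)
                pairs.add((min(h1, h2), max(h1, h2)))
        if not pairs:
            h1, h2 = hom2, hom2 | het
            pairs.add((min(h1, h2), max(h1, h2)))
            log.info("no candidate haplotypes resolve individual %d; fallback split", idx)
        pair_lists[idx] = sorted(pairs)
        pool.update(h for p in pairs for h in p)
    return pair_lists


def code_to_string(code: int, L: int) -> str:
    return "".join("1" if code >> i & 1 else "0" for i in range(L))


def string_to_code(h: str) -> int:
    return sum(1 << i for i, c in enumerate(h) if c == "1")


class HaplotypeFrequencyEM(BaseEstimator):
    """EM estimator of haplotype frequencies under HWE.

    Attributes after fit: ``haplotypes_`` (binary strings, site order of
    the input), ``frequencies_``, ``loglik_``, ``n_iter_``,
    ``tied_restarts_`` (True when distinct restart optima share the best
    likelihood within tolerance).
    """

    def __init__(
        self,
        tol: float = 1e-8,
        max_iter: int = 1000,
        restarts: int = 10,
        random_state: int = 0,
        max_het_full: int = 12,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.restarts = restarts
        self.random_state = random_state
        self.max_het_full = max_het_full

    def fit(self, G, y=None):
        X, _ = _dosages(G)
        if X.shape[1] > MAX_SITES:
            raise ValueError(
                f"{X.shape[1]} sites exceed the {MAX_SITES}-site limit; subset the SNP set"
            )
        keep = ~(X == MISSING_DOSAGE).any(axis=0)
        if not keep.all():
            log.info("dropping %d sites with missing dosages", int((~keep).sum()))
            X = X[:, keep]
        self._kept_sites = np.flatnonzero(keep)
        L = X.shape[1]
        pair_lists = _pair_lists(X, self.max_het_full)
        codes = sorted({h for pairs in pair_lists for hh in pairs for h in hh})
        index = {h: i for i, h in enumerate(codes)}
        K = len(codes)
        n = len(pair_lists)
        # flatten for vectorized E-steps
        flat_i, flat_j, owner = [], [], []
        for ind, pairs in enumerate(pair_lists):
            for h1, h2 in pairs:
                flat_i.append(index[h1])
                flat_j.append(index[h2])
                owner.append(ind)
        flat_i = np.array(flat_i)
        flat_j = np.array(flat_j)
        owner = np.array(owner)
        mult = np.where(flat_i == flat_j, 1.0, 2.0)

        rng = np.random.default_rng(self.random_state)
        best = None
        optima = []
        for r in range(self.restarts):
            f = np.full(K, 1.0 / K) if r == 0 else rng.dirichlet(np.ones(K))
            prev_ll = -np.inf
            for it in range(self.max_iter):
                w = mult * f[flat_i] * f[flat_j]
                totals = np.bincount(owner, weights=w, minlength=n)
                ll = float(np.log(np.maximum(totals, 1e-300)).sum())
                w = w / totals[owner]
                counts = np.bincount(flat_i, weights=w, minlength=K) + np.bincount(
                    flat_j, weights=w, minlength=K
                )
                f_new = counts / (2.0 * n)
                delta = np.abs(f_new - f).max()
                f = f_new
                if ll < prev_ll - 1e-9:
                    raise RuntimeError("EM log-likelihood decreased (implementation bug)")
                if delta < self.tol:
                    break
                prev_ll = ll
            optima.append((ll, f, it + 1))
            if best is None or ll > best[0] + 1e-9:
                best = (ll, f, it + 1)
        self.tied_restarts_ = any(
            abs(ll - best[0]) <= 1e-6 and np.abs(f - best[1]).sum() / 2 > 1e-3
            for ll, f, _ in optima
        )
        ll, f, iters = best
        nz = f > 1e-12
        self.haplotypes_ = [code_to_string(c, L) for c, z in zip(codes, nz) if z]
        self._codes = [c for c, z in zip(codes, nz) if z]
        self.frequencies_ = f[nz] / f[nz].sum()
        self.loglik_ = ll
        self.n_iter_ = iters
        self.n_sites_ = L
        return self

    @property
    def frequency_map(self) -> dict[str, float]:
        return dict(zip(self.haplotypes_, self.frequencies_))


def em_haplotype_frequencies(
    G, tol: float = 1e-8, max_iter: int = 1000, restarts: int = 10, seed: int = 0
) -> dict[str, float]:
    """Haplotype string -> frequency (thin wrapper over the estimator)."""
    return (
        HaplotypeFrequencyEM(tol=tol, max_iter=max_iter, restarts=restarts, random_state=seed)
        .fit(G)
        .frequency_map
    )


@dataclass
class HaplotypeSet:
    haplotypes: list[str]
    frequencies: np.ndarray
    assignments: dict  # sample_id -> (hap1, hap2, posterior)
    flagged: list = field(default_factory=list)
    tied: list = field(default_factory=list)

    def chromosome_strings(self) -> list[tuple[str, str]]:
        return [(s, h) for s, (h1, h2, _) in self.assignments.items() for h in (h1, h2)]


def assign_phase(G, frequencies: dict[str, float]) -> HaplotypeSet:
    """Maximum-posterior phase per individual given haplotype frequencies.

    Individuals whose genotype is incompatible with every positive-
    frequency haplotype pair get a uniform-augmentation assignment and
    are flagged; exact posterior ties are broken lexicographically and
    recorded in ``tied``.
    """
    X, sample_ids = _dosages(G)
    L = X.shape[1]
    fmap = {string_to_code(h): p for h, p in frequencies.items()}
    assignments, flagged, tied = {}, [], []
    for row, sid in zip(X, sample_ids):
        hom2, het = _row_masks(row)
        fixed = hom2 | het
        pairs = sorted(
            {
                (min(h1, hom2 | (het & ~h1)), max(h1, hom2 | (het & ~h1)))
                for h1 in fmap
                if (h1 & ~fixed) == 0 and (hom2 & ~h1) == 0
            }
        )
        if not pairs:
            if int((row == 1).sum()) <= 12:
                pairs = _compatible_pairs(row)
            else:
                pairs = [(hom2, hom2 | het)]
        probs = np.array(
            [
                (1.0 if h1 == h2 else 2.0) * fmap.get(h1, 0.0) * fmap.get(h2, 0.0)
                for h1, h2 in pairs
            ]
        )
        if probs.sum() == 0:
            probs = np.ones(len(pairs))
            flagged.append(sid)
        probs = probs / probs.sum()
        best_p = probs.max()
        cand = [pairs[i] for i in np.flatnonzero(probs >= best_p - 1e-12)]
        if len(cand) > 1:
            tied.append(sid)
        h1, h2 = min(cand)
        assignments[sid] = (code_to_string(h1, L), code_to_string(h2, L), float(best_p))
    seen: dict[str, int] = {}
    for _, (h1, h2, _) in assignments.items():
        for h in (h1, h2):
            seen[h] = seen.get(h, 0) + 1
    hap_list = sorted(seen)
    total = sum(seen.values())
    return HaplotypeSet(
        haplotypes=hap_list,
        frequencies=np.array([seen[h] / total for h in hap_list]),
        assignments=assignments,
        flagged=flagged,
        tied=tied,
    )


def haplotype_group_freqs(hs: HaplotypeSet, panel: PopulationPanel) -> pd.DataFrame:
    """Per-group haplotype frequency table over assigned chromosomes."""
    rows = []
    for sid, (h1, h2, _) in hs.assignments.items():
        cl = panel.cluster.get(sid)
        if cl is None:
            continue
        rows += [(h1, cl), (h2, cl)]
    df = pd.DataFrame(rows, columns=["haplotype", "group"])
    table = df.groupby("group")["haplotype"].value_counts(normalize=True).unstack(fill_value=0.0).T
    return table.reindex(sorted(table.index))
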