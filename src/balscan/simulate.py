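"""Synthetic-data generators with known ground truth.

Four scenarios cover what the inference pipeline needs:

* neutral Kingman coalescent loci, either with a scaled mutation rate
  ``theta`` or conditioned on a fixed number of segregating sites
  (the null model for the neutrality tests);
* an n-island structured coalescent (differentiation nulls);
* a locus carrying two deeply diverged haplotype clades segregating at
  intermediate frequency (the balanced-polymorphism positive control,
  built by construction with truth labels rather than by a
  selection-aware coalescent);
* a genome-background per-SNP F_st distribution under the
  Balding-Nichols model.

Time is measured in units of 2N generations throughout; conversion to
years happens only in the network-dating calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HaplotypeMatrix, PopulationPanel, VariantSite


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class CoalescentConfig:
    n: int
    theta: float | None = None
    fixed_S: int | None = None
    rho: float = 0.0
    locus_length: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if (self.theta is None) == (self.fixed_S is None):
            raise ValueError("exactly one of theta / fixed_S must be set")
        if self.n < 2:
            raise ValueError("need n >= 2 chromosomes")
        if self.fixed_S is not None and self.rho > 0:
            raise NotImplementedError("rho > 0 unsupported in fixed-S mode")
        if self.rho > 0:
            raise NotImplementedError("recombination (rho > 0) not implemented")


@dataclass(frozen=True)
class StructuredConfig:
    demes: int
    n_per_deme: tuple
    migration_4Nm: float
    seed: int = 0
    merge_at: float | None = None  # forced final merge depth when migration is 0

    def __post_init__(self):
        if self.demes < 2:
            raise ValueError("need >= 2 demes")
        if len(self.n_per_deme) != self.demes:
            raise ValueError("n_per_deme length must equal demes")
        if self.migration_4Nm < 0:
            raise ValueError("migration rate must be >= 0")
        if self.migration_4Nm == 0 and self.merge_at is None:
            raise ValueError("zero migration requires a forced merge depth (merge_at)")


@dataclass(frozen=True)
class DeepCladeConfig:
    freq_cladeA_per_group: dict
    n_per_group: dict
    split_depth: int = 20
    within_clade: CoalescentConfig | None = None  # template; n is overridden per clade
    locus_length: int = 10_000
    seed: int = 0

    def __post_init__(self):
        for g, f in self.freq_cladeA_per_group.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"clade-A frequency for {g} outside [0,1]")
        if self.split_depth < 1:
            raise ValueError("split_depth must be >= 1")
        if set(self.n_per_group) != set(self.freq_cladeA_per_group):
            raise ValueError("n_per_group and freq_cladeA_per_group must cover the same groups")


@dataclass(frozen=True)
class BackgroundConfig:
    n_snps: int
    fst_target: float
    n_per_cluster: dict
    ancestral_freq_range: tuple = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fst_target < 1:
            raise ValueError("fst_target must be in (0,1)")


@dataclass(frozen=True)
class TreeSummary:
    tmrca: float
    total_branch_length: float


# ---------------------------------------------------------------------------
# Kingman coalescent


def _coalescent_tree(n: int, rng: np.random.Generator):
    """One Kingman tree: per-branch (leaf bitmask, length) and summaries.

    With k active lineages the waiting time to the next coalescence is
    Exponential with rate k(k-1)/2, time in units of 2N generations.
    """
    masks = [1 << i for i in range(n)]
    birth = [0.0] * n
    t = 0.0
    branch_masks: list[int] = []
    branch_lens: list[float] = []
    ks = np.arange(n, 1, -1)
    waits = rng.standard_exponential(n - 1) * (2.0 / (ks * (ks - 1)))
    u1 = rng.random(n - 1)
    u2 = rng.random(n - 1)
    for step, k in enumerate(ks):
        t += waits[step]
        i = int(u1[step] * k)
        j = int(u2[step] * (k - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        branch_masks.append(masks[i])
        branch_lens.append(t - birth[i])
        branch_masks.append(masks[j])
        branch_lens.append(t - birth[j])
        masks[i] |= masks[j]
        birth[i] = t
        del masks[j], birth[j]
    return branch_masks, np.array(branch_lens), t


def _branch_leaf_counts(n: int, rng: np.random.Generator):
    """Branch lengths and descendant-leaf counts only (fast SFS path)."""
    counts = [1] * n
    birth = [0.0] * n
    t = 0.0
    out_len = np.empty(2 * (n - 1))
    out_cnt = np.empty(2 * (n - 1), dtype=np.int64)
    ks = np.arange(n, 1, -1)
    waits = rng.standard_exponential(n - 1) * (2.0 / (ks * (ks - 1)))
    u1 = rng.random(n - 1)
    u2 = rng.random(n - 1)
    w = 0
    for step, k in enumerate(ks):
        t += waits[step]
        i = int(u1[step] * k)
        j = int(u2[step] * (k - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        out_len[w] = t - birth[i]
        out_cnt[w] = counts[i]
        out_len[w + 1] = t - birth[j]
        out_cnt[w + 1] = counts[j]
        w += 2
        counts[i] += counts[j]
        birth[i] = t
        del counts[j], birth[j]
    return out_len, out_cnt, t


def _mutation_count(cfg: CoalescentConfig, total_len: float, rng) -> int:
    if cfg.fixed_S is not None:
        return cfg.fixed_S
    return int(rng.poisson(cfg.theta * total_len / 2.0))


def simulate_sfs_counts(n: int, S: int, rng: np.random.Generator) -> np.ndarray:
    """Derived-allele counts of S mutations dropped on one fixed-S tree.

    Mutations land on branches with probability proportional to branch
    length (infinite-sites).  Returns an integer array of length S with
    entries in 1..n-1.
    """
    lens, cnts, _ = _branch_leaf_counts(n, rng)
    if S == 0:
        return np.empty(0, dtype=np.int64)
    idx = rng.choice(len(lens), size=S, p=lens / lens.sum())
    return cnts[idx]


def simulate_coalescent(
    cfg: CoalescentConfig, chrom: str = "chrSim", sample_prefix: str = "sim"
) -> tuple[HaplotypeMatrix, TreeSummary]:
    """Simulate one neutral locus; returns the phased matrix and tree summary.

    Coding is ancestral/derived (1 = derived).  Mutation positions are
    distinct uniform draws over ``locus_length``.
    """
    rng = np.random.default_rng(cfg.seed)
    masks, lens, tmrca = _coalescent_tree(cfg.n, rng)
    total = float(lens.sum())
    S = _mutation_count(cfg, total, rng)
    if S > cfg.locus_length:
        raise ValueError(f"{S} mutations do not fit in locus_length {cfg.locus_length}")
    if S > 0:
        bidx = rng.choice(len(lens), size=S, p=lens / total)
        pos = np.sort(rng.choice(cfg.locus_length, size=S, replace=False))
    else:
        bidx, pos = np.empty(0, np.intp), np.empty(0, np.int64)
    data = np.zeros((S, cfg.n), dtype=np.int8)
    for row, b in enumerate(bidx):
        m = masks[b]
        for leaf in range(cfg.n):
            if m >> leaf & 1:
                data[row, leaf] = 1
    sites = [
        VariantSite(chrom, int(p), f"{chrom}:{int(p) + 1}", "A", "G", ancestral_allele="A")
        for p in pos
    ]
    sample_ids = [f"{sample_prefix}{j // 2}" for j in range(cfg.n)]
    H = HaplotypeMatrix(sites, data, sample_ids, coding="ancestral/derived")
    return H, TreeSummary(tmrca=tmrca, total_branch_length=total)


# ---------------------------------------------------------------------------
# structured coalescent (n-island)


def simulate_island(
    cfg: StructuredConfig, theta: float, locus_length: int = 100_000, chrom: str = "chrSim"
) -> tuple[HaplotypeMatrix, np.ndarray]:
    """n-island structured coalescent with per-lineage migration rate M/2.

    Returns the phased matrix plus the deme label of every chromosome.
    With ``migration_4Nm == 0`` lineages are forcibly pooled into one
    deme at time ``merge_at``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_tot = int(sum(cfg.n_per_deme))
    demes, masks, birth = [], [], []
    leaf = 0
    for d, nd in enumerate(cfg.n_per_deme):
        for _ in range(nd):
            demes.append(d)
            masks.append(1 << leaf)
            birth.append(0.0)
            leaf += 1
    t = 0.0
    merged = False
    branch_masks: list[int] = []
    branch_lens: list[float] = []
    M = cfg.migration_4Nm
    while len(masks) > 1:
        k_per = np.bincount(demes, minlength=cfg.demes)
        coal_rates = k_per * (k_per - 1) / 2.0
        rate = float(coal_rates.sum()) + M / 2.0 * len(masks)
        if rate == 0:
            if cfg.merge_at is None:
                raise RuntimeError("no events possible and no forced merge configured")
            t = max(t, cfg.merge_at)
            demes = [0] * len(masks)
            merged = True
            continue
        dt = rng.exponential(1.0 / rate)
        if not merged and cfg.merge_at is not None and t + dt >= cfg.merge_at:
            t = cfg.merge_at
            demes = [0] * len(masks)
            merged = True
            continue
        t += dt
        if rng.random() < coal_rates.sum() / rate:
            # coalescence: choose deme by rate, then a pair inside it
            d = rng.choice(cfg.demes, p=coal_rates / coal_rates.sum())
            members = [x for x, dd in enumerate(demes) if dd == d]
            i, j = rng.choice(len(members), size=2, replace=False)
            i, j = sorted((members[i], members[j]))
            branch_masks += [masks[i], masks[j]]
            branch_lens += [t - birth[i], t - birth[j]]
            masks[i] |= masks[j]
            birth[i] = t
            del masks[j], birth[j], demes[j]
        else:
            x = int(rng.integers(len(masks)))
            choices = [d for d in range(cfg.demes) if d != demes[x]]
            demes[x] = int(rng.choice(choices))
    lens = np.array(branch_lens)
    total = float(lens.sum())
    S = int(rng.poisson(theta * total / 2.0))
    if S > locus_length:
        raise ValueError("locus too short for realized mutation count")
    data = np.zeros((S, n_tot), dtype=np.int8)
    if S:
        bidx = rng.choice(len(lens), size=S, p=lens / total)
        pos = np.sort(rng.choice(locus_length, size=S, replace=False))
        for row, b in enumerate(bidx):
            m = branch_masks[b]
            for lf in range(n_tot):
                if m >> lf & 1:
                    data[row, lf] = 1
    else:
        pos = np.empty(0, np.int64)
    sites = [
        VariantSite(chrom, int(p), f"{chrom}:{int(p) + 1}", "A", "G", ancestral_allele="A")
        for p in pos
    ]
    labels = np.repeat(np.arange(cfg.demes), cfg.n_per_deme)
    sample_ids = []
    for d, nd in enumerate(cfg.n_per_deme):
        sample_ids += [f"d{d}_s{i // 2}" for i in range(nd)]
    H = HaplotypeMatrix(sites, data, sample_ids, coding="ancestral/derived")
    return H, labels


# ---------------------------------------------------------------------------
# deep two-clade balanced locus


def simulate_deep_clades(cfg: DeepCladeConfig):
    """Two deeply diverged haplotype clades segregating within groups.

    Each clade's internal variation comes from an independent neutral
    coalescent; ``split_depth`` fixed inter-clade differences are planted
    at distinct sites, with the derived state carried by clade A.  Truth
    clade labels are returned per chromosome.

    Returns ``(H, clade_labels, group_labels)`` with ``clade_labels`` in
    {"A", "B"}.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = list(cfg.n_per_group)
    # decide clade membership per chromosome first
    clade_per_chrom: list[str] = []
    group_per_chrom: list[str] = []
    for g in groups:
        draws = rng.random(cfg.n_per_group[g]) < cfg.freq_cladeA_per_group[g]
        clade_per_chrom += ["A" if d else "B" for d in draws]
        group_per_chrom += [g] * cfg.n_per_group[g]
    clade_per_chrom = np.array(clade_per_chrom)
    group_per_chrom = np.array(group_per_chrom)
    nA = int((clade_per_chrom == "A").sum())
    nB = len(clade_per_chrom) - nA

    within = cfg.within_clade or CoalescentConfig(n=2, fixed_S=0)

    def clade_sites(n_chroms: int, seed: int) -> np.ndarray:
        if n_chroms < 2:
            return np.empty((0, max(n_chroms, 0)), dtype=np.int8)
        sub = CoalescentConfig(
            n=n_chroms,
            theta=within.theta,
            fixed_S=within.fixed_S,
            locus_length=cfg.locus_length,
            seed=seed,
        )
        h, _ = simulate_coalescent(sub)
        return h.data

    dataA = clade_sites(nA, int(rng.integers(2**31)))
    dataB = clade_sites(nB, int(rng.integers(2**31)))
    n_sites = cfg.split_depth + dataA.shape[0] + dataB.shape[0]
    if n_sites > cfg.locus_length:
        raise ValueError(
            f"locus_length {cfg.locus_length} too short for {n_sites} sites"
        )
    n_tot = len(clade_per_chrom)
    blocks = []
    # split sites: derived (1) on every clade-A chromosome
    split_block = np.zeros((cfg.split_depth, n_tot), dtype=np.int8)
    split_block[:, clade_per_chrom == "A"] = 1
    blocks.append(split_block)
    if dataA.shape[0]:
        blkA = np.zeros((dataA.shape[0], n_tot), dtype=np.int8)
        blkA[:, clade_per_chrom == "A"] = dataA
        blocks.append(blkA)
    if dataB.shape[0]:
        blkB = np.zeros((dataB.shape[0], n_tot), dtype=np.int8)
        blkB[:, clade_per_chrom == "B"] = dataB
        blocks.append(blkB)
    data = np.concatenate(blocks, axis=0)
    # drop sites monomorphic in the pooled sample (e.g. clade empty)
    seg = (data.sum(axis=1) > 0) & (data.sum(axis=1) < n_tot)
    is_split = np.zeros(data.shape[0], dtype=bool)
    is_split[: cfg.split_depth] = True
    data, is_split = data[seg], is_split[seg]
    # scatter sites across the locus so diagnostic sites intersperse with
    # within-clade polymorphism
    perm = rng.permutation(data.shape[0])
    data, is_split = data[perm], is_split[perm]
    pos = np.sort(rng.choice(cfg.locus_length, size=data.shape[0], replace=False))
    n_split_seen = 0
    sites = []
    for i, p in enumerate(pos):
        if is_split[i]:
            n_split_seen += 1
            sid = f"split{n_split_seen}"
        else:
            sid = f"snp{i + 1}"
        sites.append(VariantSite("chrClade", int(p), sid, "A", "G", ancestral_allele="A"))
    sample_ids = [f"{g}_{i // 2}" for i, g in enumerate(group_per_chrom)]
    H = HaplotypeMatrix(sites, data, sample_ids, coding="ancestral/derived")
    return H, clade_per_chrom, group_per_chrom


def split_site_ids(H: HaplotypeMatrix) -> list[str]:
    """Ids of the planted inter-clade diagnostic sites."""
    return [s.id for s in H.sites if s.id.startswith("split")]


# ---------------------------------------------------------------------------
# diploid cohort assembly


def make_cohort(
    H: HaplotypeMatrix,
    group_labels: np.ndarray,
    clade_labels: np.ndarray,
    disease_group: str | None = None,
    disease_source: str | None = None,
    n_disease: int = 0,
    disease_enrichment: float = 0.0,
    seed: int = 0,
):
    """Pair chromosomes into diploids (Hardy-Weinberg within group).

    Optionally adds a disease group of ``n_disease`` individuals whose
    chromosomes are resampled from ``disease_source`` with the clade-A
    frequency boosted by ``disease_enrichment``.

    Returns ``(GenotypeMatrix, PopulationPanel, clade_pair_truth, cohort_H)``
    where the truth maps sample_id -> (clade, clade) of its two
    chromosomes and ``cohort_H`` is the phased cohort matrix the
    genotypes were collapsed from.
    """
    from .io import to_genotypes

    rng = np.random.default_rng(seed)
    group_labels = np.asarray(group_labels)
    clade_labels = np.asarray(clade_labels)
    cols: list[int] = []
    sample_ids: list[str] = []
    pop: dict[str, str] = {}
    clu: dict[str, str] = {}
    truth: dict[str, tuple] = {}
    for g in dict.fromkeys(group_labels):
        idx = np.flatnonzero(group_labels == g)
        idx = rng.permutation(idx)
        for k in range(len(idx) // 2):
            sid = f"{g}_ind{k}"
            cols += [int(idx[2 * k]), int(idx[2 * k + 1])]
            sample_ids += [sid, sid]
            pop[sid] = clu[sid] = str(g)
            truth[sid] = (clade_labels[idx[2 * k]], clade_labels[idx[2 * k + 1]])
    if disease_group is not None:
        src = np.flatnonzero(group_labels == disease_source)
        if not len(src):
            raise ValueError(f"no chromosomes in source group {disease_source!r}")
        srcA = src[clade_labels[src] == "A"]
        srcB = src[clade_labels[src] == "B"]
        p0 = len(srcA) / len(src)
        p = p0 + disease_enrichment
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"enriched clade-A frequency {p:.3f} outside [0,1]")
        for k in range(n_disease):
            sid = f"{disease_group}_ind{k}"
            pair = []
            for _ in range(2):
                pool = srcA if (rng.random() < p and len(srcA)) else srcB
                if not len(pool):
                    pool = src
                pair.append(int(rng.choice(pool)))
            cols += pair
            sample_ids += [sid, sid]
            pop[sid] = clu[sid] = disease_group
            truth[sid] = (clade_labels[pair[0]], clade_labels[pair[1]])
    data = H.data[:, cols]
    cohort = HaplotypeMatrix(list(H.sites), data, sample_ids, coding=H.coding)
    return to_genotypes(cohort), PopulationPanel(pop, clu), truth, cohort


def simulate_bn_genotypes(
    n_snps: int,
    fst: float,
    n_per_cluster: dict,
    ancestral_freq_range: tuple = (0.05, 0.95),
    seed: int = 0,
):
    """Unlinked diploid genotypes under the Balding-Nichols model.

    Cluster allele frequencies are Beta-distributed around a shared
    ancestral frequency with differentiation parameter ``fst``;
    individual dosages are Binomial(2, p_cluster).  Returns
    ``(GenotypeMatrix, cluster_labels)`` — the substrate for ancestry-
    assignment experiments at a known differentiation level.
    """
    from .core import GenotypeMatrix

    rng = np.random.default_rng(seed)
    lo, hi = ancestral_freq_range
    p = rng.uniform(lo, hi, size=n_snps)
    a, b = p * (1 - fst) / fst, (1 - p) * (1 - fst) / fst
    blocks, labels, sample_ids = [], [], []
    for c, n in n_per_cluster.items():
        pc = rng.beta(a, b)
        blocks.append(rng.binomial(2, pc, size=(n, n_snps)).astype(np.int8))
        labels += [c] * n
        sample_ids += [f"{c}_{i}" for i in range(n)]
    sites = [
        VariantSite("chrBN", i, f"bn{i + 1}", "A", "G", ancestral_allele="A")
        for i in range(n_snps)
    ]
    G = GenotypeMatrix(sites, np.vstack(blocks), sample_ids)
    return G, np.array(labels)


# ---------------------------------------------------------------------------
# Balding-Nichols genome background


def simulate_background_fst(cfg: BackgroundConfig, estimator: str = "wright"):
    """Per-SNP F_st background under the Balding-Nichols model.

    For each SNP an ancestral frequency p is drawn uniformly from
    ``ancestral_freq_range``; each cluster's frequency is
    Beta(p(1-F)/F, (1-p)(1-F)/F); allele counts are binomial.  Pairwise
    per-SNP F_st is computed with the differentiation module.  SNPs
    monomorphic in a pooled pair are excluded from that pair's values.

    Returns dict (clusterA, clusterB) -> array of F_st values.
    """
    from .fst import fst_from_frequencies

    rng = np.random.default_rng(cfg.seed)
    clusters = list(cfg.n_per_cluster)
    lo, hi = cfg.ancestral_freq_range
    p = rng.uniform(lo, hi, size=cfg.n_snps)
    F = cfg.fst_target
    a, b = p * (1 - F) / F, (1 - p) * (1 - F) / F
    freqs = {}
    for c in clusters:
        pc = rng.beta(a, b)
        n = cfg.n_per_cluster[c]
        freqs[c] = rng.binomial(n, pc) / n
    out = {}
    for i, ca in enumerate(clusters):
        for cb in clusters[i + 1 :]:
            pa, pb = freqs[ca], freqs[cb]
            na, nb = cfg.n_per_cluster[ca], cfg.n_per_cluster[cb]
            fst = fst_from_frequencies(pa, na, pb, nb, estimator=estimator)
            out[(ca, cb)] = fst[~np.isnan(fst)]
    return out
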