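"""Site-frequency-spectrum descriptive and neutrality statistics.

The battery per locus/group is: number of segregating sites S, per-site
nucleotide diversity pi, Watterson's theta, Tajima's D, and Fu & Li's D
and F (outgroup variants when the matrix is polarized, starred variants
otherwise).  Significance is assessed against fixed-S neutral coalescent
replicates with the (1+k)/(R+1) one-tailed estimator, and multiplicity
is handled by the adaptive Benjamini-Hochberg (lowest-slope) procedure.

A statistic that is undefined (S = 0, or a degenerate variance) is
reported as ``None``, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import HaplotypeMatrix
from .simulate import CoalescentConfig, simulate_sfs_counts

STATISTICS = ("pi_locus", "tajima_d", "fuli_d", "fuli_f", "fuli_d_star", "fuli_f_star")


# ---------------------------------------------------------------------------
# descriptive statistics


def derived_counts(H: HaplotypeMatrix) -> np.ndarray:
    return H.data.sum(axis=1).astype(np.int64)


def segregating_sites(H: HaplotypeMatrix) -> int:
    if H.n_chromosomes == 0:
        raise ValueError("empty matrix")
    c = derived_counts(H)
    return int(((c > 0) & (c < H.n_chromosomes)).sum())


def _pi_locus(counts: np.ndarray, n: int) -> float:
    """Mean pairwise difference: sum over sites of c(n-c)/C(n,2)."""
    return float((counts * (n - counts)).sum() * 2.0 / (n * (n - 1)))


def nucleotide_diversity(H: HaplotypeMatrix, locus_length: int) -> float:
    """Per-site pi; invariant positions enter through ``locus_length``."""
    if locus_length < H.n_sites:
        raise ValueError(f"locus_length {locus_length} < site count {H.n_sites}")
    return _pi_locus(derived_counts(H), H.n_chromosomes) / locus_length


def harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def watterson_theta(H: HaplotypeMatrix, locus_length: int | None = None) -> float:
    """theta_W = S / a_n; per site when locus_length is given."""
    th = segregating_sites(H) / harmonic(H.n_chromosomes)
    return th / locus_length if locus_length else th


# ---------------------------------------------------------------------------
# Tajima's D


def _tajima_constants(n: int):
    a1 = harmonic(n)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def _tajima_from_counts(counts: np.ndarray, n: int, consts=None) -> float | None:
    S = int(((counts > 0) & (counts < n)).sum())
    if S == 0:
        return None
    a1, e1, e2 = consts or _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    return (_pi_locus(counts, n) - S / a1) / math.sqrt(var)


def tajimas_D(H: HaplotypeMatrix) -> float | None:
    """Tajima (1989) D; None when S = 0."""
    return _tajima_from_counts(derived_counts(H), H.n_chromosomes)


# ---------------------------------------------------------------------------
# Fu & Li's D and F


def _fuli_constants(n: int):
    """Variance constants for the outgroup and starred Fu & Li statistics.

    Corrected forms (the original report contains typos); validated by the
    neutral-simulation calibration in the test suite.
    """
    nf = float(n)
    an = harmonic(n)
    bn = harmonic(n, 2)
    an1 = an + 1.0 / nf
    if n > 2:
        cn = 2.0 * (nf * an - 2.0 * (nf - 1)) / ((nf - 1) * (nf - 2))
    else:
        cn = 1.0
    # outgroup D
    vD = 1.0 + (an**2 / (bn + an**2)) * (cn - (nf + 1) / (nf - 1))
    uD = an - 1.0 - vD
    # outgroup F
    vF = (cn + 2.0 * (nf**2 + nf + 3) / (9.0 * nf * (nf - 1)) - 2.0 / (nf - 1)) / (an**2 + bn)
    uF = (
        1.0
        + (nf + 1) / (3.0 * (nf - 1))
        - 4.0 * ((nf + 1) / (nf - 1) ** 2) * (an1 - 2.0 * nf / (nf + 1))
    ) / an - vF
    # starred (no outgroup) variants
    if n > 2:
        dn = cn + (nf - 2) / (nf - 1) ** 2 + (2.0 / (nf - 1)) * (
            1.5 - (2.0 * an1 - 3.0) / (nf - 2) - 1.0 / nf
        )
    else:
        dn = 2.0
    vDs = (
        (nf / (nf - 1)) ** 2 * bn
        + an**2 * dn
        - 2.0 * (nf * an * (an + 1)) / (nf - 1) ** 2
    ) / (an**2 + bn)
    uDs = (nf / (nf - 1)) * (an - nf / (nf - 1)) - vDs
    vFs = (
        dn
        + 2.0 * (nf**2 + nf + 3) / (9.0 * nf * (nf - 1))
        - (2.0 / (nf - 1)) * (4.0 * bn - 6.0 + 8.0 / nf)
    ) / (an**2 + bn)
    uFs = (
        nf / (nf - 1)
        + (nf + 1) / (3.0 * (nf - 1))
        - 4.0 / (nf * (nf - 1))
        + 4.0 * ((nf + 2) / ((nf + 1) * (nf - 1))) * (an1 - 2.0 * nf / (nf + 1))
    ) / an - vFs
    return dict(an=an, uD=uD, vD=vD, uF=uF, vF=vF, uDs=uDs, vDs=vDs, uFs=uFs, vFs=vFs)


def _fuli_from_counts(counts, n, polarized: bool, consts=None):
    S = int(((counts > 0) & (counts < n)).sum())
    if S == 0:
        return None, None
    k = consts or _fuli_constants(n)
    pi = _pi_locus(counts, n)
    if polarized:
        eta_e = int((counts == 1).sum())  # derived singletons (external branches)
        D = (S - k["an"] * eta_e) / math.sqrt(k["uD"] * S + k["vD"] * S * S)
        F = (pi - eta_e) / math.sqrt(k["uF"] * S + k["vF"] * S * S)
        return D, F
    eta_s = int(((counts == 1) | (counts == n - 1)).sum())  # minor-allele singletons
    D = ((n / (n - 1.0)) * S - k["an"] * eta_s) / math.sqrt(k["uDs"] * S + k["vDs"] * S * S)
    F = (pi - ((n - 1.0) / n) * eta_s) / math.sqrt(k["uFs"] * S + k["vFs"] * S * S)
    return D, F


def fu_li_D_F(H: HaplotypeMatrix, polarized: bool = True):
    """Fu & Li's (D, F): outgroup variants when ``polarized``, else starred.

    ``polarized=True`` requires ancestral/derived coding; singletons are
    then counted on the derived allele (external-branch mutations).
    """
    if polarized and H.coding != "ancestral/derived":
        raise ValueError("polarized Fu & Li statistics need ancestral/derived coding")
    return _fuli_from_counts(derived_counts(H), H.n_chromosomes, polarized)


# ---------------------------------------------------------------------------
# simulation p-values


def _stat_fn(statistic: str, n: int, polarized: bool = True):
    if statistic == "pi_locus":
        return lambda c: _pi_locus(c, n)
    if statistic == "tajima_d":
        consts = _tajima_constants(n)
        return lambda c: _tajima_from_counts(c, n, consts)
    consts = _fuli_constants(n)
    if statistic in ("fuli_d", "fuli_d_star"):
        pol = statistic == "fuli_d"
        return lambda c: _fuli_from_counts(c, n, pol, consts)[0]
    if statistic in ("fuli_f", "fuli_f_star"):
        pol = statistic == "fuli_f"
        return lambda c: _fuli_from_counts(c, n, pol, consts)[1]
    raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")


def simulate_null_statistics(
    statistic: str, n: int, S: int, reps: int, seed: int
) -> np.ndarray:
    """Null distribution of a statistic under the fixed-S coalescent."""
    rng = np.random.default_rng(seed)
    fn = _stat_fn(statistic, n)
    out = np.empty(reps)
    for r in range(reps):
        v = fn(simulate_sfs_counts(n, S, rng))
        out[r] = np.nan if v is None else v
    return out


def simulate_null_table(
    n: int, S: int, reps: int, seed: int, polarized: bool = True
) -> dict[str, np.ndarray]:
    """Null distributions of the whole battery from one shared set of
    fixed-S replicates (pi_locus, Tajima's D, Fu & Li's D and F)."""
    rng = np.random.default_rng(seed)
    tc = _tajima_constants(n)
    fc = _fuli_constants(n)
    out = {k: np.empty(reps) for k in ("pi_locus", "tajima_d", "fuli_d", "fuli_f")}
    for r in range(reps):
        c = simulate_sfs_counts(n, S, rng)
        out["pi_locus"][r] = _pi_locus(c, n)
        out["tajima_d"][r] = _tajima_from_counts(c, n, tc)
        d, f = _fuli_from_counts(c, n, polarized, fc)
        out["fuli_d"][r] = d
        out["fuli_f"][r] = f
    return out


def pvalue_from_null(observed: float, null: np.ndarray, tail: str) -> float:
    """One-tailed (1 + k)/(R + 1) empirical p-value against a null sample."""
    defined = null[~np.isnan(null)]
    k = int((defined >= observed).sum() if tail == "upper" else (defined <= observed).sum())
    return (1 + k) / (len(defined) + 1)


def neutrality_pvalue(
    observed: float,
    cfg: CoalescentConfig,
    statistic: str,
    reps: int = 10_000,
    tail: str = "upper",
    seed: int = 0,
) -> float:
    """One-tailed simulation p-value, (1 + k)/(reps + 1) so p is never 0."""
    if observed is None:
        raise ValueError("observed statistic is undefined; no p-value")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    if cfg.fixed_S is None:
        raise NotImplementedError("p-values are computed under the fixed-S null")
    null = simulate_null_statistics(statistic, cfg.n, cfg.fixed_S, reps, seed)
    defined = null[~np.isnan(null)]
    if len(defined) < reps / 2:
        raise RuntimeError("statistic undefined in more than half of the replicates")
    if tail == "upper":
        k = int((defined >= observed).sum())
    else:
        k = int((defined <= observed).sum())
    return (1 + k) / (len(defined) + 1)


# ---------------------------------------------------------------------------
# adaptive Benjamini-Hochberg


def abh_adjust(pvals, alpha: float = 0.01) -> np.ndarray:
    """Adaptive BH: lowest-slope estimate of m0, then step-up with m0.

    The number of true nulls m0 is estimated from the ordered p-values by
    the lowest-slope recipe: compute m0_i = (m + 1 - i)/(1 - p_(i)) and
    take the first i where the sequence starts increasing.  Adjusted
    values are clipped to [raw, 1] and are monotone in rank.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    with np.errstate(divide="ignore"):
        m0_seq = np.where(ps < 1.0, (m + 1 - np.arange(1, m + 1)) / (1.0 - ps), np.inf)
    with np.errstate(invalid="ignore"):
        diffs = np.diff(m0_seq)
    inc = np.flatnonzero(np.nan_to_num(diffs, nan=-1.0) > 0)
    if inc.size:
        m0 = int(min(m, math.ceil(min(m0_seq[inc[0] + 1], m))))
    else:
        m0 = m
    m0 = max(m0, 1)
    bh = m0 * ps / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(bh[::-1])[::-1])
    adj = np.maximum(adj, ps)
    out = np.empty(m)
    out[order] = adj
    return out


def estimate_m0(pvals) -> int:
    """Lowest-slope m0 estimate alone (exposed for diagnostics)."""
    p = np.sort(np.asarray(pvals, dtype=float))
    m = p.size
    with np.errstate(divide="ignore"):
        m0_seq = np.where(p < 1.0, (m + 1 - np.arange(1, m + 1)) / (1.0 - p), np.inf)
    diffs = np.diff(m0_seq)
    inc = np.flatnonzero(np.nan_to_num(diffs, nan=-1.0) > 0)
    if inc.size:
        return max(1, int(min(m, math.ceil(min(m0_seq[inc[0] + 1], m)))))
    return m


# ---------------------------------------------------------------------------
# the per-locus battery


@dataclass
class NeutralityResult:
    locus: str
    group: str
    n_chromosomes: int
    S: int
    pi_per_site: float
    theta_w_per_site: float
    tajima_d: float | None
    fuli_d: float | None
    fuli_f: float | None
    p_pi: float | None = None
    p_tajima_d: float | None = None
    p_fuli_d: float | None = None
    p_fuli_f: float | None = None
    tails: dict = field(default_factory=dict)
    adj_p: dict = field(default_factory=dict)
    polarized: bool = True


def _auto_tail(observed: float) -> str:
    return "upper" if observed >= 0 else "lower"


def neutrality_battery(
    H: HaplotypeMatrix,
    locus: str,
    locus_length: int,
    group: str = "all",
    reps: int = 10_000,
    seed: int = 0,
    polarized: bool | None = None,
) -> NeutralityResult:
    """Full descriptive + neutrality battery for one locus/group.

    p-values come from fixed-S neutral replicates: the upper tail for the
    diversity excess (pi) and for positive observed D/F values, the lower
    tail for negative ones; the tail used is recorded per statistic.
    """
    if polarized is None:
        polarized = H.coding == "ancestral/derived"
    n = H.n_chromosomes
    S = segregating_sites(H)
    pi = nucleotide_diversity(H, locus_length)
    res = NeutralityResult(
        locus=locus,
        group=group,
        n_chromosomes=n,
        S=S,
        pi_per_site=pi,
        theta_w_per_site=watterson_theta(H, locus_length),
        tajima_d=tajimas_D(H),
        fuli_d=None,
        fuli_f=None,
        polarized=polarized,
    )
    res.fuli_d, res.fuli_f = fu_li_D_F(H, polarized=polarized)
    if S == 0 or reps <= 0:
        return res
    null = simulate_null_table(n, S, reps, seed, polarized=polarized)
    stats = {
        "p_pi": ("pi_locus", pi * locus_length, "upper"),
        "p_tajima_d": ("tajima_d", res.tajima_d, None),
        "p_fuli_d": ("fuli_d", res.fuli_d, None),
        "p_fuli_f": ("fuli_f", res.fuli_f, None),
    }
    for attr, (name, obs, tail) in stats.items():
        if obs is None:
            continue
        tail = tail or _auto_tail(obs)
        res.tails[attr] = tail
        setattr(res, attr, pvalue_from_null(obs, null[name], tail))
    return res


def neutrality_table(results: list[NeutralityResult], alpha: float = 0.01) -> pd.DataFrame:
    """Tabulate results with ABH-adjusted p-values across the whole table.

    All defined raw p-values across loci, groups and statistics enter one
    adaptive-BH family, mirroring a multi-gene, multi-group scan.
    """
    rows = []
    keyed = []
    for r in results:
        row = {
            "locus": r.locus,
            "group": r.group,
            "N": r.n_chromosomes,
            "S": r.S,
            "pi_per_site": r.pi_per_site,
            "theta_w_per_site": r.theta_w_per_site,
            "tajima_d": r.tajima_d,
            "fuli_d": r.fuli_d,
            "fuli_f": r.fuli_f,
            "p_pi": r.p_pi,
            "p_tajima_d": r.p_tajima_d,
            "p_fuli_d": r.p_fuli_d,
            "p_fuli_f": r.p_fuli_f,
        }
        rows.append(row)
        for stat in ("p_pi", "p_tajima_d", "p_fuli_d", "p_fuli_f"):
            if row[stat] is not None:
                keyed.append((len(rows) - 1, stat, row[stat]))
    df = pd.DataFrame(rows)
    for stat in ("p_pi", "p_tajima_d", "p_fuli_d", "p_fuli_f"):
        df["adj_" + stat] = np.nan
    if keyed:
        adj = abh_adjust([p for _, _, p in keyed], alpha=alpha)
        for (i, stat, _), a in zip(keyed, adj):
            df.loc[i, "adj_" + stat] = a
            results[i].adj_p[stat] = float(a)
    df["significant"] = (
        df[[c for c in df.columns if c.startswith("adj_")]].min(axis=1) <= alpha
    )
    return df
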