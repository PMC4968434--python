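"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written from first principles (explicit loops, direct
formula transcription) and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


def seg_sites_brute(data: np.ndarray) -> int:
    count = 0
    for row in data:
        alleles = set(int(x) for x in row)
        if len(alleles) > 1:
            count += 1
    return count


def pi_locus_brute(data: np.ndarray) -> float:
    """Mean pairwise Hamming distance over all chromosome pairs."""
    n = data.shape[1]
    total = 0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int((data[:, i] != data[:, j]).sum())
            npairs += 1
    return total / npairs


def tajima_d_brute(data: np.ndarray) -> float | None:
    n = data.shape[1]
    S = seg_sites_brute(data)
    if S == 0:
        return None
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_locus_brute(data) - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fuli_brute(data: np.ndarray, polarized: bool = True):
    """Fu & Li D and F directly from their definitions (derived coding)."""
    n = data.shape[1]
    S = seg_sites_brute(data)
    if S == 0:
        return None, None
    an = sum(1.0 / i for i in range(1, n))
    bn = sum(1.0 / i**2 for i in range(1, n))
    an1 = an + 1.0 / n
    cn = 2.0 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2)) if n > 2 else 1.0
    pi = pi_locus_brute(data)
    if polarized:
        eta = sum(1 for row in data if int(row.sum()) == 1)
        vD = 1.0 + (an**2 / (bn + an**2)) * (cn - (n + 1) / (n - 1))
        uD = an - 1.0 - vD
        D = (S - an * eta) / math.sqrt(uD * S + vD * S * S)
        vF = (cn + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) / (an**2 + bn)
        uF = (
            1.0
            + (n + 1) / (3.0 * (n - 1))
            - 4.0 * ((n + 1) / (n - 1) ** 2) * (an1 - 2.0 * n / (n + 1))
        ) / an - vF
        F = (pi - eta) / math.sqrt(uF * S + vF * S * S)
        return D, F
    eta = sum(1 for row in data if int(row.sum()) in (1, n - 1))
    dn = cn + (n - 2) / (n - 1) ** 2 + (2.0 / (n - 1)) * (
        1.5 - (2.0 * an1 - 3.0) / (n - 2) - 1.0 / n
    )
    vDs = ((n / (n - 1)) ** 2 * bn + an**2 * dn - 2.0 * n * an * (an + 1) / (n - 1) ** 2) / (
        an**2 + bn
    )
    uDs = (n / (n - 1)) * (an - n / (n - 1)) - vDs
    Ds = ((n / (n - 1)) * S - an * eta) / math.sqrt(uDs * S + vDs * S * S)
    vFs = (
        dn + 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1)) - (2.0 / (n - 1)) * (4 * bn - 6 + 8.0 / n)
    ) / (an**2 + bn)
    uFs = (
        n / (n - 1)
        + (n + 1) / (3.0 * (n - 1))
        - 4.0 / (n * (n - 1))
        + 4.0 * ((n + 2) / ((n + 1) * (n - 1))) * (an1 - 2.0 * n / (n + 1))
    ) / an - vFs
    Fs = (pi - ((n - 1) / n) * eta) / math.sqrt(uFs * S + vFs * S * S)
    return Ds, Fs


def fst_wright_brute(pA: float, nA: int, pB: float, nB: int) -> float | None:
    pbar = (nA * pA + nB * pB) / (nA + nB)
    hT = 2 * pbar * (1 - pbar)
    if hT == 0:
        return None
    hS = (nA * 2 * pA * (1 - pA) + nB * 2 * pB * (1 - pB)) / (nA + nB)
    return (hT - hS) / hT


def r2_brute(x, y) -> float | None:
    """Squared correlation from raw sums."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    vx = sxx - sx * sx / n
    vy = syy - sy * sy / n
    if vx == 0 or vy == 0:
        return None
    cov = sxy - sx * sy / n
    return cov * cov / (vx * vy)


def abh_brute(pvals, alpha: float = 0.01):
    """Step-by-step adaptive BH (lowest-slope m0, then step-up with m0)."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    ps = [p[i] for i in order]
    # lowest-slope m0 estimate
    m0_seq = []
    for i in range(1, m + 1):
        denom = 1.0 - ps[i - 1]
        m0_seq.append((m + 1 - i) / denom if denom > 0 else math.inf)
    m0 = m
    for i in range(1, m):
        if not (math.isinf(m0_seq[i]) and math.isinf(m0_seq[i - 1])) and m0_seq[i] > m0_seq[i - 1]:
            m0 = min(m, math.ceil(min(m0_seq[i], m)))
            break
    m0 = max(1, m0)
    # BH step-up with m replaced by m0
    adj = [min(1.0, m0 * ps[i] / (i + 1)) for i in range(m)]
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    adj = [max(a, ps[i]) for i, a in enumerate(adj)]
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = adj[rank]
    return out, m0


def percentile_nearest_rank_brute(values, pct: float) -> float:
    v = sorted(values)
    rank = math.ceil(pct / 100.0 * len(v))
    return v[max(rank, 1) - 1]


def random_matrix(rng, n_sites=None, n_chrom=None) -> np.ndarray:
    n_sites = n_sites or int(rng.integers(1, 15))
    n_chrom = n_chrom or int(rng.integers(4, 20))
    # mixture of frequencies so singletons and intermediates both occur
    data = np.zeros((n_sites, n_chrom), dtype=np.int8)
    for i in range(n_sites):
        p = rng.beta(0.5, 0.5)
        data[i] = rng.random(n_chrom) < p
    return data
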