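"""Independent brute-force oracles for the summary statistics.

Everything here is written as a literal, loop-based transcription of the
defining formulas, deliberately sharing no code with the package, so the
vectorised implementations can be checked for exact agreement on small
fixtures.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations

import numpy as np


def pi_oracle(haps: np.ndarray) -> float:
    """Mean pairwise difference count between haplotype columns."""
    S, n = haps.shape
    if n < 2:
        return 0.0
    total = 0
    pairs = 0
    for i, j in combinations(range(n), 2):
        total += int(np.sum(haps[:, i] != haps[:, j]))
        pairs += 1
    return total / pairs


def watterson_oracle(S: int, n: int) -> float:
    a1 = sum(1.0 / i for i in range(1, n))
    return S / a1


def tajima_d_oracle(haps: np.ndarray) -> float:
    """Tajima's D from the 1989 constants, written out longhand."""
    S, n = haps.shape
    seg = [i for i in range(S) if 0 < haps[i].sum() < n]
    S = len(seg)
    if S == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = pi_oracle(haps[seg])
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def dist_moments_oracle(vecs: np.ndarray):
    """(var, skew, excess kurtosis) of city-block distances between rows."""
    d = [
        float(np.sum(np.abs(vecs[i] - vecs[j])))
        for i, j in combinations(range(vecs.shape[0]), 2)
    ]
    d = np.asarray(d)
    mu = d.mean()
    m2 = ((d - mu) ** 2).mean()
    if m2 == 0:
        return 0.0, float("nan"), float("nan")
    m3 = ((d - mu) ** 3).mean()
    m4 = ((d - mu) ** 4).mean()
    return m2, m3 / m2**1.5, m4 / m2**2 - 3.0


def h_stats_oracle(haps: np.ndarray):
    """(n_haps, H1, H12, H2/H1) from haplotype string frequencies."""
    n = haps.shape[1]
    counts = Counter(tuple(haps[:, j]) for j in range(n))
    p = sorted((c / n for c in counts.values()), reverse=True)
    h1 = sum(x * x for x in p)
    if len(p) == 1:
        return 1, h1, h1, 0.0
    h12 = (p[0] + p[1]) ** 2 + sum(x * x for x in p[2:])
    return len(p), h1, h12, (h1 - p[0] ** 2) / h1


def r2_pair_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Haplotype r^2 from the 2x2 gamete table."""
    n = x.size
    pa = x.mean()
    pb = y.mean()
    pab = np.mean((x == 1) & (y == 1))
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom == 0:
        return float("nan")
    return (pab - pa * pb) ** 2 / denom


def zns_oracle(haps: np.ndarray) -> float:
    S = haps.shape[0]
    vals = [
        r2_pair_oracle(haps[i], haps[j]) for i, j in combinations(range(S), 2)
    ]
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def omega_oracle(haps: np.ndarray, cap: float = 1e4) -> float:
    """All-splits evaluation of the Kim-Nielsen omega statistic."""
    S = haps.shape[0]
    if S < 4:
        return float("nan")
    r2 = np.zeros((S, S))
    for i, j in combinations(range(S), 2):
        v = r2_pair_oracle(haps[i], haps[j])
        r2[i, j] = r2[j, i] = 0.0 if math.isnan(v) else v
    best = -np.inf
    for ell in range(2, S - 1):
        left = range(ell)
        right = range(ell, S)
        wl = sum(r2[i, j] for i, j in combinations(left, 2))
        wr = sum(r2[i, j] for i, j in combinations(right, 2))
        cross = sum(r2[i, j] for i in left for j in right)
        npairs = ell * (ell - 1) / 2 + (S - ell) * (S - ell - 1) / 2
        if cross <= 1e-12:
            om = cap
        else:
            om = ((wl + wr) / npairs) / (cross / (ell * (S - ell)))
        best = max(best, min(om, cap))
    return best


def fis_oracle(dosages: np.ndarray, maf_min: float) -> float:
    S, n = dosages.shape
    hobs, hexp = [], []
    for i in range(S):
        p = dosages[i].sum() / (2 * n)
        if min(p, 1 - p) < maf_min:
            continue
        hobs.append(np.mean(dosages[i] == 1))
        hexp.append(2 * p * (1 - p))
    if not hexp or np.mean(hexp) == 0:
        return float("nan")
    return 1.0 - np.mean(hobs) / np.mean(hexp)


def beta_oracle(
    positions: np.ndarray,
    counts: np.ndarray,
    n: int,
    core: int,
    flank_bp: int,
    p: float,
    folded: bool,
) -> float:
    """Literal transcription of the similarity-weighted theta difference.

    theta_beta counts each flanking variant with weight
    ``(1 - |f - f_core|)^p`` and divides by the matching expectation
    normaliser; theta_W is S/a_n; beta is their difference.
    """
    a_n = sum(1.0 / i for i in range(1, n))
    core_pos = positions[core]
    flank = [
        k
        for k in range(len(positions))
        if k != core and abs(int(positions[k]) - int(core_pos)) <= flank_bp
    ]
    if not flank:
        return 0.0
    if folded:
        x = min(counts[core], n - counts[core]) / n
        num = 0.0
        for k in flank:
            f = min(counts[k], n - counts[k]) / n
            num += (1 - abs(f - x)) ** p
        denom = 0.0
        for j in range(1, n // 2 + 1):
            w = (1 - abs(j / n - x)) ** p
            dup = 1.0 if j == n - j else 0.0
            denom += w * (1.0 / j + 1.0 / (n - j)) / (1.0 + dup)
    else:
        x = counts[core] / n
        num = sum((1 - abs(counts[k] / n - x)) ** p for k in flank)
        denom = sum((1 - abs(i / n - x)) ** p / i for i in range(1, n))
    return num / denom - len(flank) / a_n


def k2p_oracle(P: float, Q: float) -> float:
    """Kimura 2-parameter distance, independent closed form."""
    return -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
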