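"""Windowed population-genetic summary statistics.

Implements the feature vector used to characterise diversity landscapes:
nucleotide diversity (pi), Watterson's theta and Tajima's D, moments of the
pairwise-difference distribution, haplotype homozygosities (H1, H12,
H2/H1), LD summaries (ZnS, Kim-Nielsen omega, LD-decay profiles), the
BetaScan-style beta(1) balancing-selection score, and the inbreeding
coefficient F_is.  Statistics are computed per genomic window; undefined
values are returned as NaN (never 0).

Conventions
-----------
* pi is an unbiased per-window sum of site heterozygosities,
  ``sum 2 p q n/(n-1)`` over ``n`` haplotypes, equal to the mean number of
  pairwise differences between haplotypes.
* r^2 uses phased haplotype LD ``D^2/(pA qA pB qB)`` when haplotypes are
  available, and squared genotype-dosage Pearson correlation
  (Rogers-Huff style) otherwise.
* Haplotype statistics use true haplotypes when phased, otherwise
  multilocus genotype strings ("diplotypes").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .genotypes import GenotypeMatrix

__all__ = [
    "WindowSpec",
    "pi_window",
    "watterson_tajima",
    "pairwise_dist_moments",
    "haplotype_homozygosity",
    "zns",
    "r_squared_matrix",
    "omega_max",
    "beta_score",
    "fis_window",
    "ld_decay_profile",
    "compute_window_table",
    "WINDOW_STAT_COLUMNS",
]


def _in_window(gm: GenotypeMatrix, window) -> GenotypeMatrix:
    if window is None:
        return gm
    return gm.window(int(window[0]), int(window[1]))


def _segregating(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Drop sites not segregating in this sample."""
    if gm.n_sites == 0:
        return gm
    counts = gm.dosages.astype(int).sum(axis=1)
    keep = (counts > 0) & (counts < gm.n_haplotypes)
    if keep.all():
        return gm
    return GenotypeMatrix(
        positions=gm.positions[keep],
        dosages=gm.dosages[keep],
        haplotypes=None if gm.haplotypes is None else gm.haplotypes[keep],
        sequence_length=gm.sequence_length,
        ancestral_known=gm.ancestral_known[keep],
    )


# ---------------------------------------------------------------------------
# frequency-based statistics
# ---------------------------------------------------------------------------


def pi_window(gm: GenotypeMatrix, window=None) -> float:
    """Nucleotide diversity: mean pairwise differences between haplotypes.

    Computed from per-site allele frequencies with the unbiased factor
    ``n/(n-1)``; an empty window gives 0.
    """
    sub = _segregating(_in_window(gm, window))
    n = sub.n_haplotypes
    if sub.n_sites == 0:
        return 0.0
    if n < 2:
        raise ValueError("pi requires at least 2 haplotypes")
    p = sub.allele_frequencies()
    return float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1))


def _harmonic(n: int, power: int = 1) -> float:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i**power))


def watterson_tajima(gm: GenotypeMatrix, window=None) -> tuple[float, float]:
    """Watterson's theta (per window) and Tajima's D.

    ``theta_W = S / a1``; D follows the Tajima (1989) normalisation.  With
    no segregating sites theta is 0 and D is NaN (undefined, not 0).
    """
    sub = _segregating(_in_window(gm, window))
    n = sub.n_haplotypes
    S = sub.n_sites
    if n < 2:
        raise ValueError("theta_W requires at least 2 haplotypes")
    a1 = _harmonic(n)
    theta_w = S / a1
    if S == 0 or n < 4:
        return theta_w, float("nan")
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return theta_w, float("nan")
    pi = pi_window(sub)
    return theta_w, float((pi - theta_w) / math.sqrt(var))


# ---------------------------------------------------------------------------
# pairwise-difference distribution
# ---------------------------------------------------------------------------


def _genome_vectors(gm: GenotypeMatrix) -> np.ndarray:
    """Per-genome site vectors: haplotypes when phased, else dosages."""
    if gm.phased:
        return gm.haplotypes.T.astype(float)
    return gm.dosages.T.astype(float)


def pairwise_distances(gm: GenotypeMatrix, window=None) -> np.ndarray:
    """All pairwise difference counts between sampled genomes (city-block)."""
    sub = _segregating(_in_window(gm, window))
    vecs = _genome_vectors(sub)
    if vecs.shape[0] < 2:
        return np.zeros(0)
    if sub.n_sites == 0:
        k = vecs.shape[0]
        return np.zeros(k * (k - 1) // 2)
    return pdist(vecs, metric="cityblock")


def pairwise_dist_moments(gm: GenotypeMatrix, window=None):
    """(variance, skewness, excess kurtosis) of pairwise difference counts.

    Population (biased) moments over the ``k (k - 1) / 2`` distances; a
    monomorphic window gives ``(0, nan, nan)``.
    """
    d = pairwise_distances(gm, window)
    if d.size < 3:
        raise ValueError("need at least 3 genomes for distance moments")
    if np.all(d == d[0]):
        return float(np.var(d)), float("nan"), float("nan")
    return (
        float(np.var(d)),
        float(_skew(d, bias=True)),
        float(_kurtosis(d, fisher=True, bias=True)),
    )


# ---------------------------------------------------------------------------
# haplotype homozygosity
# ---------------------------------------------------------------------------


def haplotype_frequencies(gm: GenotypeMatrix, window=None) -> np.ndarray:
    """Sorted (descending) frequencies of distinct haplotypes in the window.

    Unphased input falls back to multilocus genotype strings (diplotypes).
    """
    sub = _segregating(_in_window(gm, window))
    mat = sub.haplotypes if sub.phased else sub.dosages
    k = mat.shape[1]
    if k == 0:
        return np.ones(1)
    if sub.n_sites == 0:
        return np.ones(1)
    _, counts = np.unique(mat.T, axis=0, return_counts=True)
    freqs = np.sort(counts / k)[::-1]
    return freqs


def haplotype_homozygosity(gm: GenotypeMatrix, window=None):
    """(n_haps, H1, H12, H2/H1) from sorted haplotype frequencies p1 >= p2...

    ``H1 = sum p_i^2``; ``H12 = (p1 + p2)^2 + sum_{i>=3} p_i^2`` (soft-sweep
    sensitive); ``H2/H1 = (H1 - p1^2) / H1``.  An empty window is a single
    haplotype class: (1, 1, 1, 0).
    """
    p = haplotype_frequencies(gm, window)
    h1 = float(np.sum(p**2))
    if p.size == 1:
        return 1, h1, h1, 0.0
    h12 = float((p[0] + p[1]) ** 2 + np.sum(p[2:] ** 2))
    h2_h1 = float((h1 - p[0] ** 2) / h1)
    return int(p.size), h1, h12, h2_h1


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def r_squared_matrix(gm: GenotypeMatrix, window=None) -> np.ndarray:
    """Pairwise r^2 between segregating sites.

    Phased: ``r^2 = D^2 / (pA qA pB qB)`` with ``D = pAB - pA pB`` from
    haplotypes.  Unphased: squared Pearson correlation of dosages.
    """
    sub = _segregating(_in_window(gm, window))
    S = sub.n_sites
    if S < 2:
        return np.zeros((S, S))
    if sub.phased:
        H = sub.haplotypes.astype(float)
        n = H.shape[1]
        p = H.mean(axis=1)
        pab = (H @ H.T) / n
        D = pab - np.outer(p, p)
        denom = np.outer(p * (1 - p), p * (1 - p))
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(denom > 0, D * D / denom, np.nan)
    else:
        G = sub.dosages.astype(float)
        Gc = G - G.mean(axis=1, keepdims=True)
        cov = Gc @ Gc.T
        sd = np.sqrt(np.diag(cov))
        denom = np.outer(sd, sd)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(denom > 0, (cov / denom) ** 2, np.nan)
    np.fill_diagonal(r2, 1.0)
    return np.clip(r2, 0.0, 1.0)


def zns(gm: GenotypeMatrix, window=None) -> float:
    """Kelly's ZnS: mean r^2 over all pairs of segregating sites.

    NaN with fewer than 2 segregating sites.
    """
    r2 = r_squared_matrix(gm, window)
    S = r2.shape[0]
    if S < 2:
        return float("nan")
    iu = np.triu_indices(S, k=1)
    return float(np.nanmean(r2[iu]))


def omega_max(gm: GenotypeMatrix, window=None, cap: float = 1e4) -> float:
    """Kim-Nielsen omega maximised over split points.

    For a split after site ``l`` (1-based) among ``S`` segregating sites::

        omega(l) = [ (C(l,2) + C(S-l,2))^-1 * sum within-side r^2 ]
                   / [ (l (S-l))^-1 * sum cross-side r^2 ]

    maximised over ``l in [2, S-2]``.  NaN when S < 4; when the cross-side
    LD sum is zero the statistic is capped at ``cap``.
    """
    r2 = r_squared_matrix(gm, window)
    S = r2.shape[0]
    if S < 4:
        return float("nan")
    r2 = np.nan_to_num(r2, nan=0.0)
    best = -np.inf
    iu = np.triu_indices(S, k=1)
    total = r2[iu].sum()
    rowsum = r2.sum(axis=1) - 1.0  # exclude the diagonal
    col_prefix = np.cumsum(r2, axis=0)
    within_left = 0.0
    left_rowsum = rowsum[0]
    for ell in range(2, S - 1):
        # move site ell-1 (0-based) into the left side
        within_left += col_prefix[ell - 2, ell - 1]  # sum r2[i, ell-1], i < ell-1
        left_rowsum += rowsum[ell - 1]
        right = S - ell
        cross = left_rowsum - 2.0 * within_left
        within_right = total - within_left - cross
        denom_pairs = ell * (ell - 1) / 2 + right * (right - 1) / 2
        num = (within_left + within_right) / denom_pairs
        om = cap if cross <= 1e-12 else num / (cross / (ell * right))
        best = max(best, min(om, cap))
    return float(best)


def ld_decay_profile(
    gm: GenotypeMatrix,
    max_dist: int,
    bins: int | np.ndarray = 20,
    pair_thinning: int = 1,
) -> pd.DataFrame:
    """Median r^2 as a function of pairwise site distance.

    ``pair_thinning = k`` keeps every k-th segregating site before forming
    pairs (the conventional thinning for dense data).  Returns a DataFrame
    with bin edges, midpoints, pair counts and the median r^2 per bin
    (NaN for empty bins).
    """
    sub = _segregating(gm)
    if pair_thinning > 1:
        idx = np.arange(0, sub.n_sites, pair_thinning)
        sub = GenotypeMatrix(
            positions=sub.positions[idx],
            dosages=sub.dosages[idx],
            haplotypes=None if sub.haplotypes is None else sub.haplotypes[idx],
            sequence_length=sub.sequence_length,
            ancestral_known=sub.ancestral_known[idx],
        )
    edges = (
        np.linspace(0, max_dist, bins + 1)
        if np.isscalar(bins)
        else np.asarray(bins, dtype=float)
    )
    S = sub.n_sites
    dists: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    if S >= 2:
        r2 = r_squared_matrix(sub)
        pos = sub.positions
        for i in range(S - 1):
            j_hi = int(np.searchsorted(pos, pos[i] + max_dist, side="right"))
            if j_hi <= i + 1:
                continue
            dists.append(pos[i + 1 : j_hi] - pos[i])
            vals.append(r2[i, i + 1 : j_hi])
    if dists:
        d = np.concatenate(dists).astype(float)
        v = np.concatenate(vals)
    else:
        d = np.zeros(0)
        v = np.zeros(0)
    which = np.digitize(d, edges[1:-1], right=False)
    med = np.full(edges.size - 1, np.nan)
    count = np.zeros(edges.size - 1, dtype=int)
    for b in range(edges.size - 1):
        sel = v[which == b]
        sel = sel[~np.isnan(sel)]
        count[b] = sel.size
        if sel.size:
            med[b] = np.median(sel)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "bin_mid": 0.5 * (edges[:-1] + edges[1:]),
            "n_pairs": count,
            "median_r2": med,
        }
    )


# ---------------------------------------------------------------------------
# beta (balancing-selection) score
# ---------------------------------------------------------------------------


def _beta_weight(f: np.ndarray, core: float, p: float) -> np.ndarray:
    return (1.0 - np.abs(f - core)) ** p


def beta_score(
    gm: GenotypeMatrix,
    core_site: int,
    flank_bp: int = 1000,
    p: float = 2.0,
    folded: bool | None = None,
) -> float:
    """beta(1) score of a core variant: ``theta_beta - theta_W`` over the flank.

    ``theta_beta`` is a frequency-weighted Watterson-type estimator in which
    each flanking variant is weighted by its allele-frequency similarity to
    the core, ``w = (1 - |f - f_core|)**p``; variants matching the core
    frequency count fully, dissimilar ones are down-weighted, so clusters of
    intermediate-frequency variants around a balanced site give beta > 0.

    ``folded=None`` (default) uses the unfolded spectrum only when the
    ancestral state is known at the core and all flanking sites; otherwise
    the folded version (minor-allele frequencies) is used.  With no
    flanking variants the score is 0.
    """
    sub = _segregating(gm)
    if not 0 <= core_site < sub.n_sites:
        raise IndexError("core_site out of range after restricting to segregating sites")
    n = sub.n_haplotypes
    pos = sub.positions
    core_pos = pos[core_site]
    lo, hi = np.searchsorted(pos, [core_pos - flank_bp, core_pos + flank_bp + 1])
    flank = np.arange(lo, hi)
    flank = flank[flank != core_site]
    if flank.size == 0:
        return 0.0
    counts = sub.dosages.astype(int).sum(axis=1)
    if folded is None:
        folded = not (
            sub.ancestral_known[core_site] and np.all(sub.ancestral_known[flank])
        )
    an = _harmonic(n)
    S = flank.size
    theta_w = S / an
    if folded:
        core_f = min(counts[core_site], n - counts[core_site]) / n
        fk = np.minimum(counts[flank], n - counts[flank]) / n
        w_obs = _beta_weight(fk, core_f, p)
        j = np.arange(1, n // 2 + 1)
        wj = _beta_weight(j / n, core_f, p)
        dup = (j == n - j).astype(float)
        denom = float(np.sum(wj * (1.0 / j + 1.0 / (n - j)) / (1.0 + dup)))
    else:
        core_f = counts[core_site] / n
        fk = counts[flank] / n
        w_obs = _beta_weight(fk, core_f, p)
        i = np.arange(1, n)
        wi = _beta_weight(i / n, core_f, p)
        denom = float(np.sum(wi / i))
    theta_beta = float(np.sum(w_obs)) / denom
    return float(theta_beta - theta_w)


# ---------------------------------------------------------------------------
# inbreeding coefficient
# ---------------------------------------------------------------------------


def fis_window(gm: GenotypeMatrix, window=None, maf_min: float = 0.05) -> float:
    """F_is: ``1 - mean(H_obs) / mean(H_exp)`` over sites with MAF >= maf_min.

    ``H_exp = 2 p q`` per site.  NaN when no site qualifies.
    """
    sub = _in_window(gm, window)
    if sub.n_sites == 0 or sub.n_individuals == 0:
        return float("nan")
    p = sub.allele_frequencies()
    maf = np.minimum(p, 1 - p)
    keep = maf >= maf_min
    if not np.any(keep):
        return float("nan")
    h_obs = (sub.dosages[keep] == 1).mean(axis=1)
    h_exp = 2.0 * p[keep] * (1.0 - p[keep])
    mean_exp = float(np.mean(h_exp))
    if mean_exp == 0:
        return float("nan")
    return float(1.0 - np.mean(h_obs) / mean_exp)


# ---------------------------------------------------------------------------
# window table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowSpec:
    """Genomic window layout: 100 kb default for empirical-style data,
    40 kb for full-scale simulated chromosomes (scale down with the
    chromosome for desk-size runs)."""

    size: int = 100_000
    step: int | None = None
    min_coverage_fraction: float = 0.1

    def __post_init__(self) -> None:
        step = self.size if self.step is None else self.step
        if not 0 < step <= self.size:
            raise ValueError("0 < step <= size required")
        if not 0.0 <= self.min_coverage_fraction <= 1.0:
            raise ValueError("min_coverage_fraction must be in [0, 1]")

    @property
    def effective_step(self) -> int:
        return self.size if self.step is None else self.step

    def windows(self, length: int) -> np.ndarray:
        starts = np.arange(0, length, self.effective_step, dtype=np.int64)
        stops = np.minimum(starts + self.size, length)
        return np.column_stack([starts, stops])


WINDOW_STAT_COLUMNS = [
    "start",
    "end",
    "S",
    "pi",
    "theta_w",
    "tajima_d",
    "dist_var",
    "dist_skew",
    "dist_kurt",
    "n_haps",
    "h1",
    "h12",
    "h2_h1",
    "zns",
    "omega_max",
    "beta",
    "fis",
    "coverage_fraction",
]

_NORMALIZABLE = [
    c for c in WINDOW_STAT_COLUMNS if c not in ("start", "end", "coverage_fraction")
]


def compute_window_table(
    gm: GenotypeMatrix,
    spec: WindowSpec = WindowSpec(),
    normalize: bool = False,
    beta_flank_bp: int = 1000,
    fis_maf_min: float = 0.05,
) -> pd.DataFrame:
    """All summary statistics per non-overlapping (or stepped) window.

    The per-window ``beta`` column is the mean beta(1) score over all
    segregating cores in the window.  When ``normalize`` is on each
    statistic is z-scored across the windows of the chromosome (skipped,
    with a warning, when only one window exists); the default is off.
    """
    length = gm.sequence_length
    if length is None:
        length = int(gm.positions[-1]) + 1 if gm.n_sites else 1
    seg = _segregating(gm)
    rows = []
    for start, stop in spec.windows(length):
        sub = seg.window(int(start), int(stop))
        S = sub.n_sites
        pi = pi_window(sub)
        theta_w, taj_d = watterson_tajima(sub)
        if sub.n_individuals >= 2 and sub.n_haplotypes >= 3:
            dv, ds, dk = pairwise_dist_moments(sub)
        else:
            dv, ds, dk = float("nan"), float("nan"), float("nan")
        n_haps, h1, h12, h2_h1 = haplotype_homozygosity(sub)
        z = zns(sub)
        om = omega_max(sub)
        if S:
            betas = [
                beta_score(sub, i, flank_bp=beta_flank_bp) for i in range(S)
            ]
            beta = float(np.mean(betas))
        else:
            beta = float("nan")
        fis = fis_window(sub, maf_min=fis_maf_min)
        rows.append(
            dict(
                start=int(start),
                end=int(stop),
                S=S,
                pi=pi,
                theta_w=theta_w,
                tajima_d=taj_d,
                dist_var=dv,
                dist_skew=ds,
                dist_kurt=dk,
                n_haps=n_haps,
                h1=h1,
                h12=h12,
                h2_h1=h2_h1,
                zns=z,
                omega_max=om,
                beta=beta,
                fis=fis,
                coverage_fraction=1.0,
            )
        )
    table = pd.DataFrame(rows, columns=WINDOW_STAT_COLUMNS)
    if normalize:
        if len(table) < 2:
            warnings.warn(
                "cannot normalize a single window; returning raw values",
                stacklevel=2,
            )
        else:
            for col in _NORMALIZABLE:
                v = table[col].to_numpy(dtype=float)
                sd = np.nanstd(v)
                if sd > 0:
                    table[col] = (v - np.nanmean(v)) / sd
    return table
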