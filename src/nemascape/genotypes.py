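"""Biallelic genotype matrices sampled from simulations or read from VCF.

The central in-memory container is :class:`GenotypeMatrix`: biallelic SNVs
(rows) by diploid individuals (columns), with physical positions in base
pairs and, when the data are phased (simulated samples always are), the
underlying haplotypes.  Dosages count derived/alternate alleles per
individual and take values in {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix", "make_fixture_genotypes"]


@dataclass
class GenotypeMatrix:
    """Sites x diploid-individuals matrix of biallelic variants.

    Parameters
    ----------
    positions
        0-based physical positions (bp), strictly increasing, one per site.
    dosages
        ``(n_sites, n_individuals)`` array with entries in {0, 1, 2}.
    haplotypes
        Optional ``(n_sites, 2 * n_individuals)`` phased 0/1 array; columns
        ``2i`` and ``2i + 1`` are the two haplotypes of individual ``i``.
    sequence_length
        Length of the chromosome the sites live on (bp).
    ancestral_known
        Per-site flag: True where the 0 allele is a known ancestral state,
        so the 1 allele is derived (unfolded).  Defaults to all True for
        simulated data and all False for unpolarised input.
    """

    positions: np.ndarray
    dosages: np.ndarray
    haplotypes: np.ndarray | None = None
    sequence_length: int | None = None
    ancestral_known: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D sites x individuals array")
        if self.positions.shape[0] != self.dosages.shape[0]:
            raise ValueError("positions and dosages disagree on site count")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (
                self.dosages.shape[0],
                2 * self.dosages.shape[1],
            ):
                raise ValueError("haplotypes shape does not match dosages")
            if not np.array_equal(
                self.haplotypes[:, ::2] + self.haplotypes[:, 1::2], self.dosages
            ):
                raise ValueError("dosages are not the sum of the two haplotypes")
        if self.ancestral_known is None:
            flag = self.haplotypes is not None
            self.ancestral_known = np.full(self.positions.shape[0], flag)
        else:
            self.ancestral_known = np.asarray(self.ancestral_known, dtype=bool)

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_individuals(self) -> int:
        return int(self.dosages.shape[1])

    @property
    def n_haplotypes(self) -> int:
        return 2 * self.n_individuals

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    def site_slice(self, start: int, stop: int) -> slice:
        """Index slice of sites with position in ``[start, stop)``."""
        lo, hi = np.searchsorted(self.positions, [start, stop])
        return slice(int(lo), int(hi))

    def window(self, start: int, stop: int) -> "GenotypeMatrix":
        """Sub-matrix restricted to positions in ``[start, stop)``."""
        sl = self.site_slice(start, stop)
        return GenotypeMatrix(
            positions=self.positions[sl],
            dosages=self.dosages[sl],
            haplotypes=None if self.haplotypes is None else self.haplotypes[sl],
            sequence_length=self.sequence_length,
            ancestral_known=self.ancestral_known[sl],
        )

    def allele_frequencies(self) -> np.ndarray:
        """Derived/alternate allele frequency per site (over haplotypes)."""
        if self.n_individuals == 0:
            return np.zeros(self.n_sites)
        return self.dosages.astype(float).sum(axis=1) / self.n_haplotypes

    @classmethod
    def from_haplotypes(
        cls,
        positions: np.ndarray,
        haplotypes: np.ndarray,
        sequence_length: int | None = None,
    ) -> "GenotypeMatrix":
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        dosages = haplotypes[:, ::2] + haplotypes[:, 1::2]
        return cls(
            positions=positions,
            dosages=dosages,
            haplotypes=haplotypes,
            sequence_length=sequence_length,
        )


def make_fixture_genotypes(
    n_ind: int,
    n_sites: int,
    freq_spectrum,
    fis: float = 0.0,
    seed: int | None = None,
    sequence_length: int | None = None,
) -> GenotypeMatrix:
    """Draw independent biallelic sites with a target inbreeding coefficient.

    Genotypes at a site with allele frequency ``p`` are drawn from the
    inbreeding-adjusted Hardy-Weinberg probabilities

    ``P(hom ref) = q^2 + F p q``, ``P(het) = 2 p q (1 - F)``,
    ``P(hom alt) = p^2 + F p q``,

    independently across sites.  ``F = 0`` is Hardy-Weinberg equilibrium,
    ``F = 1`` removes all heterozygotes, ``F = -1`` (at ``p = 0.5``) makes
    every individual heterozygous.

    Parameters
    ----------
    freq_spectrum
        Either a scalar frequency used for all sites, or an array of
        per-site frequencies in (0, 1) of length ``n_sites``.
    fis
        Target inbreeding coefficient in [-1, 1].

    Raises
    ------
    ValueError
        If any genotype probability would be negative (invalid ``F``/``p``
        combination, e.g. ``F < -q/p``).
    """
    rng = np.random.default_rng(seed)
    p = np.broadcast_to(np.asarray(freq_spectrum, dtype=float), (n_sites,)).copy()
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    if not -1.0 <= fis <= 1.0:
        raise ValueError("fis must lie in [-1, 1]")
    q = 1.0 - p
    pq = p * q
    probs = np.stack(
        [q * q + fis * pq, 2.0 * pq * (1.0 - fis), p * p + fis * pq], axis=1
    )
    if np.any(probs < -1e-12):
        raise ValueError("negative genotype probability: fis incompatible with p")
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    # inverse-CDF draw per site x individual
    cum = np.cumsum(probs, axis=1)
    u = rng.random((n_sites, n_ind))
    dosages = (u[:, :, None] > cum[:, None, :]).sum(axis=2).astype(np.int8)
    # phase: heterozygotes get a random haplotype order
    haps = np.zeros((n_sites, 2 * n_ind), dtype=np.int8)
    haps[:, ::2] = (dosages == 2).astype(np.int8)
    haps[:, 1::2] = (dosages == 2).astype(np.int8)
    het = dosages == 1
    first = rng.random((n_sites, n_ind)) < 0.5
    haps[:, ::2][het & first] = 1
    haps[:, 1::2][het & ~first] = 1
    if sequence_length is None:
        sequence_length = max(1000, 10 * n_sites)
    positions = np.sort(
        rng.choice(sequence_length, size=n_sites, replace=False)
    ).astype(np.int64)
    return GenotypeMatrix(
        positions=positions,
        dosages=haps[:, ::2] + haps[:, 1::2],
        haplotypes=haps,
        sequence_length=sequence_length,
    )
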