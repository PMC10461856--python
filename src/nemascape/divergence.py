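"""Divergence from an ancestral sequence and mating-system estimators.

Covers the Tamura (1992) distance (a Kimura 2-parameter generalisation
accounting for GC content), windowed substitution spectra collapsed to the
six strand-symmetric classes, the equilibrium map between the inbreeding
coefficient F_is and the selfing/outcrossing rate, and Watterson-based
effective population size with the ``Ne = N/2`` full-selfing adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AlignedPair",
    "SubstitutionSpectrum",
    "SaturationError",
    "tamura_distance",
    "substitution_spectrum",
    "spectrum_table",
    "aligned_pair_from_fasta",
    "diversity_divergence_ratio",
    "outcrossing_from_fis",
    "fis_from_selfing",
    "ne_from_watterson",
]

_BASE_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
_CODE = np.full(256, -1, dtype=np.int8)
for b, c in _BASE_CODE.items():
    _CODE[b] = c
    _CODE[b + 32] = c  # lower case

# Directed change (anc_code, der_code) -> strand-symmetric class index.
# Classes: 0 C>T|G>A, 1 T>C|A>G, 2 A>T|T>A, 3 C>G|G>C, 4 A>C|T>G, 5 C>A|G>T
CLASS_NAMES = ("C>T|G>A", "T>C|A>G", "A>T|T>A", "C>G|G>C", "A>C|T>G", "C>A|G>T")
_TRANSITION_CLASSES = (0, 1)
_PAIR_CLASS = {
    (1, 3): 0, (2, 0): 0,  # C->T, G->A
    (3, 1): 1, (0, 2): 1,  # T->C, A->G
    (0, 3): 2, (3, 0): 2,  # A->T, T->A
    (1, 2): 3, (2, 1): 3,  # C->G, G->C
    (0, 1): 4, (3, 2): 4,  # A->C, T->G
    (1, 0): 5, (2, 3): 5,  # C->A, G->T
}
_CLASS_LUT = np.full((4, 4), -1, dtype=np.int8)
for (a, d), k in _PAIR_CLASS.items():
    _CLASS_LUT[a, d] = k


class SaturationError(ValueError):
    """Tamura/K2P log argument non-positive: distances saturated."""


@dataclass
class AlignedPair:
    """Ancestral and derived sequences of equal length with a usable mask.

    Only unmasked sites where both bases are in {A, C, G, T} enter any
    count; everything else (N, gaps, masked intervals) is ignored.
    """

    ancestral: np.ndarray
    derived: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ancestral = _encode(self.ancestral)
        self.derived = _encode(self.derived)
        if self.ancestral.shape != self.derived.shape:
            raise ValueError("ancestral and derived sequences differ in length")
        if self.mask is None:
            self.mask = np.ones(self.ancestral.shape[0], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.ancestral.shape:
                raise ValueError("mask length does not match sequences")

    def __len__(self) -> int:
        return int(self.ancestral.shape[0])

    @property
    def usable(self) -> np.ndarray:
        return self.mask & (self.ancestral >= 0) & (self.derived >= 0)


def _encode(seq) -> np.ndarray:
    if isinstance(seq, str):
        seq = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        return _CODE[seq]
    arr = np.asarray(seq)
    if arr.dtype.kind in "US":
        joined = "".join(arr.tolist()) if arr.ndim else str(arr)
        return _encode(joined)
    if arr.dtype == np.uint8:
        return _CODE[arr]
    return arr.astype(np.int8)


def tamura_distance(P: float, Q: float, gc: float) -> float:
    """Tamura (1992) distance from transition/transversion proportions.

    ``d = -h ln(1 - P/h - Q) - (1 - h)/2 * ln(1 - 2Q)`` with
    ``h = 2 * gc * (1 - gc)``.  At ``gc = 0.5`` this reduces to the Kimura
    2-parameter distance.  Raises :class:`SaturationError` when a log
    argument is non-positive (saturated divergence).
    """
    if not (0 <= P < 1 and 0 <= Q < 1):
        raise ValueError("P and Q must lie in [0, 1)")
    if not 0 < gc < 1:
        raise ValueError("GC content must lie in (0, 1)")
    h = 2.0 * gc * (1.0 - gc)
    arg1 = 1.0 - P / h - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        raise SaturationError("substitution proportions beyond the model's range")
    return float(-h * np.log(arg1) - 0.5 * (1.0 - h) * np.log(arg2))


@dataclass
class SubstitutionSpectrum:
    """Counts of the six strand-symmetric substitution classes per window."""

    window: tuple[int, int]
    counts: np.ndarray  # length 6, order CLASS_NAMES
    n_usable: int

    @property
    def n_substitutions(self) -> int:
        return int(self.counts.sum())

    @property
    def ts_tv(self) -> float:
        ts = self.counts[list(_TRANSITION_CLASSES)].sum()
        tv = self.counts.sum() - ts
        return float(ts / tv) if tv > 0 else float("nan")

    @property
    def P(self) -> float:
        """Transition proportion over usable sites."""
        ts = self.counts[list(_TRANSITION_CLASSES)].sum()
        return float(ts / self.n_usable) if self.n_usable else float("nan")

    @property
    def Q(self) -> float:
        """Transversion proportion over usable sites."""
        tv = self.counts.sum() - self.counts[list(_TRANSITION_CLASSES)].sum()
        return float(tv / self.n_usable) if self.n_usable else float("nan")


def substitution_spectrum(
    pair: AlignedPair, windows=None
) -> list[SubstitutionSpectrum]:
    """Per-window substitution class counts between ancestral and derived.

    ``windows`` is an iterable of ``(start, stop)`` half-open intervals;
    ``None`` means one window spanning the pair.  Windows with zero usable
    sites yield ``n_usable = 0`` (their ratios are NaN).
    """
    if windows is None:
        windows = [(0, len(pair))]
    ok = pair.usable
    out = []
    for start, stop in windows:
        sl = slice(int(start), int(stop))
        m = ok[sl]
        anc = pair.ancestral[sl][m]
        der = pair.derived[sl][m]
        changed = anc != der
        counts = np.zeros(6, dtype=np.int64)
        if changed.any():
            cls = _CLASS_LUT[anc[changed], der[changed]]
            counts = np.bincount(cls, minlength=6).astype(np.int64)
        out.append(
            SubstitutionSpectrum(
                window=(int(start), int(stop)),
                counts=counts,
                n_usable=int(m.sum()),
            )
        )
    return out


def spectrum_table(
    pair: AlignedPair,
    windows=None,
    min_usable: int = 0,
    gc_from: str = "ancestral",
) -> pd.DataFrame:
    """Tidy per-window divergence table: class counts, Ts/Tv, GC, Tamura d.

    ``gc_from`` selects whether window GC content (the Tamura parameter) is
    computed from the ancestral sequence (default) or the mean of both.
    Windows with fewer than ``min_usable`` usable sites get NaN distances
    (the conventional floor is ~30% of the window length).
    """
    specs = substitution_spectrum(pair, windows)
    rows = []
    for sp in specs:
        start, stop = sp.window
        sl = slice(start, stop)
        m = pair.usable[sl]
        anc = pair.ancestral[sl][m]
        der = pair.derived[sl][m]
        if anc.size:
            gc_a = float(np.isin(anc, (1, 2)).mean())
            gc_d = float(np.isin(der, (1, 2)).mean())
            gc = gc_a if gc_from == "ancestral" else 0.5 * (gc_a + gc_d)
        else:
            gc = float("nan")
        d = float("nan")
        if sp.n_usable >= max(min_usable, 1) and 0 < gc < 1:
            try:
                d = tamura_distance(sp.P, sp.Q, gc)
            except SaturationError:
                d = float("nan")
        row = dict(start=start, end=stop, n_usable=sp.n_usable)
        row.update({name: int(c) for name, c in zip(CLASS_NAMES, sp.counts)})
        row.update(ts_tv=sp.ts_tv, gc=gc, tamura_d=d)
        rows.append(row)
    return pd.DataFrame(rows)


def aligned_pair_from_fasta(
    ancestral_fasta, derived_fasta, record: str | int = 0, mask=None
) -> AlignedPair:
    """Load ancestral and derived sequences from FASTA files (Biopython).

    ``record`` selects a sequence by index or id; ``mask`` is an optional
    :class:`~nemascape.io.CoverageMask` of usable intervals converted to a
    per-site flag array.
    """
    from Bio import SeqIO

    def pick(path):
        recs = list(SeqIO.parse(str(path), "fasta"))
        if isinstance(record, int):
            return str(recs[record].seq)
        for r in recs:
            if r.id == record:
                return str(r.seq)
        raise KeyError(f"record {record!r} not found in {path}")

    anc = pick(ancestral_fasta)
    der = pick(derived_fasta)
    flags = None
    if mask is not None:
        flags = np.zeros(len(anc), dtype=bool)
        for s, e in mask.intervals:
            flags[s:e] = True
    return AlignedPair(anc, der, mask=flags)


def diversity_divergence_ratio(
    stats_table: pd.DataFrame, divergence_table: pd.DataFrame
) -> pd.DataFrame:
    """Join per-window diversity and divergence tables on (start, end) and
    emit ``pi_over_divergence``; windows with zero or missing divergence
    yield NaN."""
    merged = stats_table.merge(
        divergence_table[["start", "end", "tamura_d"]], on=["start", "end"]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = merged["pi"] / merged["tamura_d"]
    merged["pi_over_divergence"] = ratio.where(merged["tamura_d"] > 0)
    return merged


def outcrossing_from_fis(fis: float) -> float:
    """Equilibrium outcrossing rate ``1 - s`` with ``s = 2 Fis / (1 + Fis)``.

    ``Fis = 0.86`` gives 0.0753 (7.5% outcrossing).  Negative Fis has no
    selfing interpretation and raises a ValueError.
    """
    if not 0.0 <= fis <= 1.0:
        raise ValueError("fis must lie in [0, 1] for a selfing interpretation")
    return float(1.0 - 2.0 * fis / (1.0 + fis))


def fis_from_selfing(s: float) -> float:
    """Equilibrium inbreeding coefficient ``F = s / (2 - s)`` (inverse map)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("selfing rate must lie in [0, 1]")
    return float(s / (2.0 - s))


def ne_from_watterson(
    theta_per_site: float, mu: float, selfing_adjust: bool = False
) -> float:
    """Effective population size from Watterson's theta: ``N = theta/(4 mu)``.

    With ``selfing_adjust`` the returned value is halved (``Ne = N/2``), the
    equilibrium expectation for a completely self-fertilising population.
    """
    if theta_per_site <= 0 or mu <= 0:
        raise ValueError("theta and mu must be positive")
    n = theta_per_site / (4.0 * mu)
    return float(n / 2.0) if selfing_adjust else float(n)
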