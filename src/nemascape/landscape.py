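"""Arm-center-arm chromosome models and Marey-map domain fitting.

Holocentric *Caenorhabditis* chromosomes carry two peripheral "arm" domains
of high recombination flanking a central domain where crossovers are rare.
This module holds the piecewise-constant recombination/mutation landscape
used by the simulator (:class:`ChromosomeModel`), and fits the boundaries
of the central domain to Marey-map data (cumulative genetic position in cM
against physical position in bp) by continuous 3-segment piecewise-linear
least squares with bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "ChromosomeModel",
    "MareyMap",
    "DomainBoundaries",
    "build_chromosome_model",
    "central_domain_fraction",
    "fit_domain_boundaries",
    "load_reference_domains",
]


class ConfigurationError(ValueError):
    """Invalid chromosome-model configuration."""


class DomainError(ValueError):
    """Domain boundaries incompatible with the chromosome."""


class FittingError(ValueError):
    """Marey-map fit cannot be performed (too few markers)."""


@dataclass(frozen=True)
class ChromosomeModel:
    """Piecewise-constant recombination and mutation landscape.

    ``domain_edges = (b1, b2)`` split ``[0, length_bp)`` into left arm
    ``[0, b1)``, center ``[b1, b2)`` and right arm ``[b2, length_bp)``.
    ``rec_rates`` are per-base per-generation crossover probabilities for
    the three domains; ``mut_multipliers`` scale ``base_mut_rate`` per
    domain (landscape codes 1-1-1, 1.15-1-1.15, 1.5-1-1.5, 2-1-2).
    """

    length_bp: int
    domain_edges: tuple[int, int]
    rec_rates: tuple[float, float, float]
    mut_multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0)
    base_mut_rate: float = 0.0

    def __post_init__(self) -> None:
        b1, b2 = self.domain_edges
        if self.length_bp <= 0:
            raise ConfigurationError("chromosome length must be positive")
        if not 0 < b1 < b2 < self.length_bp:
            raise ConfigurationError(
                "domain edges must satisfy 0 < b1 < b2 < length_bp"
            )
        if any(r < 0 for r in self.rec_rates):
            raise ConfigurationError("recombination rates must be >= 0")
        if any(m <= 0 for m in self.mut_multipliers):
            raise ConfigurationError("mutation multipliers must be > 0")
        if self.base_mut_rate < 0:
            raise ConfigurationError("mutation rate must be >= 0")

    # -- geometry (cached: these sit on the simulator's per-generation path)
    @cached_property
    def domain_bounds(self) -> np.ndarray:
        """Domain breakpoints including both chromosome ends."""
        return np.array(
            [0, self.domain_edges[0], self.domain_edges[1], self.length_bp],
            dtype=np.int64,
        )

    @cached_property
    def bounds_float(self) -> np.ndarray:
        return self.domain_bounds.astype(float)

    @cached_property
    def domain_lengths(self) -> np.ndarray:
        return np.diff(self.domain_bounds)

    @cached_property
    def mut_rates(self) -> np.ndarray:
        """Per-base mutation rate in each domain."""
        return self.base_mut_rate * np.asarray(self.mut_multipliers, dtype=float)

    @cached_property
    def rec_cum(self) -> np.ndarray:
        """Cumulative genetic map (Morgans) at the domain bounds."""
        return np.concatenate(
            [[0.0], np.cumsum(np.asarray(self.rec_rates) * self.domain_lengths)]
        )

    @cached_property
    def mut_cum(self) -> np.ndarray:
        """Cumulative mutational input per gamete at the domain bounds."""
        return np.concatenate([[0.0], np.cumsum(self.mut_rates * self.domain_lengths)])

    def expected_crossovers(self) -> float:
        """Integral of the crossover intensity: mean crossovers per gamete."""
        return float(self.rec_cum[-1])

    def map_length_cM(self) -> float:
        """Genetic map length in centimorgans (100 x expected crossovers)."""
        return 100.0 * self.expected_crossovers()

    def expected_mutations(self) -> float:
        """Mean new mutations per gamete per generation."""
        return float(self.mut_cum[-1])

    def domain_of(self, positions) -> np.ndarray:
        """Domain index (0 left arm, 1 center, 2 right arm) per position."""
        pos = np.asarray(positions)
        return np.clip(
            np.searchsorted(self.domain_bounds[1:3], pos, side="right"), 0, 2
        )

    def scaled(self, length_factor: float, rate_factor: float) -> "ChromosomeModel":
        """Desk-scale variant: shrink lengths and inflate per-base rates.

        With ``rate_factor = 1 / length_factor`` the map length and total
        mutational input per gamete are preserved.
        """
        return ChromosomeModel(
            length_bp=int(round(self.length_bp * length_factor)),
            domain_edges=(
                int(round(self.domain_edges[0] * length_factor)),
                int(round(self.domain_edges[1] * length_factor)),
            ),
            rec_rates=tuple(r * rate_factor for r in self.rec_rates),
            mut_multipliers=self.mut_multipliers,
            base_mut_rate=self.base_mut_rate * rate_factor,
        )


def build_chromosome_model(
    arm_len: float,
    center_len: float,
    arm_rec: float,
    center_rec: float,
    base_mut: float,
    mut_multipliers=(1.0, 1.0, 1.0),
) -> ChromosomeModel:
    """Symmetric arm-center-arm model: ``[0, arm) [arm, arm+center) [..., L)``.

    The default full-scale nematode setup is 1 Mb arms at 2.5e-7 crossovers
    per bp per generation around a 1 Mb center at 1e-9, with a uniform
    2e-8 per-bp mutation rate.
    """
    if arm_len <= 0 or center_len <= 0:
        raise ConfigurationError("domain lengths must be positive")
    arm_len = int(round(arm_len))
    center_len = int(round(center_len))
    return ChromosomeModel(
        length_bp=2 * arm_len + center_len,
        domain_edges=(arm_len, arm_len + center_len),
        rec_rates=(arm_rec, center_rec, arm_rec),
        mut_multipliers=tuple(float(m) for m in mut_multipliers),
        base_mut_rate=base_mut,
    )


@dataclass
class MareyMap:
    """Markers of one chromosome: physical position (bp) vs genetic (cM).

    Records are sorted by physical position on construction.  ``kind``
    records whether the map is sex-averaged or single-sex (X maps from
    female-only crosses); the fit treats both identically.
    """

    physical_pos: np.ndarray
    genetic_pos: np.ndarray
    chrom: str = ""
    kind: str = "sex-averaged"

    def __post_init__(self) -> None:
        phys = np.asarray(self.physical_pos, dtype=float)
        gen = np.asarray(self.genetic_pos, dtype=float)
        if phys.shape != gen.shape or phys.ndim != 1:
            raise ValueError("physical and genetic positions must be 1-D, equal length")
        order = np.argsort(phys, kind="stable")
        self.physical_pos = phys[order]
        self.genetic_pos = gen[order]

    def __len__(self) -> int:
        return int(self.physical_pos.shape[0])

    @property
    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.genetic_pos) >= -1e-9))


@dataclass
class DomainBoundaries:
    """Fitted central-domain boundaries with bootstrap 95% CIs.

    Slopes are reported in cM/Mb for the left arm, center, and right arm;
    no ordering of slopes is enforced (reported as found).
    """

    left_arm_end: float
    right_arm_start: float
    boundary_CIs: tuple[tuple[float, float], tuple[float, float]]
    domain_slopes: tuple[float, float, float]
    intercept_cM: float = 0.0
    degenerate: bool = False
    rss: float = float("nan")
    chrom: str = ""

    def predicted_cM(self, positions) -> np.ndarray:
        """Fitted genetic position at the given physical positions."""
        x = np.asarray(positions, dtype=float)
        s = np.asarray(self.domain_slopes, dtype=float) / 1e6  # cM per bp
        b1, b2 = self.left_arm_end, self.right_arm_start
        y = self.intercept_cM + s[0] * np.minimum(x, b1)
        y += s[1] * np.clip(x - b1, 0.0, b2 - b1)
        y += s[2] * np.clip(x - b2, 0.0, None)
        return y


def central_domain_fraction(bounds, chrom_size: float) -> float:
    """Percent of the chromosome occupied by the central domain.

    ``100 * (right_arm_start - left_arm_end) / chrom_size``; accepts a
    :class:`DomainBoundaries` or a ``(left_arm_end, right_arm_start)`` pair
    in bp.
    """
    if isinstance(bounds, DomainBoundaries):
        left, right = bounds.left_arm_end, bounds.right_arm_start
    else:
        left, right = bounds
    if not 0 <= left <= right <= chrom_size:
        raise DomainError("boundaries must satisfy 0 <= left <= right <= size")
    return 100.0 * (right - left) / chrom_size


def _piecewise_rss(x: np.ndarray, y: np.ndarray, b1: float, b2: float):
    """Continuous 3-segment least squares at fixed breakpoints.

    Basis [1, x, (x-b1)+, (x-b2)+]; continuity of the fit is built into the
    basis (a Marey map is cumulative).  Returns (rss, coefficients).
    """
    X = np.column_stack(
        [
            np.ones_like(x),
            x,
            np.clip(x - b1, 0.0, None),
            np.clip(x - b2, 0.0, None),
        ]
    )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def _fit_breaks(
    x: np.ndarray,
    y: np.ndarray,
    min_per_segment: int = 2,
    n_grid: int = 40,
    starts: np.ndarray | None = None,
):
    """Grid search over marker midpoints refined by Nelder-Mead."""
    mids = 0.5 * (x[1:] + x[:-1])
    if mids.size > n_grid:
        idx = np.unique(np.linspace(0, mids.size - 1, n_grid).round().astype(int))
        cand = mids[idx]
    else:
        cand = mids

    def valid(b1, b2):
        if not (x[0] < b1 < b2 < x[-1]):
            return False
        n_left = np.searchsorted(x, b1)
        n_right = x.size - np.searchsorted(x, b2)
        n_center = x.size - n_left - n_right
        return min(n_left, n_center, n_right) >= min_per_segment

    best = (np.inf, None, None)
    if starts is None:
        for i, b1 in enumerate(cand):
            for b2 in cand[i + 1 :]:
                if not valid(b1, b2):
                    continue
                rss, _ = _piecewise_rss(x, y, b1, b2)
                if rss < best[0]:
                    best = (rss, b1, b2)
    else:
        b1, b2 = starts
        if valid(b1, b2):
            best = (_piecewise_rss(x, y, b1, b2)[0], b1, b2)
        else:
            # fall back to a coarse scan when the warm start is infeasible
            return _fit_breaks(x, y, min_per_segment, n_grid=15)
    if best[1] is None:
        raise FittingError("no valid breakpoint pair with enough markers per segment")

    span = x[-1] - x[0]

    def objective(b):
        b1, b2 = b
        if not valid(b1, b2):
            return np.inf
        return _piecewise_rss(x, y, b1, b2)[0]

    res = minimize(
        objective,
        x0=np.array([best[1], best[2]], dtype=float),
        method="Nelder-Mead",
        options={
            "xatol": max(1e-9 * span, 1e-6),
            "fatol": 1e-12 * max(1.0, best[0]),
            "maxiter": 400,
        },
    )
    if np.isfinite(res.fun) and res.fun <= best[0]:
        b1, b2 = float(res.x[0]), float(res.x[1])
        rss, coef = _piecewise_rss(x, y, b1, b2)
    else:
        b1, b2 = float(best[1]), float(best[2])
        rss, coef = _piecewise_rss(x, y, b1, b2)
    return b1, b2, rss, coef


def fit_domain_boundaries(
    marey: MareyMap,
    n_boot: int = 1000,
    seed: int | None = None,
    min_per_segment: int = 2,
    degenerate_tol: float = 0.01,
    n_grid: int = 40,
) -> DomainBoundaries:
    """Fit the two central-domain boundaries of a Marey map.

    A continuous 3-segment piecewise-linear model is fit by least squares;
    the two breakpoints are located by an exhaustive grid over marker
    midpoints followed by local Nelder-Mead refinement.  95% percentile
    confidence intervals come from ``n_boot`` nonparametric bootstrap
    resamples of the marker set (refit from the point-estimate warm start).

    The fit is flagged ``degenerate`` when the best 2-breakpoint model does
    not improve the residual sum of squares of a single straight line by at
    least ``degenerate_tol`` (relative), i.e. no breakpoint is supported.
    """
    if len(marey) < 6 or len(marey) < 3 * min_per_segment:
        raise FittingError("need at least 6 markers (>= 2 per segment) to fit")
    x = marey.physical_pos
    y = marey.genetic_pos
    b1, b2, rss3, coef = _fit_breaks(x, y, min_per_segment, n_grid=n_grid)

    # 1-segment reference for the degeneracy check
    X1 = np.column_stack([np.ones_like(x), x])
    c1, _, _, _ = np.linalg.lstsq(X1, y, rcond=None)
    r1 = y - X1 @ c1
    rss1 = float(r1 @ r1)
    scale = float(np.var(y) * y.size) or 1.0
    degenerate = rss1 / scale < 1e-12 or (rss1 - rss3) < degenerate_tol * rss1
    if degenerate:
        warnings.warn(
            "piecewise fit not better than a single line; boundaries unreliable",
            stacklevel=2,
        )

    slopes_bp = np.array([coef[1], coef[1] + coef[2], coef[1] + coef[2] + coef[3]])

    rng = np.random.default_rng(seed)
    boots = np.empty((0, 2))
    if n_boot > 0:
        bs = []
        for _ in range(n_boot):
            idx = np.sort(rng.integers(0, x.size, size=x.size))
            xb, yb = x[idx], y[idx]
            # drop duplicate x to keep the design well-posed
            keep = np.concatenate([[True], np.diff(xb) > 0])
            xb, yb = xb[keep], yb[keep]
            if xb.size < 3 * min_per_segment:
                continue
            try:
                bb1, bb2, _, _ = _fit_breaks(
                    xb, yb, min_per_segment, starts=np.array([b1, b2])
                )
            except FittingError:
                continue
            bs.append((bb1, bb2))
        if bs:
            boots = np.asarray(bs)
    if boots.size:
        lo1, hi1 = np.percentile(boots[:, 0], [2.5, 97.5])
        lo2, hi2 = np.percentile(boots[:, 1], [2.5, 97.5])
        cis = ((float(lo1), float(hi1)), (float(lo2), float(hi2)))
    else:
        cis = ((b1, b1), (b2, b2))

    return DomainBoundaries(
        left_arm_end=b1,
        right_arm_start=b2,
        boundary_CIs=cis,
        domain_slopes=tuple(slopes_bp * 1e6),
        intercept_cM=float(coef[0]),
        degenerate=bool(degenerate),
        rss=rss3,
        chrom=marey.chrom,
    )


def load_reference_domains() -> pd.DataFrame:
    """Packaged central-domain boundary table for the six *C. remanei*
    chromosomes (F2 genetic map of the PX506 x PX553 cross).

    Columns: chrom, left_arm_end_kb, right_arm_start_kb, per-domain rates
    in cM/Mb, and chromosome size in bp.  Boundaries are 1-based kb, as
    conventionally reported; multiply by 1000 for bp.
    """
    with resources.files("nemascape.data").joinpath("cremanei_domains.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
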