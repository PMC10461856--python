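"""Forward-time diploid Wright-Fisher simulator with partial selfing.

The model: ``N`` diploid individuals, discrete non-overlapping generations.
Each offspring is produced independently; with probability equal to the
selfing rate a single parent is drawn proportional to fitness and
contributes two independent gametes, otherwise two distinct parents are
drawn (fitness-proportional, with replacement across offspring).  Gametes
recombine as an inhomogeneous Poisson process over the arm-center-arm
recombination landscape (no interference, no obligate crossover) and pick
up new mutations at the landscape's domain-scaled rates.  Mutations carry
a selection class (neutral / deleterious / beneficial / balancing), a
selection coefficient and a dominance coefficient; fitness is
multiplicative across sites.  Mutations fixed in the population are pruned
each generation and logged as substitutions.

Positions are discrete base pairs; a new mutation landing on a position
currently segregating (or drawn twice in one generation) is redrawn, an
infinite-sites approximation on integer coordinates, so all segregating
sites are biallelic.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from .genotypes import GenotypeMatrix
from .landscape import ChromosomeModel, build_chromosome_model

__all__ = [
    "DominanceMixture",
    "DFEConfig",
    "Mutation",
    "MutationRegistry",
    "Population",
    "SimulationConfig",
    "ScenarioResult",
    "SimulationExtinctError",
    "fitness_of",
    "draw_crossovers",
    "make_gamete",
    "apply_mutations",
    "next_generation",
    "run_simulation",
    "sample_genotypes",
    "full_scale_model",
    "desk_scale_model",
    "desk_scale_config",
]

KLASS_NAMES = ("neutral", "deleterious", "beneficial", "balancing")


class SimulationExtinctError(RuntimeError):
    """Every individual has fitness zero: the population is inviable."""


# ---------------------------------------------------------------------------
# DFE configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DominanceMixture:
    """Mixture of uniform and beta components for dominance coefficients.

    ``components`` is a sequence of ``(weight, kind, p1, p2)`` with kind
    "uniform" (low, high) or "beta" (alpha, beta); weights are normalised.
    """

    components: tuple = ((1.0, "uniform", 0.0, 1.0),)

    def draw(self, size: int, rng: np.random.Generator) -> np.ndarray:
        weights = np.array([c[0] for c in self.components], dtype=float)
        weights /= weights.sum()
        which = rng.choice(len(self.components), size=size, p=weights)
        out = np.empty(size)
        for i, (_, kind, p1, p2) in enumerate(self.components):
            m = which == i
            n = int(m.sum())
            if not n:
                continue
            if kind == "uniform":
                out[m] = rng.uniform(p1, p2, size=n)
            elif kind == "beta":
                out[m] = rng.beta(p1, p2, size=n)
            else:
                raise ValueError(f"unknown mixture component kind {kind!r}")
        return out


# Deleterious dominance skews recessive; beneficial is near-additive.
_DEL_DOMINANCE = DominanceMixture(
    ((0.5, "uniform", 0.0, 0.3), (0.5, "beta", 2.0, 8.0))
)
_BEN_DOMINANCE = DominanceMixture(
    ((0.5, "uniform", 0.3, 0.7), (0.5, "beta", 5.0, 5.0))
)


@dataclass(frozen=True)
class DFEConfig:
    """Distribution of fitness effects of new mutations.

    ``class_fractions`` orders (neutral, deleterious, beneficial,
    balancing) and must sum to 1.  |s| of deleterious and s of beneficial
    mutations are gamma-distributed with the given (shape, mean);
    balancing mutations have fixed effect ``bal_s`` and act by symmetric
    overdominance by default (heterozygote advantage ``1 + bal_s``), or by
    negative frequency dependence with ``balancing_mode =
    "frequency_dependent"``.
    """

    class_fractions: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    del_gamma: tuple[float, float] = (0.3, 0.01)  # (shape, mean |s|)
    ben_gamma: tuple[float, float] = (0.5, 0.005)
    bal_s: float = 0.01
    del_dominance: DominanceMixture = _DEL_DOMINANCE
    ben_dominance: DominanceMixture = _BEN_DOMINANCE
    balancing_mode: str = "overdominance"

    def __post_init__(self) -> None:
        f = np.asarray(self.class_fractions, dtype=float)
        if f.size != 4 or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("class fractions must be 4 non-negative values summing to 1")
        for shape, mean in (self.del_gamma, self.ben_gamma):
            if shape <= 0 or mean <= 0:
                raise ValueError("gamma parameters must be positive")
        if self.balancing_mode not in ("overdominance", "frequency_dependent"):
            raise ValueError("unknown balancing mode")

    # regime presets matching the four selection regimes of the study design
    @classmethod
    def neutral(cls) -> "DFEConfig":
        return cls()

    @classmethod
    def with_deleterious(cls) -> "DFEConfig":
        """Neutral plus 10% deleterious mutations."""
        return cls(class_fractions=(0.9, 0.1, 0.0, 0.0))

    @classmethod
    def with_beneficial(cls) -> "DFEConfig":
        """Neutral, 10% deleterious, 1% beneficial."""
        return cls(class_fractions=(0.89, 0.1, 0.01, 0.0))

    @classmethod
    def with_balancing(cls) -> "DFEConfig":
        """Neutral, 10% deleterious, 1% balancing."""
        return cls(class_fractions=(0.89, 0.1, 0.0, 0.01))

    def draw_effects(self, klasses: np.ndarray, rng: np.random.Generator):
        """Selection and dominance coefficients for the given class codes."""
        n = klasses.size
        s = np.zeros(n)
        h = np.full(n, 0.5)
        m = klasses == K.KLASS_DELETERIOUS
        if m.any():
            shape, mean = self.del_gamma
            s[m] = -rng.gamma(shape, mean / shape, size=int(m.sum()))
            h[m] = self.del_dominance.draw(int(m.sum()), rng)
        m = klasses == K.KLASS_BENEFICIAL
        if m.any():
            shape, mean = self.ben_gamma
            s[m] = rng.gamma(shape, mean / shape, size=int(m.sum()))
            h[m] = self.ben_dominance.draw(int(m.sum()), rng)
        m = klasses == K.KLASS_BALANCING
        if m.any():
            s[m] = self.bal_s
            h[m] = 0.5
        return s, h

    def scaled(self, factor: float) -> "DFEConfig":
        """Rescale selection strength by ``factor``.

        Desk-scale runs shrink N while inflating per-base rates; keeping
        the population-scaled selection strength N*s requires inflating
        selection coefficients by the same factor as mu and r.
        """
        return replace(
            self,
            del_gamma=(self.del_gamma[0], self.del_gamma[1] * factor),
            ben_gamma=(self.ben_gamma[0], self.ben_gamma[1] * factor),
            bal_s=self.bal_s * factor,
        )

    @property
    def bal_mode_code(self) -> int:
        return (
            K.BAL_OVERDOMINANCE
            if self.balancing_mode == "overdominance"
            else K.BAL_FREQUENCY_DEPENDENT
        )


# ---------------------------------------------------------------------------
# mutation registry and population state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Mutation:
    """Immutable view of one mutation's record."""

    id: int
    position: int
    sel_s: float
    h: float
    klass: str
    origin_generation: int


class MutationRegistry:
    """Append-only store of all mutations ever created in a run.

    Numpy columns (position, selection coefficient, dominance, class code,
    origin generation) indexed by mutation id; ``active`` marks mutations
    currently segregating.  Active positions are kept in a set so new draws
    can be rejected (infinite-sites on integers).
    """

    def __init__(self, capacity: int = 1024) -> None:
        self.n = 0
        self.pos = np.zeros(capacity, dtype=np.int64)
        self.sel = np.zeros(capacity)
        self.dom = np.zeros(capacity)
        self.klass = np.zeros(capacity, dtype=np.int8)
        self.origin = np.zeros(capacity, dtype=np.int32)
        self.active = np.zeros(capacity, dtype=bool)
        self.selmask = np.zeros(capacity, dtype=np.uint8)
        self.active_positions: set[int] = set()
        self.substitutions: list[tuple[int, int]] = []  # (mutation id, fixed gen)

    def _grow(self, need: int) -> None:
        cap = self.pos.size
        if self.n + need <= cap:
            return
        new_cap = max(2 * cap, self.n + need)
        for name in ("pos", "sel", "dom", "klass", "origin", "active", "selmask"):
            arr = getattr(self, name)
            new = np.zeros(new_cap, dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)

    def add_batch(self, positions, sel, dom, klass, generation: int) -> np.ndarray:
        positions = np.asarray(positions, dtype=np.int64)
        k = positions.size
        self._grow(k)
        lo = self.n
        sl = slice(lo, lo + k)
        self.pos[sl] = positions
        self.sel[sl] = sel
        self.dom[sl] = dom
        self.klass[sl] = klass
        self.origin[sl] = generation
        self.active[sl] = True
        self.selmask[sl] = (np.asarray(sel) != 0.0).astype(np.uint8)
        self.n += k
        self.active_positions.update(positions.tolist())
        return np.arange(lo, lo + k, dtype=np.int32)

    def deactivate(self, ids: np.ndarray, fixed: bool = False, generation: int = -1):
        self.active[ids] = False
        self.active_positions.difference_update(self.pos[ids].tolist())
        if fixed:
            self.substitutions.extend((int(i), generation) for i in ids)

    def record(self, mid: int) -> Mutation:
        return Mutation(
            id=int(mid),
            position=int(self.pos[mid]),
            sel_s=float(self.sel[mid]),
            h=float(self.dom[mid]),
            klass=KLASS_NAMES[int(self.klass[mid])],
            origin_generation=int(self.origin[mid]),
        )

    @property
    def n_active(self) -> int:
        return int(self.active[: self.n].sum())


class Population:
    """2N haploid genomes as position-sorted sparse mutation-id lists.

    ``active_ids`` caches the registry ids currently segregating so the
    per-generation bookkeeping never scans the whole (append-only)
    registry.
    """

    def __init__(
        self,
        flat: np.ndarray,
        offs: np.ndarray,
        registry: MutationRegistry,
        counts: np.ndarray,
        generation: int = 0,
        active_ids: np.ndarray | None = None,
        flat_pos: np.ndarray | None = None,
    ) -> None:
        self.flat = np.asarray(flat, dtype=np.int32)
        self.offs = np.asarray(offs, dtype=np.int64)
        if flat_pos is None:
            flat_pos = registry.pos[self.flat]
        self.flat_pos = np.asarray(flat_pos, dtype=np.int32)
        self.registry = registry
        self.counts = counts  # allele count per registry id (length >= registry.n)
        self.generation = generation
        if active_ids is None:
            active_ids = np.flatnonzero(registry.active[: registry.n]).astype(np.int32)
        self.active_ids = active_ids
        # selected-only per-haplotype sublists (filled by the kernel when
        # selection is active; rebuilt lazily otherwise)
        self.sel_flat: np.ndarray | None = None
        self.sel_pos: np.ndarray | None = None
        self.sel_offs: np.ndarray | None = None

    def _selected_sublists(self):
        if self.sel_offs is None:
            reg = self.registry
            mask = reg.selmask[self.flat].astype(bool)
            csum = np.concatenate([[0], np.cumsum(mask)])
            self.sel_flat = self.flat[mask]
            self.sel_pos = self.flat_pos[mask]
            self.sel_offs = csum[self.offs]
        return self.sel_flat, self.sel_pos, self.sel_offs

    @classmethod
    def empty(cls, n_individuals: int, registry: MutationRegistry | None = None):
        registry = registry or MutationRegistry()
        return cls(
            flat=np.zeros(0, dtype=np.int32),
            offs=np.zeros(2 * n_individuals + 1, dtype=np.int64),
            registry=registry,
            counts=np.zeros(max(registry.n, 1), dtype=np.int32),
        )

    @classmethod
    def from_genotype_matrix(cls, gm: GenotypeMatrix, generation: int = 0):
        """Seed a population with standing variation (neutral sites)."""
        if not gm.phased:
            raise ValueError("seeding a population requires phased haplotypes")
        registry = MutationRegistry(capacity=max(64, 2 * gm.n_sites))
        ids = registry.add_batch(
            gm.positions,
            np.zeros(gm.n_sites),
            np.full(gm.n_sites, 0.5),
            np.zeros(gm.n_sites, dtype=np.int8),
            generation,
        )
        haps = gm.haplotypes
        flat_parts = []
        offs = np.zeros(gm.n_haplotypes + 1, dtype=np.int64)
        for hcol in range(gm.n_haplotypes):
            carried = ids[haps[:, hcol] == 1]
            flat_parts.append(carried)
            offs[hcol + 1] = offs[hcol] + carried.size
        flat = (
            np.concatenate(flat_parts)
            if flat_parts
            else np.zeros(0, dtype=np.int32)
        )
        counts = np.zeros(registry.n, dtype=np.int32)
        np.add.at(counts, flat, 1)
        return cls(flat, offs, registry, counts, generation)

    @property
    def n_individuals(self) -> int:
        return (self.offs.size - 1) // 2

    @property
    def n_haplotypes(self) -> int:
        return self.offs.size - 1

    def haplotype(self, h: int) -> np.ndarray:
        return self.flat[self.offs[h] : self.offs[h + 1]]

    def individual(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        return self.haplotype(2 * i), self.haplotype(2 * i + 1)

    def allele_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """(active mutation ids, frequency) over the 2N haplotypes."""
        act = self.active_ids
        return act, self.counts[act] / self.n_haplotypes

    def expected_heterozygosity(self) -> float:
        """Sum over segregating sites of 2 p q (population frequencies)."""
        _, p = self.allele_frequencies()
        return float(np.sum(2.0 * p * (1.0 - p)))

    def observed_heterozygosity(self) -> float:
        """Mean per-individual count of heterozygous sites."""
        total = 0
        for i in range(self.n_individuals):
            a, b = self.individual(i)
            total += np.setxor1d(a, b, assume_unique=True).size
        return total / self.n_individuals


# ---------------------------------------------------------------------------
# reference (pure numpy) per-operation primitives
# ---------------------------------------------------------------------------


def fitness_of(
    genome_pair,
    registry: MutationRegistry,
    balancing_mode: str = "overdominance",
    freq: np.ndarray | None = None,
) -> float:
    """Fitness of one individual: multiplicative across mutation sites.

    Reference implementation used directly in tests and as the oracle for
    the vectorised population kernel.  ``genome_pair`` is the pair of
    haploid mutation-id arrays; ``freq`` (per-mutation population
    frequency) is needed only for frequency-dependent balancing selection.
    """
    a, b = (np.asarray(g, dtype=np.int64) for g in genome_pair)
    hom = np.intersect1d(a, b, assume_unique=True)
    het = np.setxor1d(a, b, assume_unique=True)
    w = 1.0
    for ids, zyg in ((het, 1), (hom, 2)):
        for m in ids:
            s = registry.sel[m]
            if s == 0.0:
                continue
            if registry.klass[m] == K.KLASS_BALANCING:
                if balancing_mode == "overdominance":
                    if zyg == 1:
                        w *= 1.0 + s
                else:
                    se = s * (1.0 - 2.0 * (0.0 if freq is None else freq[m]))
                    w *= (1.0 + 0.5 * se) if zyg == 1 else (1.0 + se)
            else:
                w *= (1.0 + registry.dom[m] * s) if zyg == 1 else (1.0 + s)
    return max(w, 0.0)


def draw_crossovers(
    model: ChromosomeModel, rng: np.random.Generator, n_gametes: int
):
    """Crossover positions per gamete: inhomogeneous Poisson over domains.

    Counts are Poisson with mean equal to the map length in Morgans;
    positions are drawn from the normalised crossover intensity by inverse
    transform over the cumulative genetic map.  Returns (flat sorted
    positions, offsets) like the haplotype layout.
    """
    cum_map = model.rec_cum
    total = float(cum_map[-1])
    k = rng.poisson(total, size=n_gametes) if total > 0 else np.zeros(n_gametes, dtype=np.int64)
    n_total = int(k.sum())
    offs = np.zeros(n_gametes + 1, dtype=np.int64)
    np.cumsum(k, out=offs[1:])
    if n_total == 0:
        return np.zeros(0), offs
    u = rng.random(n_total) * total
    xpos = np.interp(u, cum_map, model.bounds_float)
    gid = np.repeat(np.arange(n_gametes), k)
    order = np.lexsort((xpos, gid))
    return xpos[order], offs


def make_gamete(
    individual, model: ChromosomeModel, rng: np.random.Generator, registry=None
) -> np.ndarray:
    """One recombinant gamete from an individual's two haplotypes.

    Reference implementation (the population kernel assembles all gametes
    of a generation at once).  ``individual`` is a (hapA, hapB) pair of
    mutation-id arrays; ``registry`` supplies positions (ids themselves
    when omitted, useful for synthetic tests where id == position).
    """
    a, b = (np.asarray(g, dtype=np.int64) for g in individual)
    pos_of = (lambda ids: ids.astype(float)) if registry is None else (
        lambda ids: registry.pos[ids].astype(float)
    )
    bp, _ = draw_crossovers(model, rng, 1)
    start = int(rng.integers(2))
    take_a = (start + np.searchsorted(bp, pos_of(a), side="left")) % 2 == 0
    take_b = (start + np.searchsorted(bp, pos_of(b), side="left")) % 2 == 1
    merged = np.concatenate([a[take_a], b[take_b]])
    return merged[np.argsort(pos_of(merged), kind="stable")]


def _draw_mutation_positions(
    model: ChromosomeModel, rng: np.random.Generator, n: int, taken: set[int]
) -> np.ndarray:
    """n distinct integer positions sampled proportional to the local
    mutation rate, rejecting positions already segregating."""
    cum = model.mut_cum
    total = float(cum[-1])
    out = np.empty(n, dtype=np.int64)
    got = 0
    batch = set()
    while got < n:
        u = rng.random(n - got) * total
        raw = np.floor(np.interp(u, cum, model.bounds_float)).astype(np.int64)
        raw = np.minimum(raw, model.length_bp - 1)
        for p in raw:
            ip = int(p)
            if ip in taken or ip in batch:
                continue
            out[got] = ip
            batch.add(ip)
            got += 1
            if got == n:
                break
    return out


def apply_mutations(
    gamete: np.ndarray,
    model: ChromosomeModel,
    dfe: DFEConfig,
    rng: np.random.Generator,
    registry: MutationRegistry,
    generation: int = 0,
) -> np.ndarray:
    """Add new mutations to one gamete (count ~ Poisson of the landscape
    integral; positions proportional to local rate; effects from the DFE).
    Reference implementation for the batched path in
    :func:`next_generation`."""
    n_new = int(rng.poisson(model.expected_mutations()))
    if n_new == 0:
        return gamete
    positions = _draw_mutation_positions(model, rng, n_new, registry.active_positions)
    klasses = rng.choice(
        4, size=n_new, p=np.asarray(dfe.class_fractions)
    ).astype(np.int8)
    s, h = dfe.draw_effects(klasses, rng)
    ids = registry.add_batch(positions, s, h, klasses, generation)
    merged = np.concatenate([np.asarray(gamete, dtype=np.int32), ids])
    return merged[np.argsort(registry.pos[merged], kind="stable")]


# ---------------------------------------------------------------------------
# configuration and orchestration
# ---------------------------------------------------------------------------


def full_scale_model(mut_multipliers=(1.0, 1.0, 1.0)) -> ChromosomeModel:
    """Full-scale chromosome: 1 Mb arms (2.5e-7) around a 1 Mb center
    (1e-9), base mutation rate 2e-8."""
    return build_chromosome_model(1e6, 1e6, 2.5e-7, 1e-9, 2e-8, mut_multipliers)


def desk_scale_model(mut_multipliers=(1.0, 1.0, 1.0)) -> ChromosomeModel:
    """Desk-scale chromosome: 100 kb domains with per-base rates x10, so a
    ten-fold smaller population preserves N*r*L and N*mu*L."""
    return full_scale_model(mut_multipliers).scaled(0.1, 10.0)


@dataclass
class SimulationConfig:
    """Everything one forward run needs.

    ``selfing_rate`` is a probability or a schedule ``[(generation, rate),
    ...]`` applied from each listed generation on; ``demography`` likewise
    reschedules N.  ``burn_in`` defaults to 10N generations; the run lasts
    ``burn_in + generations``.  Snapshot generations are absolute (0-based
    from the start); the final generation is always snapshot.
    """

    N: int
    model: ChromosomeModel
    selfing_rate: float | list = 0.0
    dfe: DFEConfig = field(default_factory=DFEConfig)
    generations: int = 0
    burn_in: int | None = None
    sample_size: int = 100
    seed: int | None = None
    demography: list | None = None
    snapshot_generations: tuple = ()
    keep_population: bool = False

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("population size must be positive")
        if self.burn_in is None:
            self.burn_in = 10 * self.N
        if self.burn_in < 0:
            raise ValueError("burn-in must be >= 0")
        for _, rate in self.selfing_schedule():
            if not 0.0 <= rate <= 1.0:
                raise ValueError("selfing rate must lie in [0, 1]")

    def selfing_schedule(self) -> list[tuple[int, float]]:
        if isinstance(self.selfing_rate, (int, float)):
            return [(0, float(self.selfing_rate))]
        return sorted((int(g), float(r)) for g, r in self.selfing_rate)

    def demography_schedule(self) -> list[tuple[int, int]]:
        if not self.demography:
            return [(0, self.N)]
        sched = sorted((int(g), int(n)) for g, n in self.demography)
        if not sched or sched[0][0] > 0:
            sched.insert(0, (0, self.N))
        return sched

    @property
    def total_generations(self) -> int:
        return self.burn_in + self.generations


def desk_scale_config(
    selfing_rate=0.0,
    dfe: DFEConfig | None = None,
    mut_multipliers=(1.0, 1.0, 1.0),
    N: int = 500,
    sample_size: int = 50,
    seed: int | None = None,
    scale_selection: bool = True,
    **kwargs,
) -> SimulationConfig:
    """Scaled-down study conditions: N=500 on a 300 kb chromosome with
    per-base rates x10, preserving the population-scaled parameters of
    the full-size design (N=5000, 3 Mb).

    DFE gamma means are parameterised at full scale; by default they are
    inflated by the same x10 factor so N*s is preserved alongside N*mu*L
    and N*r*L (set ``scale_selection=False`` to keep raw coefficients).
    """
    dfe = dfe or DFEConfig()
    if scale_selection:
        dfe = dfe.scaled(10.0)
    return SimulationConfig(
        N=N,
        model=desk_scale_model(mut_multipliers),
        selfing_rate=selfing_rate,
        dfe=dfe,
        sample_size=sample_size,
        seed=seed,
        **kwargs,
    )


@dataclass
class ScenarioResult:
    """Replicate output: sampled genotype snapshots plus provenance."""

    config: SimulationConfig
    seed: int | None
    snapshots: dict  # generation -> GenotypeMatrix
    substitutions: list  # Mutation records of fixed mutations
    started_at: float
    runtime_s: float
    final_population: Population | None = None

    @property
    def final_sample(self) -> GenotypeMatrix:
        return self.snapshots[max(self.snapshots)]


def _sample_parents(
    rng: np.random.Generator, n_parents: int, n_children: int, w: np.ndarray | None
):
    if w is None:
        return rng.integers(0, n_parents, size=n_children)
    total = w.sum()
    if total <= 0:
        raise SimulationExtinctError("all individuals have zero fitness")
    cdf = np.cumsum(w)
    return np.searchsorted(cdf, rng.random(n_children) * total, side="right").clip(
        0, n_parents - 1
    )


def next_generation(
    pop: Population,
    model: ChromosomeModel,
    dfe: DFEConfig,
    selfing_rate: float,
    rng: np.random.Generator,
    n_offspring: int | None = None,
) -> Population:
    """Produce the next generation (fitness, mating, recombination,
    mutation, fixation pruning) using the batched kernel."""
    reg = pop.registry
    n_par = pop.n_individuals
    n_off = n_par if n_offspring is None else int(n_offspring)
    n_gam = 2 * n_off

    # fitness (skip entirely when no selected mutation segregates)
    w = None
    if pop.active_ids.size and np.any(reg.selmask[pop.active_ids] != 0):
        w = np.empty(n_par)
        if dfe.bal_mode_code == K.BAL_FREQUENCY_DEPENDENT:
            freq = pop.counts[: reg.n] / pop.n_haplotypes
        else:
            freq = np.zeros(1)
        sflat, spos, soffs = pop._selected_sublists()
        K.fitness_population(
            sflat,
            spos,
            soffs,
            reg.sel,
            reg.dom,
            reg.klass,
            freq,
            dfe.bal_mode_code,
            w,
        )
        if w.max() <= 0:
            raise SimulationExtinctError("all individuals have zero fitness")

    # mating: one parent (selfing) or two distinct parents per offspring
    p1 = _sample_parents(rng, n_par, n_off, w)
    p2 = _sample_parents(rng, n_par, n_off, w)
    selfer = rng.random(n_off) < selfing_rate
    p2[selfer] = p1[selfer]
    if n_par > 1:
        clash = ~selfer & (p1 == p2)
        while clash.any():
            p2[clash] = _sample_parents(rng, n_par, int(clash.sum()), w)
            clash = ~selfer & (p1 == p2)

    parents = np.empty(n_gam, dtype=np.int64)
    parents[0::2] = p1
    parents[1::2] = p2
    hapA = (2 * parents).astype(np.int64)
    hapB = hapA + 1
    starts = rng.integers(0, 2, size=n_gam, dtype=np.int8)

    xo_pos, xo_offs = draw_crossovers(model, rng, n_gam)
    xo_int = np.floor(xo_pos).astype(np.int32)

    # new mutations, batched over all gametes
    n_new = rng.poisson(model.expected_mutations(), size=n_gam)
    total_new = int(n_new.sum())
    new_offs = np.zeros(n_gam + 1, dtype=np.int64)
    np.cumsum(n_new, out=new_offs[1:])
    if total_new:
        positions = _draw_mutation_positions(
            model, rng, total_new, reg.active_positions
        )
        klasses = rng.choice(
            4, size=total_new, p=np.asarray(dfe.class_fractions)
        ).astype(np.int8)
        s, h = dfe.draw_effects(klasses, rng)
        new_ids = reg.add_batch(positions, s, h, klasses, pop.generation + 1)
        gid = np.repeat(np.arange(n_gam), n_new)
        order = np.lexsort((positions, gid))
        new_ids = new_ids[order].astype(np.int32)
        new_pos = positions[order].astype(np.int32)
    else:
        new_ids = np.zeros(0, dtype=np.int32)
        new_pos = np.zeros(0, dtype=np.int32)

    # assemble
    par_sizes = pop.offs[hapA + 1] - pop.offs[hapA] + pop.offs[hapB + 1] - pop.offs[hapB]
    cap = int(par_sizes.sum()) + total_new
    out_flat = np.empty(cap, dtype=np.int32)
    out_pos = np.empty(cap, dtype=np.int32)
    out_offs = np.empty(n_gam + 1, dtype=np.int64)
    counts = np.zeros(reg.n, dtype=np.int32)
    frac = np.asarray(dfe.class_fractions)
    emit_sel = 1 if (frac[1:].sum() > 0 or np.any(reg.selmask[pop.active_ids] != 0)) else 0
    if emit_sel:
        sel_flat = np.empty(cap, dtype=np.int32)
        sel_pos = np.empty(cap, dtype=np.int32)
        sel_offs = np.empty(n_gam + 1, dtype=np.int64)
    else:
        sel_flat = np.empty(0, dtype=np.int32)
        sel_pos = np.empty(0, dtype=np.int32)
        sel_offs = np.empty(1, dtype=np.int64)
    used = K.assemble_generation(
        pop.flat,
        pop.flat_pos,
        pop.offs,
        hapA,
        hapB,
        starts,
        xo_int,
        xo_offs,
        new_ids,
        new_pos,
        new_offs,
        out_flat,
        out_pos,
        out_offs,
        counts,
        reg.selmask,
        emit_sel,
        sel_flat,
        sel_pos,
        sel_offs,
    )
    out_flat = out_flat[:used]
    out_pos = out_pos[:used]

    # prune: lost and fixed mutations leave the active set
    cand = (
        np.concatenate([pop.active_ids, new_ids])
        if new_ids.size
        else pop.active_ids
    )
    c = counts[cand]
    lost = cand[c == 0]
    fixed = cand[c == n_gam]
    if lost.size:
        reg.deactivate(lost)
    if fixed.size:
        reg.deactivate(fixed, fixed=True, generation=pop.generation + 1)
        keep = np.ones(reg.n, dtype=bool)
        keep[fixed] = False
        kept = keep[out_flat]
        csum = np.concatenate([[0], np.cumsum(kept)])
        out_offs = csum[out_offs]
        out_flat = out_flat[kept]
        out_pos = out_pos[kept]
        counts[fixed] = 0
    if lost.size or fixed.size:
        active = cand[(c > 0) & (c < n_gam)]
    else:
        active = cand

    child = Population(
        out_flat, out_offs, reg, counts, pop.generation + 1, active, out_pos
    )
    if emit_sel:
        ns = int(sel_offs[n_gam])
        sel_flat = sel_flat[:ns]
        sel_pos = sel_pos[:ns]
        if fixed.size:
            keep_s = keep[sel_flat]
            csum_s = np.concatenate([[0], np.cumsum(keep_s)])
            sel_offs = csum_s[sel_offs]
            sel_flat = sel_flat[keep_s]
            sel_pos = sel_pos[keep_s]
        child.sel_flat = sel_flat
        child.sel_pos = sel_pos
        child.sel_offs = sel_offs
    return child


def sample_genotypes(
    pop: Population, n: int, rng: np.random.Generator
) -> GenotypeMatrix:
    """Sample ``n`` diploid individuals without replacement and return the
    biallelic sites segregating in the sample (phased)."""
    if n > pop.n_individuals:
        raise ValueError("cannot sample more individuals than the population holds")
    chosen = np.sort(rng.choice(pop.n_individuals, size=n, replace=False))
    hap_rows = np.empty(2 * n, dtype=np.int64)
    hap_rows[0::2] = 2 * chosen
    hap_rows[1::2] = 2 * chosen + 1

    reg = pop.registry
    scount = np.zeros(reg.n, dtype=np.int32)
    for h in hap_rows:
        np.add.at(scount, pop.flat[pop.offs[h] : pop.offs[h + 1]], 1)
    seg = np.flatnonzero((scount > 0) & (scount < 2 * n))
    order = np.argsort(reg.pos[seg], kind="stable")
    seg = seg[order]
    row_of = np.full(reg.n, -1, dtype=np.int64)
    row_of[seg] = np.arange(seg.size)
    haps = np.zeros((seg.size, 2 * n), dtype=np.int8)
    for j, h in enumerate(hap_rows):
        ids = pop.flat[pop.offs[h] : pop.offs[h + 1]]
        rows = row_of[ids]
        haps[rows[rows >= 0], j] = 1
    return GenotypeMatrix.from_haplotypes(
        positions=reg.pos[seg],
        haplotypes=haps,
        sequence_length=None,
    )


def run_simulation(cfg: SimulationConfig, initial: Population | None = None) -> ScenarioResult:
    """Run burn-in plus scheduled events and collect genotype snapshots.

    The RNG is fully determined by ``cfg.seed``.  Selfing-rate and
    population-size changes take effect from their scheduled generation.
    Snapshots sample ``cfg.sample_size`` individuals (capped at N).
    """
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed)
    pop = initial if initial is not None else Population.empty(cfg.N)
    selfing_sched = cfg.selfing_schedule()
    demo_sched = cfg.demography_schedule()
    snapshots_at = set(int(g) for g in cfg.snapshot_generations)
    snapshots_at.add(cfg.total_generations)
    snaps: dict[int, GenotypeMatrix] = {}

    selfing = selfing_sched[0][1]
    n_next = pop.n_individuals
    if 0 in snapshots_at:
        snaps[0] = sample_genotypes(pop, min(cfg.sample_size, pop.n_individuals), rng)
    for gen in range(cfg.total_generations):
        for g_ev, rate in selfing_sched:
            if g_ev == gen:
                selfing = rate
        for g_ev, n_ev in demo_sched:
            if g_ev == gen:
                n_next = n_ev
        pop = next_generation(pop, cfg.model, cfg.dfe, selfing, rng, n_next)
        if pop.generation in snapshots_at:
            k = min(cfg.sample_size, pop.n_individuals)
            gm = sample_genotypes(pop, k, rng)
            gm.sequence_length = cfg.model.length_bp
            snaps[pop.generation] = gm
    subs = [pop.registry.record(i) for i, _ in pop.registry.substitutions]
    return ScenarioResult(
        config=cfg,
        seed=cfg.seed,
        snapshots=snaps,
        substitutions=subs,
        started_at=t0,
        runtime_s=time.time() - t0,
        final_population=pop if cfg.keep_population else None,
    )
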