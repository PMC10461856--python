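"""Experiment designs: selfing x mutation-landscape x selection grids,
decay of ancestral diversity after a switch to selfing, demographic
perturbations, and the domain comparison statistics (Cohen's d plus the
Fisher-Pitman permutation test).

Replicate seeds derive deterministically from ``(base_seed, cell index,
replicate index)`` so every grid cell is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .landscape import ChromosomeModel
from .simulate import (
    DFEConfig,
    SimulationConfig,
    SimulationExtinctError,
    run_simulation,
)
from .sumstats import WindowSpec, compute_window_table

__all__ = [
    "ScenarioGrid",
    "ComparisonResult",
    "derive_seed",
    "run_replicates",
    "run_scenario_grid",
    "decay_experiment",
    "demography_experiment",
    "compare_domains",
    "domain_means",
    "DEFAULT_LANDSCAPES",
    "DEFAULT_REGIMES",
]

DEFAULT_LANDSCAPES = {
    "1-1-1": (1.0, 1.0, 1.0),
    "1.15-1-1.15": (1.15, 1.0, 1.15),
    "1.5-1-1.5": (1.5, 1.0, 1.5),
    "2-1-2": (2.0, 1.0, 2.0),
}

DEFAULT_REGIMES = {
    "neutral": DFEConfig.neutral,
    "deleterious": DFEConfig.with_deleterious,
    "beneficial": DFEConfig.with_beneficial,
    "balancing": DFEConfig.with_balancing,
}


def derive_seed(base_seed: int, *indices: int) -> int:
    """Deterministic child seed below 2**31 from a base seed and indices."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class ScenarioGrid:
    """Cells of the main simulation experiment.

    ``selfing_levels`` maps labels to selfing rates (or to the string
    ``"bottleneck"`` for the outcrossing-inbreeding column: an outcrossing
    population reduced to ``bottleneck_pairs`` mating pairs for the last
    ``bottleneck_generations`` generations before sampling).
    """

    base_config: SimulationConfig
    selfing_levels: dict = field(
        default_factory=lambda: {
            "outcrossing": 0.0,
            "selfing90": 0.90,
            "selfing98": 0.98,
            "selfing99.9": 0.999,
            "selfing100": 1.0,
        }
    )
    mutation_landscapes: dict = field(
        default_factory=lambda: dict(DEFAULT_LANDSCAPES)
    )
    selection_regimes: dict = field(
        default_factory=lambda: {k: v() for k, v in DEFAULT_REGIMES.items()}
    )
    replicates: int = 2
    base_seed: int = 0
    window: WindowSpec = field(default_factory=lambda: WindowSpec(size=20_000))
    bottleneck_pairs: int = 2
    bottleneck_generations: int = 5

    def cells(self):
        i = 0
        for s_label, s_val in self.selfing_levels.items():
            for m_label, mult in self.mutation_landscapes.items():
                for r_label, dfe in self.selection_regimes.items():
                    yield i, (s_label, s_val), (m_label, mult), (r_label, dfe)
                    i += 1

    def cell_config(self, s_val, mult, dfe, seed) -> SimulationConfig:
        model = self.base_config.model
        model = replace(model, mut_multipliers=tuple(mult))
        cfg = replace(
            self.base_config, model=model, dfe=dfe, seed=seed, selfing_rate=0.0
        )
        if s_val == "bottleneck":
            total = cfg.total_generations
            demo = list(cfg.demography or [])
            demo.append(
                (total - self.bottleneck_generations, 2 * self.bottleneck_pairs)
            )
            cfg = replace(
                cfg,
                demography=demo,
                sample_size=min(cfg.sample_size, 2 * self.bottleneck_pairs),
            )
        else:
            cfg = replace(cfg, selfing_rate=float(s_val))
        return cfg


def run_replicates(cfg: SimulationConfig, n_reps: int, base_seed: int, cell: int = 0):
    """Run ``n_reps`` replicates; an extinct replicate is retried with the
    next derived seed (at most 3 attempts)."""
    results = []
    for rep in range(n_reps):
        for attempt in range(3):
            seed = derive_seed(base_seed, cell, rep, attempt)
            try:
                results.append(run_simulation(replace(cfg, seed=seed)))
                break
            except SimulationExtinctError:
                if attempt == 2:
                    raise
    return results


def run_scenario_grid(grid: ScenarioGrid) -> pd.DataFrame:
    """Simulate every cell x replicate and summarise windowed statistics.

    Returns a tidy frame with one row per (cell, replicate, window) and
    all summary statistics; aggregate across replicates with
    :func:`grid_summary`.
    """
    frames = []
    for i, (s_label, s_val), (m_label, mult), (r_label, dfe) in grid.cells():
        cfg = grid.cell_config(s_val, mult, dfe, seed=None)
        results = run_replicates(cfg, grid.replicates, grid.base_seed, cell=i)
        for rep, res in enumerate(results):
            table = compute_window_table(res.final_sample, grid.window)
            table.insert(0, "selfing", s_label)
            table.insert(1, "landscape", m_label)
            table.insert(2, "regime", r_label)
            table.insert(3, "replicate", rep)
            frames.append(table)
    return pd.concat(frames, ignore_index=True)


def grid_summary(tidy: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of each statistic per cell and window position."""
    stats = [
        c
        for c in tidy.columns
        if c
        not in ("selfing", "landscape", "regime", "replicate", "start", "end")
    ]
    g = tidy.groupby(["selfing", "landscape", "regime", "start", "end"])[stats]
    out = g.agg(["mean", "std"])
    out.columns = [f"{a}_{b}" for a, b in out.columns]
    return out.reset_index()


def decay_experiment(
    target_selfing: float = 1.0,
    record_every: int = 250,
    horizon: int = 1500,
    reps: int = 20,
    base_config: SimulationConfig | None = None,
    base_seed: int = 0,
    window: WindowSpec | None = None,
) -> pd.DataFrame:
    """Diversity decay after an outcrossing population switches to selfing.

    Burn-in is fully outcrossing; at its end the population switches to
    ``target_selfing`` (0.98 and 1.0 are the canonical levels) and samples
    are taken every ``record_every`` generations for ``horizon``
    generations.  Returns per snapshot and replicate the mean pi per
    window in the high-recombination arms and over the whole chromosome.
    """
    cfg = base_config or _default_decay_config()
    window = window or WindowSpec(size=20_000)
    snaps = tuple(
        cfg.burn_in + k
        for k in range(0, horizon + 1, record_every)
    )
    cfg = replace(
        cfg,
        generations=horizon,
        selfing_rate=[(0, 0.0), (cfg.burn_in, float(target_selfing))],
        snapshot_generations=snaps,
    )
    rows = []
    model = cfg.model
    for rep in range(reps):
        res = _run_with_retry(cfg, base_seed, rep)
        for gen, gm in sorted(res.snapshots.items()):
            table = compute_window_table(gm, window)
            arm = _domain_of_windows(table, model) != 1
            rows.append(
                dict(
                    replicate=rep,
                    generation=gen - cfg.burn_in,
                    pi_arms=float(table.loc[arm, "pi"].mean()),
                    pi_total=float(table["pi"].mean()),
                )
            )
    return pd.DataFrame(rows)


def _default_decay_config() -> SimulationConfig:
    from .simulate import desk_scale_config

    return desk_scale_config(dfe=DFEConfig.with_deleterious())


def _run_with_retry(cfg: SimulationConfig, base_seed: int, rep: int):
    for attempt in range(3):
        try:
            return run_simulation(
                replace(cfg, seed=derive_seed(base_seed, rep, attempt))
            )
        except SimulationExtinctError:
            if attempt == 2:
                raise


def _domain_of_windows(table: pd.DataFrame, model: ChromosomeModel) -> np.ndarray:
    mids = (table["start"].to_numpy() + table["end"].to_numpy()) // 2
    return model.domain_of(mids)


def demography_experiment(
    mode: str = "growth",
    reps: int = 20,
    base_config: SimulationConfig | None = None,
    base_seed: int = 0,
    window: WindowSpec | None = None,
    growth_rate: float = 0.03,
    growth_generations: int = 100,
    fluct_high_factor: float = 3.0,
    fluct_phase: int = 10,
    fluct_iterations: int = 5,
) -> pd.DataFrame:
    """Fold change of every statistic after a recent demographic change.

    ``growth``: exponential growth (3% per generation for 100 generations,
    roughly a 19-fold increase).  ``fluctuation``: the population jumps to
    ``fluct_high_factor * N`` and back each ``fluct_phase`` generations for
    ``fluct_iterations`` iterations.  Statistics are compared between the
    burn-in generation and the end; returns per-replicate fold changes
    (end / burn-in) with NaN where the burn-in value is 0 or undefined.
    """
    cfg = base_config or _default_demography_config()
    window = window or WindowSpec(size=20_000)
    n0 = cfg.N
    if mode == "growth":
        demo = [
            (cfg.burn_in + g, int(round(n0 * (1.0 + growth_rate) ** (g + 1))))
            for g in range(growth_generations)
        ]
        horizon = growth_generations
    elif mode == "fluctuation":
        demo = []
        for it in range(fluct_iterations):
            start = cfg.burn_in + 2 * it * fluct_phase
            demo.append((start, int(round(n0 * fluct_high_factor))))
            demo.append((start + fluct_phase, n0))
        horizon = 2 * fluct_iterations * fluct_phase
    else:
        raise ValueError("mode must be 'growth' or 'fluctuation'")
    cfg = replace(
        cfg,
        generations=horizon,
        demography=demo,
        snapshot_generations=(cfg.burn_in,),
    )
    stats = None
    rows = []
    for rep in range(reps):
        res = _run_with_retry(cfg, base_seed, rep)
        t0 = compute_window_table(res.snapshots[cfg.burn_in], window)
        t1 = compute_window_table(res.final_sample, window)
        if stats is None:
            stats = [
                c for c in t0.columns if c not in ("start", "end", "coverage_fraction")
            ]
        m0 = t0[stats].mean(numeric_only=True)
        m1 = t1[stats].mean(numeric_only=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = m1 / m0
        row = {"replicate": rep, "mode": mode}
        row.update({s: float(fold[s]) for s in stats})
        row.update({f"burnin_{s}": float(m0[s]) for s in stats})
        row.update({f"end_{s}": float(m1[s]) for s in stats})
        rows.append(row)
    return pd.DataFrame(rows)


def _default_demography_config() -> SimulationConfig:
    from .simulate import desk_scale_config

    return desk_scale_config()  # neutral: the canonical demography design


# ---------------------------------------------------------------------------
# statistical comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonResult:
    """Cohen's d plus Fisher-Pitman permutation test for two groups."""

    cohens_d: float
    perm_Z: float
    perm_p: float
    n_perm: int
    exact: bool
    groups: tuple[str, str] = ("a", "b")

    @property
    def p_report(self) -> str:
        """p-value string; Monte-Carlo p below resolution reported as a bound."""
        if not self.exact and self.perm_p <= 1.0 / (self.n_perm + 1):
            return f"< {1.0 / (self.n_perm + 1):g}"
        return f"{self.perm_p:g}"


def compare_domains(
    values_a,
    values_b,
    n_perm: int = 9999,
    seed: int | None = None,
    exact_limit: int = 100_000,
    groups: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Standardised mean difference and Fisher-Pitman permutation test.

    Cohen's d uses the pooled (n-1) standard deviation; with zero pooled
    variance d is NaN but the permutation p remains valid.  The test
    statistic is the difference of group means; labels are permuted
    exactly (all ``C(n, n_a)`` assignments) when feasible, otherwise by
    ``n_perm`` Monte-Carlo shuffles with ``p = (1 + #{|T*| >= |T|}) /
    (n_perm + 1)``.  ``perm_Z = (T - mean(T*)) / sd(T*)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    na, nb = a.size, b.size
    obs = a.mean() - b.mean()

    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    d = float(abs(obs) / np.sqrt(pooled)) if pooled > 0 else float("nan")

    data = np.concatenate([a, b])
    total = data.sum()
    n = na + nb
    eps = 1e-12 * (1.0 + abs(obs))

    if comb(n, na) <= exact_limit:
        sums_a = np.array(
            [data[list(idx)].sum() for idx in combinations(range(n), na)]
        )
        perm_stats = sums_a / na - (total - sums_a) / nb
        n_used = perm_stats.size
        p = float(np.mean(np.abs(perm_stats) >= abs(obs) - eps))
        exact = True
    else:
        rng = np.random.default_rng(seed)
        perm_stats = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(data)
            perm_stats[i] = perm[:na].mean() - perm[na:].mean()
        n_used = n_perm
        p = float((1 + np.sum(np.abs(perm_stats) >= abs(obs) - eps)) / (n_perm + 1))
        exact = False
    sd = perm_stats.std()
    z = float((obs - perm_stats.mean()) / sd) if sd > 0 else float("nan")
    return ComparisonResult(
        cohens_d=d, perm_Z=z, perm_p=p, n_perm=n_used, exact=exact, groups=groups
    )


def domain_means(
    table: pd.DataFrame, model: ChromosomeModel, stat: str = "pi"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window values of ``stat`` split into (arms, center) by window
    midpoint."""
    dom = _domain_of_windows(table, model)
    v = table[stat].to_numpy(dtype=float)
    return v[dom != 1], v[dom == 1]
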