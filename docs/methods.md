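# Methods

This note records the modelling assumptions, parameter choices, numerical
conventions and known limitations behind `nemascape`. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Forward simulator

**Reproduction.** Discrete non-overlapping generations of `N` diploids.
For each offspring independently: with probability `s` (the selfing rate)
one parent is drawn with probability proportional to fitness and
contributes two independent gametes; otherwise two parents are drawn
fitness-proportionally with replacement across offspring, redrawn if
identical (strict biparental outcrossing). Selfing is therefore a
per-offspring, not per-parent, property. Fitness is multiplicative over
sites — heterozygote factor `1 + h·s`, homozygote `1 + s`, floored at 0 —
and a generation in which every individual has fitness 0 raises an
extinction error (experiment drivers retry with the next derived seed, at
most three times).

**Recombination.** Crossovers per gamete are Poisson with mean equal to
the map integral `∑ r_d · L_d`; positions follow the piecewise-constant
intensity by inverse transform. No crossover interference and no obligate
chiasma: the rate map is taken at face value, so nematode single-crossover
meiosis is deliberately not modelled. The default full-scale chromosome is
3 Mb — 1 Mb arms at 2.5×10⁻⁷/bp/gen around a 1 Mb center at 10⁻⁹ — giving
0.501 expected crossovers (a 50.1 cM map).

**Mutation.** New mutations per gamete are Poisson with mean
`μ · ∑ m_d · L_d`; positions are integers drawn proportional to local
rate. A draw landing on a currently-segregating position (or drawn twice
in a batch) is redrawn: an infinite-sites approximation on discrete
coordinates, so every segregating site is biallelic. (SLiM-style mutation
stacking is thus replaced by rejection; at the default densities
collisions are ~10⁻³ per draw.) Mutations fixed in the population are
pruned from all genomes each generation and logged as substitutions.

**Selection classes and the DFE.** Class fractions follow the four
regimes of the study design: neutral; 90/10 neutral/deleterious;
89/10/1 adding beneficial; 89/10/1 adding balancing. The published design
delegates the numeric DFE to supplementary scripts, so the package
defaults are chosen once as field-plausible values and are fully
configurable: deleterious |s| ~ Gamma(shape 0.3, mean 0.01), beneficial
s ~ Gamma(0.5, 0.005), both parameterised at full scale (N = 5000);
dominance drawn per mutation from
0.5·U(0, 0.3) + 0.5·Beta(2, 8) for deleterious (recessive-shifted) and
0.5·U(0.3, 0.7) + 0.5·Beta(5, 5) for beneficial (near-additive).
Balancing mutations default to symmetric overdominance — heterozygote
factor `1 + s_bal` (default 0.01), homozygote 1 — with a negative
frequency-dependent alternative (`s_eff = s_bal(1 − 2p)`, `h = 0.5`)
behind a config switch; both are standard idioms and the choice is
reported with the output.

**Implementation.** Genomes are sparse position-sorted mutation lists in
flat arrays; one numba kernel assembles a whole generation of gametes by
copying position-contiguous blocks between crossovers and tallies allele
counts, a second computes fitness from selected-only sublists. All
randomness comes from a single `numpy.random.Generator`, so a run is
bit-reproducible from its seed; experiment grids derive child seeds as
`SeedSequence(base, cell, replicate, attempt)` (kept below 2³¹).

## Desk-scale study conditions

The full-size design (N = 5000, 3 Mb, μ = 2×10⁻⁸, 10N burn-in, 50
replicates) is available but cluster-sized. The desk defaults shrink
lengths ×10 and inflate per-base rates ×10, so `N·r·L` and `N·μ·L` are
preserved: **N = 500, L = 300 kb (100 kb domains), μ = 2×10⁻⁷, arm
recombination 2.5×10⁻⁶, 10N = 5000-generation burn-in, 20 replicates**,
sampling 50 diploids. Selection coefficients are inflated by the same
×10 factor, the standard rescaling that preserves N·s alongside N·μ·L and
N·r·L (disable with `scale_selection=False`); with s unscaled the
population-scaled strength of selection would be ten-fold weaker than the
full-size design. The non-neutral calibration batteries use the combined
deleterious-plus-beneficial regime — the design's canonical non-neutral
scenario class — because recurrent hitchhiking in the low-recombination
center is what produces the strong arm/center contrast; background
selection alone at this mutational input (deleterious rate 2×10⁻³ per
gamete in the center) predicts only a ~10% contrast
(`B ≈ exp(−U/s_het)`), real but underpowered at 20 replicates. Simulated windows are 20 kb, keeping the 75-windows-
per-chromosome granularity of 40 kb windows on 3 Mb. The decay-of-diversity
designs run at N = 300 with horizons expressed in units of N (snapshots
every N/2 up to 1N with selection; every 2N/3 up to 4N/3 for the neutral
variance check), which keeps the "decay within ~1N generations"
comparison meaningful while fitting the batteries in minutes. The
demographic designs follow the published schedules: 3% exponential growth
for 100 generations (≈19-fold), and fluctuation phases of 10 generations
at 3N and 10 at N, iterated five times (the alternative 5-generation
phasing is available via config).

## Window statistics

* **π** is the sum over sites of `2p̂q̂ · n/(n−1)` on `n` haplotypes,
  identically the mean pairwise difference count (asserted against a
  brute-force oracle).
* **θ_W = S/a₁**; **Tajima's D** uses the 1989 normalisation. `S = 0`
  yields θ_W = 0 and D = NaN — undefined statistics are always NaN,
  never 0, and TSVs encode them as `NA`.
* **Distance moments** (variance, skew, excess kurtosis) are population
  moments of the C(k,2) city-block distances between sampled genomes —
  haplotypes when phased, dosage vectors otherwise.
* **Haplotype homozygosities** use true haplotypes for simulated data and
  multilocus genotype strings ("diplotypes") for unphased input; the mode
  is whichever the container carries. `H1 = ∑pᵢ²`,
  `H12 = (p₁+p₂)² + ∑_{i≥3}pᵢ²`, `H2/H1 = (H1 − p₁²)/H1`.
* **r²** is haplotype `D²/(p_A q_A p_B q_B)` when phased, squared
  genotype-dosage Pearson correlation (Rogers–Huff) otherwise; **ZnS**
  averages it over all site pairs.
* **ω** follows the split-point form
  `[(C(ℓ,2)+C(S−ℓ,2))⁻¹ ∑ within r²] / [(ℓ(S−ℓ))⁻¹ ∑ cross r²]`,
  maximised over ℓ ∈ [2, S−2]; a zero cross-side sum caps the statistic
  at a configurable 10⁴. Because the windowing layer already uses one
  sub-window per window, ω is computed on the window's full site set.
* **β(1)** is implemented in the weighted-estimator framework:
  `θ̂_β = ∑_k w(f_k) / ∑_i w(f_i) ξ-normaliser` with similarity weight
  `w = (1 − |f − f_core|)^p` (p = 2 default), folded over minor-allele
  frequencies whenever ancestral states are unavailable (the default for
  unpolarised input; simulated data are unfolded); `β = θ̂_β − θ̂_W` over a
  1 kb default flank. The per-window `beta` column is the mean over all
  segregating cores in the window.
* **F_IS** is `1 − mean(H_obs)/mean(H_exp)` over sites with minor-allele
  frequency ≥ 0.05 (configurable; `H_exp = 2p̂q̂`).
* **LD decay** reports per-distance-bin medians of r², with optional
  site thinning (every k-th site) for dense data.
* Optional z-score normalisation across a chromosome's windows is off by
  default.

## Marey-map domain fitting

A Marey map is cumulative, so the 3-segment model is constrained
continuous: basis `[1, x, (x−b₁)₊, (x−b₂)₊]`, least squares at fixed
breakpoints, breakpoints located by an exhaustive grid over (subsampled)
marker midpoints refined by Nelder–Mead. The fit is flagged degenerate
when the 2-breakpoint model fails to improve a single line's residual sum
of squares by 1% (relative), or the line fits exactly. Confidence
intervals are 95% percentile intervals from nonparametric bootstrap
resamples of the marker set (default 1000), refit from the point-estimate
warm start. Internally coordinates are 0-based half-open; boundary
reports are written 1-based in kb, the convention of published domain
tables. **Known limitation:** the bootstrap under-disperses breakpoint
locations (break estimators are non-regular), and measured marginal CI
coverage at desk scale is ~88–90% rather than nominal 95%; the test suite
asserts coverage at that calibrated level.

## Divergence

The Tamura (1992) distance
`d = −h ln(1 − P/h − Q) − ½(1−h) ln(1 − 2Q)`, `h = 2θ_GC(1−θ_GC)`, uses
the transition proportion P and transversion proportion Q over usable
(unmasked, unambiguous) sites, with GC content taken from the ancestral
sequence of the window (configurable to the average of both). Saturated
windows raise an explicit error at the function level and become NaN in
tables. Substitutions are counted in the six strand-symmetric classes;
at θ_GC = 0.5 the distance reduces to Kimura's 2-parameter form, which the
tests verify against an independent closed form.

## Statistical comparisons

Cohen's d uses the pooled (n−1) standard deviation. The Fisher–Pitman
permutation test permutes group labels with the difference of means as
statistic: exact enumeration of all C(n, n_a) assignments when that count
is ≤ 10⁵, otherwise Monte-Carlo with `p = (1 + #{|T*| ≥ |T|})/(n_perm+1)`;
`Z = (T − mean T*)/sd T*`. Zero pooled variance makes d NaN while the
permutation p remains valid.

## What the synthetic data do and do not emulate

The simulator generates biallelic SNVs with realistic arm/center
structure, selfing-induced homozygosity, linked selection and LD — the
features the statistics are designed to read. It does not model gene
conversion, crossover interference, X-chromosome hemizygosity,
hyper-divergent haplotypes, population structure or migration, sequencing
error, or missing genotypes; coverage masks enter only through the
window-filter layer. Passing tests therefore demonstrate correctness of
the estimators and the qualitative causal contrasts (selection ×
recombination × mating system × mutation landscape) at reduced scale, not
quantitative agreement with any particular natural population.

## Numerical conventions

0-based half-open coordinates internally; VCF written 1-based with
placeholder A/T alleles (simulated variants carry no nucleotide
identity); BED half-open. Windows are `[start, start+size)`, last window
truncated at the chromosome end. Ties in the piecewise-fit grid resolve
toward the earlier candidate; crossover positions are real-valued and a
mutation exactly at a breakpoint stays with the pre-crossover haplotype
(a measure-zero convention shared by the kernel and the reference
implementation).
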