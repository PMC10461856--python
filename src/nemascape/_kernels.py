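"""Numba hot loops for the forward simulator.

Haplotypes are stored sparsely: ``flat`` holds registry indices of the
mutations carried by each haplotype, with ``flat_pos`` carrying their
genomic positions inline (avoids scattered registry gathers), both sorted
by position, and ``offs`` delimiting haplotypes
(``flat[offs[h]:offs[h+1]]`` is haplotype ``h``).  All randomness is drawn
outside the kernels from a single numpy Generator, so runs are
bit-reproducible from the seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_PMAX = np.int32(np.iinfo(np.int32).max)

KLASS_NEUTRAL = 0
KLASS_DELETERIOUS = 1
KLASS_BENEFICIAL = 2
KLASS_BALANCING = 3

BAL_OVERDOMINANCE = 0
BAL_FREQUENCY_DEPENDENT = 1


@njit(cache=True)
def assemble_generation(
    flat,
    flat_pos,
    offs,
    hapA,
    hapB,
    starts,
    xo_pos,
    xo_offs,
    new_idx,
    new_pos,
    new_offs,
    out_flat,
    out_pos,
    out_offs,
    counts,
    selmask,
    emit_sel,
    sel_flat,
    sel_pos,
    sel_offs,
):
    """Build all gametes of the next generation and tally allele counts.

    Gamete ``g`` copies position-contiguous blocks from parental haplotype
    rows ``hapA[g]``/``hapB[g]``, starting on ``starts[g]`` (0 = A) and
    switching source at each crossover in
    ``xo_pos[xo_offs[g]:xo_offs[g+1]]`` (sorted; a mutation at position p
    stays with the pre-crossover source when p <= crossover).  New
    mutations (position-sorted per gamete) are merged in afterwards.

    When ``emit_sel`` is non-zero, mutations flagged in ``selmask`` are
    additionally written to a selected-only sublist per gamete, which is
    what the fitness kernel traverses (most mutations are neutral).
    Returns the total number of entries written to ``out_flat``.
    """
    n_gam = hapA.shape[0]
    k = 0
    ks = 0
    out_offs[0] = 0
    if emit_sel != 0:
        sel_offs[0] = 0
    for g in range(n_gam):
        a = hapA[g]
        b = hapB[g]
        ia = offs[a]
        ea = offs[a + 1]
        ib = offs[b]
        eb = offs[b + 1]
        xi = xo_offs[g]
        xe = xo_offs[g + 1]
        cur = starts[g]
        gstart = k
        while True:
            bp = xo_pos[xi] if xi < xe else _PMAX
            if cur == 0:
                while ia < ea and flat_pos[ia] <= bp:
                    out_flat[k] = flat[ia]
                    out_pos[k] = flat_pos[ia]
                    counts[flat[ia]] += 1
                    k += 1
                    ia += 1
                while ib < eb and flat_pos[ib] <= bp:
                    ib += 1
            else:
                while ib < eb and flat_pos[ib] <= bp:
                    out_flat[k] = flat[ib]
                    out_pos[k] = flat_pos[ib]
                    counts[flat[ib]] += 1
                    k += 1
                    ib += 1
                while ia < ea and flat_pos[ia] <= bp:
                    ia += 1
            if xi < xe:
                xi += 1
                cur = 1 - cur
            else:
                break
        # splice in this gamete's new mutations (rare) by backward merge
        im = new_offs[g]
        em = new_offs[g + 1]
        if em > im:
            n_new = em - im
            i = k - 1
            w = k + n_new - 1
            j = em - 1
            while j >= im:
                while i >= gstart and out_pos[i] > new_pos[j]:
                    out_flat[w] = out_flat[i]
                    out_pos[w] = out_pos[i]
                    i -= 1
                    w -= 1
                out_flat[w] = new_idx[j]
                out_pos[w] = new_pos[j]
                counts[new_idx[j]] += 1
                j -= 1
                w -= 1
            k += n_new
        out_offs[g + 1] = k
        if emit_sel != 0:
            for t in range(gstart, k):
                m = out_flat[t]
                if selmask[m] != 0:
                    sel_flat[ks] = m
                    sel_pos[ks] = out_pos[t]
                    ks += 1
            sel_offs[g + 1] = ks
    return k


@njit(cache=True)
def fitness_population(flat, flat_pos, offs, sel, dom, klass, freq, bal_mode, w):
    """Multiplicative fitness per diploid individual.

    Heterozygous site: factor ``1 + h s``; homozygous: ``1 + s``.
    Balancing sites use symmetric overdominance (het ``1 + s``, hom 1) or,
    in frequency-dependent mode, ``s_eff = s (1 - 2 p)`` with ``h = 0.5``.
    Fitness is floored at 0.
    """
    n_ind = w.shape[0]
    big = _PMAX
    for i in range(n_ind):
        ia = offs[2 * i]
        ea = offs[2 * i + 1]
        ib = offs[2 * i + 1]
        eb = offs[2 * i + 2]
        wi = 1.0
        while ia < ea or ib < eb:
            pa = flat_pos[ia] if ia < ea else big
            pb = flat_pos[ib] if ib < eb else big
            if pa < pb:
                m = flat[ia]
                ia += 1
                zyg = 1
            elif pb < pa:
                m = flat[ib]
                ib += 1
                zyg = 1
            else:
                m = flat[ia]
                ia += 1
                ib += 1
                zyg = 2
            s = sel[m]
            if s != 0.0:
                if klass[m] == KLASS_BALANCING:
                    if bal_mode == BAL_OVERDOMINANCE:
                        if zyg == 1:
                            wi *= 1.0 + s
                    else:
                        se = s * (1.0 - 2.0 * freq[m])
                        wi *= (1.0 + 0.5 * se) if zyg == 1 else (1.0 + se)
                else:
                    wi *= (1.0 + dom[m] * s) if zyg == 1 else (1.0 + s)
        w[i] = wi if wi > 0.0 else 0.0
    return w
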