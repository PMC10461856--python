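"""Divergence from an ancestral sequence: Tamura distance and the
substitution spectrum.

Mutagenises a random ancestral sequence with a transition bias, then
recovers the per-window Tamura (1992) distance, the six strand-symmetric
substitution classes, and the transition/transversion ratio.
"""

import numpy as np

from nemascape import AlignedPair
from nemascape.divergence import spectrum_table

rng = np.random.default_rng(3)
L = 200_000
bases = np.array(list("ACGT"))
anc = rng.choice(bases, L)

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
der = anc.copy()
r = rng.random(L)
ts = r < 0.06  # 6% transitions
tv = (r >= 0.06) & (r < 0.10)  # 4% transversions
der[ts] = [TRANSITION[b] for b in anc[ts]]
for i in np.flatnonzero(tv):
    choices = [b for b in "ACGT" if b != anc[i] and b != TRANSITION[anc[i]]]
    der[i] = choices[rng.integers(2)]

pair = AlignedPair("".join(anc), "".join(der))
windows = [(s, s + 50_000) for s in range(0, L, 50_000)]
table = spectrum_table(pair, windows, min_usable=1000)
print(table[["start", "end", "n_usable", "ts_tv", "gc", "tamura_d"]].round(4).to_string(index=False))
print(f"\nmean Tamura distance: {table['tamura_d'].mean():.4f} "
      "(injected 10% raw divergence, corrected upward for multiple hits)")
print("-> the Ts/Tv ratio recovers the injected 1.5 transition bias and the")
print("   distance exceeds the raw mismatch fraction, as the model corrects")
print("   for unobserved repeat substitutions.")
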