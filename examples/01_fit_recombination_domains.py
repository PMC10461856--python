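"""Fit arm/center recombination-domain boundaries to a Marey map.

Builds a synthetic Marey map shaped like chromosome I of an outcrossing
nematode genetic map (high-recombination arms around a cold center),
fits the 3-segment piecewise-linear model with bootstrap CIs, and prints
the recovered boundaries, per-domain rates in cM/Mb, and the fraction of
the chromosome occupied by the central domain.
"""

import numpy as np

from nemascape import MareyMap, central_domain_fraction, fit_domain_boundaries

rng = np.random.default_rng(0)
LENGTH = 17_247_545
TRUE_BREAKS = (5_803_000, 13_007_000)
SLOPES = (5.197, 0.673, 3.529)  # cM/Mb

x = np.sort(rng.uniform(0, LENGTH, 400))
s = np.asarray(SLOPES) / 1e6
y = (
    s[0] * np.minimum(x, TRUE_BREAKS[0])
    + s[1] * np.clip(x - TRUE_BREAKS[0], 0, TRUE_BREAKS[1] - TRUE_BREAKS[0])
    + s[2] * np.clip(x - TRUE_BREAKS[1], 0, None)
    + rng.normal(0, 0.4, x.size)  # marker noise in cM
)
marey = MareyMap(physical_pos=x, genetic_pos=y, chrom="I")

fit = fit_domain_boundaries(marey, n_boot=200, seed=1)
(lo1, hi1), (lo2, hi2) = fit.boundary_CIs
print(f"left arm ends   : {fit.left_arm_end/1e3:8.0f} kb  (95% CI {lo1/1e3:.0f}-{hi1/1e3:.0f})")
print(f"right arm starts: {fit.right_arm_start/1e3:8.0f} kb  (95% CI {lo2/1e3:.0f}-{hi2/1e3:.0f})")
print("domain rates    : %.2f / %.2f / %.2f cM/Mb" % fit.domain_slopes)
frac = central_domain_fraction(fit, LENGTH)
print(f"central domain  : {frac:.1f}% of the chromosome")
print("-> the central low-recombination domain occupies roughly 40% of the")
print("   chromosome, matching the arm-center-arm organisation the map encodes.")
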