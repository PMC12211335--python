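"""EHH decay around a sweep core versus a neutral core.

EHH at distance x is the probability that two haplotypes drawn from the
group are identical from the core out to x.  Around a swept core the
tropical group keeps one long shared haplotype, so EHH stays high; at a
neutral core it collapses within a few SNPs.
"""

import numpy as np

from sweepscan import SimConfig, SweepSpec, ehh, haplotype_block, simulate_panel

cfg = SimConfig(seed=1, sweeps=[SweepSpec(start=5_000_001, end=5_100_000, beta=0.9)])
panel, popmap, truths = simulate_panel(cfg)
idx = panel.sample_indices(popmap.samples_of({"Egypt", "Uganda"}))
H, positions, _ = haplotype_block(panel, idx, "1")

t = truths[0]
sweep_core = int(np.argmin(np.abs(positions - (t.start + t.end) // 2)))
neutral_core = int(np.argmin(np.abs(positions - 2_000_000)))

for name, core in (("sweep core", sweep_core), ("neutral core", neutral_core)):
    curve = ehh(H, positions, core, "right")
    print(f"{name} at {positions[core]:,} bp (truncation: {curve.truncation})")
    for d, v in list(zip(curve.distances, curve.values))[:6]:
        print(f"  +{int(d):>6,} bp  EHH = {v:.3f}")
    print()

print(
    "At the sweep core 18 of 20 tropical haplotypes are identical, so EHH\n"
    "plateaus near C(18,2)/C(20,2) = 0.805 across the swept interval; at the\n"
    "neutral core unlinked sites drive EHH below the 0.05 cutoff within a\n"
    "few hundred bp."
)
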