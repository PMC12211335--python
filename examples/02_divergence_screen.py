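"""Screen for population-specific allele-frequency divergence.

Flags SNPs whose ALT frequency is >= 0.6 in one country (with at least
three called individuals) while staying < 0.3 in the five others — the
signature of an allele advantageous in one environment.  A hard sweep is
injected into Egypt alone; the screen is single-country by construction,
so only alleles high in exactly one population qualify.
"""

from sweepscan import (
    SimConfig,
    SweepSpec,
    allele_frequencies,
    divergent_site_report,
    divergent_sites,
    simulate_panel,
)

cfg = SimConfig(
    seed=1,
    sweeps=[SweepSpec(start=5_000_001, end=5_100_000, target_pops=("Egypt",), beta=0.9)],
)
panel, popmap, truths = simulate_panel(cfg)
freqs = allele_frequencies(panel, popmap)
selected = divergent_sites(freqs, high=0.6, low=0.3, min_called_ind=3)

for pop in popmap.populations:
    print(f"{pop:<14} {len(selected[pop]):>4} divergent SNPs")

report = divergent_site_report(panel, freqs, selected)
t = truths[0]
in_sweep = report[
    (report["pos"] >= t.start) & (report["pos"] <= t.end) & (report["population"] == "Egypt")
]
print()
print(in_sweep.head(8).to_string(index=False))
print()
print(
    f"{len(in_sweep)} of Egypt's divergent SNPs fall inside the injected\n"
    f"{t.start:,}-{t.end:,} interval, where the donor haplotype pushed ALT\n"
    "frequencies past 0.6 while every other country stayed below 0.3; the\n"
    "remaining hits are background drift at the Balding-Nichols F = 0.05."
)
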