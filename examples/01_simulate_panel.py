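"""Simulate a six-population genotype panel with injected sweeps.

Generates the standard synthetic study: 6 countries x 5 diploid Holstein-
Friesian-like samples, 30,000 biallelic SNPs on a 10 Mb chromosome with
background differentiation F = 0.05, and five 100 kb hard sweeps injected
into the tropical group (Egypt + Uganda).  Writes a phased VCF, the
population map and the sweep truth table.
"""

from sweepscan import SimConfig, simulate_study

cfg = SimConfig(seed=1)
paths = simulate_study(cfg, "scratch/example_sim")

print(f"panel VCF     : {paths['vcf']}")
print(f"population map: {paths['popmap']}")
print(f"sweep truth   : {paths['truth']}")
print()
with open(paths["truth"]) as fh:
    print(fh.read().rstrip())
print()
print(
    "Each truth row is one injected hard sweep: inside [start, end] a\n"
    "fraction beta of the tropical group's haplotypes was replaced by one\n"
    "donor haplotype, creating the frequency/diversity/homozygosity\n"
    "signature the scans test for."
)
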