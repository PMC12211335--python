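"""Synthetic multi-population genotype panels with injected selective sweeps.

The neutral background follows the Balding-Nichols model: each site draws an
ancestral frequency p ~ Uniform(range), each population draws its own
frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) — so the drift parameter F equals
the expected Fst among populations — and phased haplotype alleles are
Bernoulli draws at the population frequency.  Sites are unlinked, which makes
neutral haplotype homozygosity decay immediately and leaves sweep injection
as the only source of long shared haplotypes.

A hard sweep is injected by copying one donor haplotype over a fraction beta
of the target group's haplotypes inside an interval, jointly producing the
three sweep signatures the scans test for: shifted allele frequencies
(Fst), reduced diversity (pi ratio) and one long high-frequency haplotype
(XP-EHH).

The default configuration mirrors the study design the package emulates:
six populations of five diploid individuals, a tropical group of two
populations carrying five 100 kb sweeps at beta = 0.9 on a 10 Mb chromosome
with 30,000 SNPs and background F = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel, PanelError, PopulationMap
from .vcf_io import write_population_map, write_vcf

DEFAULT_POPS = ("Egypt", "Uganda", "Finland", "Netherlands", "Portugal", "SouthAfrica")
DEFAULT_GROUPS = {
    "tropical": {"Egypt", "Uganda"},
    "cold": {"Finland", "Netherlands"},
}


@dataclass
class SweepSpec:
    """One injected hard sweep: interval, target populations, haplotype fraction."""

    start: int
    end: int
    target_pops: tuple[str, ...] = ("Egypt", "Uganda")
    beta: float = 0.9
    chrom: str = "1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise PanelError(f"sweep fraction beta {self.beta} outside [0, 1]")
        if self.start > self.end:
            raise PanelError("sweep interval start > end")


@dataclass
class SweepTruth:
    """Simulator record of an injected sweep, the ground truth for recovery tests."""

    chrom: str
    start: int
    end: int
    target_pops: tuple[str, ...]
    beta: float
    donor_haplotype: int
    n_replaced: int


def default_sweeps(
    chrom_length: int = 10_000_000,
    n_sweeps: int = 5,
    sweep_length: int = 100_000,
    target_pops: tuple[str, ...] = ("Egypt", "Uganda"),
    beta: float = 0.9,
) -> list[SweepSpec]:
    """Evenly spaced non-overlapping sweep intervals along the chromosome."""
    spacing = chrom_length // (n_sweeps + 1)
    specs = []
    for i in range(1, n_sweeps + 1):
        start = i * spacing + 1
        specs.append(
            SweepSpec(start=start, end=start + sweep_length - 1, target_pops=target_pops, beta=beta)
        )
    return specs


@dataclass
class SimConfig:
    """Generator parameters; the defaults emulate the study panel."""

    n_pops: int = 6
    samples_per_pop: int = 5
    chrom_length: int = 10_000_000
    n_sites: int = 30_000
    background_f: float = 0.05
    anc_freq_range: tuple[float, float] = (0.05, 0.95)
    pop_names: tuple[str, ...] = DEFAULT_POPS
    groups: dict[str, set[str]] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    sweeps: list[SweepSpec] = field(default_factory=default_sweeps)
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self) -> None:
        if not 0.0 < self.background_f < 1.0:
            raise PanelError(f"background F {self.background_f} outside (0, 1)")
        if len(self.pop_names) != self.n_pops:
            raise PanelError("pop_names length does not match n_pops")
        ivals = sorted((s.start, s.end) for s in self.sweeps)
        for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise PanelError("sweep intervals overlap")
        for s in self.sweeps:
            if s.end > self.chrom_length:
                raise PanelError("sweep interval extends beyond the chromosome")


def simulate_neutral(config: SimConfig) -> tuple[GenotypePanel, PopulationMap]:
    """Draw a neutral Balding-Nichols panel; fully reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    S = config.n_sites
    positions = np.sort(rng.choice(config.chrom_length, size=S, replace=False)) + 1
    lo, hi = config.anc_freq_range
    p_anc = rng.uniform(lo, hi, size=S)
    F = config.background_f
    shape = (1.0 - F) / F

    n_ind = config.n_pops * config.samples_per_pop
    calls = np.empty((n_ind, S, 2), dtype=np.int8)
    for k in range(config.n_pops):
        p_pop = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        rows = slice(k * config.samples_per_pop, (k + 1) * config.samples_per_pop)
        calls[rows] = (
            rng.random((config.samples_per_pop, S, 2)) < p_pop[None, :, None]
        ).astype(np.int8)

    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = bases[rng.integers(0, 4, size=S)]
    alt = bases[(np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in ref]) + rng.integers(1, 4, size=S)) % 4]

    samples = [
        f"{pop}_{i + 1}" for pop in config.pop_names for i in range(config.samples_per_pop)
    ]
    panel = GenotypePanel(
        chroms=np.array([config.chrom] * S, dtype=object),
        positions=positions.astype(np.int64),
        ref=ref,
        alt=alt,
        calls=calls,
        phased=np.ones(S, dtype=bool),
        samples=samples,
    )
    assignment = {
        s: pop for pop in config.pop_names for s in samples if s.startswith(pop + "_")
    }
    popmap = PopulationMap(assignment=assignment, groups=dict(config.groups))
    return panel, popmap


def inject_sweep(
    panel: GenotypePanel,
    popmap: PopulationMap,
    spec: SweepSpec,
    rng: np.random.Generator,
) -> tuple[GenotypePanel, SweepTruth]:
    """Copy one donor haplotype over a fraction beta of target haplotypes in the interval.

    Non-target populations are untouched.  The donor is chosen uniformly
    among the target group's haplotypes and is always among the replaced set;
    the replaced count is beta times the target haplotype count, rounded to
    nearest.  Returns a new panel (the input is not modified) and the truth
    record.
    """
    target_samples = popmap.samples_of(set(spec.target_pops))
    if not target_samples:
        raise PanelError(f"no samples in target populations {spec.target_pops}")
    idx = panel.sample_indices(target_samples)
    sites = np.flatnonzero(
        (panel.chroms == spec.chrom)
        & (panel.positions >= spec.start)
        & (panel.positions <= spec.end)
    )
    n_hap = 2 * idx.size
    donor = int(rng.integers(0, n_hap))
    n_replace = int(round(spec.beta * n_hap))

    calls = panel.calls.copy()
    truth = SweepTruth(
        chrom=spec.chrom,
        start=spec.start,
        end=spec.end,
        target_pops=tuple(spec.target_pops),
        beta=spec.beta,
        donor_haplotype=donor,
        n_replaced=n_replace,
    )
    if n_replace > 0 and sites.size > 0:
        others = np.setdiff1d(np.arange(n_hap), [donor])
        chosen = np.concatenate(
            [[donor], rng.choice(others, size=n_replace - 1, replace=False)]
        ) if n_replace > 1 else np.array([donor])
        donor_alleles = calls[idx[donor // 2]][sites, donor % 2]
        for hap in chosen:
            calls[idx[hap // 2], sites, hap % 2] = donor_alleles
    out = GenotypePanel(
        chroms=panel.chroms,
        positions=panel.positions,
        ref=panel.ref,
        alt=panel.alt,
        calls=calls,
        phased=panel.phased,
        samples=list(panel.samples),
    )
    return out, truth


def simulate_panel(config: SimConfig) -> tuple[GenotypePanel, PopulationMap, list[SweepTruth]]:
    """Neutral background plus every configured sweep, in one call."""
    panel, popmap = simulate_neutral(config)
    rng = np.random.default_rng((config.seed, 0x5EED))
    truths = []
    for spec in config.sweeps:
        panel, truth = inject_sweep(panel, popmap, spec, rng)
        truths.append(truth)
    return panel, popmap, truths


def write_truth(truths: list[SweepTruth], path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "target_pops": ",".join(t.target_pops),
                "beta": t.beta,
                "donor_haplotype": t.donor_haplotype,
                "n_replaced": t.n_replaced,
            }
            for t in truths
        ]
    ).to_csv(path, sep="\t", index=False)


def simulate_study(config: SimConfig, outdir) -> dict[str, Path]:
    """Write the full synthetic study: phased VCF, population map, sweep truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, popmap, truths = simulate_panel(config)
    paths = {
        "vcf": outdir / "panel.vcf",
        "popmap": outdir / "popmap.tsv",
        "truth": outdir / "sweep_truth.tsv",
    }
    write_vcf(panel, paths["vcf"], contig_lengths={config.chrom: config.chrom_length})
    write_population_map(popmap, paths["popmap"])
    write_truth(truths, paths["truth"])
    return paths
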