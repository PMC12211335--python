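import numpy as np
import pytest

from sweepscan import GenotypePanel, PopulationMap


def panel_from_genotypes(genotypes, positions=None, chrom="1", phased=True, samples=None):
    """Build a small panel from a per-site list of genotype pairs.

    ``genotypes[j][i]`` is the (a, b) allele pair of sample i at site j, with
    (-1, -1) for missing.
    """
    n_sites = len(genotypes)
    n_samples = len(genotypes[0])
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"S{i + 1}" for i in range(n_samples)]
    calls = np.array(genotypes, dtype=np.int8).transpose(1, 0, 2)
    return GenotypePanel(
        chroms=np.array([chrom] * n_sites, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["C"] * n_sites, dtype=object),
        calls=calls,
        phased=np.full(n_sites, phased, dtype=bool),
        samples=samples,
    )


def six_pop_map(samples_per_pop=5, pops=("Egypt", "Uganda", "Finland", "Netherlands", "Portugal", "SouthAfrica")):
    assignment = {
        f"{p}_{i + 1}": p for p in pops for i in range(samples_per_pop)
    }
    return PopulationMap(
        assignment=assignment,
        groups={"tropical": {"Egypt", "Uganda"}, "cold": {"Finland", "Netherlands"}},
    )


@pytest.fixture
def make_panel():
    return panel_from_genotypes


@pytest.fixture
def popmap30():
    """Six populations of five diploid samples each."""
    return six_pop_map()
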