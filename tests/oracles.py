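"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take different computational routes from the package:

* WC84 via the ANOVA mean-squares decomposition computed from raw genotype
  tallies (allele indicators per individual), instead of the closed-form
  component expressions.
* EHH via explicit enumeration of all haplotype pairs.
* Nucleotide diversity via the average number of pairwise differences.
"""

import itertools

import numpy as np


def wc84_anova(genotypes_per_pop):
    """(a, b, c) from per-population lists of diploid ALT-dosage genotypes.

    Mean-squares route: SSG (within individuals) from heterozygosity, SSI
    (among individuals within populations) from individual dosages, SSP
    (among populations) from sample frequencies.
    """
    r = len(genotypes_per_pop)
    n = np.array([len(g) for g in genotypes_per_pop], dtype=float)
    N = n.sum()
    p = np.array([np.mean(g) / 2.0 for g in genotypes_per_pop])
    p_bar = (n * p).sum() / N

    ssg = sum((np.array(g) == 1).sum() for g in genotypes_per_pop) * 0.5
    msg = ssg / N

    ssi = 0.0
    for g, pi in zip(genotypes_per_pop, p):
        ssi += (2.0 * (np.array(g) / 2.0 - pi) ** 2).sum()
    msi = ssi / (N - r)

    ssp = (2.0 * n * (p - p_bar) ** 2).sum()
    msp = ssp / (r - 1)

    n_bar = N / r
    n_c = (N - (n**2).sum() / N) / (r - 1)
    c = msg
    b = (msi - msg) / 2.0
    a = (msp - msi) / (2.0 * n_c)
    return a, b, c


def ehh_pairs(H, core, target):
    """EHH at ``target`` from ``core`` by enumerating all haplotype pairs."""
    lo, hi = min(core, target), max(core, target)
    idents = 0
    pairs = list(itertools.combinations(range(H.shape[0]), 2))
    for i, j in pairs:
        if np.array_equal(H[i, lo : hi + 1], H[j, lo : hi + 1]):
            idents += 1
    return idents / len(pairs)


def pi_pairwise(haplotype_alleles):
    """Mean pairwise differences at one site from the list of allele calls."""
    diffs = 0
    pairs = list(itertools.combinations(haplotype_alleles, 2))
    for x, y in pairs:
        diffs += int(x != y)
    return diffs / len(pairs)


def random_genotype_site(rng, n_pops=None):
    """Random per-population diploid genotype lists for oracle comparisons."""
    r = n_pops or int(rng.integers(2, 7))
    out = []
    for _ in range(r):
        n_i = int(rng.integers(3, 26))
        p = rng.uniform(0.02, 0.98)
        hap = rng.random((n_i, 2)) < p
        out.append(hap.sum(axis=1).astype(int).tolist())
    return out


def summaries_from_genotypes(genotypes_per_pop):
    """(n, p, h) per population, the inputs of the closed-form route."""
    n = [len(g) for g in genotypes_per_pop]
    p = [np.mean(g) / 2.0 for g in genotypes_per_pop]
    h = [np.mean(np.array(g) == 1) for g in genotypes_per_pop]
    return n, p, h
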