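"""Site filtering and the allele-frequency divergence screen.

Two filtering regimes are implemented:

* :func:`qc_filter` — the quality-control pass applied once after variant
  calling: drop sites with a missing-genotype rate above 5% or a pooled minor
  allele frequency below 5%.
* :func:`scan_filter` — the stricter pre-scan pass: missing rate at most 5%
  AND missing-genotype count at most 2, applied as a conjunction of keep
  conditions.

The divergence screen flags SNPs whose ALT frequency is high (>= 0.6) in one
focal population while staying low (< 0.3) in every other population — a
signature of a locally advantageous allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel, PanelError, PopulationMap


@dataclass
class FilterStats:
    """Per-criterion removal counts from a filtering pass."""

    n_in: int
    n_out: int
    removed_missing_rate: int = 0
    removed_maf: int = 0
    removed_missing_count: int = 0


@dataclass
class SiteFrequencyTable:
    """Per-site, per-population allele counts and frequencies.

    All arrays have shape ``(n_pops, n_sites)``.  ``alt_freq`` is NaN where a
    population has zero called individuals at a site.
    """

    populations: list[str]
    n_ind_called: np.ndarray
    alt_count: np.ndarray
    het_count: np.ndarray

    @property
    def n_hap_called(self) -> np.ndarray:
        return 2 * self.n_ind_called

    @property
    def alt_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_ind_called > 0, self.alt_count / (2.0 * self.n_ind_called), np.nan
            )


def _pooled_counts(panel: GenotypePanel, sample_idx=None):
    calls = panel.calls if sample_idx is None else panel.calls[sample_idx]
    missing = (calls == -1).any(axis=2)
    alt = np.where(missing[..., None], 0, calls).sum(axis=2)
    n_called = (~missing).sum(axis=0)
    alt_count = np.where(missing, 0, alt).sum(axis=0)
    return n_called, alt_count, missing


def qc_filter(
    panel: GenotypePanel, max_missing_rate: float = 0.05, min_maf: float = 0.05
) -> tuple[GenotypePanel, FilterStats]:
    """Drop sites with missing rate > ``max_missing_rate`` or pooled MAF < ``min_maf``.

    MAF is computed over called alleles pooled across all samples.  Returns the
    filtered panel and per-criterion removal counts (a site failing both rules
    is counted under each).
    """
    n = panel.n_samples
    n_called, alt_count, _ = _pooled_counts(panel)
    miss_rate = (n - n_called) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt_count / (2.0 * n_called), np.nan)
    maf = np.fmin(freq, 1.0 - freq)
    fail_miss = miss_rate > max_missing_rate
    fail_maf = ~(maf >= min_maf)  # NaN (no calls) fails
    keep = ~(fail_miss | fail_maf)
    stats = FilterStats(
        n_in=panel.n_sites,
        n_out=int(keep.sum()),
        removed_missing_rate=int(fail_miss.sum()),
        removed_maf=int(fail_maf.sum()),
    )
    return panel.subset_sites(keep), stats


def scan_filter(
    panel: GenotypePanel, max_missing_rate: float = 0.05, max_missing_count: int = 2
) -> tuple[GenotypePanel, FilterStats]:
    """Keep sites with missing rate <= ``max_missing_rate`` AND missing count <= ``max_missing_count``."""
    n = panel.n_samples
    n_called, _, _ = _pooled_counts(panel)
    n_missing = n - n_called
    fail_rate = n_missing / n > max_missing_rate
    fail_count = n_missing > max_missing_count
    keep = ~(fail_rate | fail_count)
    stats = FilterStats(
        n_in=panel.n_sites,
        n_out=int(keep.sum()),
        removed_missing_rate=int(fail_rate.sum()),
        removed_missing_count=int(fail_count.sum()),
    )
    return panel.subset_sites(keep), stats


def allele_frequencies(panel: GenotypePanel, popmap: PopulationMap) -> SiteFrequencyTable:
    """Tabulate per-population called counts, ALT counts and heterozygote counts."""
    pops = popmap.populations
    for pop in pops:
        if not popmap.samples_of(pop):
            raise PanelError(f"population {pop!r} has no samples")
    n_ind = np.zeros((len(pops), panel.n_sites), dtype=np.int64)
    alt = np.zeros_like(n_ind)
    het = np.zeros_like(n_ind)
    for k, pop in enumerate(pops):
        idx = panel.sample_indices(popmap.samples_of(pop))
        calls = panel.calls[idx]
        missing = (calls == -1).any(axis=2)
        n_ind[k] = (~missing).sum(axis=0)
        alt[k] = np.where(missing, 0, calls.sum(axis=2)).sum(axis=0)
        het[k] = (~missing & (calls[..., 0] != calls[..., 1])).sum(axis=0)
    return SiteFrequencyTable(
        populations=list(pops), n_ind_called=n_ind, alt_count=alt, het_count=het
    )


def divergent_sites(
    freqs: SiteFrequencyTable,
    high: float = 0.6,
    low: float = 0.3,
    min_called_ind: int = 3,
    allele: str = "alt",
) -> dict[str, np.ndarray]:
    """Per-population sets of divergent sites.

    A site is selected for population P when P's allele frequency is
    ``>= high`` with at least ``min_called_ind`` called individuals, and every
    other population's frequency is strictly ``< low`` (an undefined frequency
    disqualifies the site).  ``allele="alt"`` screens the ALT allele only;
    ``allele="both"`` also accepts sites satisfying the mirrored REF-allele
    criterion.
    """
    if high < low:
        raise PanelError(f"high cutoff {high} below low cutoff {low}")
    if allele not in ("alt", "both"):
        raise PanelError(f"allele must be 'alt' or 'both', got {allele!r}")

    def _screen(f: np.ndarray) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for k, pop in enumerate(freqs.populations):
            others = np.delete(np.arange(len(freqs.populations)), k)
            focal_ok = (f[k] >= high) & (freqs.n_ind_called[k] >= min_called_ind)
            others_f = f[others]
            others_ok = np.all(~np.isnan(others_f) & (others_f < low), axis=0)
            out[pop] = np.flatnonzero(focal_ok & others_ok)
        return out

    result = _screen(freqs.alt_freq)
    if allele == "both":
        mirrored = _screen(1.0 - freqs.alt_freq)
        result = {
            pop: np.union1d(result[pop], mirrored[pop]) for pop in freqs.populations
        }
    # high >= low makes double selection impossible; assert the invariant
    all_sets = list(result.values())
    for i in range(len(all_sets)):
        for j in range(i + 1, len(all_sets)):
            assert not np.intersect1d(all_sets[i], all_sets[j]).size
    return result


def divergent_site_report(
    panel: GenotypePanel, freqs: SiteFrequencyTable, selected: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Flat table of divergent sites: chrom, pos, focal population, focal and max-other AF."""
    rows = []
    f = freqs.alt_freq
    for pop, sites in selected.items():
        k = freqs.populations.index(pop)
        others = np.delete(np.arange(len(freqs.populations)), k)
        for j in sites:
            rows.append(
                {
                    "chrom": panel.chroms[j],
                    "pos": int(panel.positions[j]),
                    "population": pop,
                    "focal_af": float(f[k, j]),
                    "max_other_af": float(np.nanmax(f[others, j])),
                }
            )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "population", "focal_af", "max_other_af"])
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
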