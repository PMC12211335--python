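"""Core in-memory containers for the scan pipeline.

The central object is :class:`GenotypePanel`, a dense matrix of biallelic SNP
genotypes for all samples, with per-site chromosome, position, alleles and a
phase flag.  Genotypes are stored as allele indices (0 = REF, 1 = ALT) with
``-1`` marking a missing allele; half-missing calls are normalised to fully
missing on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


class PanelError(ValueError):
    """Malformed panel, map or annotation input."""


class PhaseError(PanelError):
    """Phased genotypes required but unphased records present."""


@dataclass
class GenotypePanel:
    """Biallelic SNP genotypes for a set of diploid samples.

    Attributes
    ----------
    chroms : ndarray of str, shape (n_sites,)
        Chromosome name per site; sites are grouped by chromosome.
    positions : ndarray of int64, shape (n_sites,)
        1-based coordinates, strictly increasing within each chromosome.
    ref, alt : ndarray of str, shape (n_sites,)
        Single-base REF and ALT alleles.
    calls : ndarray of int8, shape (n_samples, n_sites, 2)
        Allele indices per sample and site; both entries are ``-1`` when the
        genotype is missing (no half-missing calls).
    phased : ndarray of bool, shape (n_sites,)
        True where every genotype at the site used the phased separator.
    samples : list of str
        Ordered sample names.
    """

    chroms: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    phased: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.phased = np.asarray(self.phased, dtype=bool)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise PanelError("calls must have shape (n_samples, n_sites, 2)")
        if self.calls.shape[0] != len(self.samples):
            raise PanelError("calls row count does not match sample count")
        if self.calls.shape[1] != len(self.positions):
            raise PanelError("calls column count does not match site count")
        # normalise half-missing genotypes to fully missing
        half = (self.calls == MISSING).any(axis=2) & ~(self.calls == MISSING).all(axis=2)
        if half.any():
            self.calls[half] = MISSING
        for chrom in self.chrom_ids:
            pos = self.positions[self.chroms == chrom]
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise PanelError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def chrom_ids(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chroms:
            seen.setdefault(str(c), None)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_sites): True where the genotype is missing."""
        return (self.calls == MISSING).any(axis=2)

    def subset_sites(self, mask: np.ndarray) -> "GenotypePanel":
        """Return a panel restricted to the sites where ``mask`` is True."""
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_sites, dtype=bool)
            idx[mask] = True
            mask = idx
        return GenotypePanel(
            chroms=self.chroms[mask],
            positions=self.positions[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            calls=self.calls[:, mask, :],
            phased=self.phased[mask],
            samples=list(self.samples),
        )

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise PanelError(f"sample {exc.args[0]!r} not in panel") from exc


@dataclass
class PopulationMap:
    """Sample-to-population assignment plus named population groups.

    ``groups`` maps a group name (e.g. ``"tropical"``) to a set of population
    labels; group label sets must be pairwise disjoint.
    """

    assignment: dict[str, str]
    groups: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [set(v) for v in self.groups.values()]
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                common = labels[i] & labels[j]
                if common:
                    raise PanelError(f"groups share population labels: {sorted(common)}")

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.assignment.values():
            seen.setdefault(p, None)
        return list(seen)

    def samples_of(self, labels) -> list[str]:
        """Samples belonging to any of the given population labels, in map order."""
        if isinstance(labels, str):
            labels = {labels}
        labels = set(labels)
        return [s for s, p in self.assignment.items() if p in labels]

    def group_labels(self, group: str) -> set[str]:
        try:
            return set(self.groups[group])
        except KeyError as exc:
            raise PanelError(f"unknown group {group!r}") from exc


@dataclass
class GeneAnnotation:
    """Gene records (chrom, start, end, strand, name); 1-based inclusive."""

    chrom: list[str]
    start: np.ndarray
    end: np.ndarray
    strand: list[str]
    gene_name: list[str]

    def __len__(self) -> int:
        return len(self.gene_name)


@dataclass
class CandidateRegion:
    """A merged genomic interval flagged by a scan.

    ``start``/``end`` are 1-based inclusive and span the union of the member
    windows.  ``stats`` holds the per-method peak statistics contributing to
    the call; ``genes`` is filled by annotation.
    """

    chrom: str
    start: int
    end: int
    n_windows: int
    peak_stat: float
    label: str
    stats: dict[str, float] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start + 1
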