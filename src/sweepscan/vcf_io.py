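"""File-format frontends: VCF, population map TSV, BED export, GFF3 genes.

Only biallelic SNP records enter the panel; indels and multiallelic records
are skipped and counted.  Internal coordinates are 1-based inclusive (VCF
convention); BED export converts to 0-based half-open.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .panel import (
    MISSING,
    CandidateRegion,
    GeneAnnotation,
    GenotypePanel,
    PanelError,
    PhaseError,
    PopulationMap,
)


def read_vcf(path, require_phased: bool = False) -> tuple[GenotypePanel, int]:
    """Read a VCF/VCF.gz into a :class:`GenotypePanel`.

    Returns ``(panel, n_skipped)`` where ``n_skipped`` counts records dropped
    for not being biallelic SNPs.  With ``require_phased``, any retained
    genotype written with the unphased separator raises :class:`PhaseError`
    naming the first offending record.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise PanelError(f"{path}: VCF has no samples / GT field")

    chroms: list[str] = []
    positions: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    calls: list[np.ndarray] = []
    phased: list[bool] = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        gts = np.array(rec.genotypes, dtype=np.int64)  # (n_samples, 3): a0, a1, phased
        if gts.shape[1] < 3:
            raise PanelError(f"{path}: record {rec.CHROM}:{rec.POS} lacks a diploid GT")
        site = gts[:, :2].astype(np.int8)
        missing = (site == MISSING).any(axis=1)
        site[missing] = MISSING
        site_phased = bool(gts[~missing, 2].all()) if (~missing).any() else True
        if require_phased and not site_phased:
            raise PhaseError(
                f"{path}: unphased genotype at {rec.CHROM}:{rec.POS} "
                "but phased input required"
            )
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        calls.append(site)
        phased.append(site_phased)
    vcf.close()

    n_sites = len(positions)
    call_matrix = (
        np.stack(calls, axis=1) if n_sites else np.zeros((len(samples), 0, 2), np.int8)
    )
    panel = GenotypePanel(
        chroms=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        calls=call_matrix,
        phased=np.array(phased, dtype=bool),
        samples=samples,
    )
    return panel, skipped


def write_vcf(panel: GenotypePanel, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write the panel as a minimal VCF 4.2 text file (``.gz`` -> bgzip-free gzip)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.chrom_ids:
            if contig_lengths and chrom in contig_lengths:
                fh.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        for j in range(panel.n_sites):
            sep = "|" if panel.phased[j] else "/"
            gts = []
            for i in range(panel.n_samples):
                a, b = panel.calls[i, j]
                if a == MISSING:
                    gts.append(f".{sep}.")
                else:
                    gts.append(f"{a}{sep}{b}")
            fh.write(
                f"{panel.chroms[j]}\t{panel.positions[j]}\t.\t{panel.ref[j]}\t"
                f"{panel.alt[j]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_population_map(path, panel: GenotypePanel) -> PopulationMap:
    """Read a ``sample<TAB>population[<TAB>group]`` TSV covering the panel's samples."""
    assignment: dict[str, str] = {}
    group_of_pop: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise PanelError(f"{path}:{lineno}: expected at least 2 tab-separated columns")
            sample, pop = fields[0], fields[1]
            if sample in assignment:
                raise PanelError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignment[sample] = pop
            if len(fields) >= 3 and fields[2]:
                group_of_pop[pop] = fields[2]
    missing = [s for s in panel.samples if s not in assignment]
    if missing:
        raise PanelError(f"{path}: samples missing from population map: {missing}")
    assignment = {s: assignment[s] for s in panel.samples}
    groups: dict[str, set[str]] = {}
    for pop, grp in group_of_pop.items():
        groups.setdefault(grp, set()).add(pop)
    return PopulationMap(assignment=assignment, groups=groups)


def write_population_map(popmap: PopulationMap, path) -> None:
    group_of_pop = {p: g for g, pops in popmap.groups.items() for p in pops}
    with open(path, "w") as fh:
        for sample, pop in popmap.assignment.items():
            grp = group_of_pop.get(pop, "")
            fh.write(f"{sample}\t{pop}\t{grp}\n" if grp else f"{sample}\t{pop}\n")


def write_regions_bed(regions: list[CandidateRegion], path) -> None:
    """Write candidate regions as BED6 (0-based half-open; score = peak statistic)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.label}\t{r.peak_stat:.6g}\t.\n")


def _parse_gff_attributes(col: str, path, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in col.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise PanelError(f"{path}:{lineno}: malformed GFF3 attribute {item!r}")
        key, _, value = item.partition("=")
        attrs[key] = value
    return attrs


def read_gff_genes(path) -> GeneAnnotation:
    """Read ``gene``-type records from a GFF3 file.

    The gene name is taken from the ``Name=`` attribute, falling back to
    ``ID=``.  A gene with ``start > end`` or a malformed attribute column is a
    parse error reporting the line number.
    """
    chrom: list[str] = []
    start: list[int] = []
    end: list[int] = []
    strand: list[str] = []
    names: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise PanelError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            if cols[2] != "gene":
                continue
            s, e = int(cols[3]), int(cols[4])
            if s > e:
                raise PanelError(f"{path}:{lineno}: gene start {s} > end {e}")
            attrs = _parse_gff_attributes(cols[8], path, lineno)
            name = attrs.get("Name") or attrs.get("ID")
            if name is None:
                raise PanelError(f"{path}:{lineno}: gene record lacks Name= and ID=")
            chrom.append(cols[0])
            start.append(s)
            end.append(e)
            strand.append(cols[6])
            names.append(name)
    return GeneAnnotation(
        chrom=chrom,
        start=np.array(start, dtype=np.int64),
        end=np.array(end, dtype=np.int64),
        strand=strand,
        gene_name=names,
    )
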