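"""Threshold selection, peak calling and the two genome scans.

Two scans are provided:

* :func:`within_country_scan` — one-vs-rest windowed weighted Fst per
  population (50 kb windows, 25 kb step), nearest-rank top-0.1% threshold per
  scan, and a peak rule requiring at least three consecutive outlier windows.
* :func:`sweep_scan` — the tropical-vs-cold three-statistic intersection on a
  shared non-overlapping 25 kb scheme: a window is a sweep candidate iff its
  weighted Fst and pi ratio each reach their top-1% thresholds AND its
  windowed XP-EHH statistic exceeds 2.  Adjacent candidate windows merge;
  single-window sweeps are allowed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import pi_ratio, windowed_pi
from .fst import windowed_weighted_fst
from .haplotype import windowed_xpehh, xpehh_scan
from .panel import CandidateRegion, GeneAnnotation, GenotypePanel, PanelError, PopulationMap


@dataclass
class ScanConfig:
    """Parameters of the two scans and the shared filters."""

    # within-country signature scan
    within_window: int = 50_000
    within_step: int = 25_000
    within_top_fraction: float = 0.001
    min_consecutive: int = 3
    # tropical-vs-cold sweep scan
    sweep_window: int = 25_000
    fst_top_fraction: float = 0.01
    ratio_top_fraction: float = 0.01
    xpehh_threshold: float = 2.0
    xpehh_stat: str = "xpehh_mean"
    # shared
    min_sites: int = 1
    epsilon: float = 1e-8
    ehh_cutoff: float = 0.05
    max_extend: int = 1_000_000

    def __post_init__(self) -> None:
        for f in (self.within_top_fraction, self.fst_top_fraction, self.ratio_top_fraction):
            if not 0 < f < 1:
                raise PanelError(f"top fraction {f} outside (0, 1)")
        if not math.isfinite(self.xpehh_threshold):
            raise PanelError("xpehh threshold must be finite")


@dataclass
class ScanResult:
    """Regions plus the thresholds and window tables behind them."""

    regions: list[CandidateRegion]
    thresholds: dict[str, float]
    windows: dict[str, pd.DataFrame] = field(default_factory=dict)


def quantile_threshold(values, top_fraction: float) -> float:
    """Nearest-rank upper quantile: the k-th largest value, k = ceil(f * n).

    Windows with value >= the returned threshold are outliers, so at least a
    ``top_fraction`` share of windows qualifies (ties included).
    """
    values = np.asarray(values, dtype=np.float64)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise PanelError("cannot take a quantile of an empty vector")
    k = math.ceil(top_fraction * values.size)
    return float(np.sort(values)[::-1][k - 1])


def call_peaks(
    windows: pd.DataFrame,
    threshold: float,
    stat: str = "weighted_fst",
    min_consecutive: int = 3,
    step: int | None = None,
    label: str = "peak",
) -> list[CandidateRegion]:
    """Merge runs of >= ``min_consecutive`` consecutive outlier windows.

    Windows are consecutive when they are adjacent under the scheme's step
    (successive starts differ by ``step``, inferred from the table when not
    given).  Region span is the union of member windows; ``peak_stat`` is the
    maximum member statistic.
    """
    if windows.empty:
        return []
    windows = windows.sort_values(["chrom", "start"], kind="stable")
    if step is None:
        diffs = windows.groupby("chrom", sort=False)["start"].diff().dropna()
        step = int(diffs.min()) if len(diffs) else int(
            windows["end"].iloc[0] - windows["start"].iloc[0] + 1
        )
    regions: list[CandidateRegion] = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        hot = sub[sub[stat] >= threshold]
        if hot.empty:
            continue
        starts = hot["start"].to_numpy()
        run_start = 0
        for i in range(1, len(hot) + 1):
            if i == len(hot) or starts[i] - starts[i - 1] != step:
                run = hot.iloc[run_start:i]
                if len(run) >= min_consecutive:
                    regions.append(
                        CandidateRegion(
                            chrom=str(chrom),
                            start=int(run["start"].min()),
                            end=int(run["end"].max()),
                            n_windows=len(run),
                            peak_stat=float(run[stat].max()),
                            label=label,
                            stats={stat: float(run[stat].max())},
                        )
                    )
                run_start = i
    return regions


def within_country_scan(
    panel: GenotypePanel, popmap: PopulationMap, config: ScanConfig | None = None
) -> dict[str, ScanResult]:
    """One-vs-rest signature scan for every population.

    Each country is contrasted against all remaining samples pooled (a
    two-population weighted Fst).  Thresholds are nearest-rank top fractions
    of each country's own window distribution, so countries with weaker
    overall differentiation get lower cutoffs.
    """
    config = config or ScanConfig()
    pops = popmap.populations
    if len(pops) < 2:
        raise PanelError("within-country scan needs at least 2 populations")
    results: dict[str, ScanResult] = {}
    for pop in pops:
        rest = {p for p in pops if p != pop}
        windows = windowed_weighted_fst(
            panel,
            popmap,
            [{pop}, rest],
            window_size=config.within_window,
            step=config.within_step,
            min_sites=config.min_sites,
        )
        threshold = quantile_threshold(windows["weighted_fst"], config.within_top_fraction)
        regions = call_peaks(
            windows,
            threshold,
            stat="weighted_fst",
            min_consecutive=config.min_consecutive,
            step=config.within_step,
            label=pop,
        )
        results[pop] = ScanResult(
            regions=regions,
            thresholds={"weighted_fst": threshold},
            windows={"fst": windows},
        )
    return results


def sweep_scan(
    panel: GenotypePanel,
    popmap: PopulationMap,
    groupA: set[str] | str,
    groupB: set[str] | str,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Three-statistic sweep intersection between candidate group A and reference B.

    On the shared non-overlapping window scheme a window qualifies iff
    weighted Fst >= its top-1% threshold, pi ratio (B over A) >= its top-1%
    threshold, and the windowed XP-EHH statistic (A vs B) > 2.  Adjacent
    qualifying windows merge into regions carrying all three statistics.
    """
    config = config or ScanConfig()
    A = {groupA} if isinstance(groupA, str) else set(groupA)
    B = {groupB} if isinstance(groupB, str) else set(groupB)
    if A & B:
        raise PanelError("sweep scan groups must be disjoint")
    w = config.sweep_window

    fst_w = windowed_weighted_fst(
        panel, popmap, [A, B], window_size=w, step=w, min_sites=config.min_sites
    )
    pi_a = windowed_pi(panel, popmap, A, window_size=w)
    pi_b = windowed_pi(panel, popmap, B, window_size=w)
    ratio_w = pi_ratio(pi_b, pi_a, epsilon=config.epsilon)
    scores, dropped = xpehh_scan(
        panel, popmap, A, B, cutoff=config.ehh_cutoff, max_extend=config.max_extend
    )
    xp_w = windowed_xpehh(scores, window_size=w)

    fst_thr = quantile_threshold(fst_w["weighted_fst"], config.fst_top_fraction)
    ratio_thr = quantile_threshold(ratio_w["ratio"], config.ratio_top_fraction)

    keys = ["chrom", "start"]
    merged = (
        fst_w[keys + ["end", "n_sites", "weighted_fst"]]
        .merge(ratio_w[keys + ["ratio", "pi_ref", "pi_target"]], on=keys, how="inner")
        .merge(xp_w[keys + ["xpehh_mean", "xpehh_max"]], on=keys, how="inner")
    )
    xstat = config.xpehh_stat
    merged["candidate"] = (
        (merged["weighted_fst"] >= fst_thr)
        & (merged["ratio"] >= ratio_thr)
        & (merged[xstat] > config.xpehh_threshold)
    )

    regions: list[CandidateRegion] = []
    cand = merged[merged["candidate"]].sort_values(keys, kind="stable")
    for chrom, sub in cand.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        run_start = 0
        for i in range(1, len(sub) + 1):
            if i == len(sub) or starts[i] - starts[i - 1] != w:
                run = sub.iloc[run_start:i]
                regions.append(
                    CandidateRegion(
                        chrom=str(chrom),
                        start=int(run["start"].min()),
                        end=int(run["end"].max()),
                        n_windows=len(run),
                        peak_stat=float(run["weighted_fst"].max()),
                        label="sweep",
                        stats={
                            "weighted_fst": float(run["weighted_fst"].max()),
                            "pi_ratio": float(run["ratio"].max()),
                            "xpehh": float(run[xstat].max()),
                        },
                    )
                )
                run_start = i
    return ScanResult(
        regions=regions,
        thresholds={
            "weighted_fst": fst_thr,
            "pi_ratio": ratio_thr,
            "xpehh": config.xpehh_threshold,
        },
        windows={
            "merged": merged,
            "fst": fst_w,
            "pi_ratio": ratio_w,
            "xpehh": xp_w,
            "xpehh_sites": scores,
        },
    )


def annotate_regions(
    regions: list[CandidateRegion], genes: GeneAnnotation
) -> list[CandidateRegion]:
    """Attach all gene records overlapping each region by >= 1 bp (closed intervals)."""
    gene_chroms = set(genes.chrom)
    region_chroms = {r.chrom for r in regions}
    if regions and len(genes) and not (gene_chroms & region_chroms):
        import warnings

        warnings.warn(
            "no chromosome names shared between regions and gene annotation",
            stacklevel=2,
        )
    order = np.argsort(genes.start, kind="stable")
    for r in regions:
        hits = [
            genes.gene_name[i]
            for i in order
            if genes.chrom[i] == r.chrom
            and genes.start[i] <= r.end
            and genes.end[i] >= r.start
        ]
        r.genes = hits
    return regions


def regions_table(regions: list[CandidateRegion]) -> pd.DataFrame:
    """Flat report mirroring the sweep-summary layout (one row per region)."""
    rows = []
    for r in regions:
        row = {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "region_mb": f"{r.start / 1e6:.2f}-{r.end / 1e6:.2f}",
            "label": r.label,
            "n_windows": r.n_windows,
            "peak_stat": r.peak_stat,
        }
        row.update(r.stats)
        row["genes"] = ",".join(r.genes)
        rows.append(row)
    base_cols = ["chrom", "start", "end", "region_mb", "label", "n_windows", "peak_stat", "genes"]
    if not rows:
        return pd.DataFrame(columns=base_cols)
    df = pd.DataFrame(rows)
    stat_cols = [c for c in df.columns if c not in base_cols]
    return df[base_cols[:-1] + stat_cols + ["genes"]]
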