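"""EHH decay, integrated EHH and the cross-population XP-EHH scan.

EHH at distance x from a core site is the probability that two haplotypes
drawn at random from the group are identical over the interval from the core
through x.  Integrating the decay curve over physical distance in both
directions gives iHH; the log ratio of the two groups' iHH values, ln(iHH_A /
iHH_B), standardized genome-wide, is XP-EHH.  Positive standardized scores
indicate unusually long haplotype homozygosity in group A — the signature of
an incomplete or recent sweep in that group.

The cross-population convention is used throughout: each group's EHH is
computed over all of its haplotypes, unpartitioned by core allele.
Integration is over physical distance (bp); the decay cutoff (default 0.05)
and maximum extension (default 1 Mb) bound each curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd

from .fst import make_windows
from .panel import GenotypePanel, PanelError, PhaseError, PopulationMap


@dataclass
class EhhCurve:
    """One direction of an EHH decay curve from a core site.

    ``distances`` (bp from the core, starting at 0) and ``values`` (EHH,
    starting at 1.0) are parallel arrays; ``truncation`` records why the
    curve stopped: "cutoff", "chromosome_end" or "max_extend".
    """

    core: int
    direction: str
    distances: np.ndarray
    values: np.ndarray
    truncation: str


def haplotype_block(
    panel: GenotypePanel, sample_idx: np.ndarray, chrom: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phased 0/1 haplotype matrix for one chromosome and sample subset.

    Sites with any missing genotype among the chosen samples are excluded
    (complete-case rule).  Returns ``(H, positions, site_index)`` where ``H``
    has one row per haplotype (2 per diploid) and ``site_index`` maps the
    block's columns back to panel site indices.
    """
    cmask = panel.chroms == chrom
    site_idx = np.flatnonzero(cmask)
    calls = panel.calls[np.ix_(sample_idx, site_idx)]
    complete = ~(calls == -1).any(axis=(0, 2))
    site_idx = site_idx[complete]
    if not panel.phased[site_idx].all():
        bad = site_idx[~panel.phased[site_idx]][0]
        raise PhaseError(
            f"unphased genotypes at {panel.chroms[bad]}:{panel.positions[bad]}; "
            "haplotype statistics require phased input"
        )
    calls = calls[:, complete, :]
    # interleave the two haplotypes of each sample
    H = calls.transpose(0, 2, 1).reshape(-1, calls.shape[1]).astype(np.uint8)
    return H, panel.positions[site_idx], site_idx


def _ehh_values(counts: np.ndarray, n_pairs: float) -> float:
    return float((counts * (counts - 1)).sum() / 2.0 / n_pairs)


def ehh(
    H: np.ndarray,
    positions: np.ndarray,
    core: int,
    direction: str,
    cutoff: float = 0.05,
    max_extend: int = 1_000_000,
) -> EhhCurve:
    """EHH decay curve from ``core`` (a column index of ``H``) in one direction.

    At each successive site the haplotypes are partitioned by their allele
    string from the core through that site; EHH is the fraction of haplotype
    pairs still identical.  The curve starts at (0, 1.0) and stops after the
    first point below ``cutoff`` (that point included), at the chromosome
    end, or once the next site lies beyond ``max_extend`` bp.
    """
    N = H.shape[0]
    if N < 2:
        raise PanelError("EHH needs at least 2 haplotypes")
    if direction not in ("left", "right"):
        raise PanelError(f"direction must be 'left' or 'right', got {direction!r}")
    n_pairs = N * (N - 1) / 2.0
    step = 1 if direction == "right" else -1
    core_pos = int(positions[core])

    distances = [0.0]
    values = [1.0]
    labels = H[:, core].astype(np.int64)
    truncation = "chromosome_end"
    j = core + step
    while 0 <= j < H.shape[1]:
        dist = abs(int(positions[j]) - core_pos)
        if dist > max_extend:
            truncation = "max_extend"
            break
        labels = labels * 2 + H[:, j]
        _, labels, counts = np.unique(labels, return_inverse=True, return_counts=True)
        e = _ehh_values(counts, n_pairs)
        distances.append(float(dist))
        values.append(e)
        if e < cutoff:
            truncation = "cutoff"
            break
        j += step
    return EhhCurve(
        core=core,
        direction=direction,
        distances=np.array(distances),
        values=np.array(values),
        truncation=truncation,
    )


def ihh(left: EhhCurve, right: EhhCurve) -> float:
    """Integrated EHH: trapezoidal area under both decay arms, in bp.

    The final trapezoid down to the first sub-cutoff point is included.  A
    site whose curves have a single support point on both sides (no flanking
    sites) integrates to 0, the degenerate case callers drop.
    """
    total = 0.0
    for curve in (left, right):
        if len(curve.distances) >= 2:
            total += float(np.trapezoid(curve.values, curve.distances))
    return total


def _group_ihh(H, positions, core, cutoff, max_extend) -> float:
    return ihh(
        ehh(H, positions, core, "left", cutoff, max_extend),
        ehh(H, positions, core, "right", cutoff, max_extend),
    )


@numba.njit(cache=True)
def _ihh_all_cores(H, positions, cutoff, max_extend):  # pragma: no cover - jitted
    """iHH at every site of a haplotype block (fast path).

    Identical by construction to running :func:`ehh` in both directions and
    integrating with :func:`ihh`; the trapezoid down to the first sub-cutoff
    point is included and labels are re-compressed at every step.
    """
    N, S = H.shape
    n_pairs = N * (N - 1) / 2.0
    out = np.zeros(S)
    labels = np.empty(N, np.int64)
    counts = np.empty(2 * N, np.int64)
    remap = np.empty(2 * N, np.int64)
    for core in range(S):
        total = 0.0
        for direction in (-1, 1):
            for i in range(N):
                labels[i] = H[i, core]
            prev_e = 1.0
            prev_d = 0.0
            j = core + direction
            while 0 <= j < S:
                d = abs(positions[j] - positions[core])
                if d > max_extend:
                    break
                counts[:] = 0
                for i in range(N):
                    labels[i] = labels[i] * 2 + H[i, j]
                    counts[labels[i]] += 1
                pairs = 0.0
                k = 0
                for v in range(2 * N):
                    if counts[v] > 0:
                        pairs += counts[v] * (counts[v] - 1) / 2.0
                        remap[v] = k
                        k += 1
                for i in range(N):
                    labels[i] = remap[labels[i]]
                e = pairs / n_pairs
                total += (prev_e + e) / 2.0 * (d - prev_d)
                prev_e = e
                prev_d = d
                if e < cutoff:
                    break
                j += direction
        out[core] = total
    return out


def xpehh_scan(
    panel: GenotypePanel,
    popmap: PopulationMap,
    groupA: set[str] | str,
    groupB: set[str] | str,
    cutoff: float = 0.05,
    max_extend: int = 1_000_000,
) -> tuple[pd.DataFrame, int]:
    """Per-site XP-EHH between two population groups.

    Group A is the candidate group (e.g. tropical): positive standardized
    scores indicate longer haplotype homozygosity there.  Sites with missing
    genotypes in either group are excluded before haplotype construction;
    sites where either group's iHH is 0 are dropped and counted.  Returns the
    per-site table (chrom, pos, ihh_a, ihh_b, xpehh_raw, xpehh_std) and the
    dropped-site count.
    """
    labelsA = {groupA} if isinstance(groupA, str) else set(groupA)
    labelsB = {groupB} if isinstance(groupB, str) else set(groupB)
    idxA = panel.sample_indices(popmap.samples_of(labelsA))
    idxB = panel.sample_indices(popmap.samples_of(labelsB))
    if idxA.size == 0 or idxB.size == 0:
        raise PanelError("both groups need at least one sample")
    union = np.concatenate([idxA, idxB])

    rows = []
    dropped = 0
    for chrom in panel.chrom_ids:
        # shared complete-case site set across A u B keeps the cores aligned
        _, positions, site_idx = haplotype_block(panel, union, chrom)
        HA = _rows_for(panel, idxA, site_idx)
        HB = _rows_for(panel, idxB, site_idx)
        pos64 = positions.astype(np.int64)
        ihh_a_all = _ihh_all_cores(HA, pos64, cutoff, max_extend)
        ihh_b_all = _ihh_all_cores(HB, pos64, cutoff, max_extend)
        for core in range(len(positions)):
            ihh_a = float(ihh_a_all[core])
            ihh_b = float(ihh_b_all[core])
            if ihh_a == 0.0 or ihh_b == 0.0:
                dropped += 1
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(positions[core]),
                    "ihh_a": ihh_a,
                    "ihh_b": ihh_b,
                    "xpehh_raw": float(np.log(ihh_a / ihh_b)),
                }
            )
    table = pd.DataFrame(rows, columns=["chrom", "pos", "ihh_a", "ihh_b", "xpehh_raw"])
    if len(table) >= 2:
        raw = table["xpehh_raw"].to_numpy()
        sd = raw.std(ddof=0)
        table["xpehh_std"] = (raw - raw.mean()) / sd if sd > 0 else 0.0
    else:
        table["xpehh_std"] = 0.0
    return table, dropped


def _rows_for(panel: GenotypePanel, sample_idx: np.ndarray, site_idx: np.ndarray) -> np.ndarray:
    calls = panel.calls[np.ix_(sample_idx, site_idx)]
    return calls.transpose(0, 2, 1).reshape(-1, calls.shape[1]).astype(np.uint8)


def windowed_xpehh(scores: pd.DataFrame, window_size: int = 25_000) -> pd.DataFrame:
    """Aggregate per-site standardized XP-EHH into non-overlapping windows.

    Emits mean and max standardized score plus the scored-site count per
    window; windows with no scored sites are omitted.  The scan statistic
    applied downstream is the window mean by default.
    """
    rows = []
    for chrom in scores["chrom"].unique():
        sub = scores[scores["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        std = sub["xpehh_std"].to_numpy()
        for start in make_windows(pos, window_size, window_size):
            end = start + window_size - 1
            in_win = (pos >= start) & (pos <= end)
            if not in_win.any():
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "n_sites": int(in_win.sum()),
                    "xpehh_mean": float(std[in_win].mean()),
                    "xpehh_max": float(std[in_win].max()),
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "xpehh_mean", "xpehh_max"]
    )
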