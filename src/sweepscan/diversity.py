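"""Windowed nucleotide diversity (pi) and the cross-group pi ratio.

Per-site diversity is the unbiased expected heterozygosity
``2 k (n - k) / (n (n - 1))`` for ``k`` ALT alleles among ``n`` called
haplotypes.  Windowed pi divides the per-window sum by the window length in
bp (including invariant positions), the convention of windowed-diversity
tools; the ratio reference/target flags diversity loss in the target group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fst import make_windows
from .panel import GenotypePanel, PanelError, PopulationMap


def site_pi(n_hap_called: int, alt_count: int) -> float:
    """Unbiased per-site heterozygosity among ``n_hap_called`` haplotypes."""
    n = int(n_hap_called)
    k = int(alt_count)
    if n < 2:
        raise PanelError(f"site pi undefined for {n} called haplotypes")
    return 2.0 * k * (n - k) / (n * (n - 1))


def windowed_pi(
    panel: GenotypePanel,
    popmap: PopulationMap,
    group: set[str] | str,
    window_size: int = 25_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Non-overlapping windowed pi for one population group.

    Every window over the covered span is emitted (pi = 0 where no
    polymorphic called sites fall in the window).  The last window of each
    chromosome is divided by its clipped length; chromosome length defaults
    to the window end covering the last SNP.
    """
    labels = {group} if isinstance(group, str) else set(group)
    idx = panel.sample_indices(popmap.samples_of(labels))
    if idx.size == 0:
        raise PanelError(f"group {sorted(labels)} has no samples")
    calls = panel.calls[idx]
    missing = (calls == -1).any(axis=2)
    n_hap = 2 * (~missing).sum(axis=0).astype(np.float64)
    alt = np.where(missing, 0, calls.sum(axis=2)).sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(
            n_hap >= 2, 2.0 * alt * (n_hap - alt) / (n_hap * (n_hap - 1)), 0.0
        )

    rows = []
    for chrom in panel.chrom_ids:
        cmask = panel.chroms == chrom
        pos = panel.positions[cmask]
        pi_c = per_site[cmask]
        chrom_len = (chrom_lengths or {}).get(chrom)
        starts = make_windows(pos, window_size, window_size)
        for start in starts:
            end = start + window_size - 1
            if chrom_len is not None:
                end = min(end, chrom_len)
            in_win = (pos >= start) & (pos <= end)
            pi_sum = float(pi_c[in_win].sum())
            length = end - start + 1
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "n_sites": int(in_win.sum()),
                    "pi_sum": pi_sum,
                    "pi": pi_sum / length,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "pi_sum", "pi"])


def pi_ratio(
    reference_pi: pd.DataFrame, target_pi: pd.DataFrame, epsilon: float = 1e-8
) -> pd.DataFrame:
    """Per-window ratio (pi_reference + eps) / (pi_target + eps).

    Reference is the non-candidate (e.g. cold-climate) group and target the
    candidate (e.g. tropical) group, so large ratios flag diversity reduction
    in the target.  Windows where both pi values are exactly 0 get ratio 1
    (no evidence).  The two tables must share the identical windowing scheme.
    """
    if epsilon <= 0:
        raise PanelError("epsilon must be positive")
    keys = ["chrom", "start", "end"]
    if len(reference_pi) != len(target_pi) or not (
        reference_pi[keys].reset_index(drop=True).equals(
            target_pi[keys].reset_index(drop=True)
        )
    ):
        raise PanelError("pi tables do not share the same windowing scheme")
    ref = reference_pi.reset_index(drop=True)
    tgt = target_pi.reset_index(drop=True)
    out = ref[keys].copy()
    out["n_sites_ref"] = ref["n_sites"]
    out["n_sites_target"] = tgt["n_sites"]
    out["pi_ref"] = ref["pi"]
    out["pi_target"] = tgt["pi"]
    ratio = (ref["pi"] + epsilon) / (tgt["pi"] + epsilon)
    both_zero = (ref["pi"] == 0) & (tgt["pi"] == 0)
    out["ratio"] = np.where(both_zero, 1.0, ratio)
    return out
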