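"""Weir & Cockerham (1984) variance-component Fst, per site and windowed.

The per-site estimator decomposes allelic variance into three components:
``a`` (among populations), ``b`` (among individuals within populations) and
``c`` (within individuals), with theta = a / (a + b + c).  Windowed values are
the ratio of summed components over the window's sites ("weighted" Fst), not
the mean of per-site ratios; this downweights low-information sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel, PanelError, PopulationMap


class FstError(PanelError):
    pass


@dataclass
class FstComponents:
    """Per-site WC84 variance components; arrays share shape (n_sites,)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def theta(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)


def wc_components(n, p, h) -> FstComponents:
    """WC84 components from per-population summaries.

    Parameters
    ----------
    n, p, h : array-like, shape (r,) or (r, n_sites)
        Called-individual counts, ALT allele frequencies and observed
        heterozygote proportions for each of r >= 2 populations.

    Every population must have ``n_i >= 1``; callers skip sites where a
    population has no calls.  ``n_bar == 1`` (all populations a single
    individual) leaves the within-population component undefined and raises.
    """
    n = np.atleast_2d(np.asarray(n, dtype=np.float64).T).T
    p = np.atleast_2d(np.asarray(p, dtype=np.float64).T).T
    h = np.atleast_2d(np.asarray(h, dtype=np.float64).T).T
    r = n.shape[0]
    if r < 2:
        raise FstError("need at least 2 populations")
    if (n < 1).any():
        raise FstError("every population needs at least one called individual")

    n_bar = n.sum(axis=0) / r
    if (n_bar <= 1).any():
        raise FstError("n_bar = 1: within-population component undefined")
    n_c = (r * n_bar - (n**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n * p).sum(axis=0) / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n * h).sum(axis=0) / (r * n_bar)

    inner = p_bar * (1 - p_bar) - ((r - 1) / r) * s2
    a = (n_bar / n_c) * (s2 - (inner - h_bar / 4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (inner - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar)
    c = h_bar / 2
    return FstComponents(a=np.squeeze(a), b=np.squeeze(b), c=np.squeeze(c))


def site_components(
    panel: GenotypePanel, popmap: PopulationMap, grouping: list[set[str] | str]
) -> FstComponents:
    """Per-site components for a grouping of population labels.

    Each grouping element (a label or label set) is pooled into one
    "population" for the estimator.  Sites where any pooled group has zero
    called individuals, or where ``n_bar <= 1``, get NaN components.
    """
    if len(grouping) < 2:
        raise FstError("grouping needs at least two label sets")
    sets = [({g} if isinstance(g, str) else set(g)) for g in grouping]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if sets[i] & sets[j]:
                raise FstError("grouping label sets must be disjoint")

    r = len(sets)
    S = panel.n_sites
    n = np.zeros((r, S))
    p = np.zeros((r, S))
    h = np.zeros((r, S))
    for k, labels in enumerate(sets):
        idx = panel.sample_indices(popmap.samples_of(labels))
        if idx.size == 0:
            raise FstError(f"grouping element {sorted(labels)} has no samples")
        calls = panel.calls[idx]
        missing = (calls == -1).any(axis=2)
        nk = (~missing).sum(axis=0).astype(np.float64)
        altk = np.where(missing, 0, calls.sum(axis=2)).sum(axis=0)
        hetk = (~missing & (calls[..., 0] != calls[..., 1])).sum(axis=0)
        n[k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(nk > 0, altk / (2 * nk), 0.0)
            h[k] = np.where(nk > 0, hetk / nk, 0.0)

    valid = (n >= 1).all(axis=0)
    n_bar = n.sum(axis=0) / r
    valid &= n_bar > 1
    comp = FstComponents(
        a=np.full(S, np.nan), b=np.full(S, np.nan), c=np.full(S, np.nan)
    )
    if valid.any():
        sub = wc_components(n[:, valid], p[:, valid], h[:, valid])
        comp.a[valid] = sub.a
        comp.b[valid] = sub.b
        comp.c[valid] = sub.c
    return comp


def make_windows(positions: np.ndarray, window_size: int, step: int) -> np.ndarray:
    """Window start coordinates [1, 1+step, ...] covering max(positions)."""
    if step > window_size:
        raise FstError("step larger than window size leaves gaps")
    if positions.size == 0:
        return np.zeros(0, dtype=np.int64)
    last = int(positions.max())
    n_win = (last - 1) // step + 1
    return np.arange(n_win, dtype=np.int64) * step + 1


def windowed_weighted_fst(
    panel: GenotypePanel,
    popmap: PopulationMap,
    grouping: list[set[str] | str],
    window_size: int,
    step: int,
    min_sites: int = 1,
) -> pd.DataFrame:
    """Sliding-window weighted Fst: sum(a) / sum(a+b+c) over each window's sites.

    Windows tile each chromosome at ``step`` bp from coordinate 1; windows with
    fewer than ``min_sites`` component-bearing sites are omitted.  The output
    also carries ``mean_fst``, the mean of per-site theta values.
    """
    comp = site_components(panel, popmap, grouping)
    denom = comp.a + comp.b + comp.c
    theta = comp.theta
    rows = []
    for chrom in panel.chrom_ids:
        cmask = panel.chroms == chrom
        pos = panel.positions[cmask]
        a_c, d_c, t_c = comp.a[cmask], denom[cmask], theta[cmask]
        ok = ~np.isnan(a_c)
        for start in make_windows(pos, window_size, step):
            end = start + window_size - 1
            in_win = ok & (pos >= start) & (pos <= end)
            n_sites = int(in_win.sum())
            if n_sites < min_sites:
                continue
            dsum = d_c[in_win].sum()
            weighted = a_c[in_win].sum() / dsum if dsum != 0 else np.nan
            site_thetas = t_c[in_win]
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "n_sites": n_sites,
                    "weighted_fst": weighted,
                    "mean_fst": float(np.nanmean(site_thetas))
                    if np.isfinite(site_thetas).any()
                    else np.nan,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "weighted_fst", "mean_fst"]
    )


def genomewide_weighted_fst(
    panel: GenotypePanel, popmap: PopulationMap, grouping: list[set[str] | str]
) -> float:
    """Single weighted Fst over all sites: sum(a) / sum(a+b+c)."""
    comp = site_components(panel, popmap, grouping)
    ok = ~np.isnan(comp.a)
    denom = (comp.a + comp.b + comp.c)[ok].sum()
    return float(comp.a[ok].sum() / denom) if denom != 0 else float("nan")
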