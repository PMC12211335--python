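import numpy as np
import pandas as pd
import pytest

from sweepscan import (
    CandidateRegion,
    GeneAnnotation,
    PanelError,
    ScanConfig,
    SimConfig,
    SweepSpec,
    annotate_regions,
    call_peaks,
    quantile_threshold,
    scan_filter,
    simulate_neutral,
    simulate_panel,
    sweep_scan,
    within_country_scan,
)


class TestQuantileThreshold:
    def test_nearest_rank_examples(self):
        values = np.arange(1, 1001)
        assert quantile_threshold(values, 0.001) == 1000
        assert quantile_threshold(values, 0.01) == 991

    def test_all_equal_degenerate(self):
        assert quantile_threshold([7.0] * 50, 0.01) == 7.0

    def test_empty_is_error(self):
        with pytest.raises(PanelError):
            quantile_threshold([], 0.01)

    def test_outlier_fraction_at_least_requested(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(10, 2000))
            values = rng.choice(rng.normal(size=max(3, n // 10)), size=n)  # ties likely
            f = float(rng.uniform(0.001, 0.2))
            thr = quantile_threshold(values, f)
            assert (values >= thr).sum() >= int(np.ceil(f * n))


def window_table(values, step=25_000, width=50_000, chrom="1"):
    starts = np.arange(len(values)) * step + 1
    return pd.DataFrame(
        {
            "chrom": [chrom] * len(values),
            "start": starts,
            "end": starts + width - 1,
            "n_sites": [10] * len(values),
            "weighted_fst": values,
        }
    )


class TestCallPeaks:
    def test_three_adjacent_windows_form_one_region(self):
        t = 0.5
        w = window_table([0.1, t + 0.01, t + 0.01, t + 0.01, 0.1])
        regions = call_peaks(w, t, min_consecutive=3, step=25_000)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (25_001, 125_000)
        assert regions[0].n_windows == 3

    def test_two_adjacent_windows_are_not_enough(self):
        w = window_table([0.1, 0.9, 0.9, 0.1])
        assert call_peaks(w, 0.5, min_consecutive=3, step=25_000) == []

    def test_five_window_run_spans_150kb(self):
        w = window_table([0.9] * 5)
        regions = call_peaks(w, 0.5, min_consecutive=3, step=25_000)
        assert len(regions) == 1
        assert regions[0].end - regions[0].start + 1 == 150_000

    def test_runs_broken_by_chromosome(self):
        w1 = window_table([0.9, 0.9], chrom="1")
        w2 = window_table([0.9], chrom="2")
        w = pd.concat([w1, w2], ignore_index=True)
        assert call_peaks(w, 0.5, min_consecutive=3, step=25_000) == []

    def test_region_count_nonincreasing_in_min_consecutive(self):
        rng = np.random.default_rng(6)
        w = window_table(rng.uniform(0, 1, 200))
        thr = quantile_threshold(w["weighted_fst"], 0.2)
        counts = [
            len(call_peaks(w, thr, min_consecutive=m, step=25_000)) for m in (1, 2, 3, 4)
        ]
        spans = [
            sum(r.span for r in call_peaks(w, thr, min_consecutive=m, step=25_000))
            for m in (1, 2, 3, 4)
        ]
        assert counts == sorted(counts, reverse=True)
        assert spans == sorted(spans, reverse=True)

    def test_peak_stat_is_member_maximum(self):
        w = window_table([0.6, 0.9, 0.7])
        regions = call_peaks(w, 0.5, min_consecutive=3, step=25_000)
        assert regions[0].peak_stat == pytest.approx(0.9)


class TestWithinCountryScan:
    def test_recovers_injected_region_for_target_country(self):
        """A 150 kb block of fixed differences in one country yields one region there.

        Uses a chromosome long enough that the top-0.1% nearest-rank
        threshold admits >= 3 windows (k = ceil(0.001 * n_windows) = 3);
        the fixed-difference windows tie at theta = 1 and merge into a run.
        """
        cfg = SimConfig(seed=14, n_sites=18_000, chrom_length=60_000_000, sweeps=[])
        panel, popmap = simulate_neutral(cfg)
        start, end = 30_000_001, 30_150_000
        region = (panel.positions >= start) & (panel.positions <= end)
        egypt_idx = panel.sample_indices(popmap.samples_of("Egypt"))
        other_idx = np.setdiff1d(np.arange(panel.n_samples), egypt_idx)
        panel.calls[np.ix_(egypt_idx, np.flatnonzero(region))] = 1
        panel.calls[np.ix_(other_idx, np.flatnonzero(region))] = 0

        filtered, _ = scan_filter(panel)
        results = within_country_scan(filtered, popmap)
        egypt = results["Egypt"].regions
        assert len(egypt) == 1
        assert egypt[0].start <= end and egypt[0].end >= start
        assert egypt[0].n_windows >= 3
        assert egypt[0].peak_stat == pytest.approx(1.0)

    def test_thresholds_are_per_country_nearest_rank(self):
        cfg = SimConfig(seed=15, n_sites=3000, chrom_length=1_000_000, sweeps=[])
        panel, popmap = simulate_neutral(cfg)
        filtered, _ = scan_filter(panel)
        results = within_country_scan(filtered, popmap)
        for pop, res in results.items():
            w = res.windows["fst"]["weighted_fst"]
            assert res.thresholds["weighted_fst"] == quantile_threshold(w, 0.001)

    def test_neutral_panel_rarely_has_peaks(self):
        zero_seeds = 0
        for seed in range(30, 50):
            cfg = SimConfig(seed=seed, n_sites=3000, chrom_length=1_000_000, sweeps=[])
            panel, popmap = simulate_neutral(cfg)
            filtered, _ = scan_filter(panel)
            results = within_country_scan(filtered, popmap)
            if all(not r.regions for r in results.values()):
                zero_seeds += 1
        assert zero_seeds >= 18

    def test_min_consecutive_one_always_finds_regions(self):
        cfg = SimConfig(seed=16, n_sites=3000, chrom_length=1_000_000, sweeps=[])
        panel, popmap = simulate_neutral(cfg)
        filtered, _ = scan_filter(panel)
        results = within_country_scan(filtered, popmap, ScanConfig(min_consecutive=1))
        assert all(len(r.regions) >= 1 for r in results.values())


class TestSweepScan:
    def test_single_injected_sweep_recovered(self):
        cfg = SimConfig(seed=1, sweeps=[SweepSpec(start=5_000_001, end=5_100_000)])
        panel, popmap, truths = simulate_panel(cfg)
        filtered, _ = scan_filter(panel)
        res = sweep_scan(
            filtered, popmap, popmap.group_labels("tropical"), popmap.group_labels("cold")
        )
        t = truths[0]
        overlapping = [r for r in res.regions if r.start <= t.end and r.end >= t.start]
        assert overlapping
        r = overlapping[0]
        assert r.stats["weighted_fst"] >= res.thresholds["weighted_fst"]
        assert r.stats["pi_ratio"] >= res.thresholds["pi_ratio"]
        assert r.stats["xpehh"] > res.thresholds["xpehh"]

    def test_group_swap_suppresses_detection(self):
        cfg = SimConfig(seed=1, sweeps=[SweepSpec(start=5_000_001, end=5_100_000)])
        panel, popmap, truths = simulate_panel(cfg)
        filtered, _ = scan_filter(panel)
        res = sweep_scan(
            filtered, popmap, popmap.group_labels("cold"), popmap.group_labels("tropical")
        )
        t = truths[0]
        assert not any(r.start <= t.end and r.end >= t.start for r in res.regions)

    def test_overlapping_groups_rejected(self):
        cfg = SimConfig(seed=2, n_sites=500, chrom_length=200_000, sweeps=[])
        panel, popmap = simulate_neutral(cfg)
        with pytest.raises(PanelError):
            sweep_scan(panel, popmap, {"Egypt"}, {"Egypt", "Finland"})


class TestAnnotateRegions:
    def _genes(self):
        return GeneAnnotation(
            chrom=["1", "1", "1"],
            start=np.array([150, 150, 201]),
            end=np.array([400, 180, 400]),
            strand=["+", "-", "+"],
            gene_name=["G_overlap", "G_inside", "G_after"],
        )

    def test_overlap_and_boundary(self):
        regions = [CandidateRegion("1", 100, 200, 1, 0.9, "sweep")]
        out = annotate_regions(regions, self._genes())
        # [201, 400] touches [100, 200] at no base -> excluded
        assert out[0].genes == ["G_overlap", "G_inside"]

    def test_chromosome_mismatch_warns_and_leaves_empty(self):
        regions = [CandidateRegion("chr9", 100, 200, 1, 0.9, "sweep")]
        with pytest.warns(UserWarning):
            out = annotate_regions(regions, self._genes())
        assert out[0].genes == []
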