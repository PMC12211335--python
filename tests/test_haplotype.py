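import numpy as np
import pytest

from sweepscan import (
    PanelError,
    PhaseError,
    SimConfig,
    SweepSpec,
    ehh,
    haplotype_block,
    ihh,
    inject_sweep,
    simulate_neutral,
    windowed_xpehh,
    xpehh_scan,
)
from sweepscan.haplotype import EhhCurve, _ihh_all_cores

from .oracles import ehh_pairs


def hmat(rows):
    return np.array(rows, dtype=np.uint8)


class TestEhh:
    def test_identical_haplotypes_stay_at_one(self):
        H = hmat([[0, 1, 0, 1]] * 4)
        pos = np.array([100, 200, 300, 400])
        curve = ehh(H, pos, 0, "right")
        assert (curve.values == 1.0).all()
        assert curve.truncation == "chromosome_end"

    def test_partition_sizes_2_1_1(self):
        # at the flanking site the strings split into groups {2,1,1}
        H = hmat([[0, 0], [0, 0], [0, 1], [1, 0]])
        pos = np.array([100, 1100])
        curve = ehh(H, pos, 0, "right")
        assert curve.values[-1] == pytest.approx(1 / 6)

    def test_all_distinct_truncates_at_zero(self):
        H = hmat([[0, 0], [0, 1], [1, 0], [1, 1]])
        pos = np.array([100, 200])
        curve = ehh(H, pos, 0, "right")
        assert curve.values[-1] == 0.0
        assert curve.truncation == "cutoff"

    def test_monotone_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            N = int(rng.integers(2, 13))
            S = int(rng.integers(2, 20))
            H = rng.integers(0, 2, (N, S)).astype(np.uint8)
            pos = np.sort(rng.choice(10_000, S, replace=False)) + 1
            for direction in ("left", "right"):
                curve = ehh(H, pos, int(rng.integers(0, S)), direction, cutoff=0.0)
                assert curve.values[0] == 1.0
                assert (np.diff(curve.values) <= 1e-15).all()
                assert ((curve.values >= 0) & (curve.values <= 1)).all()

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            N = int(rng.integers(2, 9))
            S = int(rng.integers(2, 11))
            H = rng.integers(0, 2, (N, S)).astype(np.uint8)
            pos = np.sort(rng.choice(5_000, S, replace=False)) + 1
            core = int(rng.integers(0, S))
            curve = ehh(H, pos, core, "right", cutoff=0.0)
            for k, value in enumerate(curve.values[1:], start=1):
                assert value == pytest.approx(ehh_pairs(H, core, core + k))

    def test_single_haplotype_is_error(self):
        with pytest.raises(PanelError):
            ehh(hmat([[0, 1]]), np.array([1, 2]), 0, "right")

    def test_max_extend_truncation(self):
        H = hmat([[0, 1, 0]] * 4)
        pos = np.array([100, 200, 2_000_000])
        curve = ehh(H, pos, 0, "right", max_extend=10_000)
        assert curve.truncation == "max_extend"
        assert curve.distances[-1] == 100


def curve(core, direction, dists, vals, trunc="cutoff"):
    return EhhCurve(core, direction, np.array(dists, float), np.array(vals, float), trunc)


class TestIhh:
    def test_trapezoid_example(self):
        right = curve(0, "right", [0, 1000, 2000], [1.0, 0.5, 0.04])
        left = curve(0, "left", [0], [1.0])
        assert ihh(left, right) == pytest.approx(750 + 270)

    def test_rectangle(self):
        right = curve(0, "right", [0, 10_000], [1.0, 1.0], "chromosome_end")
        left = curve(0, "left", [0], [1.0])
        assert ihh(left, right) == pytest.approx(10_000)

    def test_symmetric_arms_double_one_arm(self):
        arm = ([0, 500, 1500], [1.0, 0.8, 0.03])
        both = ihh(curve(0, "left", *arm), curve(0, "right", *arm))
        one = ihh(curve(0, "left", [0], [1.0]), curve(0, "right", *arm))
        assert both == pytest.approx(2 * one)

    def test_degenerate_single_points_give_zero(self):
        assert ihh(curve(0, "left", [0], [1.0]), curve(0, "right", [0], [1.0])) == 0.0


class TestFastPath:
    def test_jitted_kernel_matches_reference_route(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            N = 2 * int(rng.integers(1, 11))
            S = int(rng.integers(2, 30))
            H = rng.integers(0, 2, (N, S)).astype(np.uint8)
            pos = (np.sort(rng.choice(200_000, S, replace=False)) + 1).astype(np.int64)
            fast = _ihh_all_cores(H, pos, 0.05, 1_000_000)
            ref = [
                ihh(
                    ehh(H, pos, c, "left", 0.05, 1_000_000),
                    ehh(H, pos, c, "right", 0.05, 1_000_000),
                )
                for c in range(S)
            ]
            np.testing.assert_allclose(fast, ref, rtol=1e-12, atol=1e-12)


class TestXpehhScan:
    def _sim(self, seed=4, sweeps=()):
        cfg = SimConfig(seed=seed, n_sites=1500, chrom_length=500_000, sweeps=list(sweeps))
        return simulate_neutral(cfg)

    def test_identical_groups_score_zero(self, make_panel):
        genos = [
            [(0, 1), (1, 1), (0, 0)] * 2,
            [(1, 1), (0, 1), (0, 1)] * 2,
            [(0, 0), (0, 1), (1, 1)] * 2,
        ]
        samples = [f"A_{i}" for i in range(3)] + [f"B_{i}" for i in range(3)]
        panel = make_panel(genos, samples=samples)
        from sweepscan import PopulationMap

        pm = PopulationMap(assignment={s: s[0] for s in samples})
        scores, _ = xpehh_scan(panel, pm, "A", "B")
        assert (scores["xpehh_raw"] == 0).all()

    def test_group_swap_negates_raw_scores(self):
        panel, popmap = self._sim()
        fwd, _ = xpehh_scan(panel, popmap, {"Egypt", "Uganda"}, {"Finland", "Netherlands"})
        rev, _ = xpehh_scan(panel, popmap, {"Finland", "Netherlands"}, {"Egypt", "Uganda"})
        np.testing.assert_allclose(
            fwd["xpehh_raw"].to_numpy(), -rev["xpehh_raw"].to_numpy(), atol=1e-12
        )

    def test_standardization_exact(self):
        panel, popmap = self._sim(seed=9)
        scores, _ = xpehh_scan(panel, popmap, {"Egypt"}, {"Finland"})
        std = scores["xpehh_std"].to_numpy()
        assert abs(std.mean()) < 1e-9
        assert abs(std.std(ddof=0) - 1) < 1e-9

    def test_unphased_panel_is_phase_error(self):
        panel, popmap = self._sim()
        panel.phased[:] = False
        with pytest.raises(PhaseError):
            xpehh_scan(panel, popmap, {"Egypt"}, {"Finland"})

    def test_missing_sites_excluded_from_blocks(self):
        panel, popmap = self._sim()
        panel.calls[0, 100] = -1
        idx = panel.sample_indices(popmap.samples_of({"Egypt", "Finland"}))
        H, positions, site_idx = haplotype_block(panel, idx, "1")
        assert 100 not in site_idx
        assert H.shape[0] == 2 * len(idx)

    def test_sweep_windows_exceed_genome_mean(self):
        """Injected sweeps show elevated windowed XP-EHH in the target group."""
        for seed in range(20):
            cfg = SimConfig(
                seed=seed,
                n_sites=1500,
                chrom_length=500_000,
                sweeps=[SweepSpec(start=200_001, end=300_000, beta=0.9)],
            )
            panel, popmap = simulate_neutral(cfg)
            rng = np.random.default_rng((seed, 77))
            panel, truth = inject_sweep(panel, popmap, cfg.sweeps[0], rng)
            scores, _ = xpehh_scan(
                panel, popmap, {"Egypt", "Uganda"}, {"Finland", "Netherlands"}
            )
            w = windowed_xpehh(scores, 25_000)
            inside = (w["start"] >= truth.start) & (w["end"] <= truth.end)
            assert w.loc[inside, "xpehh_mean"].mean() > w["xpehh_mean"].mean()


class TestWindowedXpehh:
    def test_mean_and_max(self):
        import pandas as pd

        scores = pd.DataFrame(
            {
                "chrom": ["1"] * 3,
                "pos": [100, 200, 300],
                "xpehh_std": [2.5, 3.0, 2.0],
            }
        )
        w = windowed_xpehh(scores, 25_000)
        assert len(w) == 1
        assert w["xpehh_mean"].iloc[0] == pytest.approx(2.5)
        assert w["xpehh_max"].iloc[0] == pytest.approx(3.0)
        assert w["n_sites"].iloc[0] == 3

    def test_empty_windows_omitted_and_zero_mean(self):
        import pandas as pd

        scores = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "pos": [100, 60_000],
                "xpehh_std": [0.0, 0.0],
            }
        )
        w = windowed_xpehh(scores, 25_000)
        assert list(w["start"]) == [1, 50_001]  # middle window omitted
        assert (w["xpehh_mean"] == 0).all()
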