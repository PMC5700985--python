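import numpy as np
import pytest
from scipy import ndimage
from skimage import measure

from sofiquant.density import DensityMap
from sofiquant.hdr_cluster import (ThresholdSweep, fit_region_count_gaussian,
                                   segment_hdrs, select_optimal_threshold,
                                   select_threshold_from_curve, summarize,
                                   sweep_thresholds)

PITCH = 26.25


def make_map(N, mask=None, pitch=PITCH):
    N = np.asarray(N, dtype=float)
    if mask is None:
        mask = np.ones_like(N, dtype=bool)
    return DensityMap(N=N, delta_avg=float(N[mask].mean()), mask=mask,
                      pitch_nm=pitch)


class TestSegmentHdrs:
    def test_threshold_above_max_gives_no_regions(self):
        dmap = make_map(np.ones((10, 10)))
        assert segment_hdrs(dmap, threshold=2.0) == []

    def test_two_blocks_areas_and_equivalent_diameter(self):
        N = np.ones((10, 10))
        N[1:3, 1:3] = 10.0
        N[6:8, 6:8] = 10.0
        dmap = make_map(N)
        regions = segment_hdrs(dmap, threshold=5.0)
        assert len(regions) == 2
        for r in regions:
            assert r.area_px == 4
            # circle of area 4 px^2: d = 2 sqrt(4/pi) ~ 2.257 px
            assert r.equivalent_diameter_nm == pytest.approx(
                2 * np.sqrt(4 / np.pi) * PITCH)

    def test_threshold_zero_yields_whole_mask(self):
        dmap = make_map(np.random.default_rng(0).random((12, 12)) + 0.5)
        regions = segment_hdrs(dmap, threshold=0.0)
        assert len(regions) == 1
        assert regions[0].area_px == 144

    def test_min_area_filter(self):
        N = np.ones((10, 10))
        N[2, 2] = 50.0           # single-pixel speck
        N[5:8, 5:8] = 50.0       # 9-px region
        dmap = make_map(N)  # delta_avg = 5.9, so the specks sit at rel ~ 8.5
        assert len(segment_hdrs(dmap, 5.0, min_area_px=1)) == 2
        assert len(segment_hdrs(dmap, 5.0, min_area_px=4)) == 1


class TestSweep:
    def test_toy_map_counts_and_relative_area(self):
        # 8x8: background 1.0, two 2x2 blocks at 5.0 -> delta_avg = 1.5
        N = np.ones((8, 8))
        N[1:3, 1:3] = 5.0
        N[5:7, 5:7] = 5.0
        dmap = make_map(N)
        assert dmap.delta_avg == pytest.approx(1.5)
        sweep = sweep_thresholds(dmap, t_max=4.0, step=0.1)
        i = sweep.nearest_index(2.0)
        assert sweep.n_regions[i] == 2
        assert sweep.relative_area[i] == pytest.approx(8 / 64)
        assert sweep.n_regions[sweep.nearest_index(4.0)] == 0

    def test_constant_map_single_region_until_one(self):
        dmap = make_map(np.full((6, 6), 2.0))
        sweep = sweep_thresholds(dmap, step=0.1)
        assert sweep.n_regions[sweep.nearest_index(0.5)] == 1
        assert sweep.n_regions[sweep.nearest_index(1.0)] == 1
        assert sweep.thresholds[-1] == pytest.approx(1.0)

    def test_total_area_identity(self, rng):
        N = ndimage.gaussian_filter(rng.random((40, 40)), 2)
        dmap = make_map(N)
        sweep = sweep_thresholds(dmap, step=0.2)
        for i in range(len(sweep.thresholds)):
            total = sum(r.area_px for r in sweep.regions_at[i])
            assert total == pytest.approx(
                sweep.relative_area[i] * sweep.roi_area_px)


class TestMonotonicityAndNesting:
    @staticmethod
    def check_one(seed):
        rng = np.random.default_rng(seed)
        N = ndimage.gaussian_filter(rng.random((48, 48)), 1.5) + 0.01
        dmap = make_map(N)
        sweep = sweep_thresholds(dmap, step=0.1)
        rel = sweep.relative_area
        assert np.all(np.diff(rel) <= 1e-12), "relative_area must not increase"
        # nesting: every suprathreshold pixel set is contained in the previous
        prev = None
        for t in sweep.thresholds:
            sel = dmap.mask & (dmap.relative >= t)
            if prev is not None:
                assert np.all(prev | ~sel), "regions must nest"
                # and each region maps into exactly one parent label
                parents = measure.label(prev, connectivity=2)
                for rp in measure.regionprops(measure.label(sel, connectivity=2)):
                    coords = rp.coords
                    labels = {parents[y, x] for y, x in coords}
                    assert len(labels) == 1 and 0 not in labels
            prev = sel

    def test_nesting_on_random_maps(self):
        for seed in range(10):
            self.check_one(seed)


class TestSelectOptimalThreshold:
    @staticmethod
    def gaussian_sweep(A, m, s, t_max=4.0, step=0.1):
        t = np.arange(0.0, t_max + step / 2, step)
        y = A * np.exp(-(t - m) ** 2 / (2 * s ** 2))
        return ThresholdSweep(thresholds=t, n_regions=y,
                              mean_area_px=np.full_like(t, np.nan),
                              mean_diameter_nm=np.full_like(t, np.nan),
                              relative_area=np.zeros_like(t),
                              regions_at=[[] for _ in t], pitch_nm=PITCH,
                              roi_area_px=100)

    def test_exact_gaussian_closed_form(self):
        sweep = self.gaussian_sweep(A=50.0, m=1.0, s=0.5)
        t_star = select_optimal_threshold(sweep)
        expected = 1.0 + 0.5 * np.sqrt(2 * np.log(50.0))
        assert abs(t_star - expected) <= 0.1

    def test_subunit_amplitude_returns_center(self):
        sweep = self.gaussian_sweep(A=0.5, m=1.0, s=0.5)
        assert select_optimal_threshold(sweep) == pytest.approx(1.0, abs=0.2)

    def test_fit_parameters_recovered(self):
        t = np.arange(0.0, 5.0, 0.1)
        y = 40.0 * np.exp(-(t - 1.2) ** 2 / (2 * 0.4 ** 2))
        A, m, s, c = fit_region_count_gaussian(t, y)
        assert A == pytest.approx(40.0, rel=0.05)
        assert m == pytest.approx(1.2, abs=0.05)
        assert s == pytest.approx(0.4, abs=0.05)
        assert c == pytest.approx(0.0, abs=0.5)

    def test_gaussian_plus_cluster_plateau(self):
        # the floor keeps the plateau of genuine clusters from widening the
        # fitted random bump
        t = np.arange(0.0, 12.0, 0.1)
        y = 60.0 * np.exp(-(t - 1.0) ** 2 / (2 * 0.5 ** 2)) + 10.0 * (t < 9)
        t_star = select_threshold_from_curve(t, y)
        expected = 1.0 + 0.5 * np.sqrt(2 * np.log(60.0))
        assert abs(t_star - expected) < 0.5

    def test_degenerate_curve_raises(self):
        sweep = self.gaussian_sweep(A=0.0, m=1.0, s=0.5)
        sweep.n_regions[:] = 0
        with pytest.raises(ValueError, match="degenerate"):
            select_optimal_threshold(sweep)


class TestSummarize:
    @staticmethod
    def sweep_with_counts(n):
        t = np.arange(0.0, 3.0, 0.1)
        return ThresholdSweep(thresholds=t,
                              n_regions=np.full_like(t, n),
                              mean_area_px=np.full_like(t, 2.0 * n),
                              mean_diameter_nm=np.full_like(t, 50.0 + n),
                              relative_area=np.full_like(t, 0.01 * n),
                              regions_at=[[] for _ in t], pitch_nm=PITCH,
                              roi_area_px=100)

    def test_boxplot_statistics(self):
        sweeps = {"g": [self.sweep_with_counts(v) for v in (1, 2, 3, 4, 5)]}
        df = summarize(sweeps, at=1.0)
        row = df[(df.group == "g") & (df.metric == "n_regions")].iloc[0]
        assert row["median"] == 3 and row.q1 == 2 and row.q3 == 4
        assert row["min"] == 1 and row["max"] == 5

    def test_single_sample_zero_iqr(self):
        df = summarize({"g": [self.sweep_with_counts(7)]}, at=0.5)
        row = df[df.metric == "n_regions"].iloc[0]
        assert row["median"] == 7 and row.q1 == row.q3 == 7

    def test_disjoint_groups_ordered(self):
        sweeps = {"low": [self.sweep_with_counts(v) for v in (1, 2)],
                  "high": [self.sweep_with_counts(v) for v in (8, 9)]}
        df = summarize(sweeps, at=1.0)
        med = df[df.metric == "n_regions"].set_index("group")["median"]
        assert med["low"] < med["high"]

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty"):
            summarize({"g": []}, at=1.0)
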