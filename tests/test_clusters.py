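"""Smoothness estimation and Monte-Carlo cluster-extent thresholds."""
import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from sdnmap.clusters import (
    ClusterThreshold,
    SmoothnessEstimate,
    apply_cluster_threshold,
    estimate_fwhm,
    simulate_cluster_threshold,
)
from sdnmap.glm import StatMap
from sdnmap.grid import Grid
from sdnmap.rates import AnalysisMask


def _mask(shape=(32, 32, 32), voxel=2.0):
    grid = Grid(shape, voxel)
    return AnalysisMask(np.ones(shape, bool), grid)


class TestEstimateFwhm:
    def test_white_noise_floors_at_voxel_size(self, rng):
        mask = _mask((64, 64, 64), 2.0)
        est = estimate_fwhm([rng.standard_normal(mask.grid.shape)], mask)
        assert est.combined_mm == pytest.approx(2.0, rel=0.15)

    @pytest.mark.parametrize("fwhm_vox", [2.0, 3.0])
    def test_recovers_applied_smoothing(self, rng, fwhm_vox):
        mask = _mask((64, 64, 64), 2.0)
        sigma = fwhm_vox / (2 * np.sqrt(2 * np.log(2)))
        noise = gaussian_filter(rng.standard_normal(mask.grid.shape), sigma, mode="constant")
        est = estimate_fwhm([noise], mask)
        assert est.combined_mm / 2.0 == pytest.approx(fwhm_vox, rel=0.15)

    def test_duplicate_maps_average_to_same_estimate(self, rng):
        mask = _mask((24, 24, 24))
        m = gaussian_filter(rng.standard_normal(mask.grid.shape), 1.2, mode="constant")
        one = estimate_fwhm([m], mask)
        two = estimate_fwhm([m, m], mask)
        assert one.fwhm_mm == two.fwhm_mm

    def test_flat_residuals_rejected(self):
        mask = _mask((16, 16, 16))
        with pytest.raises(ValueError, match="flat"):
            estimate_fwhm([np.ones(mask.grid.shape)], mask)


class TestSimulateThreshold:
    def test_alpha_one_gives_extent_one(self, rng):
        mask = _mask((16, 16, 16))
        sm = SmoothnessEstimate((4.0, 4.0, 4.0), 2.0)
        thr = simulate_cluster_threshold(sm, mask, cluster_alpha=1.0, n_sim=50, seed=1)
        assert thr.min_extent_voxels == 1

    def test_unsmoothed_noise_gives_small_extent(self):
        mask = _mask((32, 32, 32))
        sm = SmoothnessEstimate((0.0, 0.0, 0.0), 2.0)
        thr = simulate_cluster_threshold(sm, mask, voxel_p=0.005, n_sim=300, seed=2)
        assert thr.min_extent_voxels <= 5

    def test_extent_increases_with_smoothness(self):
        mask = _mask((32, 32, 32))
        lo = SmoothnessEstimate((2.0, 2.0, 2.0), 2.0)
        hi = SmoothnessEstimate((8.0, 8.0, 8.0), 2.0)
        wins = 0
        for seed in range(5):
            k_lo = simulate_cluster_threshold(lo, mask, n_sim=200, seed=seed).min_extent_voxels
            k_hi = simulate_cluster_threshold(hi, mask, n_sim=200, seed=seed).min_extent_voxels
            wins += k_hi >= k_lo
        assert wins >= 4

    def test_deterministic_under_fixed_seed(self):
        mask = _mask((24, 24, 24))
        sm = SmoothnessEstimate((5.0, 5.0, 5.0), 2.0)
        a = simulate_cluster_threshold(sm, mask, n_sim=100, seed=9)
        b = simulate_cluster_threshold(sm, mask, n_sim=100, seed=9)
        assert a.min_extent_voxels == b.min_extent_voxels


def _flood_fill_components(supra, connectivity):
    """Brute-force connected components by breadth-first search."""
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if (connectivity == 6 and order == 1) or (
                    connectivity == 18 and order <= 2
                ) or connectivity == 26:
                    offs.append((di, dj, dk))
    seen = np.zeros_like(supra, bool)
    comps = []
    for start in zip(*np.nonzero(supra)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for o in offs:
                w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= w[a] < supra.shape[a] for a in range(3)):
                    if supra[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
        comps.append(set(comp))
    return comps


class TestApplyThreshold:
    def _zmap(self, data, mask):
        return StatMap(data, "z", np.inf, "test", mask.grid, mask)

    def test_all_zero_map_gives_empty_table(self):
        mask = _mask((16, 16, 16))
        thr = ClusterThreshold(0.005, 0.05, 10, 100)
        surviving, table = apply_cluster_threshold(self._zmap(np.zeros(mask.grid.shape), mask), thr)
        assert not surviving.any()
        assert len(table) == 0

    def test_planted_blob_survives_printed_extent(self):
        # one 600-voxel blob of z=4 against the documented 513-voxel extent
        mask = _mask((32, 32, 32))
        data = np.zeros(mask.grid.shape)
        data[4:14, 4:14, 4:10] = 4.0  # 10*10*6 = 600 voxels
        thr = ClusterThreshold(0.005, 0.05, 513, 1000)
        surviving, table = apply_cluster_threshold(self._zmap(data, mask), thr)
        assert len(table) == 1
        assert table.loc[0, "size_voxels"] == 600
        assert surviving.sum() == 600

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        mask = _mask((14, 14, 14))
        data = np.where(rng.random(mask.grid.shape) < 0.2, 4.0, 0.0)
        thr = ClusterThreshold(0.005, 0.05, 3, 100, connectivity=connectivity)
        surviving, table = apply_cluster_threshold(self._zmap(data, mask), thr)
        comps = _flood_fill_components(data > 2.8, connectivity)
        expected = set().union(*[c for c in comps if len(c) >= 3]) if comps else set()
        assert set(zip(*np.nonzero(surviving))) == expected
        assert sorted(table["size_voxels"]) == sorted(
            len(c) for c in comps if len(c) >= 3
        )
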