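"""Epicenter seeds, SDN mapping and fixed-size network masks."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sdnmap.clusters import ClusterThreshold
from sdnmap.glm import StatMap, Z_CLAMP
from sdnmap.grid import Grid
from sdnmap.networks import (
    SphereSeed,
    extract_seed_rate,
    find_epicenters,
    map_sdn,
    top_percent_mask,
)
from sdnmap.rates import AnalysisMask, RateMap

GRID = Grid((24, 24, 24), 2.0)
FULL_MASK = AnalysisMask(np.ones(GRID.shape, bool), GRID)


def _zmap(data, mask=FULL_MASK):
    return StatMap(data, "z", np.inf, "test", mask.grid, mask)


def _cov(n, rng):
    return pd.DataFrame(
        {
            "age": rng.normal(76, 6, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.normal(12, 4, n),
            "tiv": rng.normal(1.46e6, 1e5, n),
        },
        index=[f"h{i}" for i in range(n)],
    )


class TestSphereSeed:
    def test_six_mm_sphere_on_two_mm_grid_has_123_voxels(self):
        seed = SphereSeed((12, 12, 12), 6.0, GRID)
        assert len(seed.member_voxels) == 123
        # lattice-point oracle: integer offsets with squared norm <= 9
        count = sum(
            1
            for di in range(-3, 4)
            for dj in range(-3, 4)
            for dk in range(-3, 4)
            if di**2 + dj**2 + dk**2 <= 9
        )
        assert count == 123

    def test_membership_symmetric_under_reflection(self):
        seed = SphereSeed((12, 12, 12), 6.0, GRID)
        offsets = seed.member_voxels - np.array([12, 12, 12])
        as_set = {tuple(o) for o in offsets}
        assert all(tuple(-o) in as_set for o in offsets)

    def test_clipped_at_grid_edge(self):
        seed = SphereSeed((0, 12, 12), 6.0, GRID)
        assert len(seed.member_voxels) < 123
        assert (seed.member_voxels >= 0).all()


class TestFindEpicenters:
    def test_seed_centered_at_cluster_peak(self):
        table = pd.DataFrame(
            [{"label": 1, "size_voxels": 60, "peak_stat": 5.0,
              "peak_i": 10, "peak_j": 12, "peak_k": 8}]
        )
        seeds = find_epicenters(_zmap(np.zeros(GRID.shape)), table, 6.0)
        assert seeds[0].center_ijk == (10, 12, 8)

    def test_no_clusters_is_an_error(self):
        with pytest.raises(ValueError, match="no epicenters"):
            find_epicenters(_zmap(np.zeros(GRID.shape)), pd.DataFrame(), 6.0)

    def test_tied_peak_resolves_to_scan_order(self):
        # two voxels tied at the cluster maximum: peak = smallest flat index
        from sdnmap.clusters import ClusterThreshold, apply_cluster_threshold

        data = np.zeros(GRID.shape)
        data[5, 5, 5] = 4.0
        data[5, 5, 6] = 4.0
        thr = ClusterThreshold(0.005, 0.05, 1, 100)
        _, table = apply_cluster_threshold(_zmap(data), thr)
        seeds = find_epicenters(_zmap(data), table, 6.0)
        assert seeds[0].center_ijk == (5, 5, 5)


class TestExtractSeedRate:
    def test_constant_map(self):
        rm = RateMap("s", np.full(GRID.shape, -0.02), GRID)
        seed = SphereSeed((12, 12, 12), 6.0, GRID)
        assert extract_seed_rate(rm, seed) == pytest.approx(-0.02)

    def test_half_and_half(self):
        data = np.zeros(GRID.shape)
        data[12:, :, :] = 2.0  # plane through the seed center
        seed = SphereSeed((12, 12, 12), 5.9, GRID)  # open center plane split
        rm = RateMap("s", data, GRID)
        # voxels with i>=12 are 2, i<12 are 0; center plane i=12 included
        pts = seed.member_voxels
        expected = data[tuple(pts.T)].mean()
        assert extract_seed_rate(rm, seed) == pytest.approx(expected)

    def test_matches_loop_oracle(self, rng):
        data = rng.standard_normal(GRID.shape)
        rm = RateMap("s", data, GRID)
        seed = SphereSeed((10, 14, 9), 6.0, GRID)
        total = sum(data[tuple(p)] for p in seed.member_voxels)
        assert extract_seed_rate(rm, seed) == pytest.approx(total / len(seed.member_voxels), abs=1e-12)

    def test_outside_mask_rejected(self):
        rm = RateMap("s", np.zeros(GRID.shape), GRID)
        seed = SphereSeed((2, 2, 2), 4.0, GRID)
        empty_region = AnalysisMask(np.zeros(GRID.shape, bool) | (np.indices(GRID.shape)[0] > 20), GRID)
        with pytest.raises(ValueError, match="no member voxels"):
            extract_seed_rate(rm, seed, empty_region)


class TestMapSdn:
    def _rates(self, values_fn, n, rng):
        maps = []
        for i in range(n):
            maps.append(RateMap(f"h{i}", values_fn(i), GRID, group="HC"))
        return maps

    def test_perfectly_coupled_voxel_hits_clamp(self, rng):
        n = 20
        cov = _cov(n, rng)
        seed_vals = rng.standard_normal(n) * 0.01 - 0.01
        base = rng.standard_normal(GRID.shape) * 0.001

        def make(i):
            d = base + rng.standard_normal(GRID.shape) * 0.002
            d[3, 3, 3] = seed_vals[i]  # this voxel equals the seed value exactly
            return d

        maps = self._rates(make, n, rng)
        seed = SphereSeed((12, 12, 12), 6.0, GRID)
        res = map_sdn(maps, seed_vals, cov, FULL_MASK, seed)
        # perfect fit leaves only float roundoff in the residuals; the z at
        # that voxel must dominate the whole map and sit in the far tail
        z = res.zmap.data
        assert np.unravel_index(np.nanargmax(z), z.shape) == (3, 3, 3)
        assert z[3, 3, 3] > 20.0
        assert z[3, 3, 3] <= Z_CLAMP

    def test_invariant_to_seed_value_shift(self, rng):
        n = 16
        cov = _cov(n, rng)
        maps = self._rates(lambda i: rng.standard_normal(GRID.shape), n, rng)
        vals = rng.standard_normal(n)
        seed = SphereSeed((12, 12, 12), 6.0, GRID)
        z1 = map_sdn(maps, vals, cov, FULL_MASK, seed).zmap.data
        z2 = map_sdn(maps, vals + 123.4, cov, FULL_MASK, seed).zmap.data
        assert np.allclose(z1, z2, atol=1e-8)

    def test_zero_variance_seed_rejected(self, rng):
        n = 16
        cov = _cov(n, rng)
        maps = self._rates(lambda i: rng.standard_normal(GRID.shape), n, rng)
        seed = SphereSeed((12, 12, 12), 6.0, GRID)
        with pytest.raises(ValueError, match="zero-variance"):
            map_sdn(maps, np.ones(n), cov, FULL_MASK, seed)

    def test_null_coupling_calibrated(self, rng):
        # voxel rates independent of seed values: ~0.5% of voxels at p<0.005
        n = 30
        cov = _cov(n, rng)
        maps = self._rates(lambda i: rng.standard_normal(GRID.shape), n, rng)
        vals = rng.standard_normal(n)
        seed = SphereSeed((12, 12, 12), 6.0, GRID)
        res = map_sdn(maps, vals, cov, FULL_MASK, seed)
        frac = float((2 * stats.norm.sf(np.abs(res.zmap.data)) < 0.005).mean())
        se = np.sqrt(0.005 * 0.995 / GRID.n_voxels)
        assert abs(frac - 0.005) < 4 * se


class TestTopPercentMask:
    def test_full_percent_returns_mask(self, rng):
        z = _zmap(rng.standard_normal(GRID.shape))
        net = top_percent_mask(z, 100.0)
        assert np.array_equal(net.data, FULL_MASK.data)

    def test_ten_of_ten_unique_values(self, rng):
        grid = Grid((12, 12, 12), 2.0)
        m = np.zeros(grid.shape, bool)
        m.ravel()[:10] = True
        mask = AnalysisMask(m, grid)
        data = np.zeros(grid.shape)
        data.ravel()[:10] = np.arange(10.0)
        z = StatMap(data, "z", np.inf, "t", grid, mask)
        net = top_percent_mask(z, 10.0, mask)
        assert net.size_voxels == 1
        assert net.data.ravel()[9]  # the argmax voxel

    def test_matches_sort_oracle_and_nesting(self, rng):
        z = _zmap(rng.standard_normal(GRID.shape))
        prev = None
        n_mask = FULL_MASK.n_voxels
        for pct in range(1, 11):
            net = top_percent_mask(z, float(pct))
            n_keep = int(np.ceil(pct / 100 * n_mask))
            assert net.size_voxels == n_keep
            cutoff = np.sort(z.data.ravel())[::-1][n_keep - 1]
            assert z.data[net.data].min() >= cutoff - 1e-12
            if prev is not None:
                assert (prev & ~net.data).sum() == 0  # nested
            prev = net.data

    def test_percent_out_of_range_rejected(self, rng):
        z = _zmap(rng.standard_normal(GRID.shape))
        for pct in (0.0, -1.0, 101.0):
            with pytest.raises(ValueError):
                top_percent_mask(z, pct)
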