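"""Kernel UDs, LSCV bandwidth, isopleths, BA overlap, permutation test."""
import numpy as np
import pytest

from sulakit.space_use import (
    UDGrid,
    ba_overlap,
    fit_kernel_ud,
    isopleth_mask,
    isopleth_mass,
    lscv_bandwidth,
    lscv_score,
    make_grid,
    permutation_test,
    reference_bandwidth,
)

EXTENT = (-25.5, -23.5, 15.5, 17.5)


def cloud(rng, center, n=60, sd=0.15):
    return np.column_stack(
        [rng.normal(center[0], sd, n), rng.normal(center[1], sd, n)]
    )


@pytest.fixture()
def grid():
    return make_grid(EXTENT)


class TestKernelUD:
    def test_mass_normalized(self, rng, grid):
        ud = fit_kernel_ud(cloud(rng, (-24.5, 16.5)), *grid, h=0.1)
        assert ud.mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert (ud.mass >= 0).all()

    def test_single_point_peaks_in_containing_cell(self, grid):
        pt = np.array([[-24.5177, 16.4423]])
        ud = fit_kernel_ud(pt, *grid, h=0.05, min_points=1)
        iy, ix = np.unravel_index(ud.mass.argmax(), ud.mass.shape)
        lon, lat = grid
        assert abs(lon[ix] - pt[0, 0]) <= 0.04 + 1e-12
        assert abs(lat[iy] - pt[0, 1]) <= 0.04 + 1e-12

    def test_matches_naive_mixture_oracle(self, rng):
        """Cellwise equality with a double-loop Gaussian-mixture density."""
        pts = cloud(rng, (-24.6, 16.4), n=20)
        lon = np.linspace(-25.2, -24.0, 30)
        lat = np.linspace(15.9, 17.1, 30)
        h = 0.12
        ud = fit_kernel_ud(pts, lon, lat, h)
        naive = np.zeros((30, 30))
        for iy in range(30):
            for ix in range(30):
                for p in pts:
                    d2 = (lon[ix] - p[0]) ** 2 + (lat[iy] - p[1]) ** 2
                    naive[iy, ix] += np.exp(-d2 / (2 * h**2))
        naive /= naive.sum()
        assert np.abs(ud.mass - naive).max() < 1e-10

    def test_too_few_points_rejected(self, grid):
        with pytest.raises(ValueError):
            fit_kernel_ud(np.zeros((3, 2)), *grid, h=0.1)


class TestLSCV:
    def test_within_factor_two_of_reference_rule(self, rng):
        pts = cloud(rng, (-24.5, 16.5), n=400, sd=0.2)
        h, degenerate = lscv_bandwidth(pts)
        href = reference_bandwidth(pts)
        assert not degenerate
        assert href / 2 <= h <= href * 2

    def test_returned_h_is_local_minimum(self, rng):
        pts = cloud(rng, (-24.5, 16.5), n=150, sd=0.2)
        h, _ = lscv_bandwidth(pts)
        assert lscv_score(pts, h) <= lscv_score(pts, h / 2)
        assert lscv_score(pts, h) <= lscv_score(pts, 2 * h)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            lscv_bandwidth(cloud(rng, (-24.5, 16.5), n=8))

    def test_identical_points_degenerate(self):
        with pytest.raises(ValueError):
            lscv_bandwidth(np.tile([[-24.5, 16.5]], (15, 1)))


class TestIsopleth:
    def test_level_one_covers_all_positive_mass(self, rng, grid):
        ud = fit_kernel_ud(cloud(rng, (-24.5, 16.5)), *grid, h=0.1)
        mask = isopleth_mask(ud, 1.0)
        assert mask.sum() == (ud.mass > 0).sum()

    def test_core_region_nested_in_home_range(self, rng, grid):
        ud = fit_kernel_ud(cloud(rng, (-24.5, 16.5)), *grid, h=0.1)
        fr = isopleth_mask(ud, 0.50)
        hr = isopleth_mask(ud, 0.95)
        assert not (fr & ~hr).any()

    def test_minimality_against_sort_and_scan_oracle(self, rng, grid):
        ud = fit_kernel_ud(cloud(rng, (-24.5, 16.5), n=80), *grid, h=0.08)
        for level in (0.5, 0.95):
            mask = isopleth_mask(ud, level)
            enclosed = float(ud.mass[mask].sum())
            assert enclosed >= level
            largest = float(ud.mass[mask].min()) if mask.any() else 0.0
            # Oracle: dropping the smallest included cell must fall below level
            assert enclosed - ud.mass[mask].min() < level or np.isclose(
                largest, 0.0
            )

    def test_bad_level_rejected(self, rng, grid):
        ud = fit_kernel_ud(cloud(rng, (-24.5, 16.5)), *grid, h=0.1)
        with pytest.raises(ValueError):
            isopleth_mask(ud, 0.0)


class TestBAOverlap:
    def test_identical_uds_give_one(self, rng, grid):
        ud = fit_kernel_ud(cloud(rng, (-24.5, 16.5)), *grid, h=0.1)
        assert ba_overlap(ud, ud, 0.95) == pytest.approx(1.0, abs=1e-12)
        assert ba_overlap(ud, ud, None) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_give_zero(self, grid):
        lon, lat = grid
        m1 = np.zeros((len(lat), len(lon)))
        m2 = np.zeros_like(m1)
        m1[:5, :5] = 1.0 / 25
        m2[-5:, -5:] = 1.0 / 25
        ud1 = UDGrid(lon, lat, m1, 0.1)
        ud2 = UDGrid(lon, lat, m2, 0.1)
        assert ba_overlap(ud1, ud2, None) == 0.0

    def test_matches_naive_sqrt_sum_oracle(self, rng, grid):
        lon, lat = grid
        for _ in range(5):
            a = rng.random((len(lat), len(lon)))
            b = rng.random((len(lat), len(lon)))
            ud1 = UDGrid(lon, lat, a / a.sum(), 0.1)
            ud2 = UDGrid(lon, lat, b / b.sum(), 0.1)
            naive = sum(
                np.sqrt(ud1.mass[i, j] * ud2.mass[i, j])
                for i in range(len(lat))
                for j in range(len(lon))
            )
            assert ba_overlap(ud1, ud2, None) == pytest.approx(naive, abs=1e-12)

    def test_symmetry_and_range(self, rng, grid):
        ud1 = fit_kernel_ud(cloud(rng, (-24.7, 16.4)), *grid, h=0.1)
        ud2 = fit_kernel_ud(cloud(rng, (-24.3, 16.7)), *grid, h=0.1)
        ba = ba_overlap(ud1, ud2, 0.95)
        assert ba == ba_overlap(ud2, ud1, 0.95)
        assert 0.0 <= ba <= 1.0

    def test_grid_mismatch_rejected(self, rng, grid):
        ud1 = fit_kernel_ud(cloud(rng, (-24.5, 16.5)), *grid, h=0.1)
        lon2, lat2 = make_grid((-25.5, -23.5, 15.0, 17.0))
        ud2 = fit_kernel_ud(cloud(rng, (-24.5, 16.0)), lon2, lat2, h=0.1)
        with pytest.raises(ValueError):
            ba_overlap(ud1, ud2)


def groups_from_common_distribution(rng, n_a=4, n_b=4, center=(-24.5, 16.5)):
    pa = {f"a{i}": cloud(rng, center, n=25, sd=0.2) for i in range(n_a)}
    pb = {f"b{i}": cloud(rng, center, n=25, sd=0.2) for i in range(n_b)}
    return pa, pb


class TestPermutationTest:
    GRID = make_grid((-25.3, -23.7, 15.7, 17.3))

    def test_default_produces_1000_permutations(self, rng):
        pa, pb = groups_from_common_distribution(rng)
        res = permutation_test(pa, pb, *self.GRID, h=0.1, seed=1)
        assert res.n_perm == 1000
        assert len(res.permuted_ba) == 1000

    def test_null_calibration_p_approximately_uniform(self):
        """Exchangeable groups: mean p over 50 seeded runs is near 0.5."""
        ps = []
        for seed in range(50):
            r = np.random.default_rng(1000 + seed)
            pa, pb = groups_from_common_distribution(r)
            res = permutation_test(pa, pb, *self.GRID, h=0.1, n_perm=99, seed=seed)
            ps.append(res.p_value)
        assert 0.35 <= float(np.mean(ps)) <= 0.65

    def test_power_for_separated_groups(self):
        """Distinct foraging centers: p <= 0.05 in >= 95% of seeded runs."""
        hits = 0
        runs = 50
        for seed in range(runs):
            r = np.random.default_rng(2000 + seed)
            pa = {f"a{i}": cloud(r, (-24.9, 16.2), n=25, sd=0.1) for i in range(4)}
            pb = {f"b{i}": cloud(r, (-24.1, 16.8), n=25, sd=0.1) for i in range(4)}
            res = permutation_test(pa, pb, *self.GRID, h=0.1, n_perm=99, seed=seed)
            hits += res.p_value <= 0.05
        assert hits / runs >= 0.95

    def test_single_individual_group_rejected(self, rng):
        pa, pb = groups_from_common_distribution(rng, n_a=1)
        with pytest.raises(ValueError):
            permutation_test(pa, pb, *self.GRID, h=0.1)

    def test_p_value_definition(self, rng):
        pa, pb = groups_from_common_distribution(rng)
        res = permutation_test(pa, pb, *self.GRID, h=0.1, n_perm=199, seed=3)
        assert res.p_value == (res.permuted_ba < res.observed_ba).sum() / 199

    def test_mass_enclosed_meets_levels(self, rng):
        ud = fit_kernel_ud(cloud(rng, (-24.5, 16.5), n=500), *make_grid(EXTENT), h=0.08)
        assert isopleth_mass(ud, 0.50) >= 0.50
        assert isopleth_mass(ud, 0.95) >= 0.95
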