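"""Gamma analysis, profiles, difference histograms and isodose contours."""

import numpy as np
import pytest

from protonprep import (
    GammaParams,
    dose_difference_histogram,
    extract_isodose,
    extract_profile,
    gamma_index,
)
from protonprep.errors import DomainError, GeometryMismatchError

from conftest import make_grid
from oracles import brute_force_gamma


class TestGammaBasics:
    def test_identical_grids_all_zero(self, small_grid_pair):
        ref, _ = small_grid_pair
        res = gamma_index(ref, ref)
        assert res.pass_rate == 100.0
        assert np.nanmax(res.gamma_map) == 0.0
        assert res.n_passing == res.n_evaluated

    def test_threshold_excludes_low_dose_voxels(self):
        vals = np.full((3, 3, 3), 0.09)
        vals[1, 1, 1] = 1.0  # normalization voxel
        ref = make_grid(vals)
        res = gamma_index(ref, ref, GammaParams(low_dose_threshold=10.0))
        assert res.n_evaluated == 1  # only the 100% voxel
        assert res.excluded.sum() == 26

    def test_zero_reference_is_error(self):
        ref = make_grid(np.zeros((3, 3, 3)))
        with pytest.raises(DomainError):
            gamma_index(ref, ref)

    def test_ramp_shifted_by_dta_gives_unit_gamma(self):
        """Closed form: a 1D linear ramp shifted by s has, at interior
        points, gamma = min over r of sqrt(r^2/dta^2 + (g(r-s))^2/dD^2)
        with g the dose gradient; for a shallow ramp shifted by exactly
        the DTA the minimum is essentially the pure-distance solution,
        gamma = 1 (attained at r = s = dta)."""
        n = 24
        spacing = 2.0
        x = np.arange(n) * spacing
        ramp = 1.0 + 0.001 * x  # shallow: dose term negligible at r = s
        vals = np.tile(ramp, (4, 4, 1))
        ref = make_grid(vals, spacing=spacing)
        shift = 5.0
        ev_vals = np.tile(1.0 + 0.001 * (x - shift), (4, 4, 1))
        ev = make_grid(ev_vals, spacing=spacing)
        params = GammaParams(dose_criterion=7.0, dta_criterion=5.0, low_dose_threshold=0.0)
        res = gamma_index(ref, ev, params)
        interior = res.gamma_map[:, :, 3:-3]
        assert np.nanmax(interior) <= 1.0 + 1e-6
        assert res.pass_rate == 100.0

    def test_uniform_ramp_closed_form(self):
        """Pure dose offset on a flat field: gamma = |offset| / dD exactly
        (no spatial trade-off can help a spatially uniform difference)."""
        ref = make_grid(np.full((4, 6, 6), 1.0))
        ev = make_grid(np.full((4, 6, 6), 1.035))
        params = GammaParams(dose_criterion=7.0, dta_criterion=5.0, low_dose_threshold=0.0)
        res = gamma_index(ref, ev, params)
        assert np.nanmax(np.abs(res.gamma_map - 0.5)) < 1e-6


class TestGammaOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ref_vals = rng.uniform(0.2, 2.0, (6, 8, 8))
        ev_vals = ref_vals * (1 + rng.normal(0, 0.05, ref_vals.shape))
        ref, ev = make_grid(ref_vals), make_grid(ev_vals)
        params = GammaParams(search_radius_factor=1.5)
        res = gamma_index(ref, ev, params)
        oracle = brute_force_gamma(ref, ev, params)
        m = np.isfinite(oracle)
        assert np.nanmax(np.abs(res.gamma_map[m] - oracle[m])) < 1e-3
        assert np.array_equal(res.gamma_map[m] <= 1, oracle[m] <= 1)

    def test_local_mode_matches_oracle(self):
        rng = np.random.default_rng(9)
        ref_vals = rng.uniform(0.5, 2.0, (4, 6, 6))
        ev_vals = ref_vals * (1 + rng.normal(0, 0.06, ref_vals.shape))
        ref, ev = make_grid(ref_vals), make_grid(ev_vals)
        params = GammaParams(normalization="local", search_radius_factor=1.5)
        res = gamma_index(ref, ev, params)
        oracle = brute_force_gamma(ref, ev, params)
        m = np.isfinite(oracle)
        assert np.nanmax(np.abs(res.gamma_map[m] - oracle[m])) < 1e-3


class TestGammaProperties:
    def test_loosening_criteria_never_decreases_pass_rate(self):
        rates = {}
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ref_vals = rng.uniform(0.2, 2.0, (5, 6, 6))
            ev_vals = ref_vals * (1 + rng.normal(0, 0.08, ref_vals.shape))
            ref, ev = make_grid(ref_vals), make_grid(ev_vals)
            base = gamma_index(ref, ev, GammaParams(3.0, 2.0)).pass_rate
            looser_dd = gamma_index(ref, ev, GammaParams(6.0, 2.0)).pass_rate
            looser_dta = gamma_index(ref, ev, GammaParams(3.0, 4.0)).pass_rate
            assert looser_dd >= base - 1e-9
            assert looser_dta >= base - 1e-9
            rates[seed] = base

    def test_global_mode_scale_invariance(self, small_grid_pair):
        ref, ev = small_grid_pair
        res1 = gamma_index(ref, ev)
        ref2 = make_grid(ref.values * 7.3)
        ev2 = make_grid(ev.values * 7.3)
        res2 = gamma_index(ref2, ev2)
        assert np.allclose(res1.gamma_map, res2.gamma_map, equal_nan=True, atol=1e-12)

    def test_plane_selector_restricts_to_slice(self, small_grid_pair):
        ref, ev = small_grid_pair
        res = gamma_index(ref, ev, plane=("axial", 3))
        assert res.gamma_map.shape == ref.shape[1:]
        full = gamma_index(ref, ev)
        # 2D search space is a subset of 3D: per-voxel gamma can only grow
        m = np.isfinite(res.gamma_map)
        assert np.all(res.gamma_map[m] >= full.gamma_map[3][m] - 1e-12)


class TestProfiles:
    def test_constant_grid_constant_profile(self):
        g = make_grid(np.full((4, 4, 4), 2.0))
        prof = extract_profile(g, [0, 0, 0], [9, 9, 9], 10)
        assert np.allclose(prof.values, 2.0)
        assert prof.positions[0] == 0.0
        assert prof.positions[-1] == pytest.approx(np.sqrt(3) * 9)

    def test_first_sample_at_image_position(self, rng):
        g = make_grid(rng.uniform(1, 2, (4, 4, 4)), origin=(5.0, -3.0, 2.0))
        prof = extract_profile(g, [5.0, -3.0, 2.0], [5.0, -3.0, 8.0], 5)
        assert prof.values[0] == pytest.approx(g.physical()[0, 0, 0], rel=1e-12)

    def test_linear_ramp_closed_form(self):
        n, spacing = 10, 2.0
        vals = np.tile(np.arange(n) * 0.1, (4, 4, 1))
        g = make_grid(vals, spacing=spacing)
        prof = extract_profile(g, [0, 6, 6], [18, 6, 6], 37)
        expected = 0.1 * prof.positions / spacing
        assert np.allclose(prof.values, expected, atol=1e-9)

    def test_endpoint_outside_is_bounds_error(self):
        g = make_grid(np.ones((3, 3, 3)))
        with pytest.raises(IndexError):
            extract_profile(g, [0, 0, 0], [100, 0, 0], 5)


class TestHistogram:
    def test_identical_grids_single_bin(self, small_grid_pair):
        ref, _ = small_grid_pair
        edges, counts, n_under, n_over = dose_difference_histogram(ref, ref, 20.0, 40)
        assert n_under == n_over == 0
        center_bin = np.digitize(0.0, edges) - 1
        assert counts[center_bin] == ref.values.size

    def test_five_percent_global_scale_at_max_voxel(self, rng):
        vals = rng.uniform(0.2, 1.0, (4, 4, 4))
        vals[2, 2, 2] = 1.0  # the normalization (max-dose) voxel
        ref = make_grid(vals)
        ev = make_grid(vals * 1.05)
        edges, counts, _, _ = dose_difference_histogram(ref, ev, 20.0, 400)
        diff_at_max = (1.05 - 1.0) / 1.0 * 100
        bin_idx = np.digitize(diff_at_max, edges) - 1
        assert counts[bin_idx] >= 1  # the max voxel lands exactly at +5%

    def test_truncation_counts_overflow(self):
        ref = make_grid(np.full((3, 3, 3), 1.0))
        vals = np.full((3, 3, 3), 1.0)
        vals[0, 0, 0] = 1.25  # +25% of max
        ev = make_grid(vals)
        _, counts, n_under, n_over = dose_difference_histogram(ref, ev, 20.0, 10)
        assert n_over == 1 and n_under == 0
        assert counts.sum() == 26

    def test_geometry_mismatch_rejected(self, rng):
        a = make_grid(rng.uniform(0, 1, (3, 3, 3)), spacing=2.0)
        b = make_grid(rng.uniform(0, 1, (3, 3, 3)), spacing=3.0)
        with pytest.raises(GeometryMismatchError):
            dose_difference_histogram(a, b)


class TestIsodose:
    def test_constant_slice_no_contours(self):
        g = make_grid(np.full((3, 5, 5), 1.0))
        out = extract_isodose(g, ("axial", 1), [0.5])
        assert out[0.5] == []

    def test_gaussian_contour_radius(self):
        n, spacing, sigma = 41, 1.0, 8.0
        c = (n - 1) / 2 * spacing
        x = np.arange(n) * spacing
        xx, yy = np.meshgrid(x, x)
        slab = np.exp(-((xx - c) ** 2 + (yy - c) ** 2) / (2 * sigma**2))
        g = make_grid(np.stack([slab] * 3), spacing=spacing)
        r_target = 10.0
        level = float(np.exp(-(r_target**2) / (2 * sigma**2)))
        contours = extract_isodose(g, ("axial", 1), [level])[level]
        assert len(contours) == 1
        radii = np.hypot(contours[0][:, 0] - c, contours[0][:, 1] - c)
        assert abs(radii.mean() - r_target) < spacing

    def test_level_above_max_is_empty(self):
        g = make_grid(np.full((3, 4, 4), 1.0))
        assert extract_isodose(g, ("axial", 0), [5.0])[5.0] == []
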