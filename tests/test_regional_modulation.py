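import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mertbolus as mb


def direct_rm(values, p_mask, q_mask, sf, mode, spacing):
    """Independent oracle: literal double-loop evaluation of the regional
    smoothing definition (strict r_pq < SF, simultaneous update)."""
    out = values.copy()
    pidx = np.argwhere(p_mask)
    qidx = np.argwhere(q_mask)
    for pi, pj in pidx:
        num, den = 0.0, 1.0
        for qi, qj in qidx:
            if (qi, qj) == (pi, pj):
                continue
            r = spacing * np.hypot(qi - pi, qj - pj)
            if r < sf:
                w = np.exp(-r ** 2 / (2 * sf ** 2))
                num += w * values[qi, qj]
                den += w
        out[pi, pj] = num / den if mode == 1 else (values[pi, pj] + num) / den
    return out


class TestSmoothKernel:
    @pytest.mark.parametrize("mode", [1, 2])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_direct_summation_oracle(self, mode, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 5, (20, 20))
        p = rng.random((20, 20)) < 0.15
        got = mb.smooth(values, p, sf=6.0, mode=mode, spacing=2.5)
        want = direct_rm(values, p, ~p, 6.0, mode, 2.5)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_null_field_mode1_gives_zero(self):
        values = np.zeros((10, 10))
        p = np.zeros((10, 10), bool)
        p[4:6, 4:6] = True
        out = mb.smooth(values, p, sf=5.0, mode=1, spacing=2.5)
        np.testing.assert_array_equal(out, 0.0)

    def test_mode2_preserves_constant_field(self):
        values = np.full((12, 12), 7.3)
        p = np.zeros((12, 12), bool)
        p[3:9, 3:9] = True
        out = mb.smooth(values, p, sf=10.0, mode=2, spacing=2.5)
        np.testing.assert_allclose(out, 7.3, atol=1e-12)

    def test_mode1_shrinks_constant_field(self):
        values = np.full((12, 12), 4.0)
        p = np.zeros((12, 12), bool)
        p[5, 5] = True
        out = mb.smooth(values, p, sf=10.0, mode=1, spacing=2.5)
        assert 0 < out[5, 5] < 4.0  # c * sum(w) / (1 + sum(w))

    def test_empty_qset_mode1_zero_mode2_identity(self):
        # region covers the whole grid -> no q points at all
        values = np.full((8, 8), 2.5)
        p = np.ones((8, 8), bool)
        out1 = mb.smooth(values, p, sf=5.0, mode=1, spacing=2.5)
        out2 = mb.smooth(values, p, sf=5.0, mode=2, spacing=2.5)
        np.testing.assert_array_equal(out1, 0.0)
        np.testing.assert_array_equal(out2, values)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000), mode=st.sampled_from([1, 2]))
    def test_output_bounded_by_input_magnitudes(self, seed, mode):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 10, (15, 15))
        p = rng.random((15, 15)) < 0.2
        out = mb.smooth(values, p, sf=7.5, mode=mode, spacing=2.5)
        assert np.max(np.abs(out)) <= np.max(np.abs(values)) + 1e-12


class TestHotspotSmoothing:
    def test_empty_region_is_identity(self):
        values = np.random.default_rng(0).normal(0, 3, (10, 10))
        out = mb.hotspot_smoothing(values, np.zeros((10, 10), bool))
        np.testing.assert_array_equal(out, values)

    def test_isolated_spike_is_damped(self):
        values = np.zeros((15, 15))
        values[7, 7] = 12.0
        region = np.zeros((15, 15), bool)
        region[7, 7] = True
        out = mb.hotspot_smoothing(values, region, sf=10.0, spacing=2.5)
        assert abs(out[7, 7]) < 12.0
        # neighbours are q points and must not change
        assert out[7, 8] == 0.0


class TestCoverageSmoothing:
    def test_empty_region_is_identity(self):
        values = np.random.default_rng(1).normal(0, 3, (10, 10))
        out = mb.coverage_smoothing(values, np.zeros((10, 10), bool))
        np.testing.assert_array_equal(out, values)

    def test_negative_region_retained_and_annulus_pulled_negative(self):
        values = np.zeros((21, 21))
        region = np.zeros((21, 21), bool)
        region[8:13, 8:13] = True
        values[region] = -5.0
        out = mb.coverage_smoothing(values, region, sf=10.0, spacing=2.5)
        np.testing.assert_array_equal(out[region], -5.0)
        from scipy.ndimage import distance_transform_edt
        dist = distance_transform_edt(~region) * 2.5
        annulus = (dist > 0) & (dist <= 10.0)
        assert np.all(out[annulus] <= 0.0)
        assert np.all(out[annulus] > -5.0)
        inner_ring = (dist > 0) & (dist <= 2.6)
        assert np.all(out[inner_ring] < 0.0)

    def test_all_affected_points_nonpositive_for_negative_region(self):
        rng = np.random.default_rng(5)
        values = np.zeros((21, 21))
        region = rng.random((21, 21)) < 0.1
        values[region] = rng.uniform(-8, -1, region.sum())
        out = mb.coverage_smoothing(values, region, sf=10.0, spacing=2.5)
        assert np.all(out <= 1e-12)


class TestIrregularitySmoothing:
    def test_constant_grid_is_identity(self):
        values = np.full((15, 15), 6.0)
        out = mb.irregularity_smoothing(values, sf=10.0, spacing=2.5)
        np.testing.assert_array_equal(out, values)

    def test_step_edge_gradient_reduced(self):
        values = np.zeros((20, 20))
        values[10:, :] = 10.0
        out = mb.irregularity_smoothing(values, sf=10.0, spacing=2.5)
        g_pre = np.hypot(*np.gradient(values, 2.5))
        g_post = np.hypot(*np.gradient(out, 2.5))
        assert g_post.max() < g_pre.max()

    def test_smooth_hill_mostly_unflagged(self):
        ii, jj = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        r2 = (ii - 20.0) ** 2 + (jj - 20.0) ** 2
        values = 10.0 * np.exp(-r2 / (2 * 14.0 ** 2))
        gx, gy = np.gradient(values, 2.5)
        mag = np.hypot(gx, gy)
        flagged = mag > 2.0 * mag.mean()
        assert flagged.sum() <= 0.05 * values.size
        out = mb.irregularity_smoothing(values, sf=10.0, spacing=2.5)
        assert np.max(np.abs(out - values)) < 1.0


class TestMarginAdjustment:
    def test_kernel_definition(self):
        k = mb.MarginKernel(sigma=10.0)
        assert k(0.0) == 1.0
        assert k(k.k1) == pytest.approx(0.01, abs=1e-12)
        # branch values at the inner boundary (r_pm = 0)
        assert 10.0 * (1 - k(max(k.k1 - 0.0, 0.0))) == pytest.approx(9.9)
        assert -10.0 * (1 + k(max(k.k1 - 0.0, 0.0))) == pytest.approx(-10.1)
        # r_pm >= K1: full kernel, positive thickness zeroed
        assert 10.0 * (1 - k(max(k.k1 - k.k1, 0.0))) == 0.0

    def test_default_sigma_grows_with_energy_and_applicator(self):
        s1 = mb.MarginKernel.default_sigma(9.0, 10.0)
        assert s1 == pytest.approx(np.sqrt(90.0))
        assert mb.MarginKernel.default_sigma(16.0, 10.0) > s1
        assert mb.MarginKernel.default_sigma(9.0, 14.0) > s1

    @pytest.fixture
    def square_proj(self):
        proj = np.zeros((41, 41), bool)
        proj[8:33, 8:33] = True  # 62.5 mm square at 2.5 mm spacing
        return proj

    def test_positive_branch_factor_in_unit_interval(self, square_proj):
        values = np.where(square_proj, 10.0, 0.0)
        kernel = mb.MarginKernel(sigma=10.0, border_width=10.0)
        out = mb.margin_adjustment(values, square_proj, kernel, spacing=2.5,
                                   center=(20, 20))
        changed = out != values
        assert changed.any()
        assert np.all(out[changed] >= 0.0)
        assert np.all(out[changed] < 10.0)

    def test_negative_branch_increases_magnitude(self, square_proj):
        values = np.where(square_proj, -10.0, 0.0)
        kernel = mb.MarginKernel(sigma=10.0, border_width=10.0)
        out = mb.margin_adjustment(values, square_proj, kernel, spacing=2.5,
                                   center=(20, 20))
        changed = out != values
        assert np.all(out[changed] <= -10.0)
        assert np.all(out[changed] >= -20.0)

    def test_interior_and_outside_untouched(self, square_proj):
        rng = np.random.default_rng(2)
        values = rng.normal(5, 1, (41, 41))
        kernel = mb.MarginKernel(sigma=10.0, border_width=10.0)
        out = mb.margin_adjustment(values, square_proj, kernel, spacing=2.5,
                                   center=(20, 20))
        from scipy.ndimage import distance_transform_edt
        inner = square_proj & (distance_transform_edt(square_proj) * 2.5
                               > 10.0 + 1e-9)
        np.testing.assert_array_equal(out[inner], values[inner])
        np.testing.assert_array_equal(out[~square_proj], values[~square_proj])


class TestExtrudeOutside:
    @pytest.fixture
    def disk_proj(self):
        ii, jj = np.meshgrid(np.arange(41), np.arange(41), indexing="ij")
        return (ii - 20.0) ** 2 + (jj - 20.0) ** 2 <= 8.0 ** 2

    def test_constant_boundary_extrudes_constant(self, disk_proj):
        values = np.where(disk_proj, 4.2, 0.0)
        aperture = np.ones((41, 41), bool)
        out = mb.extrude_outside(values, disk_proj, aperture, spacing=2.5,
                                 center=(20, 20))
        np.testing.assert_allclose(out[~disk_proj], 4.2)

    def test_cosine_boundary_profile_extrudes_radially(self, disk_proj):
        ii, jj = np.meshgrid(np.arange(41), np.arange(41), indexing="ij")
        theta = np.arctan2(jj - 20.0, ii - 20.0)
        values = np.where(disk_proj, np.cos(theta), 0.0)
        aperture = np.ones((41, 41), bool)
        out = mb.extrude_outside(values, disk_proj, aperture, spacing=2.5,
                                 center=(20, 20))
        outside = ~disk_proj
        # polar construction oracle: the outside point inherits cos(theta)
        assert np.max(np.abs(out[outside] - np.cos(theta[outside]))) < 0.2

    def test_beyond_aperture_zeroed(self, disk_proj):
        values = np.where(disk_proj, 4.2, 1.0)
        aperture = np.zeros((41, 41), bool)
        aperture[5:36, 5:36] = True
        out = mb.extrude_outside(values, disk_proj, aperture, spacing=2.5,
                                 center=(20, 20))
        assert np.all(out[~aperture] == 0.0)

    def test_idempotent(self, disk_proj):
        rng = np.random.default_rng(9)
        values = np.where(disk_proj, rng.normal(5, 2, (41, 41)), 0.0)
        aperture = np.ones((41, 41), bool)
        once = mb.extrude_outside(values, disk_proj, aperture, spacing=2.5,
                                  center=(20, 20))
        twice = mb.extrude_outside(once, disk_proj, aperture, spacing=2.5,
                                   center=(20, 20))
        np.testing.assert_array_equal(once, twice)

    def test_empty_ptv_projection_zeroes_outside_aperture(self):
        values = np.full((11, 11), 3.0)
        aperture = np.zeros((11, 11), bool)
        aperture[3:8, 3:8] = True
        out = mb.extrude_outside(values, np.zeros((11, 11), bool), aperture,
                                 spacing=2.5, center=(5, 5))
        assert np.all(out[~aperture] == 0.0)
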