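import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mertbolus as mb
from conftest import vertical_ray
from mertbolus.errors import SpecError


@pytest.fixture(scope="module")
def hetero_ct():
    """Water with a bone slab at depth 20-25 mm and air at 35-40 mm."""
    vox = np.zeros((50, 50, 50), np.int16)
    vox[:, :, 25:30] = 800    # z 25-30 -> depth 20-25 below z_top=50
    vox[:, :, 10:15] = -1000  # depth 35-40
    return mb.CTVolume(voxels=vox, spacing=np.ones(3),
                       origin=np.array([-25.0, -25.0, 0.0]))


@pytest.fixture(scope="module")
def table():
    return mb.CETTable()


def brute_force_integral(ray, ct, table, z_from, z_to, step=0.01):
    """Independent 0.01 mm midpoint-rule oracle."""
    n = max(1, int(np.ceil((z_to - z_from) / step)))
    h = (z_to - z_from) / n
    mids = z_from + (np.arange(n) + 0.5) * h
    off = ray.t_entry or 0.0
    hu = ct.sample_hu(ray.point(mids + off))
    return float(np.sum(table(hu)) * h)


class TestCETIntegral:
    def test_water_is_identity_medium(self, water_ct, table):
        ray = vertical_ray(z_top=50.0)
        assert mb.cet_line_integral(ray, water_ct, table, 5.0, 15.0) \
            == pytest.approx(10.0, abs=1e-9)

    def test_bone_plus_water_closed_form(self, hetero_ct, table):
        # 5 mm bone (CET 1.5) then 5 mm water -> 12.5 mm water-equivalent
        ray = vertical_ray(z_top=50.0)
        weq = mb.cet_line_integral(ray, hetero_ct, table, 20.0, 30.0)
        assert weq == pytest.approx(5 * 1.5 + 5 * 1.0, abs=1e-6)

    def test_zero_range(self, water_ct, table):
        ray = vertical_ray(z_top=50.0)
        assert mb.cet_line_integral(ray, water_ct, table, 7.0, 7.0) == 0.0

    def test_out_of_volume_raises(self, water_ct, table):
        ray = vertical_ray(z_top=50.0)
        with pytest.raises(mb.errors.GeometryError):
            mb.cet_line_integral(ray, water_ct, table, 40.0, 80.0)

    def test_matches_fine_step_oracle_on_random_oblique_rays(self, hetero_ct,
                                                             table):
        rng = np.random.default_rng(42)
        for _ in range(50):
            x, y = rng.uniform(-8, 8, 2)
            tilt = rng.uniform(-0.15, 0.15, 2)
            ray = mb.Ray(origin=np.array([x, y, 55.0]),
                         direction=np.array([tilt[0], tilt[1], -1.0]),
                         t_entry=None)
            z0 = rng.uniform(7.0, 15.0)
            z1 = z0 + rng.uniform(5.0, 25.0)
            got = mb.cet_line_integral(ray, hetero_ct, table, z0, z1)
            want = brute_force_integral(ray, hetero_ct, table, z0, z1)
            assert got == pytest.approx(want, abs=0.05)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(2.0, 20.0), span=st.floats(0.5, 25.0),
           frac=st.floats(0.01, 0.99))
    def test_additive_over_subintervals(self, a, span, frac):
        vox = np.zeros((30, 30, 50), np.int16)
        vox[:, :, 20:30] = 800
        ct = mb.CTVolume(voxels=vox, spacing=np.ones(3),
                         origin=np.array([-15.0, -15.0, 0.0]))
        table = mb.CETTable()
        ray = vertical_ray(z_top=50.0)
        b = a + frac * span
        c = a + span
        whole = mb.cet_line_integral(ray, ct, table, a, c)
        parts = mb.cet_line_integral(ray, ct, table, a, b) \
            + mb.cet_line_integral(ray, ct, table, b, c)
        assert whole == pytest.approx(parts, abs=1e-6)


class TestCETTable:
    def test_default_anchors(self, table):
        assert table(0.0) == 1.0
        assert table(160.0) == pytest.approx(1.119)
        assert table(800.0) == pytest.approx(1.5)
        assert table(-1000.0) == pytest.approx(0.001)

    def test_non_monotone_rejected(self):
        with pytest.raises(SpecError):
            mb.CETTable(hu=np.array([-1000.0, 0.0, 800.0]),
                        density=np.array([0.001, 1.0, 0.9]))

    def test_water_anchor_required(self):
        with pytest.raises(SpecError):
            mb.CETTable(hu=np.array([-1000.0, 0.0, 800.0]),
                        density=np.array([0.1, 1.1, 1.5]))


def _uniform_depth_grids(plane, ptv_depth, iso_depth):
    ptv = np.full(plane.shape, np.nan)
    iso = np.full(plane.shape, np.nan)
    c = plane.center
    ptv[c - 3:c + 4, c - 3:c + 4] = ptv_depth
    iso[c - 3:c + 4, c - 3:c + 4] = iso_depth
    return ptv, iso


def _ray_grid(plane, beam):
    from mertbolus.beam_geometry import ray_directions
    dirs = ray_directions(beam, plane)
    rays = np.empty(plane.shape, dtype=object)
    for i in range(plane.n):
        for j in range(plane.n):
            rays[i, j] = mb.Ray(origin=beam.source, direction=dirs[i, j],
                                t_entry=float(beam.ssd_cm * 10.0))
    return rays


@pytest.fixture(scope="module")
def setup(water_ct):
    beam = mb.BeamSpec(energy=12.0, applicator_cm=4.0,
                       isocenter=np.array([0.0, 0.0, 50.0]))
    plane = mb.build_sbt_plane(beam, margin_mm=0.0)
    return water_ct, beam, plane, _ray_grid(plane, beam)


class TestComputeSBT:
    def test_water_gap_divided_by_bolus_cet(self, setup, table):
        ct, beam, plane, rays = setup
        ptv, iso = _uniform_depth_grids(plane, 20.0, 30.0)
        sbt = mb.compute_sbt(plane, rays, ptv, iso, ct, table)
        c = plane.center
        assert sbt.values[c, c] == pytest.approx(10.0 / 1.119, abs=1e-3)
        assert sbt.valid[c, c] and not sbt.flagged.any()
        assert np.all(sbt.values[~sbt.valid] == 0.0)

    def test_zero_gap_gives_zero(self, setup, table):
        ct, beam, plane, rays = setup
        ptv, iso = _uniform_depth_grids(plane, 25.0, 25.0)
        sbt = mb.compute_sbt(plane, rays, ptv, iso, ct, table)
        assert np.all(sbt.values == 0.0)

    def test_negative_gap_gives_negative_sbt(self, setup, table):
        ct, beam, plane, rays = setup
        ptv, iso = _uniform_depth_grids(plane, 30.0, 22.0)
        sbt = mb.compute_sbt(plane, rays, ptv, iso, ct, table)
        c = plane.center
        assert sbt.values[c, c] == pytest.approx(-8.0 / 1.119, abs=1e-3)

    def test_linearity_in_homogeneous_gap(self, setup, table):
        ct, beam, plane, rays = setup
        ptv, iso = _uniform_depth_grids(plane, 20.0, 25.0)
        s1 = mb.compute_sbt(plane, rays, ptv, iso, ct, table)
        ptv, iso = _uniform_depth_grids(plane, 20.0, 30.0)
        s2 = mb.compute_sbt(plane, rays, ptv, iso, ct, table)
        c = plane.center
        assert s2.values[c, c] == pytest.approx(2 * s1.values[c, c], abs=1e-6)

    def test_heterogeneous_gap_closed_form(self, hetero_ct, table):
        beam = mb.BeamSpec(energy=12.0, applicator_cm=4.0,
                           isocenter=np.array([0.0, 0.0, 50.0]))
        plane = mb.build_sbt_plane(beam, margin_mm=0.0)
        rays = _ray_grid(plane, beam)
        ptv, iso = _uniform_depth_grids(plane, 20.0, 30.0)
        sbt = mb.compute_sbt(plane, rays, ptv, iso, hetero_ct, table)
        c = plane.center
        assert sbt.values[c, c] == pytest.approx(12.5 / 1.119, abs=1e-3)

    def test_missing_isodose_crossing_filled_from_neighbours(self, setup,
                                                             table):
        ct, beam, plane, rays = setup
        ptv, iso = _uniform_depth_grids(plane, 20.0, 30.0)
        c = plane.center
        iso[c, c] = np.nan  # PTV ray without a 90% crossing
        sbt = mb.compute_sbt(plane, rays, ptv, iso, ct, table)
        assert sbt.flagged[c, c] and sbt.flagged.sum() == 1
        assert sbt.values[c, c] == pytest.approx(10.0 / 1.119, abs=1e-2)


class TestApplySBT:
    def test_first_iteration_thickness_equals_sbt(self):
        sbt = mb.SBTGrid(values=np.full((5, 5), 3.0), valid=np.ones((5, 5),
                                                                    bool))
        thick, clamped = mb.apply_sbt(np.zeros((5, 5)), sbt)
        np.testing.assert_allclose(thick, 3.0)
        assert clamped == 0

    def test_negative_result_clamped_to_zero(self):
        sbt = mb.SBTGrid(values=np.full((3, 3), -8.0),
                         valid=np.ones((3, 3), bool))
        thick, clamped = mb.apply_sbt(np.full((3, 3), 5.0), sbt)
        np.testing.assert_allclose(thick, 0.0)
        assert clamped == 9

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_clamped_identity_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0, 20, (6, 6))
        v = rng.uniform(-30, 30, (6, 6))
        sbt = mb.SBTGrid(values=v, valid=np.ones((6, 6), bool))
        out, clamped = mb.apply_sbt(t, sbt)
        assert np.all(out >= 0)
        assert clamped == int(np.count_nonzero(t + v < 0))
        zero_sbt = mb.SBTGrid(values=np.zeros((6, 6)),
                              valid=np.ones((6, 6), bool))
        np.testing.assert_array_equal(mb.apply_sbt(t, zero_sbt)[0], t)
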