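import numpy as np
import pytest

import mertbolus as mb


@pytest.fixture(scope="session")
def water_ct():
    """50 mm water cube at 1 mm voxels, origin at (-25, -25, 0)."""
    vox = np.zeros((50, 50, 50), dtype=np.int16)
    return mb.CTVolume(voxels=vox, spacing=np.ones(3),
                       origin=np.array([-25.0, -25.0, 0.0]))


@pytest.fixture(scope="session")
def flat_phantom():
    """Flat slab phantom with a box PTV at constant distal depth 25 mm."""
    spec = mb.PhantomSpec(size_mm=(120, 120, 100), spacing_mm=2.5,
                          ptv_half_x_mm=20, ptv_half_y_mm=20,
                          ptv_proximal_mm=5, ptv_distal_min_mm=25,
                          ptv_distal_max_mm=25)
    return mb.make_wedge_phantom(spec)


@pytest.fixture(scope="session")
def flat_beam(flat_phantom):
    ct, ss = flat_phantom
    return mb.beam_for_phantom(ct, ss["BODY"], energy=12.0, applicator_cm=6.0)


@pytest.fixture(scope="session")
def flat_design(flat_phantom, flat_beam):
    ct, ss = flat_phantom
    return mb.run_design(ct, ss, mb.DesignConfig(beam=flat_beam))


@pytest.fixture(scope="session")
def wedge_phantom():
    """Water cube with wedge PTV and distal bone/air slabs at 2.5 mm voxels."""
    spec = mb.PhantomSpec(
        size_mm=(200, 200, 200), spacing_mm=2.5,
        ptv_half_x_mm=30, ptv_half_y_mm=30,
        ptv_proximal_mm=5, ptv_distal_min_mm=20, ptv_distal_max_mm=40,
        inserts=[mb.Insert(lo=(-30, -25, 140), hi=(-5, 25, 150),
                           material="bone"),
                 mb.Insert(lo=(5, -25, 140), hi=(30, 25, 150),
                           material="air")])
    return mb.make_wedge_phantom(spec)


@pytest.fixture(scope="session")
def wedge_beam(wedge_phantom):
    ct, ss = wedge_phantom
    return mb.beam_for_phantom(ct, ss["BODY"], energy=12.0, applicator_cm=10.0)


@pytest.fixture(scope="session")
def wedge_design(wedge_phantom, wedge_beam):
    ct, ss = wedge_phantom
    return mb.run_design(ct, ss, mb.DesignConfig(beam=wedge_beam,
                                                 max_iterations=3))


def vertical_ray(x=0.0, y=0.0, z_top=50.0, entry=True):
    """Downward ray entering a slab whose surface is at z_top."""
    ray = mb.Ray(origin=np.array([x, y, z_top + 1000.0]),
                 direction=np.array([0.0, 0.0, -1.0]))
    if entry:
        ray.t_entry = 1000.0
    return ray
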