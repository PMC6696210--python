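import numpy as np
import pytest

from helix_txac.geometry import DetectorRing, SourceTrajectory
from helix_txac.phantoms import GridSpec, make_cylinder_phantom


@pytest.fixture(scope="session")
def small_ring():
    """Tiny detector for fast unit tests (7.85 mm crystal pitch)."""
    return DetectorRing(ring_radius=120.0, n_rings=4, ring_spacing=10.0,
                        crystals_per_ring=96)


@pytest.fixture(scope="session")
def desk_ring():
    return DetectorRing.desk()


@pytest.fixture(scope="session")
def small_traj():
    """Helix that fits inside the small ring and covers its axial FOV."""
    return SourceTrajectory(helix_radius=80.0, z_start=-15.0, z_end=15.0,
                            pitch=10.0, speed=200.0)


@pytest.fixture(scope="session")
def static_traj():
    """Quasi-static pellet: planar orbit at z = 0 crawling at 1 mm/s, so
    travel within any test time bin is far below the crystal pitch."""
    return SourceTrajectory(helix_radius=80.0, z_start=0.0, z_end=0.0,
                            pitch=10.0, speed=1.0)


@pytest.fixture(scope="session")
def desk_traj():
    """Default helix matching the desk ring (covers its axial FOV)."""
    return SourceTrajectory(helix_radius=100.0, z_start=-48.0, z_end=48.0,
                            pitch=24.0, speed=300.0)


@pytest.fixture(scope="session")
def water_cylinder():
    """60 mm water cylinder on a coarse grid, fits the small ring."""
    return make_cylinder_phantom(60.0, 36.0, "water", GridSpec.default(120.0, 3.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
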