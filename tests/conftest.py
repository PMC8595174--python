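import numpy as np
import pytest

from tpmsopt import geometry as geo


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def gyroid_cell_32():
    """One gyroid unit cell at 32 voxels/cell, volume fraction 0.5."""
    t = geo.calibrate_t("gyroid", 0.5, resolution=64)
    return geo.voxelize(geo.ScaffoldSpec("gyroid", t), 32)


@pytest.fixture(scope="session")
def sphere_pore_48():
    """1 mm solid block with a centred 0.3 mm-radius spherical void."""
    return geo.make_fixture("spherical_pore", size=1.0, resolution=48, radius=0.3)


def convex_ball_state(resolution=24, radius=0.3):
    """Level-set state for an analytic solid ball in void (k = -2/r < 0)."""
    from tpmsopt.growth import LevelSetState, _smoothed_volume
    h = 1.0 / resolution
    c = (np.arange(resolution) + 0.5) * h
    X, Y, Z = c[:, None, None], c[None, :, None], c[None, None, :]
    phi = radius - np.sqrt((X - 0.5) ** 2 + (Y - 0.5) ** 2 + (Z - 0.5) ** 2)
    v0 = _smoothed_volume(phi, h)
    return LevelSetState(phi=phi, spacing=h, tau=0.0, initial_solid_volume=v0,
                         initial_void_volume=phi.size * h ** 3 - v0,
                         periodic=False)
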