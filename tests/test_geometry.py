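"""TPMS field evaluation, threshold calibration and voxelisation."""

import numpy as np
import pytest

from tpmsopt import geometry as geo
from tpmsopt.geometry import (CalibrationError, NoSurfaceError, ScaffoldSpec,
                              UnsupportedTypeError, VoxelGrid, calibrate_t,
                              export_surface, field_value, make_fixture,
                              voxelize)

ALL_TYPES = list(geo.TPMS_TYPES)


@pytest.mark.parametrize("tpms_type, t, f_expected, U_expected", [
    ("primitive", 0.5, 3.0, 8.75),     # all cosines are 1 at the origin
    ("gyroid", 1.0, 0.0, -1.0),        # all sine factors vanish
    ("neovius", 1.0, 13.0, 168.0),     # 3*3 + 4*1
])
def test_field_value_at_origin(tpms_type, t, f_expected, U_expected):
    s = field_value(tpms_type, [0.0, 0.0, 0.0], t=t)
    assert s.f == pytest.approx(f_expected, abs=1e-12)
    assert s.U == pytest.approx(U_expected, abs=1e-12)


def test_unknown_type_rejected():
    with pytest.raises(UnsupportedTypeError):
        field_value("schoen-iwp", [0, 0, 0])


@pytest.mark.parametrize("tpms_type", ALL_TYPES)
def test_field_periodicity(tpms_type, rng):
    pts = rng.uniform(-2, 2, size=(50, 3))
    base = field_value(tpms_type, pts, cell_size=1.0).f
    for axis in range(3):
        shifted = pts.copy()
        shifted[:, axis] += 1.0
        other = field_value(tpms_type, shifted, cell_size=1.0).f
        np.testing.assert_allclose(other, base, rtol=0, atol=1e-9 * (1 + np.abs(base)).max())


# the Diamond variant used here (CCC + SSS + SCS + CSS) is not invariant
# under cyclic coordinate permutation, unlike the classic Schwarz D form
@pytest.mark.parametrize("tpms_type", ["primitive", "gyroid"])
def test_cyclic_permutation_symmetry(tpms_type, rng):
    pts = rng.uniform(0, 1, size=(50, 3))
    f_xyz = field_value(tpms_type, pts).f
    f_yzx = field_value(tpms_type, pts[:, [1, 2, 0]]).f
    np.testing.assert_allclose(f_yzx, f_xyz, atol=1e-12)


def test_calibrate_t_degenerate_targets():
    assert calibrate_t("gyroid", 0.0) == 0.0
    # primitive field is a sum of three cosines, so |f| <= 3 everywhere
    assert calibrate_t("primitive", 1.0, resolution=64) == pytest.approx(3.0, abs=0.01)


def test_calibrate_t_monte_carlo_oracle():
    """Independent Monte-Carlo volume integration agrees with calibration."""
    t = calibrate_t("gyroid", 0.2, resolution=100)
    rng = np.random.default_rng(12345)
    pts = rng.random((10 ** 6, 3))
    frac = np.mean(np.abs(field_value("gyroid", pts).f) <= t)
    assert frac == pytest.approx(0.2, abs=2e-3)


@pytest.mark.parametrize("tpms_type", ALL_TYPES)
def test_voxelized_vf_matches_target(tpms_type):
    t = calibrate_t(tpms_type, 0.35, resolution=64)
    grid = voxelize(ScaffoldSpec(tpms_type, t), 64)
    assert grid.volume_fraction == pytest.approx(0.35, abs=1.5e-3)


def test_vf_monotone_in_t():
    for tpms_type in ALL_TYPES:
        tmax = calibrate_t(tpms_type, 1.0, resolution=32)
        vfs = [voxelize(ScaffoldSpec(tpms_type, t), 32).volume_fraction
               for t in np.linspace(0.0, tmax, 6)]
        assert all(b >= a for a, b in zip(vfs, vfs[1:]))


def test_tiling_reproduces_per_cell_pattern():
    t = calibrate_t("diamond", 0.4, resolution=16)
    one = voxelize(ScaffoldSpec("diamond", t), 16)
    tiled = voxelize(ScaffoldSpec("diamond", t, repetitions=(2, 2, 2)), 16)
    assert tiled.shape == (32, 32, 32)
    for i in range(2):
        for j in range(2):
            for k in range(2):
                block = tiled.occupancy[16 * i:16 * (i + 1),
                                        16 * j:16 * (j + 1),
                                        16 * k:16 * (k + 1)]
                np.testing.assert_array_equal(block, one.occupancy)


def test_voxel_vf_converges_with_resolution():
    t = calibrate_t("gyroid", 0.5, resolution=128)
    diffs = []
    for n in (16, 32, 64):
        a = voxelize(ScaffoldSpec("gyroid", t), n).volume_fraction
        b = voxelize(ScaffoldSpec("gyroid", t), 2 * n).volume_fraction
        diffs.append(abs(b - a))
    assert diffs[-1] < diffs[0]


def test_voxelize_memory_guard():
    with pytest.raises(MemoryError):
        voxelize(ScaffoldSpec("gyroid", 0.5), 512, voxel_budget=10 ** 6)


def test_export_surface_sphere_area(tmp_path):
    grid = make_fixture("spherical_pore", size=1.0, resolution=100, radius=0.3)
    mesh = export_surface(grid, tmp_path / "sphere.stl")
    assert mesh.area == pytest.approx(4 * np.pi * 0.3 ** 2, rel=0.05)


def test_export_surface_roundtrip(tmp_path):
    import trimesh
    t = calibrate_t("gyroid", 0.2, resolution=32)
    grid = voxelize(ScaffoldSpec("gyroid", t), 32)
    path = tmp_path / "gyroid.stl"
    export_surface(grid, path)
    back = trimesh.load(str(path))
    assert len(back.faces) > 0


def test_export_surface_requires_interface(tmp_path):
    grid = make_fixture("solid_block", size=1.0, resolution=16)
    with pytest.raises(NoSurfaceError):
        export_surface(grid, tmp_path / "none.stl")
    with pytest.raises(NoSurfaceError):
        export_surface(VoxelGrid(np.zeros((8, 8, 8), bool), 0.1),
                       tmp_path / "none.stl")


def test_fixture_channel_geometry():
    grid = make_fixture("cyl_channel", size=1.0, resolution=64, radius=0.2)
    from scipy import ndimage
    dist = ndimage.distance_transform_edt(~grid.occupancy) * grid.spacing
    # inscribed sphere of a 0.2 mm channel has diameter 0.4 mm
    assert 2 * dist.max() == pytest.approx(0.4, abs=2 * grid.spacing)


def test_fixture_laminate_exact_fraction():
    grid = make_fixture("laminate_parallel", size=1.0, resolution=32,
                        solid_fraction=0.5)
    assert grid.volume_fraction == 0.5


def test_fixture_spherical_pore_volume():
    r = 0.3
    grid = make_fixture("spherical_pore", size=1.0, resolution=96, radius=r)
    void = grid.void_volume()
    assert void == pytest.approx(4 / 3 * np.pi * r ** 3, rel=0.02)


def test_fixture_parameter_validation():
    with pytest.raises(ValueError):
        make_fixture("spherical_pore", size=1.0, resolution=32, radius=0.6)
    with pytest.raises(ValueError):
        make_fixture("no_such_shape")
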