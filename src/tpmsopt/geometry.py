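"""Triply periodic minimal surface (TPMS) scaffold geometry.

A scaffold cell is the sheet solid ``|f| <= t`` between the two offset
isosurfaces ``f = +t`` and ``f = -t`` of a trigonometric TPMS approximation
``f``.  The threshold ``t`` controls the volume fraction; :func:`calibrate_t`
inverts that relationship numerically.  Scaffolds are discretised onto
isotropic boolean voxel grids (:class:`VoxelGrid`) which are shared by the
pore-size, finite-element and cell-growth analyses.

Six surface families are supported: Primitive, Gyroid, Split P, Diamond,
Lidinoid and Neovius.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "TPMS_TYPES",
    "ScaffoldSpec",
    "VoxelGrid",
    "FieldSample",
    "UnsupportedTypeError",
    "CalibrationError",
    "NoSurfaceError",
    "field_value",
    "calibrate_t",
    "voxelize",
    "export_surface",
    "make_fixture",
    "signed_distance",
]

TPMS_TYPES = ("primitive", "gyroid", "split_p", "diamond", "lidinoid", "neovius")

#: Refuse to allocate voxel grids larger than this (occupancy voxel count).
DEFAULT_VOXEL_BUDGET = 700 ** 3


class UnsupportedTypeError(ValueError):
    """Raised for a TPMS type name outside :data:`TPMS_TYPES`."""


class CalibrationError(RuntimeError):
    """Raised when the t-calibration bisection fails to reach tolerance."""

    def __init__(self, message: str, achieved_vf: float | None = None):
        super().__init__(message)
        self.achieved_vf = achieved_vf


class NoSurfaceError(RuntimeError):
    """Raised when a grid has no solid/void interface to triangulate."""


@dataclasses.dataclass(frozen=True)
class ScaffoldSpec:
    """Symbolic definition of one scaffold design.

    Parameters
    ----------
    tpms_type : str
        One of :data:`TPMS_TYPES` (case-insensitive).
    t : float
        Sheet-thickness threshold, dimensionless, >= 0.
    cell_size : float
        Unit cell edge length in mm (default 1.0, the design value for a
        femoral graft scaffold).
    repetitions : tuple of int
        Cell repetitions (n_x, n_y, n_z), each >= 1.  The field
        periodicities k_i = 2*pi*n_i follow from these and are never stored.
    """

    tpms_type: str
    t: float
    cell_size: float = 1.0
    repetitions: Tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self):
        object.__setattr__(self, "tpms_type", _canonical_type(self.tpms_type))
        if self.t < 0:
            raise ValueError(f"t must be >= 0, got {self.t}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        reps = tuple(int(r) for r in self.repetitions)
        if len(reps) != 3 or any(r < 1 for r in reps):
            raise ValueError(f"repetitions must be three ints >= 1, got {self.repetitions}")
        object.__setattr__(self, "repetitions", reps)

    def to_dict(self) -> dict:
        return {
            "tpms_type": self.tpms_type,
            "t": float(self.t),
            "cell_size": float(self.cell_size),
            "repetitions": list(self.repetitions),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScaffoldSpec":
        return cls(
            tpms_type=d["tpms_type"],
            t=float(d["t"]),
            cell_size=float(d.get("cell_size", 1.0)),
            repetitions=tuple(d.get("repetitions", (1, 1, 1))),
        )


@dataclasses.dataclass
class VoxelGrid:
    """Boolean occupancy grid with physical spacing.

    ``occupancy[i, j, k]`` is True where the material is solid.  The physical
    centre of voxel (i, j, k) is ``origin + (i + 1/2, j + 1/2, k + 1/2) *
    spacing`` (mm).
    """

    occupancy: np.ndarray
    spacing: float
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3:
            raise ValueError(f"occupancy must be 3-D, got ndim={self.occupancy.ndim}")
        if any(s < 2 for s in self.occupancy.shape):
            raise ValueError(f"grid must be >= 2 voxels per axis, got {self.occupancy.shape}")
        if self.spacing <= 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def volume_fraction(self) -> float:
        """Solid voxel count over total voxel count (the measured rho*)."""
        return float(np.count_nonzero(self.occupancy)) / self.occupancy.size

    @property
    def extent(self) -> Tuple[float, float, float]:
        """Physical edge lengths in mm."""
        return tuple(s * self.spacing for s in self.shape)

    @property
    def voxel_volume(self) -> float:
        return self.spacing ** 3

    def void_volume(self) -> float:
        """Total void volume in mm^3 (voxel counting)."""
        return float(np.count_nonzero(~self.occupancy)) * self.voxel_volume


@dataclasses.dataclass(frozen=True)
class FieldSample:
    """Raw TPMS field value f and the thresholded value U = f^2 - t^2.

    The solid (sheet) phase is U <= 0, equivalently |f| <= t.
    """

    f: np.ndarray | float
    U: np.ndarray | float

    def is_solid(self):
        return self.U <= 0


def _canonical_type(name: str) -> str:
    key = str(name).strip().lower().replace(" ", "_").replace("-", "_")
    aliases = {"splitp": "split_p", "schwarz_p": "primitive", "p": "primitive",
               "g": "gyroid", "d": "diamond"}
    key = aliases.get(key, key)
    if key not in TPMS_TYPES:
        raise UnsupportedTypeError(
            f"unknown TPMS type {name!r}; supported: {', '.join(TPMS_TYPES)}")
    return key


def _raw_field(tpms_type: str, x, y, z, cell_size: float):
    """Evaluate the trigonometric field f at mm coordinates (broadcasting).

    All six families reduce to products of the 1-D shorthands
    S_i = sin(2*pi*i/cell), C_i = cos(2*pi*i/cell) and their double-frequency
    counterparts, so x, y, z may be sparse (broadcastable) arrays.
    """
    w = 2.0 * math.pi / cell_size
    t = _canonical_type(tpms_type)
    if t == "primitive":
        return np.cos(w * x) + np.cos(w * y) + np.cos(w * z)
    if t == "gyroid":
        return (np.sin(w * x) * np.cos(w * y)
                + np.sin(w * y) * np.cos(w * z)
                + np.sin(w * z) * np.cos(w * x))
    if t == "diamond":
        Sx, Sy, Sz = np.sin(w * x), np.sin(w * y), np.sin(w * z)
        Cx, Cy, Cz = np.cos(w * x), np.cos(w * y), np.cos(w * z)
        return Cx * Cy * Cz + Sx * Sy * Sz + Sx * Cy * Sz + Cx * Sy * Sz
    if t == "neovius":
        Cx, Cy, Cz = np.cos(w * x), np.cos(w * y), np.cos(w * z)
        return 3.0 * (Cx + Cy + Cz) + 4.0 * Cx * Cy * Cz
    # Split P and Lidinoid share the same building blocks
    Sx, Sy, Sz = np.sin(w * x), np.sin(w * y), np.sin(w * z)
    Cx, Cy, Cz = np.cos(w * x), np.cos(w * y), np.cos(w * z)
    S2x, S2y, S2z = np.sin(2 * w * x), np.sin(2 * w * y), np.sin(2 * w * z)
    C2x, C2y, C2z = np.cos(2 * w * x), np.cos(2 * w * y), np.cos(2 * w * z)
    cross = S2x * Cy * Sz + S2y * Cz * Sx + S2z * Cx * Sy
    pair = C2x * C2y + C2y * C2z + C2z * C2x
    if t == "lidinoid":
        return cross - pair
    # split_p
    return 1.1 * cross - 0.2 * pair - 0.4 * (C2x + C2y + C2z)


def field_value(tpms_type: str, point, cell_size: float = 1.0,
                repetitions=(1, 1, 1), t: float = 0.0) -> FieldSample:
    """Evaluate the TPMS field at physical point(s) in mm.

    ``point`` is an array-like whose last axis has length 3.  The fields are
    periodic with period ``cell_size`` in each axis; ``repetitions`` only
    affects the physical extent of a scaffold, not the local field value.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    p = np.asarray(point, dtype=float)
    if p.shape[-1] != 3:
        raise ValueError("point must have 3 components on the last axis")
    f = _raw_field(tpms_type, p[..., 0], p[..., 1], p[..., 2], cell_size)
    return FieldSample(f=f, U=f * f - t * t)


def _cell_abs_field_sorted(tpms_type: str, resolution: int,
                           cell_size: float = 1.0) -> np.ndarray:
    """Sorted |f| sampled at the voxel centres of one unit cell."""
    c = (np.arange(resolution) + 0.5) * (cell_size / resolution)
    X = c[:, None, None]
    Y = c[None, :, None]
    Z = c[None, None, :]
    f = _raw_field(tpms_type, X, Y, Z, cell_size)
    return np.sort(np.abs(f), axis=None)


def calibrate_t(tpms_type: str, target_vf: float, resolution: int = 100,
                cell_size: float = 1.0, tol: float = 1e-3,
                max_iter: int = 60) -> float:
    """Find the threshold t whose voxelised volume fraction matches target_vf.

    VF(t) = #{|f| <= t} / N is non-decreasing in t, so bisection on t against
    the voxel-centre samples of one unit cell converges; voxelising at the
    same resolution with the returned t reproduces target_vf within ``tol``.
    """
    if not 0.0 <= target_vf <= 1.0:
        raise ValueError(f"target_vf must be in [0, 1], got {target_vf}")
    if target_vf == 0.0:
        return 0.0
    absf = _cell_abs_field_sorted(tpms_type, resolution, cell_size)
    n = absf.size
    if target_vf == 1.0:
        return float(absf[-1])
    lo, hi = 0.0, float(absf[-1]) * (1 + 1e-12)
    t = 0.5 * (lo + hi)
    for _ in range(max_iter):
        t = 0.5 * (lo + hi)
        vf = np.searchsorted(absf, t, side="right") / n
        if abs(vf - target_vf) <= tol:
            return float(t)
        if vf < target_vf:
            lo = t
        else:
            hi = t
    achieved = np.searchsorted(absf, t, side="right") / n
    raise CalibrationError(
        f"t-calibration for {tpms_type} did not reach |VF - {target_vf}| <= {tol} "
        f"in {max_iter} bisections (achieved VF = {achieved:.5f}); "
        f"increase resolution or tolerance", achieved_vf=float(achieved))


def voxelize(spec: ScaffoldSpec, resolution: int,
             voxel_budget: int = DEFAULT_VOXEL_BUDGET) -> VoxelGrid:
    """Sample the sheet solid |f| <= t onto a voxel grid.

    The grid has ``resolution`` voxels per unit cell and
    ``resolution * repetitions`` voxels per axis; voxels are classified at
    their centres with no sub-voxel anti-aliasing.
    """
    if resolution < 8:
        raise ValueError(f"resolution must be >= 8 voxels per cell, got {resolution}")
    dims = tuple(resolution * r for r in spec.repetitions)
    n_total = dims[0] * dims[1] * dims[2]
    if n_total > voxel_budget:
        raise MemoryError(
            f"voxel grid {dims} ({n_total} voxels) exceeds the budget of "
            f"{voxel_budget}; lower the resolution or raise voxel_budget")
    spacing = spec.cell_size / resolution
    # evaluate per-cell coordinates so every tile is classified bit-identically
    axes = [((np.arange(d) % resolution) + 0.5) * spacing for d in dims]
    X = axes[0][:, None, None]
    Y = axes[1][None, :, None]
    Z = axes[2][None, None, :]
    f = _raw_field(spec.tpms_type, X, Y, Z, spec.cell_size)
    solid = np.abs(f) <= spec.t  # U <= 0; boundary counted solid
    return VoxelGrid(occupancy=solid, spacing=spacing)


def signed_distance(grid: VoxelGrid, periodic: bool = False,
                    surface_offset: float = 0.5) -> np.ndarray:
    """Signed Euclidean distance to the solid/void interface, in mm.

    Positive inside the solid, negative in the void.  Distances are taken
    between voxel centres and shifted by ``surface_offset`` voxels so that
    the zero level sits between the two phases.  With ``periodic=True`` the
    grid is treated as one period of an infinite tiling.
    """
    occ = grid.occupancy
    if periodic:
        tiled = np.tile(occ, (3, 3, 3))
        d_in = ndimage.distance_transform_edt(tiled)
        d_out = ndimage.distance_transform_edt(~tiled)
        sx, sy, sz = occ.shape
        sl = (slice(sx, 2 * sx), slice(sy, 2 * sy), slice(sz, 2 * sz))
        d_in = d_in[sl]
        d_out = d_out[sl]
    else:
        d_in = ndimage.distance_transform_edt(occ)
        d_out = ndimage.distance_transform_edt(~occ)
    phi = np.where(occ, d_in - surface_offset, -(d_out - surface_offset))
    return phi * grid.spacing


def export_surface(grid: VoxelGrid, path) -> "trimesh.Trimesh":
    """Write the solid/void isosurface as a binary STL triangle mesh.

    Marching cubes is run on the signed-distance field of the grid (zero
    level) rather than on the raw occupancy, which removes most of the
    voxel staircase from the triangulated surface; vertex coordinates are
    in mm.  Returns the mesh that was written.
    """
    import trimesh
    from skimage import measure

    occ = grid.occupancy
    if occ.all():
        raise NoSurfaceError("grid is entirely solid; no interface to export")
    if not occ.any():
        raise NoSurfaceError("grid is entirely void; no interface to export")
    phi = signed_distance(grid)
    # the voxel EDT is a union-of-spheres field whose isosurfaces are bumpy;
    # a sub-voxel Gaussian smoothing removes the bumps (a few percent of
    # spurious area) without moving the surface by more than ~half a voxel
    phi = ndimage.gaussian_filter(phi, sigma=1.0)
    # pad with solid: marching cubes then wraps every void region in a
    # closed surface without triangulating the outer box faces
    pad = np.pad(phi, 1, mode="constant", constant_values=abs(phi).max() + grid.spacing)
    verts, faces, _, _ = measure.marching_cubes(pad, level=0.0)
    verts = (verts - 0.5) * grid.spacing  # remove pad, voxel centres -> mm
    verts = verts + np.asarray(grid.origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.export(str(path))
    return mesh


def _fixture_grid(shape, spacing) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    nx, ny, nz = shape
    x = (np.arange(nx) + 0.5) * spacing
    y = (np.arange(ny) + 0.5) * spacing
    z = (np.arange(nz) + 0.5) * spacing
    return x[:, None, None], y[None, :, None], z[None, None, :], np.zeros(shape, bool)


def make_fixture(kind: str, **params) -> VoxelGrid:
    """Analytic test geometries with known pore sizes, moduli and curvature.

    Kinds
    -----
    solid_block : fully solid box.
        ``size`` mm (scalar), ``resolution`` voxels per axis.
    slab_void : solid box with a planar void slab (flat interfaces).
        ``size``, ``resolution``, ``slab_thickness`` mm (centred, normal z).
    cyl_channel : solid box with cylindrical void channel(s) along z.
        ``size``, ``resolution``, ``radii`` mm (one channel per radius,
        spread along x at mid-y).
    spherical_pore : solid box with a centred spherical void.
        ``size``, ``resolution``, ``radius`` mm.
    laminate_series : alternating solid/void layers normal to z.
        ``size``, ``resolution``, ``solid_fraction``.
    laminate_parallel : solid walls normal to x spanning the load (z) axis.
        ``size``, ``resolution``, ``solid_fraction`` (exact when
        solid_fraction * resolution is integral).
    """
    size = float(params.get("size", 1.0))
    resolution = int(params.get("resolution", 64))
    if resolution < 2 or size <= 0:
        raise ValueError("fixture needs size > 0 and resolution >= 2")
    spacing = size / resolution
    shape = (resolution, resolution, resolution)

    if kind == "solid_block":
        occ = np.ones(shape, bool)
        return VoxelGrid(occ, spacing)

    if kind == "slab_void":
        th = float(params.get("slab_thickness", size / 4))
        if not 0 < th < size:
            raise ValueError("slab_thickness must lie inside the block")
        _, _, Z, occ = _fixture_grid(shape, spacing)
        occ[:] = True
        lo, hi = (size - th) / 2, (size + th) / 2
        occ &= ~((Z >= lo) & (Z < hi))
        return VoxelGrid(occ, spacing)

    if kind == "cyl_channel":
        radii = params.get("radii")
        if radii is None:
            radii = [float(params.get("radius", 0.2))]
        radii = [float(r) for r in np.atleast_1d(radii)]
        if any(r <= 0 or 2 * r >= size for r in radii):
            raise ValueError("channel radii must be positive and fit the block")
        X, Y, _, occ = _fixture_grid(shape, spacing)
        occ[:] = True

        def snap(c):  # centre channels on voxel centres: the medial axis
            return (np.floor(c / spacing) + 0.5) * spacing  # then lies on a column

        cy = snap(size / 2)
        centres_x = snap((np.arange(len(radii)) + 0.5) * size / len(radii))
        for cx, r in zip(np.atleast_1d(centres_x), radii):
            occ &= ~(((X - cx) ** 2 + (Y - cy) ** 2) <= r ** 2)
        return VoxelGrid(occ, spacing)

    if kind == "spherical_pore":
        r = float(params.get("radius", 0.3))
        if not 0 < 2 * r < size:
            raise ValueError("sphere must fit inside the block")
        X, Y, Z, occ = _fixture_grid(shape, spacing)
        occ[:] = True
        c = size / 2
        occ &= ~(((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2) <= r ** 2)
        return VoxelGrid(occ, spacing)

    if kind in ("laminate_series", "laminate_parallel"):
        rho = float(params.get("solid_fraction", 0.5))
        if not 0 < rho < 1:
            raise ValueError("solid_fraction must be in (0, 1)")
        n_solid = int(round(rho * resolution))
        n_solid = min(max(n_solid, 1), resolution - 1)
        occ = np.zeros(shape, bool)
        if kind == "laminate_series":
            occ[:, :, :n_solid] = True  # void layer normal to the z load axis
        else:
            occ[:n_solid, :, :] = True  # wall aligned with the z load axis
        return VoxelGrid(occ, spacing)

    raise ValueError(f"unknown fixture kind {kind!r}")
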