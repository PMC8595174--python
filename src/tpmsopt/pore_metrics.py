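"""Pore-size analysis of the scaffold void network.

The pore sizes that matter for vascularised bone ingrowth are the diameters
of the largest and smallest virtual spheres that fit inside the void network
along its medial axis: capillaries (>= 100 um across) must be able to thread
every pore, and no point of the network may be further than the ~200 um
oxygen diffusion limit from a capillary, capping pores at 400 um.

The analysis skeletonises the void phase of a 3x3x3-cell voxel model
(topological thinning), measures the Euclidean distance from each retained
skeleton voxel to the nearest solid voxel, and reports the min/max inscribed
sphere diameters.  Sweeping volume fraction then yields the admissible
volume-fraction window per TPMS type.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .geometry import ScaffoldSpec, VoxelGrid, calibrate_t, voxelize

__all__ = [
    "PoreLimits",
    "PoreSizeResult",
    "PoreWindow",
    "NoVoidError",
    "void_skeleton",
    "pore_diameters",
    "pore_window",
]

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class NoVoidError(RuntimeError):
    """Raised when a grid has no void voxels to analyse."""


@dataclasses.dataclass(frozen=True)
class PoreLimits:
    """Allowed pore diameter range in micrometres (capillary / diffusion)."""

    d_lo: float = 100.0
    d_hi: float = 400.0

    def __post_init__(self):
        if not 0 < self.d_lo < self.d_hi:
            raise ValueError(f"require 0 < d_lo < d_hi, got {self.d_lo}, {self.d_hi}")


@dataclasses.dataclass(frozen=True)
class PoreSizeResult:
    """Min/max medial inscribed-sphere diameters of the void network (um)."""

    d_min: float
    d_max: float
    skeleton_voxel_count: int

    def __post_init__(self):
        if not 0 < self.d_min <= self.d_max:
            raise ValueError(f"require 0 < d_min <= d_max, got {self.d_min}, {self.d_max}")


@dataclasses.dataclass
class PoreWindow:
    """Volume-fraction interval satisfying the pore limits for one type."""

    tpms_type: str
    vf_lo: Optional[float]
    vf_hi: Optional[float]
    table: "object" = None  # per-VF pandas DataFrame (type, vf, d_min_um, d_max_um)
    exclusion_reason: Optional[str] = None

    @property
    def empty(self) -> bool:
        return self.vf_lo is None or self.vf_hi is None or self.vf_lo > self.vf_hi

    def as_tuple(self) -> Optional[Tuple[float, float]]:
        return None if self.empty else (self.vf_lo, self.vf_hi)


def _largest_void_component(occ: np.ndarray) -> Tuple[np.ndarray, int]:
    """Boolean mask of the largest 26-connected void component."""
    void = ~occ
    if not void.any():
        raise NoVoidError("grid has no void voxels")
    labels, n = ndimage.label(void, structure=_CONN26)
    if n == 1:
        return void, 1
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    main = int(np.argmax(counts))
    return labels == main, n


def _prune_endpoints(skel: np.ndarray, passes: int) -> np.ndarray:
    """Iteratively strip skeleton endpoints (removes spurs shorter than
    ``passes`` voxels)."""
    skel = skel.copy()
    for _ in range(passes):
        nbr = ndimage.convolve(skel.astype(np.uint8), _CONN26.astype(np.uint8),
                               mode="constant")
        # nbr counts the voxel itself; an endpoint has <= 1 neighbour
        endpoints = skel & (nbr <= 2)
        if not endpoints.any():
            break
        skel &= ~endpoints
    return skel


def void_skeleton(grid: VoxelGrid, boundary_margin: int = 2,
                  prune_spurs: int = 3, component: str = "largest") -> np.ndarray:
    """Medial-axis skeleton of the largest connected void component.

    Topological thinning (Lee et al. 3-D skeletonisation) of the void phase.
    Voxels within ``boundary_margin`` of the domain faces are dropped and
    spur branches shorter than ``prune_spurs`` voxels are removed, since both
    are thinning artefacts that would otherwise contaminate the minimum
    inscribed-sphere diameter.  Returns a boolean mask (subset of the void).
    """
    if component == "all":
        void_main = ~grid.occupancy
        if not void_main.any():
            raise NoVoidError("grid has no void voxels")
    else:
        void_main, n_comp = _largest_void_component(grid.occupancy)
        if n_comp > 1:
            log.info("void has %d disconnected components; analysing the largest",
                     n_comp)
    skel = skeletonize(void_main).astype(bool)
    if not skel.any():
        # topological thinning can erode compact hole-free blobs to nothing;
        # the blob's medial point is then the EDT maximum of the component
        dist = ndimage.distance_transform_edt(~grid.occupancy)
        dist[~void_main] = 0.0
        skel = dist >= dist.max() - 1e-9
        return skel
    if boundary_margin > 0:
        m = boundary_margin
        interior = np.zeros_like(skel)
        interior[m:-m or None, m:-m or None, m:-m or None] = True
        trimmed = skel & interior
        # a small void blob near a face may lose its whole skeleton; keep the
        # untrimmed skeleton rather than failing in that case
        if trimmed.any():
            skel = trimmed
    if prune_spurs > 0:
        pruned = _prune_endpoints(skel, prune_spurs - 1)
        # never prune the skeleton away entirely (e.g. a single straight axis)
        if pruned.any():
            skel = pruned
    if not skel.any():
        raise NoVoidError("skeleton empty; grid too small to skeletonise")
    return skel


def _containment_prune_min(points: np.ndarray, radii: np.ndarray) -> float:
    """Smallest inscribed-sphere radius over skeleton points whose sphere is
    not contained in another skeleton point's sphere.

    A skeleton voxel p is redundant when some q satisfies |p - q| <= r_q - r_p:
    p's sphere then lies inside q's and defines no pore of its own.  Such
    voxels are thinning spurs hugging the wall of a larger pore; genuine
    throats survive because no neighbouring sphere swallows theirs.  Points
    are scanned in ascending radius; the first non-contained one gives the
    minimum.  Distances and radii are in voxels.
    """
    from scipy.spatial import cKDTree

    order = np.argsort(radii)
    tree = cKDTree(points)
    r_max = float(radii.max())
    for idx in order:
        p = points[idx]
        r_p = radii[idx]
        cand = np.asarray(tree.query_ball_point(p, r_max - r_p + 1e-9), dtype=int)
        cand = cand[cand != idx]
        if cand.size:
            d = np.linalg.norm(points[cand] - p, axis=1)
            if np.any(d <= radii[cand] - r_p + 1e-9):
                continue
        return float(r_p)
    return float(radii.min())


def pore_diameters(grid: VoxelGrid, limits: PoreLimits | None = None,
                   surface_correction: bool = True,
                   skeleton: np.ndarray | None = None,
                   component: str = "largest") -> PoreSizeResult:
    """Min/max inscribed-sphere diameters (um) over the void medial skeleton.

    By default only the largest connected void component is analysed (a
    capillary cannot reach a disconnected void); ``component="all"``
    skeletonises the whole void phase instead.  The distance from each
    skeleton voxel centre to the nearest solid voxel
    centre is computed with an exact Euclidean distance transform; with
    ``surface_correction`` half a voxel is subtracted to approximate the
    distance to the solid surface rather than to the solid centre.
    """
    if skeleton is None:
        skeleton = void_skeleton(grid, component=component)
    dist = ndimage.distance_transform_edt(~grid.occupancy)
    r_vox = dist[skeleton]
    pts = np.argwhere(skeleton).astype(float)
    r_min = _containment_prune_min(pts, r_vox)
    if surface_correction:
        r_min = max(r_min - 0.5, 0.5)
        r_max = max(float(r_vox.max()) - 0.5, 0.5)
    else:
        r_max = float(r_vox.max())
    um = 1000.0
    return PoreSizeResult(
        d_min=float(2 * r_min * grid.spacing * um),
        d_max=float(2 * r_max * grid.spacing * um),
        skeleton_voxel_count=int(np.count_nonzero(skeleton)),
    )


def measure_type(tpms_type: str, vf: float, resolution: int = 100,
                 cell_size: float = 1.0, tilings: int = 3) -> PoreSizeResult:
    """Pore diameters of one TPMS type at one volume fraction.

    Uses a 3x3x3 unit-cell tiling by default, which is enough to contain the
    largest and smallest void volumes of the periodic network.
    """
    t = calibrate_t(tpms_type, vf, resolution=resolution, cell_size=cell_size)
    spec = ScaffoldSpec(tpms_type, t, cell_size, (tilings,) * 3)
    grid = voxelize(spec, resolution)
    return pore_diameters(grid)


def _interp_crossing(vfs, vals, threshold) -> float:
    """VF at which vals crosses threshold, linear between sweep points."""
    vfs = np.asarray(vfs, float)
    vals = np.asarray(vals, float)
    for i in range(len(vfs) - 1):
        a, b = vals[i], vals[i + 1]
        if (a - threshold) * (b - threshold) <= 0 and a != b:
            return float(vfs[i] + (threshold - a) / (b - a) * (vfs[i + 1] - vfs[i]))
    raise ValueError("no crossing found")


def pore_window(tpms_type: str, vf_sweep: Sequence[float],
                resolution: int = 100, limits: PoreLimits | None = None,
                cell_size: float = 1.0, tilings: int = 3,
                refine_to: float = 0.0) -> PoreWindow:
    """Admissible volume-fraction window of one TPMS type under pore limits.

    Measures d_min/d_max over ``vf_sweep`` (ascending, within [0.2, 0.9]),
    locates the d_max = d_hi and d_min = d_lo crossings by linear
    interpolation, and returns the contiguous admissible interval.  With
    ``refine_to`` > 0 the sweep is adaptively refined around each crossing
    until the bracket is narrower than ``refine_to`` (extra measurements are
    added to the sweep table).  An empty window flags the type as discarded.
    """
    import pandas as pd

    limits = limits or PoreLimits()
    vfs = list(np.asarray(vf_sweep, float))
    if vfs != sorted(vfs):
        raise ValueError("vf_sweep must be sorted ascending")

    results = {}

    def measure(vf):
        if vf not in results:
            try:
                results[vf] = measure_type(tpms_type, vf, resolution, cell_size, tilings)
            except NoVoidError:
                results[vf] = None
        return results[vf]

    for vf in vfs:
        measure(vf)

    def ok(vf):
        r = results[vf]
        return r is not None and r.d_max <= limits.d_hi and r.d_min >= limits.d_lo

    def refine(lo, hi, crossing_ok_side):
        """Bisect [lo, hi] (ok-state differs at ends) down to refine_to."""
        while hi - lo > refine_to:
            mid = round(0.5 * (lo + hi), 6)
            if mid in (lo, hi):
                break
            measure(mid)
            vfs.append(mid)
            if ok(mid) == crossing_ok_side:
                hi = mid
            else:
                lo = mid
        return lo, hi

    admissible = [vf for vf in vfs if ok(vf)]

    def table():
        rows = []
        for vf in sorted(results):
            r = results[vf]
            rows.append({"type": tpms_type, "vf": vf,
                         "d_min_um": r.d_min if r else np.nan,
                         "d_max_um": r.d_max if r else np.nan})
        return pd.DataFrame(rows)

    if not admissible:
        r_any = [r for r in results.values() if r is not None]
        if r_any and all(r.d_max > limits.d_hi for r in r_any):
            reason = f"max pore > {limits.d_hi:g} um at all swept volume fractions"
        elif r_any and all(r.d_min < limits.d_lo for r in r_any):
            reason = f"min pore < {limits.d_lo:g} um at all swept volume fractions"
        else:
            reason = "no swept volume fraction satisfies both pore limits"
        return PoreWindow(tpms_type, None, None, table(), exclusion_reason=reason)

    lo_vf, hi_vf = admissible[0], admissible[-1]

    # refine / interpolate the lower (d_max = d_hi) edge
    below = [vf for vf in sorted(results) if vf < lo_vf]
    if below:
        b = below[-1]
        if refine_to > 0:
            b, lo_vf = refine(b, lo_vf, crossing_ok_side=True)
        sweep = sorted(set([b, lo_vf]))
        try:
            lo_edge = _interp_crossing(
                sweep, [results[v].d_max if results[v] else np.inf for v in sweep],
                limits.d_hi)
        except ValueError:
            lo_edge = lo_vf
    else:
        lo_edge = lo_vf  # admissible from the sweep start

    above = [vf for vf in sorted(results) if vf > hi_vf]
    if above:
        a = above[0]
        if refine_to > 0:
            hi_vf, a = refine(hi_vf, a, crossing_ok_side=False)
        sweep = sorted(set([hi_vf, a]))
        try:
            hi_edge = _interp_crossing(
                sweep, [results[v].d_min if results[v] else 0.0 for v in sweep],
                limits.d_lo)
        except ValueError:
            hi_edge = hi_vf
    else:
        hi_edge = hi_vf

    return PoreWindow(tpms_type, float(lo_edge), float(hi_edge), table())
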