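# Methods

`tpmsopt` implements a two-scale design procedure for bone-graft scaffolds
built from triply periodic minimal surfaces (TPMS).  The design space is
(scaffold type, volume fraction); the objective is the average
pre-osteoblast growth rate; the constraints are pore diameter (capillary
supply) and axial stiffness (fracture-healing mechanics).  This note
records the models, the numerical choices, and the limits of what the
package can and cannot reproduce.

## Scaffold geometry

Each TPMS family is given by a trigonometric field `f(x, y, z)` with
period equal to the unit cell size (1 mm by default).  The solid is the
*sheet* phase between the two offset isosurfaces:

    solid = { |f| <= t },   i.e.  U = f^2 - t^2 <= 0,

with `t >= 0` controlling the volume fraction.  `calibrate_t` inverts
VF(t) by bisection against the sorted `|f|` samples at the voxel centres of
one cell, so voxelising at the same resolution reproduces the target VF to
1e-3.  Voxels are classified at their centres; boundary samples (`U = 0`)
count as solid.

Two families deserve a warning.  The Split P and Lidinoid expressions used
here carry no additive offset constant, and their level sets contain
near-tangent sheet pairs.  The resulting solids are genuine solutions of
the stated equations but contain extensive thin *slit voids* (gaps of one
to three voxels at the working resolutions, i.e. tens of micrometres at a
1 mm cell).  These slits dominate the minimum-pore statistics and
contribute fast-filling volume in the growth model; see "Reproduction
limits" below.

## Pore-size analysis

Capillaries (>= 100 um across) must thread every pore, and no wall may be
farther than the ~200 um oxygen diffusion limit from one, capping pores at
400 um.  Pore sizes are measured on a 3x3x3-cell voxel model:

1. largest 26-connected void component (disconnected voids are excluded:
   a capillary cannot reach them);
2. 3-D topological thinning (Lee et al.) of that component; compact
   hole-free blobs that thinning erodes completely fall back to their
   Euclidean-distance-transform (EDT) maximum;
3. skeleton hygiene: voxels within 2 cells of the domain boundary are
   dropped, spur branches shorter than 3 voxels are pruned, and for the
   minimum a *containment* rule is applied -- a skeleton voxel whose
   inscribed sphere lies inside another skeleton voxel's sphere defines no
   pore of its own (local-thickness logic à la Hildebrand & Rüegsegger).
   Raw thinning otherwise leaves wall-hugging voxels that drive the
   minimum to one voxel;
4. `d_min`/`d_max` = twice the smallest/largest EDT radius over the
   retained skeleton, with half a voxel subtracted to measure to the solid
   surface rather than to solid voxel centres (configurable).

Sweeping volume fraction gives the admissible window per type, with
crossing points interpolated linearly and optionally refined by bisection.
`d_max` is robust (about 3% between 60 and 100 voxels/cell for the
Gyroid); `d_min` is not, because ever-finer slit voids enter the skeleton
as resolution rises.  This is a property of the geometry, not of the
estimator.

## Axial stiffness

Relative modulus follows the Gibson-Ashby law `E* = C1 rho*^n + E0`
(fit range rho* in [0.2, 0.9]).  The shipped constants per type are
(C1, n, E0): Split P (1.33, 2.04, -0.078), Gyroid (1.33, 2.68, -0.002),
Diamond (1.26, 2.74, 0.039), Lidinoid (1.38, -0.050 with n = 2.59).
Axial stiffness of a cylindrical graft of diameter D and length L is
`k = E* E pi D^2 / (4 L)`; E is stored in Pa and converted to N/mm^2
inside the formula so k comes out in N/mm (the formula is unit-sensitive).
Defaults: E = 1.8 GPa (laser-sintered Nylon), D = L = 30 mm, admissible
k in [1000, 2700] N/mm.  The stiffness window inverts the law in closed
form at both bounds and intersects with the fit range.

The voxel-FE homogeniser can regenerate the constants: every solid voxel
becomes an 8-node trilinear hexahedron (2x2x2 Gauss quadrature), the
bottom face is fixed in z with two bottom nodes pinned tangentially to
remove rigid modes, the top face gets a uniform compressive displacement,
lateral faces are traction-free, and floating clusters not linking both
faces are removed before assembly (they carry no load and would make the
system singular).  `E* = reaction / (bounding area x strain x E)`.
Poisson's ratio defaults to 0.3 (configurable).  The solver is Jacobi-
preconditioned conjugate gradients (sparse direct for small systems).
With free lateral faces the constants are boundary-condition-dependent;
a periodic-BC homogeniser would give different values.  At 32 voxels/cell
the Gyroid sweep reproduces the shipped exponent to well under 15%.

## Curvature-driven growth

Cell growth is an advancing front: the tissue surface moves into the void
along its inward normal at a speed proportional to the local mean
curvature wherever the surface is concave as seen from the void, and not
at all on flat or convex patches.  The front is the zero level of a signed
distance field `phi` (positive in scaffold + tissue):

    phi_t = lambda * max(k, 0) * |grad phi|,   k = div(grad phi / |grad phi|).

Key numerical choices (all were fixed against the analytic shrinking-
sphere solution `r(tau)^2 = r0^2 - 4 tau`, never against the study's
scaffold numbers):

- **Curvature time.**  Substituting `tau = lambda * t` removes `lambda`
  from the dynamics, so the integrator runs at `lambda = 1` and curves for
  any `lambda` are exact time rescalings.  Rate ratios, rankings and
  optimal volume fractions are therefore `lambda`-free.  The advection
  step `dt = 1e-4` is interpreted in curvature-time units (equal to the
  customary time step at `lambda = 1`), with CFL sub-stepping at safety
  factor 0.15 -- the speed is curvature, so the effective stability limit
  is diffusive (`dtau ~ h^2`).
- **Speed support.**  `max(k, 0)` is evaluated only within 2 spacings of
  the interface.  Farther out the distance field has medial-axis kinks
  whose central-difference "curvature" is an artefact; with a wider band,
  voids would nucleate tissue at their centrelines.
- **Curvature extension.**  The measured curvature at offset `phi` is
  mapped to the interface value via `k0 = k / (1 - phi k / 2)` (exact for
  spheres), so void-side cells do not drive the front with the curvature
  of a smaller sphere.
- **Gradient.**  The field is kept near a distance function, so the
  central-difference gradient is used for `|grad phi|`; the one-sided
  Godunov gradient adds a dissipative O(h k) speed bias (about +10% on the
  sphere test).
- **Redistancing.**  Sussman-type reinitialisation with a Russo-Smereka
  subcell anchor for interface cells (with bounded corrections -- the raw
  iteration is unstable in 3-D at pseudo-step 0.5 h; 0.25 h is used) runs
  whenever the front has moved ~2 cells.  Isolated single-voxel negatives
  (voids below grid resolution) are absorbed into their neighbourhood,
  since they otherwise pin the front.
- **Volumes.**  The growth curve uses a smoothed-Heaviside volume
  (half-band 1.5 h) so it is not staircase-quantised; the *fill* criterion
  counts sharp `phi < 0` voxels, because the smoothed tissue volume
  saturates a fraction of a voxel-shell below the true void volume even
  after complete closure.  "Filled" means the remaining void is below 0.5%
  of the initial void; the average growth rate is initial void volume over
  fill time.
- **Boundaries.**  Scaffold cells are periodic (one unit cell is
  simulated); analytic fixtures use edge-replicated (clamped) boundaries.

On the sphere oracle the fill time is accurate to 6-10% at 48-96
voxels/cell.  Production runs here use 64^3 per cell; the convergence
utility reproduces the expected behaviour that successive refinements
change the rate by ~1% near 10^6 voxels.

The absolute time scale `lambda` cannot be derived from the geometry; the
shipped default (1.6126e-3 mm^2/day) is anchored once so that the Split P
scaffold at volume fraction 0.44, simulated at 64^3, fills its void at
0.082 mm^3/day.  `growth.calibrate_lambda()` re-derives it for any
resolution.  All other absolute rates are predictions.

## Optimisation

Per type the pipeline intersects the pore and stiffness windows, sweeps
the growth rate over the admissible window (window edges always included)
and selects the argmax (ties break to the lower volume fraction, which
uses less material).  Growth sweeps run at `lambda = 1`; the ranking is
`lambda`-invariant.  Sweep results can be cached on disk keyed by a
content hash of (type, vf, resolution, parameters).

**Stiffness-window caveat.**  With the shipped scaling constants and the
printed defaults, the stiffness window lands at volume fractions around
0.23-0.33 -- *below* the published admissible windows, whose edges
coincide with pore-size crossings instead.  A strict intersection would
therefore be empty for every type.  The default mode treats the pore
window as binding and reports the stiffness window alongside with its
provenance; `stiffness_mode="strict"` forces the intersection, and
`manual_windows` (or the `use_published_windows` config switch) lets a
reproduction run supply the published per-type limits directly.

## Reproduction limits

Honesty notes about what the as-specified models do *not* reproduce:

- **Absolute pore diameters.**  The largest inscribed void sphere of the
  sheet-phase Gyroid at VF 0.47 is ~290 um by direct EDT measurement,
  not 400 um; the Split P and Lidinoid sheet voids never reach 400 um
  anywhere in [0.2, 0.9].  No solid-phase convention we tested (sheet,
  complement, single network) reproduces the published window edges from
  the stated skeleton-plus-distance method.  Only the Primitive/Neovius
  exclusion and the qualitative trends (d_max falls with VF; d_min falls
  with resolution of slits) reproduce.  The published windows are
  therefore offered as *inputs* for reproduction runs rather than claimed
  as outputs.
- **Lidinoid vs Split P margin.**  At the constrained optima our model
  gives the Lidinoid a ~17-20% rate advantage over Split P (converged in
  resolution), versus the published ~6%.  Gyroid and Diamond rates
  relative to Split P agree with the published ratios to a few percent.
  The discrepancy is consistent with the slit voids of the offset-free
  Lidinoid expression contributing fast-filling volume.
- **Low-VF monotonicity.**  With the bare sheet as the initial surface,
  growth at VF 0.2 starts from a nearly minimal (k ~ 0) interface and is
  *slower* than at VF 0.5 (checked up to 96^3); the published study
  reports rates decreasing monotonically over the whole range.  Inside
  the admissible windows (VF >= 0.44) our rates do decrease
  monotonically, which is what the optimum selection relies on.

## Problem sizes

Defaults used by the shipped analyses: pore windows at 60 voxels/cell on
3x3x3 cells; FE homogenisation at 32 voxels/cell on one cell; growth at
64^3 on one periodic cell (the convergence utility supports larger).
These reproduce the behaviour of finer grids to within the tolerances
stated above while keeping a full pipeline run on a single CPU in the
tens of minutes.
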