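# Methods

## Scope and model

`capforge` designs perfusable porous microcapillary scaffolds for
two-photon lithography (TPL) and implements the quantitative checks used to
compare prints against their designs. The geometric model is deliberately
parametric rather than CSG-based: the capillary wall is a swept, subdivided
cylindrical surface, and every later operation (pore cutting, elongation,
thickening) is expressed in the surface's (arc length, angle) coordinates.
This keeps all meshes watertight by construction and makes topological
invariants checkable exactly.

## Centerlines and frames

Paths come from CSV points or from generators (Hilbert curves via the
transpose/Gray-code bit algorithm; helices sampled per turn). Imported and
Hilbert polylines default to degree-1 interpolation, which keeps the arc
length exactly equal to the chord sum; an interpolating cubic through
right-angle corners would overshoot and lengthen the path, so smooth
Hilbert axes are produced by chamfering corners first
(`corner_fillet_radius`, pipeline default = the lumen radius, which
prevents the swept tube from self-intersecting at corners) and fitting the
cubic to the chamfered polyline. Arc-length parameterization uses a dense
chord table that always includes the interpolation knots.

Sweep frames are rotation-minimizing (double-reflection transport), not
Frenet: Frenet frames are undefined on the straight runs of a Hilbert
curve and flip at inflections. The initial normal is chosen in the best-fit
plane of the curve when the curve is planar (so planar scaffolds keep their
normals in-plane) and as the least-aligned coordinate axis otherwise.
Frames at arbitrary stations are read off one dense marching pass, so
nearby stations always share a consistent, twist-free field.

## Membrane

Subdivision counts are `u = ⌊P_l/(p_d+p_s)⌋` (min 1) and
`v = ⌊π·l_d/(p_d+p_s)⌋` (min 3); flooring guarantees the realized pitch is
never below the requested one, and `u·s_l = P_l`, `v·s_r = π·l_d` hold to
machine precision. `p_s` is edge-to-edge spacing, so the grid pitch is
`p_d + p_s`. The picture-frame border is `p_s/2` per side, giving openings
`(s_l−p_s) × (s_r−p_s)` ≈ `p_d`.

Side pores — those whose outward normal lies within 30° (configurable) of
the horizontal plane — are widened circumferentially by 1.5× by default,
the correction that keeps lateral openings from sealing under the
elongated TPL voxel. Widening that would merge neighbouring pores is a
hard error.

Thickening offsets each vertex along its stored radial direction
(`outward` by default, so `l_d` stays the perfusable inner diameter),
mirrors the surface, and walls every boundary loop; the result is a closed
orientable surface of genus P+1 (χ = −2P) for P pores on an open path.
A bend whose curvature radius drops below (lumen radius + wall) folds the
outer surface; `thicken` raises by default and can be set to warn instead —
the pipeline warns, because locally pinched pores on interior curves are an
accepted feature of printed scaffolds, visible in their pore-size profiles.

Smoothing is true polygonal Catmull-Clark (interior and boundary/crease
rules), applied to the quad structure when one exists; it preserves
watertightness and Euler characteristic, both asserted in tests. The pore
diameter reported by `pore_size_profile` is the maximum inscribed circle of
the opening projected on the local tangent plane; measurement conventions
differ across labs and this one is stated so numbers are comparable.

## Supports

*FOV seams.* The printer tiles its field of view; seams are two families of
parallel lines with period `fov_width − overlap`, rotated by the stitch
angle. Crossings are strict side changes of the projected path — touching
or running along a seam is not a crossing. The default FOV width (400 µm)
is an assumption documented here, not a measured value; it is configurable.

*Polygonal rings.* A revolved washer collar around the capillary outer
surface (inner diameter = capillary OD + 2·clearance), vertical beam
capsules on a polygon footprint, diagonal struts from beam tops to the
collar. Placement: evenly spaced or one ring per predicted seam crossing.

*Lattice.* Truncated-octahedron cells on the BCC lattice; every cell whose
centre is strictly inside the bounding box contributes edges, shared edges
deduplicated. Culling samples each strut at half-radius steps and removes
it if any sample comes within (radius + clearance, default clearance 2 µm ≈
half the smallest beam radius) of the capillary — measured both against the
membrane surface and against the swept lumen envelope, so struts threading
a pore or the lumen are removed as well; a full-segment test is used
because endpoint-only tests miss grazing struts. Survivors are piped into
capsules. A connectivity report (union-find over endpoints merged at
0.1 µm) flags floating islands not anchored to the base plane.

*Cones.* Frustums from the base to the capillary underside. The top plane
sits at the lowest point of the capillary *outer envelope* over the tip
footprint (probing the envelope analytically via the centerline where
available), so no cone material crosses into the capillary volume — the
subtraction that keeps chips perfusable — while the tip still touches the
tube underside. The generation half-angle is widened by the factor
`1/cos(π/n)` so that after polygonal faceting every facet still meets the
15° minimum taper, below which cured cone walls shadow the laser path.

## Chip assembly

The base is an extruded convex footprint with its top face at z = 0 (the
scaffold datum); nozzle ports are vertical annuli with bore = lumen
diameter and 508 µm OD (0.020-inch tubing), each with an annular retaining
wall that keeps sealing resin out of the scaffold. Components are
concatenated with per-component provenance retained; no boolean union is
attempted because slicers accept overlapping closed shells (overlaps are
detected and recorded, and a voxel union volume is available when the
merged volume matters). Binary STL is unitless, so a JSON sidecar records
the µm convention. Port bores are open end-to-end; routing the capillary
lumen into the port interior is the printed chip's job and is not modelled.

Decimation is a quadric edge-collapse written for this package: midpoint-
evaluated quadric costs rank edges, the optimal-position solve happens only
for collapses that pass the manifold link condition, and normal-flip
rejection plus rebuild-and-retry rounds keep the mesh watertight. A pored
membrane has a topological face floor of roughly 8–10 triangles per pore,
so deep (95%) reductions are meaningful only on subdivision-smoothed
meshes — exactly the dense meshes that need reduction before slicing.

## Imaging QC

*Registration.* Design renders (orthographic top-down rasterization, with
support-tagged components excludable the way cone supports are digitally
subtracted before analysis) and print micrographs are binarized (optional
global contrast stretch about the mean, then Otsu or fixed threshold) and
composited: design → green channel, print → red. The headline overlap is
`100·yellow/(yellow+green+red)`; normalizations against target area and
against the frame are also reported because published "overlap" figures do
not always state the denominator. Masks must be pre-aligned by the caller.

*Velocimetry.* Auto-tracking detects intensity-weighted centroids per frame
and links them with predictive globally-optimal assignment (prediction =
last position + last displacement), which keeps crossing beads unswapped;
manual mode links caller-supplied per-frame click points. Per-track speed
is mean per-frame displacement × pixel size / frame interval; "frame
interval" is used as the time base (exposure time and frame interval
coincide for the continuous acquisitions this targets). Reported as
mean ± sample SD over tracks in mm/s.

*Viability.* Green (calcein) and red (ethidium homodimer) channels are
Otsu-binarized; components ≥ `min_area_px` (default 20 px, a 4×-
magnification-scale default) are counted. A green component overlapping any
red component is counted as dead only — the dead stain marks nuclei of
dying, still-esterase-positive cells. Manual corrections (add/remove at a
position) are deterministic and audited.

## Synthetic data

The fixture generators emulate only what the estimators measure: mask pairs
are bar grids with known erosion (missing material) and shift
(deformation); bead movies are Gaussian-PSF spots drifting at an exact
speed with additive noise, with the frame interval auto-scaled per movie so
displacement is ≈6 px/frame across the 0.1–9.4 mm/s physiological band —
mirroring how camera exposure is matched to flow, and keeping the benchmark
about the estimator rather than sub-pixel detection; live/dead images are
seeded non-touching disks with known counts. They do not emulate SEM
texture, uneven illumination, bead blinking, out-of-focus beads, or
touching/overlapping cells, so passing tests demonstrate estimator
correctness, not robustness to every imaging artifact; the min-area filter
and manual-correction path are the tools for real data.

## Problem sizes and verification

The test suite and the acceptance script regenerate everything from
scratch. The reference chip is the stacked two-layer order-2 Hilbert
design (40 µm lumen, 5 µm pores, 8 µm spacing, 10 µm wall, 10 µm lattice
beams; step 100 µm and layer gap 120 µm are this package's choices for the
unstated curve scale), giving u = 221, v = 9, 1989 pores. The decimation
check runs on a single-layer order-1 scaffold smoothed by two subdivision
passes (~142k faces) — the package's chosen benchmark size for the
topology-limited 95% reduction. Velocity recovery uses 40 movies spanning
0.1–9.4 mm/s. All randomness flows from one seed.

## Known limitations

- No physical deformation model: swelling/softening of hydrogel and
  elastomer prints is out of scope; the tools quantify it from images.
- Pore openings are rectangular before smoothing; true printed pores are
  rounded by the voxel point-spread function.
- Boolean-free assembly means overlapping components keep interior shells;
  the voxel union volume is the honest merged-volume estimate.
- The self-avoidance check compares polyline segments, not the swept tube
  surface; the fillet default exists precisely to keep the tube clear at
  corners.
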