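"""Support structures for suspended microcapillaries.

Three strategies, matching how two-photon-printed scaffolds are anchored:

* **Polygonal rings** — a collar around the capillary with vertical beams
  and diagonal struts down to the substrate; placed equidistantly or at the
  predicted field-of-view (FOV) stitching seams of the printer, where
  unsupported geometry misaligns.
* **Truncated-octahedron lattice** — a space-filling strut lattice clipped
  to a bounding box, with struts that would collide with the capillary
  culled by a full-segment clearance test, then piped into capsules.
* **Cones** — frustums rising from the base to the capillary underside
  (used under soft-material scaffolds), with taper kept ≥ 15° so the cured
  cone never shadows the laser path, and the capillary envelope kept clear
  so perfusion is not blocked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import MeshError, SpecError
from .mesh import (SurfaceDistance, SurfaceMesh, point_mesh_distance,
                   points_inside, vertical_ray_hits)
from .pathgen import CenterlinePath, compute_frames_at

__all__ = [
    "FOVLayout", "PolygonalSupportSpec", "LatticeSpec", "Strut",
    "ConeSupportSpec", "predict_fov_seams", "polygonal_supports",
    "lattice_edges", "cull_struts", "pipe_struts", "connectivity_check",
    "cone_supports",
]


# ---------------------------------------------------------------------------
# FOV stitching seams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FOVLayout:
    """Tiling of the printer's field of view on the build plane.

    Seams form two families of parallel lines rotated by ``stitch_angle``
    from the x/y axes with period ``fov_width − overlap``; geometry crossing
    a seam is printed in two passes and misaligns unless supported there.
    """

    fov_width: float = 400.0
    overlap: float = 5.0
    stitch_angle: float = 15.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not self.fov_width > self.overlap >= 0:
            raise SpecError("need fov_width > overlap ≥ 0")

    @property
    def period(self) -> float:
        return self.fov_width - self.overlap


def predict_fov_seams(layout: FOVLayout, path: CenterlinePath,
                      n_samples: int = 4096) -> list[tuple[float, str]]:
    """Arc lengths where the build-plane projection of the path crosses a
    stitching seam, sorted; seam ids look like ``"x@2"`` (family, index)."""
    s = np.linspace(0.0, path.path_length, n_samples)
    pts = np.atleast_2d(path.point_at(s))[:, :2] - np.asarray(layout.origin)
    ang = np.deg2rad(layout.stitch_angle)
    rot = np.array([[np.cos(ang), np.sin(ang)], [-np.sin(ang), np.cos(ang)]])
    q = pts @ rot.T  # coordinates in the seam-aligned frame
    out = []
    for axis, name in ((0, "x"), (1, "y")):
        c = q[:, axis] / layout.period
        # snap float noise on exact seam touches, then drop those samples:
        # a crossing is a strict side change, so touching a seam (path
        # starting on one, or running along one) is not a crossing
        snap = np.abs(c - np.round(c)) < 1e-9
        c = np.where(snap, np.round(c), c)
        valid = c != np.round(c)
        ci, si = c[valid], s[valid]
        if len(ci) < 2:
            continue
        k = np.floor(ci)
        crossings = np.nonzero(np.diff(k) != 0)[0]
        for i in crossings:
            lo, hi = ci[i], ci[i + 1]
            target = max(k[i], k[i + 1])
            if (lo - target) * (hi - target) >= 0:
                continue
            frac = (target - lo) / (hi - lo)
            s_cross = si[i] + frac * (si[i + 1] - si[i])
            out.append((float(s_cross), f"{name}@{int(target)}"))
    return sorted(out)


# ---------------------------------------------------------------------------
# Polygonal ring supports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolygonalSupportSpec:
    polygon_sides: int = 6
    beam_diameter: float = 20.0
    collar_clearance: float = 0.0
    placement: str = "equidistant"       # or "at_fov_seams"
    spacing: float = 200.0               # µm, for equidistant placement
    rotational_offset: float = 0.0       # degrees

    def __post_init__(self):
        if self.polygon_sides < 3:
            raise SpecError("polygon_sides must be ≥ 3")
        if self.beam_diameter <= 0:
            raise SpecError("beam_diameter must be > 0")
        if self.placement not in ("equidistant", "at_fov_seams"):
            raise SpecError("placement must be 'equidistant' or 'at_fov_seams'")
        if self.placement == "equidistant" and self.spacing <= 0:
            raise SpecError("spacing must be > 0")


def support_positions(path: CenterlinePath, spec: PolygonalSupportSpec,
                      layout: FOVLayout | None = None) -> list[float]:
    """Arc-length anchor positions: evenly spaced, or one per FOV seam."""
    if spec.placement == "at_fov_seams":
        if layout is None:
            raise SpecError("at_fov_seams placement needs an FOVLayout")
        return [s for s, _ in predict_fov_seams(layout, path)]
    n = max(int(np.floor(path.path_length / spec.spacing)) + 1, 2)
    return list(np.linspace(0.0, path.path_length, n))


def _annulus(r_in: float, r_out: float, width: float, sections: int = 48
             ) -> SurfaceMesh:
    """Watertight washer around the z axis, centred at the origin."""
    th = 2 * np.pi * np.arange(sections) / sections
    ring = np.column_stack([np.cos(th), np.sin(th)])
    z = 0.5 * width
    layers = [np.column_stack([r * ring, np.full(sections, zz)])
              for r, zz in ((r_in, -z), (r_out, -z), (r_out, z), (r_in, z))]
    verts = np.vstack(layers)
    faces = []
    for band in range(4):  # bottom, outer, top, inner — consistent outward
        a0 = band * sections
        b0 = ((band + 1) % 4) * sections
        for i in range(sections):
            j = (i + 1) % sections
            faces.extend([[a0 + i, a0 + j, b0 + j], [a0 + i, b0 + j, b0 + i]])
    return SurfaceMesh(verts, np.asarray(faces), provenance="support")


def _rotate_z_to(vertices: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Rotate vertices so the +z axis maps onto ``axis`` (unit)."""
    M = trimesh.geometry.align_vectors([0.0, 0.0, 1.0], axis)
    return trimesh.transformations.transform_points(vertices, M)


def _capsule(p0, p1, radius, sections=24) -> SurfaceMesh | None:
    """Capsule (cylinder + hemispherical caps) from p0 to p1."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    L = float(np.linalg.norm(p1 - p0))
    if L < 1e-9:
        return None
    cap = trimesh.creation.capsule(radius=radius, height=L,
                                   count=[sections, sections])
    v = _rotate_z_to(np.asarray(cap.vertices), (p1 - p0) / L) + 0.5 * (p0 + p1)
    return SurfaceMesh(v, np.asarray(cap.faces), provenance="support")


def polygonal_supports(path: CenterlinePath, spec: PolygonalSupportSpec,
                       positions: list[float], lumen_outer_diameter: float,
                       base_z: float = 0.0) -> SurfaceMesh:
    """Collar + beams + diagonal struts at each arc-length position.

    Each assembly is a washer collar around the capillary outer surface
    (inner diameter = capillary OD + 2·collar_clearance), ``polygon_sides``
    vertical beams from the base plane up to collar height arranged on a
    polygon around it, and diagonal struts from each beam top to the collar.
    """
    if any(s < -1e-9 or s > path.path_length + 1e-9 for s in positions):
        raise SpecError("support positions must lie within [0, P_l]")
    parts: list[SurfaceMesh] = []
    r_beam = 0.5 * spec.beam_diameter
    r_in = 0.5 * lumen_outer_diameter + spec.collar_clearance
    r_out = r_in + spec.beam_diameter
    frames = compute_frames_at(path, positions) if len(positions) else []
    assemblies = 0
    for fr in frames:
        centre = fr.position
        if centre[2] - base_z < r_out + spec.beam_diameter:
            raise SpecError(
                f"capillary at s={fr.arc_length:.1f} µm is too close to the "
                "base for a collar support")
        collar = _annulus(r_in, r_out, spec.beam_diameter)
        collar.vertices = _rotate_z_to(collar.vertices, fr.tangent) + centre
        parts.append(collar)
        # polygon of vertical beams on the build plane around the collar
        ang0 = np.deg2rad(spec.rotational_offset)
        r_poly = r_out + r_beam
        for i in range(spec.polygon_sides):
            a = ang0 + 2 * np.pi * i / spec.polygon_sides
            foot = np.array([centre[0] + r_poly * np.cos(a),
                             centre[1] + r_poly * np.sin(a), base_z])
            top = foot + np.array([0.0, 0.0, centre[2] - base_z])
            beam = _capsule(foot, top, r_beam)
            if beam is not None:
                parts.append(beam)
            # diagonal strut: beam top → collar surface point
            target = centre + (r_in + 0.5 * spec.beam_diameter) * (
                np.cos(a) * fr.normal + np.sin(a) * fr.binormal)
            diag = _capsule(top, target, 0.5 * r_beam)
            if diag is not None:
                parts.append(diag)
        assemblies += 1
    out = SurfaceMesh.concatenate(parts, provenance="support")
    out.metadata["n_assemblies"] = assemblies
    out.provenance = "support"
    return out


# ---------------------------------------------------------------------------
# Truncated-octahedron lattice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatticeSpec:
    cell_size: float
    beam_diameter: float
    bounding_box: tuple = ((0.0, 0.0, 0.0), (1.0, 1.0, 1.0))
    clearance: float = 2.0
    cell_type: str = "truncated_octahedron"

    def __post_init__(self):
        if self.cell_type != "truncated_octahedron":
            raise SpecError("only the truncated_octahedron cell is supported")
        if not self.cell_size > self.beam_diameter:
            raise SpecError("cell_size must exceed beam_diameter")
        lo, hi = np.asarray(self.bounding_box[0]), np.asarray(self.bounding_box[1])
        if np.any(hi <= lo):
            raise SpecError("bounding box is degenerate")


@dataclass
class Strut:
    """A lattice edge, optionally piped into a capsule of ``radius``."""

    endpoints: np.ndarray
    radius: float = 0.0
    capped: bool = True

    def __post_init__(self):
        self.endpoints = np.asarray(self.endpoints, dtype=np.float64).reshape(2, 3)
        if np.linalg.norm(self.endpoints[1] - self.endpoints[0]) < 1e-12:
            raise SpecError("strut endpoints coincide")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.endpoints[1] - self.endpoints[0]))


# truncated octahedron: vertices are permutations of (0, ±1, ±2)·(a/4);
# its 36 edges all have length √2·(a/4)
def _trunc_oct_cell(a: float) -> tuple[np.ndarray, np.ndarray]:
    base = []
    for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
        for s1 in (-1, 1):
            for s2 in (-1, 1):
                vals = [0.0, s1 * 1.0, s2 * 2.0]
                base.append([vals[perm.index(i)] for i in range(3)])
    verts = np.unique(np.asarray(base), axis=0) * (a / 4.0)
    d = np.linalg.norm(verts[:, None] - verts[None, :], axis=2)
    elen = np.sqrt(2.0) * a / 4.0
    i, j = np.nonzero(np.isclose(d, elen))
    edges = np.unique(np.sort(np.column_stack([i, j]), axis=1), axis=0)
    return verts, edges


def lattice_edges(spec: LatticeSpec) -> list[Strut]:
    """Deduplicated strut skeleton of the truncated-octahedron tiling.

    Cells sit on the BCC lattice (cubic constant = cell_size, plus
    body-centre offsets); every cell whose centre lies strictly inside the
    bounding box contributes its edges, and edges shared between neighbouring
    cells appear once.
    """
    lo = np.asarray(spec.bounding_box[0], float)
    hi = np.asarray(spec.bounding_box[1], float)
    a = spec.cell_size
    if np.any(hi - lo < a - 1e-9):
        raise MeshError("bounding box smaller than one unit cell")
    cv, ce = _trunc_oct_cell(a)

    i0 = np.floor(lo / a).astype(int) - 1
    i1 = np.ceil(hi / a).astype(int) + 1
    centres = []
    for ix in range(i0[0], i1[0] + 1):
        for iy in range(i0[1], i1[1] + 1):
            for iz in range(i0[2], i1[2] + 1):
                for off in ((0.0, 0.0, 0.0), (0.5, 0.5, 0.5)):
                    c = (np.array([ix, iy, iz]) + off) * a
                    if np.all(c > lo + 1e-9) and np.all(c < hi - 1e-9):
                        centres.append(c)
    seen = set()
    struts: list[Strut] = []
    quant = a * 1e-6
    for c in centres:
        pts = cv + c
        for e0, e1 in ce:
            p, q = pts[e0], pts[e1]
            key = tuple(sorted(
                (tuple(np.round(p / quant).astype(np.int64)),
                 tuple(np.round(q / quant).astype(np.int64)))))
            if key in seen:
                continue
            seen.add(key)
            struts.append(Strut(np.vstack([p, q])))
    return struts


def cull_struts(edges: list[Strut], capillary_solid: SurfaceMesh,
                clearance: float = 2.0, strut_radius: float = 5.0
                ) -> list[Strut]:
    """Drop struts whose segment comes within (radius + clearance) of the
    capillary solid.

    The whole segment is sampled at half-radius steps (an endpoint-only
    inside test misses grazing struts); survivors are returned untouched.
    """
    if not edges:
        return []
    sd = SurfaceDistance(capillary_solid)
    # for parametric membranes also test against the swept lumen envelope,
    # so struts threading the perfusable volume (or a pore) are culled too
    env_tree = None
    r_env = capillary_solid.metadata.get("outer_radius")
    cpath = capillary_solid.metadata.get("path")
    if cpath is not None and r_env is not None:
        s_dense = np.linspace(0.0, cpath.path_length, 4096)
        env_tree = cKDTree(np.atleast_2d(cpath.point_at(s_dense)))
    samples = []
    counts = []
    thresholds = []
    for strut in edges:
        r = strut.radius if strut.radius > 0 else strut_radius
        step = max(r / 2.0, 1e-3)
        n = max(int(np.ceil(strut.length / step)) + 1, 2)
        t = np.linspace(0.0, 1.0, n)
        samples.append(strut.endpoints[0]
                       + t[:, None] * (strut.endpoints[1] - strut.endpoints[0]))
        counts.append(n)
        thresholds.append(r + clearance)
    all_pts = np.vstack(samples)
    d = sd.query(all_pts)
    if env_tree is not None:
        d_axis, _ = env_tree.query(all_pts)
        d = np.minimum(d, d_axis - r_env)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    kept = []
    for i, strut in enumerate(edges):
        d_min = d[offsets[i]:offsets[i + 1]].min()
        if d_min < thresholds[i]:
            continue
        # clear of the surface but possibly buried inside the solid
        mid = 0.5 * (strut.endpoints[0] + strut.endpoints[1])
        if points_inside(mid[None, :], capillary_solid)[0]:
            continue
        kept.append(strut)
    return kept


def pipe_struts(edges: list[Strut], beam_diameter: float,
                sections: int = 24) -> SurfaceMesh:
    """Convert struts into capsules (cylinders with hemispherical caps)."""
    if beam_diameter <= 0:
        raise SpecError("beam_diameter must be > 0")
    parts = []
    for strut in edges:
        cap = _capsule(strut.endpoints[0], strut.endpoints[1],
                       0.5 * beam_diameter, sections=sections)
        if cap is None:
            warnings.warn("skipping zero-length strut", stacklevel=2)
            continue
        parts.append(cap)
    out = SurfaceMesh.concatenate(parts, provenance="support")
    out.provenance = "support"
    return out


def connectivity_check(struts: list[Strut], base_z: float,
                       tol: float = 0.1) -> dict:
    """Graph connectivity of the strut skeleton against the base plane.

    Endpoints within ``tol`` µm are merged into one node.  Returns a report
    with the number of components, which components touch the base
    (endpoint z ≤ base_z + tol) and the floating islands (strut indices).
    """
    if not struts:
        return {"n_components": 0, "grounded_components": 0,
                "floating_struts": [], "all_grounded": True}
    pts = np.vstack([s.endpoints for s in struts])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(tol)
    parent = list(range(len(pts)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        parent[find(a)] = find(b)
    node = [find(i) for i in range(len(pts))]

    g = nx.Graph()
    for i, s in enumerate(struts):
        g.add_edge(node[2 * i], node[2 * i + 1], strut=i)
    grounded_nodes = {node[i] for i in range(len(pts))
                      if pts[i, 2] <= base_z + tol}
    floating = []
    grounded = 0
    comps = list(nx.connected_components(g))
    for comp in comps:
        if comp & grounded_nodes:
            grounded += 1
        else:
            floating.extend(
                d["strut"] for a, b, d in g.edges(comp, data=True))
    return {
        "n_components": len(comps),
        "grounded_components": grounded,
        "floating_struts": sorted(set(floating)),
        "all_grounded": not floating,
    }


# ---------------------------------------------------------------------------
# Cone supports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConeSupportSpec:
    """Frustum supports under the capillary for soft-material printing.

    ``taper_angle`` is measured from the vertical axis; below 15° the cured
    cone walls shadow the laser and the print fails, so smaller angles are
    rejected.
    """

    taper_angle: float = 15.0
    tip_radius: float = 6.0
    positions: tuple = ()
    subtract_capillary: bool = True
    clearance: float = 0.0
    sections: int = 48

    def __post_init__(self):
        if self.taper_angle < 15.0:
            raise SpecError("taper_angle must be ≥ 15°")
        if self.tip_radius <= 0:
            raise SpecError("tip_radius must be > 0")


def _envelope_floor(capillary_solid: SurfaceMesh, xy_probes, base_z: float):
    """Lowest z of the capillary envelope above the base over probe points.

    When the solid carries its parametric metadata (centerline + outer
    radius) the envelope is the swept outer tube, evaluated analytically —
    this is the "capillary path" geometry subtracted from supports, so cones
    stop at the tube surface instead of poking through pore openings.
    Otherwise vertical ray casting against the given mesh is used.
    """
    path = capillary_solid.metadata.get("path")
    r_out = capillary_solid.metadata.get("outer_radius")
    zs = []
    if path is not None and r_out is not None:
        s = np.linspace(0.0, path.path_length, 4096)
        c = np.atleast_2d(path.point_at(s))
        for x, y in xy_probes:
            dh2 = (c[:, 0] - x) ** 2 + (c[:, 1] - y) ** 2
            near = dh2 < r_out ** 2
            if near.any():
                z_env = c[near, 2] - np.sqrt(r_out ** 2 - dh2[near])
                z_min = float(z_env.min())
                if z_min > base_z:
                    zs.append(z_min)
    else:
        for x, y in xy_probes:
            hh = vertical_ray_hits(capillary_solid, x, y)
            hh = hh[hh > base_z]
            if len(hh):
                zs.append(float(hh.min()))
    return min(zs) if zs else None


def cone_supports(spec: ConeSupportSpec, capillary_solid: SurfaceMesh,
                  base_z: float = 0.0) -> SurfaceMesh:
    """Frustums from the base plane up to the capillary underside.

    Each anchor's frustum rises to the lowest point of the capillary outer
    envelope over the tip footprint, minus ``clearance`` — so the tip
    touches the tube underside without any cone material crossing into the
    capillary envelope (the subtraction that keeps the chip perfusable).
    The generation half-angle is widened slightly to compensate polygonal
    faceting, keeping every facet taper ≥ ``taper_angle``.  Anchors whose
    verticals miss the capillary are reported in
    ``metadata['missed_anchors']``.
    """
    ang = np.deg2rad(spec.taper_angle)
    # compensate the facet-vs-cone angle loss of an n-gon frustum
    ang_gen = np.arctan(np.tan(ang) / np.cos(np.pi / spec.sections)) + 1e-6
    parts = []
    missed = []
    th_probe = 2 * np.pi * np.arange(24) / 24
    for anchor in spec.positions:
        x, y = float(anchor[0]), float(anchor[1])
        probes = [(x, y)]
        for rr in (0.5 * spec.tip_radius, spec.tip_radius):
            probes += [(x + rr * np.cos(t), y + rr * np.sin(t))
                       for t in th_probe]
        floor = _envelope_floor(capillary_solid, probes, base_z)
        if floor is None:
            missed.append((x, y))
            continue
        z_top = floor - (spec.clearance if spec.subtract_capillary else 0.0)
        h = z_top - base_z
        if h <= 0:
            missed.append((x, y))
            continue
        r_top = spec.tip_radius
        r_base = r_top + h * np.tan(ang_gen)
        n = spec.sections
        th = 2 * np.pi * np.arange(n) / n
        ring = np.column_stack([np.cos(th), np.sin(th)])
        v_base = np.column_stack([x + r_base * ring[:, 0],
                                  y + r_base * ring[:, 1],
                                  np.full(n, base_z)])
        v_top = np.column_stack([x + r_top * ring[:, 0],
                                 y + r_top * ring[:, 1],
                                 np.full(n, z_top)])
        centre_base = np.array([[x, y, base_z]])
        centre_top = np.array([[x, y, z_top]])
        verts = np.vstack([v_base, v_top, centre_base, centre_top])
        cb, ct = 2 * n, 2 * n + 1
        faces = []
        for i in range(n):
            j = (i + 1) % n
            faces.extend([
                [i, j, n + j], [i, n + j, n + i],      # lateral, outward
                [j, i, cb],                            # base cap (down)
                [n + i, n + j, ct],                    # top cap (up)
            ])
        parts.append(SurfaceMesh(verts, np.asarray(faces), provenance="support"))
    out = SurfaceMesh.concatenate(parts, provenance="support")
    out.provenance = "support"
    out.metadata["missed_anchors"] = missed
    out.metadata["n_cones"] = len(parts)
    return out


def min_facet_taper_deg(cones: SurfaceMesh) -> float:
    """Minimum facet taper angle (degrees from vertical) over a cone mesh.

    A vertical wall has taper 0°, a horizontal face 90°; printable cones
    need every facet ≥ the spec taper.
    """
    normals = cones.face_normals()
    taper = np.degrees(np.arcsin(np.clip(np.abs(normals[:, 2]), 0, 1)))
    return float(taper.min())
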