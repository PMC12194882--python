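"""Chip assembly: base slab, nozzle ports, retaining walls, decimation, STL.

A printable chip is the porous capillary plus its supports sitting on a flat
adhesion base (top face at z = 0, the scaffold datum), with two vertical
nozzle ports whose bore continues the capillary lumen and whose outer
diameter mates 0.020-inch (508 µm) inner-diameter heat-shrink tubing.  An
annular retaining wall around each port keeps sealing resin out of the
scaffold.  Meshes are optionally decimated (default 95% face reduction, the
practical target for slicing large scaffold files) and exported as binary
STL in µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .errors import MeshError, SpecError
from .mesh import (SurfaceMesh, decimate, export_stl, import_stl,
                   points_inside, vertical_ray_hits)
from .pathgen import PathFrame  # noqa: F401  (public signature type)

__all__ = [
    "ChipSpec", "build_base", "build_nozzles", "assemble", "decimate",
    "export_stl", "import_stl", "voxel_union_volume",
]


@dataclass(frozen=True)
class ChipSpec:
    """Chip-level dimensions (µm)."""

    base_thickness: float = 20.0
    base_margin: float = 100.0
    nozzle_outer_diameter: float = 508.0   # mates 0.020-inch ID tubing
    nozzle_bore: float = 40.0              # = lumen diameter
    nozzle_height: float = 300.0
    retaining_wall_height: float = 100.0
    retaining_wall_thickness: float = 30.0

    def __post_init__(self):
        dims = ("base_thickness", "base_margin", "nozzle_outer_diameter",
                "nozzle_bore", "nozzle_height", "retaining_wall_height",
                "retaining_wall_thickness")
        bad = [d for d in dims if not getattr(self, d) > 0]
        if bad:
            raise SpecError(f"chip dimensions must be > 0: {', '.join(bad)}")
        if self.nozzle_bore >= self.nozzle_outer_diameter:
            raise SpecError("nozzle_bore must be smaller than the outer diameter")


def _extrude_convex(poly: shapely.Polygon, z0: float, z1: float,
                    provenance: str = "chip") -> SurfaceMesh:
    """Extrude a convex polygon into a watertight prism (fan caps)."""
    xy = np.asarray(poly.exterior.coords)[:-1]
    if not bool(shapely.is_ccw(shapely.LinearRing(poly.exterior))):
        xy = xy[::-1]
    n = len(xy)
    bottom = np.column_stack([xy, np.full(n, z0)])
    top = np.column_stack([xy, np.full(n, z1)])
    verts = np.vstack([bottom, top])
    faces = []
    for i in range(n):
        j = (i + 1) % n
        faces.extend([[i, j, n + j], [i, n + j, n + i]])
    for i in range(1, n - 1):  # caps (convex fan)
        faces.append([0, i + 1, i])          # bottom, facing −z
        faces.append([n, n + i, n + i + 1])  # top, facing +z
    return SurfaceMesh(verts, np.asarray(faces), provenance=provenance)


def build_base(footprint, spec: ChipSpec) -> SurfaceMesh:
    """Flat watertight adhesion slab under the scaffold, top face at z = 0.

    ``footprint`` is a shapely polygon or an (n, 2) outline in µm; it must
    be simple (non-self-intersecting).  Non-convex outlines are replaced by
    their convex hull (the slab only needs to cover the projection).
    """
    if not isinstance(footprint, shapely.Polygon):
        footprint = shapely.Polygon(np.asarray(footprint, dtype=float))
    if not footprint.is_valid:
        raise MeshError("footprint outline is self-intersecting")
    hull = footprint.convex_hull
    mesh = _extrude_convex(hull, -spec.base_thickness, 0.0)
    mesh.metadata["kind"] = "base"
    mesh.metadata["footprint_area_um2"] = float(hull.area)
    return mesh


def scaffold_footprint(meshes: list[SurfaceMesh], margin: float
                       ) -> shapely.Polygon:
    """Convex hull of the scaffold projection, offset outward by ``margin``."""
    pts = np.vstack([m.vertices[:, :2] for m in meshes if m.n_faces])
    hull = shapely.MultiPoint(pts).convex_hull.buffer(margin, quad_segs=8)
    return hull.convex_hull


def _tube(r_in: float, r_out: float, z0: float, z1: float, x: float, y: float,
          sections: int = 64) -> SurfaceMesh:
    """Vertical watertight annular tube (open bore) centred at (x, y)."""
    th = 2 * np.pi * np.arange(sections) / sections
    ring = np.column_stack([np.cos(th), np.sin(th)])
    layers = [np.column_stack([r * ring, np.full(sections, zz)])
              for r, zz in ((r_in, z0), (r_out, z0), (r_out, z1), (r_in, z1))]
    verts = np.vstack(layers)
    verts[:, 0] += x
    verts[:, 1] += y
    faces = []
    for band in range(4):
        a0 = band * sections
        b0 = ((band + 1) % 4) * sections
        for i in range(sections):
            j = (i + 1) % sections
            faces.extend([[a0 + i, a0 + j, b0 + j], [a0 + i, b0 + j, b0 + i]])
    return SurfaceMesh(verts, np.asarray(faces), provenance="chip")


def build_nozzles(path_ends: tuple[PathFrame, PathFrame], spec: ChipSpec,
                  with_retaining_wall: bool = True) -> SurfaceMesh:
    """Two hollow vertical ports continuing the capillary lumen.

    Each port is an annulus (bore = lumen diameter, OD sized for the
    heat-shrink tubing) rising from the base top; a concentric retaining
    wall keeps sealing resin away from the scaffold.  A vertical ray down
    the port centre crosses no solid — the bore is open end to end.
    """
    if len(path_ends) != 2:
        raise SpecError("need exactly two end frames")
    c0 = np.asarray(path_ends[0].position)
    c1 = np.asarray(path_ends[1].position)
    if np.linalg.norm(c1[:2] - c0[:2]) < spec.nozzle_outer_diameter:
        raise SpecError("path ends are too close together for two ports")
    parts = []
    for fr in path_ends:
        x, y = float(fr.position[0]), float(fr.position[1])
        parts.append(_tube(0.5 * spec.nozzle_bore,
                           0.5 * spec.nozzle_outer_diameter,
                           0.0, spec.nozzle_height, x, y))
        if with_retaining_wall:
            r_wall = 0.5 * spec.nozzle_outer_diameter + spec.retaining_wall_thickness
            parts.append(_tube(r_wall, r_wall + spec.retaining_wall_thickness,
                               0.0, spec.retaining_wall_height, x, y))
    out = SurfaceMesh.concatenate(parts, provenance="chip")
    out.provenance = "chip"
    out.metadata["kind"] = "nozzles"
    out.metadata["port_centres"] = [tuple(map(float, c0[:2])),
                                    tuple(map(float, c1[:2]))]
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def voxel_union_volume(meshes: list[SurfaceMesh], pitch: float) -> float:
    """Volume of the voxelized union of closed meshes (µm³).

    Centres of a regular grid are tested against each mesh by vertical ray
    parity; counted once even where components overlap.
    """
    meshes = [m for m in meshes if m.n_faces]
    if not meshes:
        return 0.0
    lo = np.min([m.bounds()[0] for m in meshes], axis=0) - pitch
    hi = np.max([m.bounds()[1] for m in meshes], axis=0) + pitch
    xs = np.arange(lo[0] + pitch / 2, hi[0], pitch)
    ys = np.arange(lo[1] + pitch / 2, hi[1], pitch)
    zs = np.arange(lo[2] + pitch / 2, hi[2], pitch)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    occupied = np.zeros(len(pts), dtype=bool)
    for m in meshes:
        b = m.bounds()
        cand = np.all((pts >= b[0] - pitch) & (pts <= b[1] + pitch), axis=1)
        cand &= ~occupied
        if cand.any():
            occupied[np.nonzero(cand)[0][points_inside(pts[cand], m)]] = True
    return float(occupied.sum()) * pitch ** 3


def _overlaps(a: SurfaceMesh, b: SurfaceMesh) -> bool:
    ba, bb = a.bounds(), b.bounds()
    if np.any(ba[1] < bb[0]) or np.any(bb[1] < ba[0]):
        return False
    # sample a few vertices of each against the other
    step = max(len(a.vertices) // 200, 1)
    if points_inside(a.vertices[::step], b).any():
        return True
    step = max(len(b.vertices) // 200, 1)
    return bool(points_inside(b.vertices[::step], a).any())


def assemble(components: list[SurfaceMesh]) -> SurfaceMesh:
    """Merge chip components into a single mesh.

    Components are concatenated with per-component provenance retained in
    ``metadata['components']``; fabrication slicers accept coincident or
    overlapping shells, so no boolean union is attempted (the voxel union
    volume is available via :func:`voxel_union_volume` when the true merged
    volume matters).  Overlap between components is detected and recorded in
    ``metadata['overlapping']``.
    """
    components = [c for c in components if c is not None]
    if not components:
        raise MeshError("nothing to assemble")
    if len(components) == 1:
        return components[0]
    overlapping = []
    for i in range(len(components)):
        for j in range(i + 1, len(components)):
            if components[i].n_faces and components[j].n_faces and \
                    _overlaps(components[i], components[j]):
                overlapping.append((i, j))
    out = SurfaceMesh.concatenate(components, provenance="chip")
    out.metadata["overlapping"] = overlapping
    return out
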