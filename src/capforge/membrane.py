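"""Porous capillary membrane generation.

The capillary wall is a cylindrical surface of lumen diameter ``l_d`` swept
along the centerline and subdivided parametrically into a grid of u (axial) ×
v (circumferential) cells:

    u = ⌊P_l / (p_d + p_s)⌋        s_l = P_l / u
    v = ⌊π·l_d / (p_d + p_s)⌋      s_r = π·l_d / v

where ``p_d`` is the pore diameter, ``p_s`` the edge-to-edge pore spacing and
``P_l`` the path arc length.  Each cell becomes a picture frame: a border of
half the pore spacing is kept and the centre becomes a rectangular through
opening, so the opening is ≈ ``p_d`` across.  Openings on the lateral sides
of the tube are widened circumferentially (default 1.5×) because the
elongated two-photon printing voxel tends to close side-facing pores.  The
framed shell is then thickened into a watertight solid membrane and may be
Catmull-Clark smoothed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .errors import DegenerateGridError, MeshError, PoreMergeError, SpecError
from .mesh import SurfaceMesh, smooth  # re-exported: smoothing is a membrane op
from .pathgen import CenterlinePath, compute_frames_at

__all__ = [
    "CapillarySpec", "SubdivisionGrid", "subdivision_grid", "sweep_shell",
    "cut_pores", "elongate_side_pores", "thicken", "smooth",
    "pore_size_profile",
]


@dataclass(frozen=True)
class CapillarySpec:
    """Tunable membrane design parameters (all lengths in µm).

    ``lumen_diameter`` is the inner, perfusable diameter; thickening grows
    the wall outward from it.  ``side_pore_elongation`` is the dimensionless
    circumferential widening applied to lateral pores.
    """

    lumen_diameter: float
    pore_diameter: float
    pore_spacing: float
    membrane_thickness: float
    side_pore_elongation: float = 1.5
    smoothing_iterations: int = 1

    def __post_init__(self):
        problems = []
        for name in ("lumen_diameter", "pore_diameter", "pore_spacing",
                     "membrane_thickness"):
            if not getattr(self, name) > 0:
                problems.append(f"{name} must be > 0")
        if self.side_pore_elongation <= 0:
            problems.append("side_pore_elongation must be > 0")
        if self.smoothing_iterations < 0:
            problems.append("smoothing_iterations must be ≥ 0")
        if not problems:
            pitch = self.pore_diameter + self.pore_spacing
            if np.pi * self.lumen_diameter < 3.0 * pitch:
                problems.append(
                    "π·lumen_diameter must allow ≥ 3 circumferential "
                    f"subdivisions (pitch {pitch} µm too large)")
        if problems:
            raise SpecError("; ".join(problems))

    @property
    def pitch(self) -> float:
        """Grid pitch: pore diameter + edge-to-edge spacing (µm)."""
        return self.pore_diameter + self.pore_spacing

    @property
    def lumen_radius(self) -> float:
        return 0.5 * self.lumen_diameter


@dataclass(frozen=True)
class SubdivisionGrid:
    """Derived subdivision counts and exact cell side lengths."""

    u: int
    v: int
    s_l: float
    s_r: float
    path_length: float
    lumen_diameter: float

    def __post_init__(self):
        if self.u < 1 or self.v < 3:
            raise SpecError("grid requires u ≥ 1 and v ≥ 3")

    @property
    def n_pores(self) -> int:
        return self.u * self.v


def subdivision_grid(path_length: float, spec: CapillarySpec,
                     rounding: str = "floor") -> SubdivisionGrid:
    """Compute the u×v pore grid for a path of length ``path_length``.

    Subdivision counts are rounded down by default so the realized spacing
    is never below the requested one (``rounding`` may be ``"nearest"``).
    """
    if path_length <= 0:
        raise SpecError("path_length must be > 0")
    pitch = spec.pitch
    circumference = np.pi * spec.lumen_diameter
    if pitch >= path_length and pitch >= circumference:
        raise DegenerateGridError(
            f"pore pitch {pitch} µm exceeds both path length and circumference")
    op = {"floor": np.floor, "nearest": np.round}[rounding]
    u = max(int(op(path_length / pitch)), 1)
    v = max(int(op(circumference / pitch)), 3)
    return SubdivisionGrid(u=u, v=v, s_l=path_length / u, s_r=circumference / v,
                           path_length=path_length,
                           lumen_diameter=spec.lumen_diameter)


# ---------------------------------------------------------------------------
# Sweeping
# ---------------------------------------------------------------------------

def _curvature_at(path: CenterlinePath, s: np.ndarray) -> np.ndarray:
    ds = max(path.path_length * 1e-4, 1e-3)
    t0 = np.atleast_2d(path.tangent_at(np.clip(s - ds, 0, path.path_length)))
    t1 = np.atleast_2d(path.tangent_at(np.clip(s + ds, 0, path.path_length)))
    return np.linalg.norm(t1 - t0, axis=1) / (2 * ds)


def sweep_shell(path: CenterlinePath, grid: SubdivisionGrid,
                spec: CapillarySpec) -> SurfaceMesh:
    """Sweep the open cylindrical shell (u×v quad grid, triangulated).

    Circumferential index 0 sits on the frame normal at every station (a
    reproducible seam).  Emits a warning naming the stations where the path
    curvature radius drops below the lumen radius (local tube
    self-intersection).
    """
    u, v = grid.u, grid.v
    R = spec.lumen_radius
    stations = np.arange(u + 1) * grid.s_l
    frames = compute_frames_at(path, stations)

    kappa = _curvature_at(path, stations)
    tight = np.nonzero(kappa > 1.0 / R)[0]
    if len(tight):
        warnings.warn(
            f"curvature radius < lumen radius at stations {tight.tolist()}: "
            "swept tube self-intersects locally", stacklevel=2)

    theta = 2.0 * np.pi * np.arange(v) / v
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    verts = np.empty(((u + 1) * v, 3))
    radial = np.empty_like(verts)
    param = np.empty(((u + 1) * v, 2))
    for k, fr in enumerate(frames):
        rad = cos_t[:, None] * fr.normal + sin_t[:, None] * fr.binormal
        verts[k * v:(k + 1) * v] = fr.position + R * rad
        radial[k * v:(k + 1) * v] = rad
        param[k * v:(k + 1) * v, 0] = stations[k]
        param[k * v:(k + 1) * v, 1] = theta

    closed = path.closed
    n_rings = u if closed else u + 1

    def vid(k, j):
        return (k % n_rings if closed else k) * v + (j % v)

    faces = []
    for k in range(u):
        for j in range(v):
            a, b = vid(k, j), vid(k, j + 1)
            c, d = vid(k + 1, j + 1), vid(k + 1, j)
            faces.extend([[a, b, c], [a, c, d]])
    if closed:
        verts = verts[: u * v]
        radial = radial[: u * v]
        param = param[: u * v]

    mesh = SurfaceMesh(verts, np.asarray(faces), provenance="membrane")
    mesh.metadata.update({
        "kind": "swept_shell", "path": path, "grid": grid, "spec": spec,
        "stations": stations, "radial": radial, "param_st": param,
        "closed": closed,
        "end_loops": [] if closed else [
            np.array([vid(0, j) for j in range(v)], dtype=np.int64),
            np.array([vid(u, j) for j in range(v)], dtype=np.int64),
        ],
    })
    return mesh


# ---------------------------------------------------------------------------
# Picture-frame pores
# ---------------------------------------------------------------------------

def cut_pores(shell: SurfaceMesh, grid: SubdivisionGrid, spec: CapillarySpec,
              elongation_factors: np.ndarray | None = None) -> SurfaceMesh:
    """Turn every grid cell into a picture frame with a rectangular opening.

    The frame border is ``p_s/2`` on each side, so openings are
    ``(s_l − p_s) × (s_r − p_s)`` ≈ ``p_d`` across.  ``elongation_factors``
    (u×v) optionally scales each opening circumferentially about the cell
    centre (used by :func:`elongate_side_pores`).  Returns an open surface
    with u·v pore loops plus two end loops for an open path.
    """
    if shell.metadata.get("kind") != "swept_shell":
        raise MeshError("cut_pores expects the shell from sweep_shell")
    g = shell.metadata["grid"]
    if (g.u, g.v) != (grid.u, grid.v):
        raise MeshError("grid does not match the one the shell was swept with")
    path: CenterlinePath = shell.metadata["path"]
    closed = shell.metadata["closed"]
    u, v = grid.u, grid.v
    R = spec.lumen_radius

    a_in = 0.5 * spec.pore_spacing          # axial inset, µm
    phi_in = 0.5 * spec.pore_spacing / R    # circumferential inset, rad
    dtheta = 2.0 * np.pi / v
    if a_in >= 0.5 * grid.s_l or phi_in >= 0.5 * dtheta:
        raise PoreMergeError(
            f"pore spacing {spec.pore_spacing} µm ≥ cell size "
            f"({grid.s_l:.3g} × {grid.s_r:.3g} µm): openings vanish")
    if elongation_factors is None:
        elongation_factors = np.ones((u, v))
    else:
        elongation_factors = np.asarray(elongation_factors, dtype=float)
        if elongation_factors.shape != (u, v):
            raise MeshError("elongation_factors must have shape (u, v)")

    stations = np.arange(u + 1) * grid.s_l
    s_lo = stations[:-1] + a_in
    s_hi = stations[1:] - a_in
    all_s = np.concatenate([stations, s_lo, s_hi])
    frames = compute_frames_at(path, all_s)
    fr_station = frames[: u + 1]
    fr_lo = frames[u + 1: 2 * u + 1]
    fr_hi = frames[2 * u + 1:]

    theta = dtheta * np.arange(v)

    def surf(fr, th):
        rad = np.cos(th) * fr.normal + np.sin(th) * fr.binormal
        return fr.position + R * rad, rad

    verts: list[np.ndarray] = []
    radial: list[np.ndarray] = []
    param: list[tuple[float, float]] = []

    def add_vert(fr, s, th):
        p, rad = surf(fr, th)
        verts.append(p)
        radial.append(rad)
        param.append((s, th))
        return len(verts) - 1

    n_rings = u if closed else u + 1
    corner = np.empty((n_rings, v), dtype=np.int64)
    for k in range(n_rings):
        for j in range(v):
            corner[k, j] = add_vert(fr_station[k], stations[k], theta[j])

    def cid(k, j):
        return corner[k % n_rings if closed else k, j % v]

    faces: list[list[int]] = []
    pore_cells: list[dict] = []
    for k in range(u):
        for j in range(v):
            th0, th1 = theta[j], theta[j] + dtheta
            th_c = 0.5 * (th0 + th1)
            half = (0.5 * dtheta - phi_in) * elongation_factors[k, j]
            if half <= 0 or half >= 0.5 * dtheta - 1e-12:
                raise PoreMergeError(
                    f"cell (u={k}, v={j}): elongation factor "
                    f"{elongation_factors[k, j]:.3g} merges or closes the pore")
            # outer corners (ccw seen from outside: +θ then +s)
            A, B = cid(k, j), cid(k, j + 1)
            C, D = cid(k + 1, j + 1), cid(k + 1, j)
            # inner opening corners
            Ai = add_vert(fr_lo[k], s_lo[k], th_c - half)
            Bi = add_vert(fr_lo[k], s_lo[k], th_c + half)
            Ci = add_vert(fr_hi[k], s_hi[k], th_c + half)
            Di = add_vert(fr_hi[k], s_hi[k], th_c - half)
            for (p, q, qi, pi) in ((A, B, Bi, Ai), (B, C, Ci, Bi),
                                   (C, D, Di, Ci), (D, A, Ai, Di)):
                faces.extend([[p, q, qi], [p, qi, pi]])
            s_c = 0.5 * (stations[k] + stations[k + 1])
            pore_cells.append({
                "cell": (k, j), "s": float(s_c), "theta": float(th_c % (2 * np.pi)),
                "loop": np.array([Ai, Bi, Ci, Di], dtype=np.int64),
                "axial_extent": float(s_hi[k] - s_lo[k]),
                "circ_extent": float(2.0 * half * R),
                "elongation": float(elongation_factors[k, j]),
            })

    mesh = SurfaceMesh(np.asarray(verts), np.asarray(faces), provenance="membrane")
    mesh.metadata.update({
        "kind": "pored_shell", "path": path, "grid": grid, "spec": spec,
        "stations": stations, "radial": np.asarray(radial),
        "param_st": np.asarray(param), "closed": closed,
        "pore_cells": pore_cells,
        "end_loops": [] if closed else [
            np.array([cid(0, j) for j in range(v)], dtype=np.int64),
            np.array([cid(u, j) for j in range(v)], dtype=np.int64),
        ],
    })
    return mesh


def elongate_side_pores(shell: SurfaceMesh, spec: CapillarySpec,
                        side_cone_deg: float = 30.0) -> SurfaceMesh:
    """Widen lateral pore openings circumferentially by the spec factor.

    A pore is lateral ("side-facing") when its outward normal lies within
    ``side_cone_deg`` of the horizontal plane — those are the openings the
    anisotropic printing voxel tends to close.  Top/bottom pores are left
    unchanged.  Raises :class:`PoreMergeError` if widening would merge
    neighbouring pores.
    """
    if shell.metadata.get("kind") != "pored_shell":
        raise MeshError("elongate_side_pores expects the shell from cut_pores")
    path: CenterlinePath = shell.metadata["path"]
    grid: SubdivisionGrid = shell.metadata["grid"]
    u, v = grid.u, grid.v
    sin_cone = np.sin(np.deg2rad(side_cone_deg))

    radial = shell.metadata["radial"]
    factors = np.ones((u, v))
    for cell in shell.metadata["pore_cells"]:
        k, j = cell["cell"]
        rad = radial[cell["loop"]].mean(axis=0)
        rad /= np.linalg.norm(rad)
        if abs(rad[2]) <= sin_cone:
            factors[k, j] = spec.side_pore_elongation

    base = sweep_shell(path, grid, spec)
    return cut_pores(base, grid, spec, elongation_factors=factors)


# ---------------------------------------------------------------------------
# Thickening
# ---------------------------------------------------------------------------

def thicken(shell: SurfaceMesh, thickness: float | None = None,
            mode: str = "outward",
            on_self_intersection: str = "error") -> SurfaceMesh:
    """Offset the open shell into a watertight solid membrane.

    ``outward`` mode (default) keeps the lumen diameter as the inner,
    perfusable diameter and grows the wall outward; ``symmetric`` splits the
    thickness across the surface.  Pore openings become through-channels
    walled by quads; end rings get annular caps.  For a membrane with P
    through-pores and two annular end caps the result has Euler
    characteristic χ = −2P (a genus P+1 surface).

    A path bend tighter than (lumen radius + thickness) folds the outer
    surface; this raises :class:`MeshError` (or warns when
    ``on_self_intersection='warn'``, accepting local pore constriction as
    printed scaffolds do on interior curves).
    """
    if shell.metadata.get("kind") not in ("swept_shell", "pored_shell"):
        raise MeshError("thicken expects a parametric shell")
    spec: CapillarySpec = shell.metadata["spec"]
    if thickness is None:
        thickness = spec.membrane_thickness
    if not thickness > 0:
        raise MeshError("thickness must be > 0")
    if mode not in ("outward", "symmetric"):
        raise MeshError("mode must be 'outward' or 'symmetric'")

    path: CenterlinePath = shell.metadata["path"]
    stations = shell.metadata["stations"]
    kappa = _curvature_at(path, stations)
    r_out = spec.lumen_radius + (thickness if mode == "outward" else 0.5 * thickness)
    bad = np.nonzero(kappa > 1.0 / r_out)[0]
    if len(bad):
        msg = (f"outer surface folds: curvature radius < {r_out:.3g} µm at "
               f"stations {bad.tolist()}")
        if on_self_intersection == "error":
            raise MeshError(msg)
        warnings.warn(msg, stacklevel=2)

    V = shell.vertices
    radial = shell.metadata["radial"]
    n = len(V)
    if mode == "outward":
        v_in = V
        v_out = V + thickness * radial
    else:
        v_in = V - 0.5 * thickness * radial
        v_out = V + 0.5 * thickness * radial
    verts = np.vstack([v_in, v_out])

    F = shell.faces
    faces_out = F + n
    faces_in = F[:, ::-1]
    # walls along every boundary loop (pore openings + end rings)
    directed = F[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    und = np.sort(directed, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary = directed[counts[inv] == 1]
    walls = []
    for a, b in boundary:
        walls.extend([[b + n, a + n, a], [b + n, a, b]])
    mesh = SurfaceMesh(verts, np.vstack([faces_in, faces_out, np.asarray(walls)]),
                       provenance="membrane")
    meta = {k: shell.metadata[k] for k in
            ("path", "grid", "spec", "stations", "closed")}
    meta["kind"] = "membrane_solid"
    meta["thickness"] = float(thickness)
    meta["mode"] = mode
    meta["outer_radius"] = r_out if mode == "outward" else spec.lumen_radius + 0.5 * thickness
    if "pore_cells" in shell.metadata:
        meta["pore_cells"] = shell.metadata["pore_cells"]
        meta["n_pores"] = len(shell.metadata["pore_cells"])
    mesh.metadata = meta
    return mesh


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def pore_size_profile(mesh: SurfaceMesh, path: CenterlinePath | None = None
                      ) -> pd.DataFrame:
    """Effective diameter of every pore opening along the path.

    For each pore the boundary loop is projected onto the local tangent
    plane and the maximum inscribed circle of the projected polygon is
    reported.  Columns: ``pore_id, cell_u, cell_v, s, theta, diameter_um,
    axial_extent_um, circ_extent_um``.  Curved paths constrict pores on the
    interior of a bend and widen them on the exterior.
    """
    cells = mesh.metadata.get("pore_cells", [])
    if path is None:
        path = mesh.metadata.get("path")
    rows = []
    for pid, cell in enumerate(cells):
        loop = mesh.vertices[cell["loop"]]
        centroid = loop.mean(axis=0)
        # local tangent-plane basis: axial (path tangent) × circumferential
        t = path.tangent_at(cell["s"]) if path is not None else None
        if t is None:
            # fall back to the loop's own plane
            _, _, vt = np.linalg.svd(loop - centroid)
            e1, e2 = vt[0], vt[1]
        else:
            rad = centroid - np.atleast_2d(path.point_at(cell["s"]))[0]
            rad = rad - np.dot(rad, t) * t
            nrm = np.linalg.norm(rad)
            rad = rad / nrm if nrm > 0 else rad
            e1, e2 = t, np.cross(rad, t)
        uv = np.column_stack([(loop - centroid) @ e1, (loop - centroid) @ e2])
        poly = shapely.Polygon(uv)
        if not poly.is_valid or poly.area <= 0:
            diameter = 0.0
        else:
            seg = shapely.maximum_inscribed_circle(poly)
            diameter = 2.0 * seg.length
        rows.append({
            "pore_id": pid, "cell_u": cell["cell"][0], "cell_v": cell["cell"][1],
            "s": cell["s"], "theta": cell["theta"], "diameter_um": diameter,
            "axial_extent_um": float(np.ptp(uv[:, 0])),
            "circ_extent_um": float(np.ptp(uv[:, 1])),
        })
    return pd.DataFrame(rows, columns=[
        "pore_id", "cell_u", "cell_v", "s", "theta", "diameter_um",
        "axial_extent_um", "circ_extent_um"])
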