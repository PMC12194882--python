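"""Centerline paths for microcapillary scaffolds.

A capillary is swept along a :class:`CenterlinePath` — an interpolating
spline through imported or generated 3D points (µm) with an arc-length
parameterization.  Built-in generators produce space-filling Hilbert curves
(the tortuous, plane-filling routes used for high-coverage vasculature) and
single/double helices.  Sweeping requires a twist-free moving frame at each
station; rotation-minimizing frames are computed with the double-reflection
method, which (unlike the Frenet frame) is well defined on straight segments.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline

from .errors import InvalidPathError, PathParseError

_DENSE_MIN = 1024


@dataclass
class PathFrame:
    """Orthonormal right-handed triad at a station on the path."""

    position: np.ndarray
    tangent: np.ndarray
    normal: np.ndarray
    binormal: np.ndarray

    @property
    def arc_length(self) -> float:
        return float(self.__dict__.get("_s", np.nan))


class CenterlinePath:
    """Ordered 3D points (µm) with an interpolating spline axis.

    Parameters
    ----------
    points : (n, 3) array
        Ordered coordinates in µm; consecutive duplicates are rejected.
    degree : int
        Spline degree (≥1); clamped to ``n − 1`` for short paths.  The cubic
        default approximates a NURBS axis through the same points.
    closed : bool
        Periodic spline through the points (first point re-used as last).
    """

    def __init__(self, points, degree: int = 3, closed: bool = False):
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        if len(pts) < 2:
            raise InvalidPathError("a path needs at least 2 points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg < 1e-9):
            bad = int(np.nonzero(seg < 1e-9)[0][0])
            raise InvalidPathError(f"consecutive duplicate points at index {bad}")
        if degree < 1:
            raise InvalidPathError("spline degree must be ≥ 1")
        self.points = pts
        self.closed = bool(closed)
        if closed:
            if np.linalg.norm(pts[0] - pts[-1]) > 1e-9:
                pts = np.vstack([pts, pts[0]])
            else:
                pts = pts.copy()
                pts[-1] = pts[0]  # periodic fit requires exact closure
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self.degree = int(min(degree, len(pts) - 1))

        # chord-length parameterization
        t = np.concatenate([[0.0], np.cumsum(seg)])
        t /= t[-1]
        if self.closed and self.degree == 3 and len(pts) >= 4:
            self._spline = make_interp_spline(t, pts, k=3, bc_type="periodic")
        else:
            self._spline = make_interp_spline(t, pts, k=self.degree)
        self._dspline = self._spline.derivative()

        n_dense = max(_DENSE_MIN, 32 * (len(pts) - 1)) + 1
        # include the interpolation parameters so polyline corners are
        # sampled exactly and the chord sum matches the true arc length
        td = np.unique(np.concatenate([np.linspace(0.0, 1.0, n_dense), t]))
        pd = self._spline(td)
        sd = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pd, axis=0), axis=1))]
        )
        self._t_dense = td
        self._s_dense = sd
        self.path_length = float(sd[-1])
        if not self.path_length > 0:
            raise InvalidPathError("path has zero length")

    # -- evaluation ------------------------------------------------------
    def _t_of_s(self, s):
        s = np.clip(np.asarray(s, dtype=np.float64), 0.0, self.path_length)
        return np.interp(s, self._s_dense, self._t_dense)

    def point_at(self, s):
        """Position(s) at arc length ``s`` (µm)."""
        return self._spline(self._t_of_s(s))

    def tangent_at(self, s):
        """Unit tangent(s) at arc length ``s``."""
        d = np.atleast_2d(self._dspline(self._t_of_s(s)))
        norms = np.linalg.norm(d, axis=1)
        if np.any(norms < 1e-12):
            raise InvalidPathError("degenerate tangent on path")
        out = d / norms[:, None]
        return out[0] if np.isscalar(s) else out

    def stations(self, n: int) -> np.ndarray:
        """``n`` arc-length-equidistant station positions in [0, P_l]."""
        if n < 2:
            raise InvalidPathError("need at least 2 stations")
        return np.linspace(0.0, self.path_length, n)

    # -- diagnostics -----------------------------------------------------
    def min_self_distance(self) -> float:
        """Minimum distance between non-adjacent polyline segments.

        Evaluated on the input polyline (generator vertices), the natural
        carrier of the self-avoidance guarantee of space-filling curves.
        """
        p = self.points
        n = len(p) - 1
        if n < 3:
            return float("inf")
        a0 = p[:-1]
        a1 = p[1:]
        best = np.inf
        for i in range(n - 2):
            j = np.arange(i + 2, n)
            if self.closed and i == 0:
                j = j[j < n - 1]
            if len(j) == 0:
                continue
            d = _segment_segment_distance(a0[i], a1[i], a0[j], a1[j])
            best = min(best, float(d.min()))
        return best


def _segment_segment_distance(p1, q1, p2, q2):
    """Distance from segment (p1, q1) to each segment (p2[i], q2[i])."""
    d1 = q1 - p1                      # (3,)
    d2 = q2 - p2                      # (m, 3)
    r = p1 - p2                       # (m, 3)
    a = float(np.dot(d1, d1))
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("j,ij->i", d1, r)
    b = np.einsum("j,ij->i", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > 1e-30,
                 np.clip((b * f - c * e) / np.where(denom > 1e-30, denom, 1.0), 0, 1),
                 0.0)
    t = (b * s + f) / np.where(e > 1e-30, e, 1.0)
    s = np.where(t < 0, np.clip(-c / a, 0, 1), s)
    s = np.where(t > 1, np.clip((b - c) / a, 0, 1), s)
    t = np.clip(t, 0.0, 1.0)
    c1 = p1 + s[:, None] * d1
    c2 = p2 + t[:, None] * d2
    return np.linalg.norm(c1 - c2, axis=1)


# ---------------------------------------------------------------------------
# Import
# ---------------------------------------------------------------------------

def load_path_csv(file, units_scale: float = 1.0, degree: int = 1,
                  closed: bool = False) -> CenterlinePath:
    """Load a centerline from a CSV of ``x,y,z`` rows.

    One point per row; an optional single header row is auto-detected;
    ``#`` starts a comment line.  Coordinates are multiplied by
    ``units_scale`` to yield µm (e.g. 1000 for mm input).

    The default ``degree=1`` keeps the path chord-exact (its arc length is
    the polyline chord sum); pass ``degree=3`` for a smooth interpolating
    axis, ideally after filleting sharp corners with
    :func:`fillet_polyline`, since an interpolating cubic overshoots at
    right-angle corners and lengthens the path.
    """
    rows: list[tuple[int, list[str]]] = []
    with open(file, newline="") as fh:
        for ln, row in enumerate(csv.reader(fh), start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            if all(not c.strip() for c in row):
                continue
            rows.append((ln, row))
    pts = []
    for i, (ln, row) in enumerate(rows):
        if len(row) != 3:
            raise PathParseError(ln, f"expected 3 columns, got {len(row)}")
        try:
            pts.append([float(c) for c in row])
        except ValueError:
            if i == 0:
                continue  # header row
            raise PathParseError(ln, f"non-numeric value in {row!r}") from None
    if len(pts) < 2:
        raise InvalidPathError(f"{file}: fewer than 2 points")
    return CenterlinePath(np.asarray(pts) * float(units_scale), degree=degree,
                          closed=closed)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _hilbert_vertices(order: int, dims: int) -> np.ndarray:
    """Integer lattice vertices of the Hilbert curve (Skilling transpose).

    Consecutive vertices differ by exactly one unit step along one axis; the
    curve visits all ``2**(order*dims)`` lattice points of the cube once.
    """
    n_pts = 1 << (order * dims)
    out = np.empty((n_pts, dims), dtype=np.int64)
    for idx in range(n_pts):
        X = [0] * dims
        for b in range(order * dims):
            bit = (idx >> (order * dims - 1 - b)) & 1
            X[b % dims] = (X[b % dims] << 1) | bit
        # transpose -> axes (Gray decode + undo excess work)
        N = 2 << (order - 1)
        t = X[dims - 1] >> 1
        for i in range(dims - 1, 0, -1):
            X[i] ^= X[i - 1]
        X[0] ^= t
        Q = 2
        while Q != N:
            P = Q - 1
            for i in range(dims - 1, -1, -1):
                if X[i] & Q:
                    X[0] ^= P
                else:
                    t = (X[0] ^ X[i]) & P
                    X[0] ^= t
                    X[i] ^= t
            Q <<= 1
        out[idx] = X
    return out


def fillet_polyline(points: np.ndarray, radius: float) -> np.ndarray:
    """Chamfer sharp interior corners before spline fitting.

    Each corner where the direction changes is replaced by two points at
    distance ``radius`` along the incoming and outgoing segments (clamped to
    49% of each segment), which the spline then rounds.  Prevents the swept
    tube from self-intersecting at right-angle corners.
    """
    pts = np.asarray(points, dtype=np.float64)
    if radius <= 0 or len(pts) < 3:
        return pts
    out = [pts[0]]
    for i in range(1, len(pts) - 1):
        a, b, c = pts[i - 1], pts[i], pts[i + 1]
        d_in = b - a
        d_out = c - b
        l_in = np.linalg.norm(d_in)
        l_out = np.linalg.norm(d_out)
        cosang = np.dot(d_in, d_out) / (l_in * l_out)
        if cosang > 1 - 1e-9:  # straight through: keep as-is
            out.append(b)
            continue
        r_in = min(radius, 0.49 * l_in)
        r_out = min(radius, 0.49 * l_out)
        out.append(b - d_in / l_in * r_in)
        out.append(b + d_out / l_out * r_out)
    out.append(pts[-1])
    return np.asarray(out)


def hilbert_path(order: int, dims: int = 2, step: float = 100.0,
                 layers: int = 1, layer_gap: float = 100.0,
                 corner_fillet_radius: float = 0.0,
                 degree: int | None = None) -> CenterlinePath:
    """Space-filling Hilbert-curve centerline.

    ``layers > 1`` stacks copies of the curve along z, each separated by
    ``layer_gap`` (beyond the curve's own z extent for 3D curves), with
    alternate layers reversed so consecutive layers join by a short vertical
    connecting segment.

    With ``corner_fillet_radius > 0`` the right-angle corners are chamfered
    and a cubic spline rounds them (recommended for sweeping: set it to the
    lumen radius to prevent tube self-intersection).  Without a fillet the
    path defaults to the exact polyline (degree 1), whose arc length is the
    unit-step count × ``step``.
    """
    if order < 1:
        raise InvalidPathError("Hilbert order must be ≥ 1")
    if dims not in (2, 3):
        raise InvalidPathError("dims must be 2 or 3")
    if layers < 1:
        raise InvalidPathError("layers must be ≥ 1")
    if step <= 0:
        raise InvalidPathError("step must be > 0")
    base = _hilbert_vertices(order, dims).astype(np.float64) * step
    if dims == 2:
        base = np.hstack([base, np.zeros((len(base), 1))])
    z_extent = base[:, 2].max() - base[:, 2].min()
    stacked = []
    for i in range(layers):
        layer = base[::-1] if i % 2 else base
        layer = layer + np.array([0.0, 0.0, i * (z_extent + layer_gap)])
        stacked.append(layer)
    pts = np.vstack(stacked)
    pts = fillet_polyline(pts, corner_fillet_radius)
    if degree is None:
        degree = 3 if corner_fillet_radius > 0 else 1
    return CenterlinePath(pts, degree=degree)


def helix_path(radius: float, pitch: float, turns: float, strands: int = 1,
               samples_per_turn: int = 32, degree: int = 3) -> list[CenterlinePath]:
    """One or two phase-offset helical centerlines (double-helix designs).

    ``pitch`` is the z rise per full turn (µm).  The second strand is offset
    by π so the two lumens sit 2·radius apart at every height.
    """
    if radius <= 0 or pitch <= 0:
        raise InvalidPathError("radius and pitch must be > 0")
    if turns <= 0:
        raise InvalidPathError("turns must be > 0")
    if strands not in (1, 2):
        raise InvalidPathError("strands must be 1 or 2")
    if samples_per_turn < 8:
        raise InvalidPathError("samples_per_turn < 8 undersamples the helix")
    n = int(np.ceil(samples_per_turn * turns)) + 1
    theta = np.linspace(0.0, 2.0 * np.pi * turns, n)
    out = []
    for k in range(strands):
        phase = np.pi * k
        pts = np.column_stack([
            radius * np.cos(theta + phase),
            radius * np.sin(theta + phase),
            pitch * theta / (2.0 * np.pi),
        ])
        out.append(CenterlinePath(pts, degree=degree))
    return out


# ---------------------------------------------------------------------------
# Rotation-minimizing frames
# ---------------------------------------------------------------------------

def _rmf(positions: np.ndarray, tangents: np.ndarray) -> np.ndarray:
    """Double-reflection rotation-minimizing normals along sampled stations."""
    n = len(positions)
    normals = np.empty_like(positions)
    t0 = tangents[0]
    # Seed normal: for planar curves pick it inside the best-fit plane, so
    # the whole twist-free field stays in-plane; for straight lines fall
    # back to the least-aligned coordinate axis.
    centered = positions - positions.mean(axis=0)
    scale = max(float(np.abs(centered).max()), 1.0)
    _, sv, vt = np.linalg.svd(centered / scale, full_matrices=True)
    sv = np.pad(sv, (0, 3 - len(sv)))
    if sv[1] > 1e-9 and sv[2] < 1e-9 * max(sv[0], 1.0):
        ref = np.cross(t0, vt[2])  # in-plane perpendicular to the tangent
    else:
        ref = np.zeros(3)
        ref[int(np.argmin(np.abs(t0)))] = 1.0
    r = ref - np.dot(ref, t0) * t0
    r /= np.linalg.norm(r)
    normals[0] = r
    for i in range(n - 1):
        v1 = positions[i + 1] - positions[i]
        c1 = np.dot(v1, v1)
        if c1 < 1e-24:
            normals[i + 1] = normals[i]
            continue
        rl = normals[i] - (2.0 / c1) * np.dot(v1, normals[i]) * v1
        tl = tangents[i] - (2.0 / c1) * np.dot(v1, tangents[i]) * v1
        v2 = tangents[i + 1] - tl
        c2 = np.dot(v2, v2)
        if c2 < 1e-24:
            r_next = rl
        else:
            r_next = rl - (2.0 / c2) * np.dot(v2, rl) * v2
        # re-orthonormalize against accumulated drift
        r_next = r_next - np.dot(r_next, tangents[i + 1]) * tangents[i + 1]
        normals[i + 1] = r_next / np.linalg.norm(r_next)
    return normals


def compute_frames_at(path: CenterlinePath, s_values) -> list[PathFrame]:
    """Rotation-minimizing frames at given arc lengths (sorted internally).

    The frame field is marched on a dense grid refined with the requested
    stations, so frames at nearby arc lengths share a consistent twist-free
    transport regardless of request granularity.
    """
    s_req = np.asarray(s_values, dtype=np.float64)
    order = np.argsort(s_req, kind="stable")
    dense = np.linspace(0.0, path.path_length, max(_DENSE_MIN, 4 * len(s_req)))
    s_all = np.unique(np.concatenate([dense, s_req[order]]))
    pos = np.atleast_2d(path.point_at(s_all))
    tan = np.atleast_2d(path.tangent_at(s_all))
    normals = _rmf(pos, tan)
    idx = np.searchsorted(s_all, s_req)
    idx = np.clip(idx, 0, len(s_all) - 1)
    frames = []
    for i, s in zip(idx, s_req):
        t = tan[i]
        nvec = normals[i]
        frame = PathFrame(
            position=pos[i].copy(), tangent=t.copy(), normal=nvec.copy(),
            binormal=np.cross(t, nvec),
        )
        frame.__dict__["_s"] = float(s)
        frames.append(frame)
    return frames


def compute_frames(path: CenterlinePath, n_stations: int) -> list[PathFrame]:
    """Rotation-minimizing frames at ``n_stations`` arc-length-equidistant
    stations; successive normals never flip (angle < 90°)."""
    if n_stations < 2:
        raise InvalidPathError("n_stations must be ≥ 2")
    return compute_frames_at(path, path.stations(n_stations))
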