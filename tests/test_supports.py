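"""FOV seams, polygonal rings, truncated-octahedron lattice, cones."""

import math
import warnings

import numpy as np
import pytest

from capforge.errors import MeshError, SpecError
from capforge.mesh import SurfaceDistance, points_inside
from capforge.pathgen import CenterlinePath
from capforge.supports import (ConeSupportSpec, FOVLayout, LatticeSpec,
                               PolygonalSupportSpec, Strut, connectivity_check,
                               cone_supports, cull_struts, lattice_edges,
                               min_facet_taper_deg, pipe_struts,
                               polygonal_supports, predict_fov_seams,
                               support_positions)


class TestFovSeams:
    def test_axis_aligned_straight_path(self):
        layout = FOVLayout(fov_width=400, overlap=0, stitch_angle=0)
        path = CenterlinePath([[0, 0, 50], [1000, 0, 50]], degree=1)
        seams = predict_fov_seams(layout, path)
        assert [round(s) for s, _ in seams] == [400, 800]

    def test_path_within_one_fov(self):
        layout = FOVLayout(fov_width=400, overlap=5, stitch_angle=0)
        path = CenterlinePath([[10, 10, 0], [200, 10, 0]], degree=1)
        assert predict_fov_seams(layout, path) == []

    def test_rotated_seams_match_segment_intersection_oracle(self):
        layout = FOVLayout(fov_width=300, overlap=0, stitch_angle=15)
        pts = np.array([[0, 0, 0], [700, 0, 0], [700, 500, 0]], dtype=float)
        path = CenterlinePath(pts, degree=1)
        seams = predict_fov_seams(layout, path)
        # brute-force: intersect each polyline segment with each seam line
        ang = math.radians(15)
        fam = [(math.cos(ang), math.sin(ang)), (-math.sin(ang), math.cos(ang))]
        oracle = []
        arc0 = 0.0
        for a, b in zip(pts[:-1], pts[1:]):
            seg = b - a
            seg_len = np.linalg.norm(seg)
            for nx, ny in fam:
                ca = a[0] * nx + a[1] * ny
                cb = b[0] * nx + b[1] * ny
                for k in range(int(min(ca, cb) // 300), int(max(ca, cb) // 300) + 2):
                    c = k * 300.0
                    if (ca - c) * (cb - c) < 0:
                        t = (c - ca) / (cb - ca)
                        oracle.append(arc0 + t * seg_len)
            arc0 += seg_len
        assert np.allclose(sorted(s for s, _ in seams), sorted(oracle), atol=1.0)

    def test_translation_covariance_by_one_period(self):
        path = CenterlinePath([[0, 0, 0], [900, 350, 0]], degree=1)
        a = FOVLayout(fov_width=300, overlap=10, stitch_angle=15, origin=(0, 0))
        period = a.period
        ang = math.radians(15)
        shift = (period * math.cos(ang), period * math.sin(ang))
        b = FOVLayout(fov_width=300, overlap=10, stitch_angle=15, origin=shift)
        sa = [s for s, _ in predict_fov_seams(a, path)]
        sb = [s for s, _ in predict_fov_seams(b, path)]
        assert np.allclose(sa, sb, atol=0.5)

    def test_invalid_layout(self):
        with pytest.raises(SpecError):
            FOVLayout(fov_width=5.0, overlap=5.0)


class TestPolygonalSupports:
    def test_n_equidistant_assemblies(self):
        path = CenterlinePath([[0, 0, 120], [2000, 0, 120]], degree=1)
        spec = PolygonalSupportSpec(spacing=100.0)
        positions = support_positions(path, spec)
        assert len(positions) == 21  # 2000/100 + 1, evenly spaced
        sup = polygonal_supports(path, spec, positions, lumen_outer_diameter=60)
        assert sup.metadata["n_assemblies"] == 21

    def test_empty_positions_empty_mesh(self):
        path = CenterlinePath([[0, 0, 120], [500, 0, 120]], degree=1)
        sup = polygonal_supports(path, PolygonalSupportSpec(), [], 60.0)
        assert sup.n_faces == 0

    def test_collar_inner_diameter(self):
        path = CenterlinePath([[0, 0, 150], [600, 0, 150]], degree=1)
        spec = PolygonalSupportSpec(beam_diameter=20, collar_clearance=1.5)
        sup = polygonal_supports(path, spec, [300.0], lumen_outer_diameter=60)
        comp = sup.metadata["components"][0]
        vs = sup.vertices[np.unique(sup.faces[comp["face_start"]:comp["face_end"]])]
        r = np.linalg.norm(vs[:, 1:] - [0.0, 150.0], axis=1)
        assert r.min() == pytest.approx(30 + 1.5, abs=1e-6)

    def test_position_out_of_range_rejected(self):
        path = CenterlinePath([[0, 0, 120], [500, 0, 120]], degree=1)
        with pytest.raises(SpecError):
            polygonal_supports(path, PolygonalSupportSpec(), [600.0], 60.0)

    def test_capillary_too_low_rejected(self):
        path = CenterlinePath([[0, 0, 10], [500, 0, 10]], degree=1)
        with pytest.raises(SpecError, match="too close"):
            polygonal_supports(path, PolygonalSupportSpec(), [250.0], 60.0)

    def test_seam_placed_supports_cover_crossings(self):
        layout = FOVLayout(fov_width=300, overlap=0, stitch_angle=0)
        path = CenterlinePath([[0, 0, 120], [1000, 0, 120]], degree=1)
        spec = PolygonalSupportSpec(placement="at_fov_seams")
        positions = support_positions(path, spec, layout)
        crossings = [s for s, _ in predict_fov_seams(layout, path)]
        for s in crossings:
            assert min(abs(s - p) for p in positions) < 1.0


class TestLattice:
    def test_single_cell_has_36_edges(self):
        spec = LatticeSpec(cell_size=200, beam_diameter=10,
                           bounding_box=((-100, -100, -100), (100, 100, 100)))
        assert len(lattice_edges(spec)) == 36

    def test_shared_edges_deduplicated(self):
        spec = LatticeSpec(cell_size=200, beam_diameter=10,
                           bounding_box=((-100, -100, -100), (300, 100, 100)))
        edges = lattice_edges(spec)
        assert len(edges) < 72
        keys = {tuple(np.round(np.sort(e.endpoints, axis=0).ravel(), 6))
                for e in edges}
        assert len(keys) == len(edges)

    def test_box_smaller_than_cell_rejected(self):
        spec = LatticeSpec(cell_size=200, beam_diameter=10,
                           bounding_box=((0, 0, 0), (50, 50, 50)))
        with pytest.raises(MeshError):
            lattice_edges(spec)

    def test_edge_set_independent_of_box_representation(self):
        a = LatticeSpec(cell_size=100, beam_diameter=10,
                        bounding_box=((-150.0, -150, -150), (150, 150, 150)))
        b = LatticeSpec(cell_size=100, beam_diameter=10,
                        bounding_box=((-150, -150, -150.0), (150.0, 150, 150)))
        key = lambda es: sorted(tuple(np.round(np.sort(e.endpoints, axis=0)
                                               .ravel(), 6)) for e in es)
        assert key(lattice_edges(a)) == key(lattice_edges(b))

    def test_all_edges_same_length(self):
        spec = LatticeSpec(cell_size=200, beam_diameter=10,
                           bounding_box=((-100, -100, -100), (100, 100, 100)))
        lengths = [e.length for e in lattice_edges(spec)]
        assert np.allclose(lengths, math.sqrt(2) * 50.0)

    def test_invalid_specs(self):
        with pytest.raises(SpecError):
            LatticeSpec(cell_size=5, beam_diameter=10)
        with pytest.raises(SpecError):
            LatticeSpec(cell_size=100, beam_diameter=10,
                        bounding_box=((0, 0, 0), (0, 1, 1)))


class TestCulling:
    def test_strut_through_lumen_removed(self, small_solid):
        through = Strut(np.array([[0.0, 0.0, -40.0], [0.0, 0.0, 160.0]]))
        assert cull_struts([through], small_solid, 2.0, 5.0) == []

    def test_far_strut_kept(self, small_solid):
        far = Strut(np.array([[0.0, 500.0, 0.0], [0.0, 500.0, 100.0]]))
        assert len(cull_struts([far], small_solid, 2.0, 5.0)) == 1

    def test_buried_strut_removed_even_if_clear_of_surface(self, small_solid):
        # short strut floating inside the lumen, away from the wall
        inside = Strut(np.array([[-5.0, 0.0, 60.0], [5.0, 0.0, 60.0]]))
        assert cull_struts([inside], small_solid, 2.0, 4.0) == []

    def test_grazing_strut_threshold(self, small_solid, small_spec):
        r_out = small_spec.lumen_radius + small_spec.membrane_thickness
        clearance, radius = 2.0, 5.0
        eps = 0.05
        for sign, expect in ((+1, 1), (-1, 0)):
            y = r_out + radius + clearance + sign * eps
            strut = Strut(np.array([[-50.0, y, 60.0], [50.0, y, 60.0]]))
            kept = cull_struts([strut], small_solid, clearance, radius)
            assert len(kept) == expect, f"sign={sign}"
            # brute-force signed-distance oracle over dense samples
            t = np.linspace(0, 1, 200)
            pts = strut.endpoints[0] + t[:, None] * (
                strut.endpoints[1] - strut.endpoints[0])
            d = SurfaceDistance(small_solid).query(pts).min()
            assert (d >= radius + clearance) == bool(expect)

    def test_survivors_clear_by_signed_distance(self, small_solid):
        spec = LatticeSpec(cell_size=120, beam_diameter=10,
                           bounding_box=((-150, -120, -30), (150, 120, 150)))
        edges = lattice_edges(spec)
        kept = cull_struts(edges, small_solid, clearance=2.0, strut_radius=5.0)
        assert 0 < len(kept) < len(edges)
        sd = SurfaceDistance(small_solid)
        for strut in kept:
            t = np.linspace(0, 1, 60)
            pts = strut.endpoints[0] + t[:, None] * (
                strut.endpoints[1] - strut.endpoints[0])
            assert sd.query(pts).min() >= 7.0 - 1e-6


class TestPiping:
    def test_capsule_volume_closed_form(self):
        L, d = 60.0, 12.0
        mesh = pipe_struts([Strut(np.array([[0, 0, 0], [0, 0, L]]))], d)
        exact = math.pi * (d / 2) ** 2 * L + 4 / 3 * math.pi * (d / 2) ** 3
        assert abs(mesh.volume() - exact) / exact < 0.02

    def test_empty_edge_list(self):
        assert pipe_struts([], 10.0).n_faces == 0

    def test_zero_length_strut_unconstructible(self):
        with pytest.raises(SpecError):
            Strut(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))

    def test_invalid_diameter(self):
        with pytest.raises(SpecError):
            pipe_struts([], 0.0)


class TestConnectivity:
    def test_full_lattice_single_grounded_component(self):
        spec = LatticeSpec(cell_size=100, beam_diameter=10,
                           bounding_box=((-100, -100, -50), (100, 100, 150)))
        report = connectivity_check(lattice_edges(spec), base_z=-50.0)
        assert report["n_components"] == 1
        assert report["all_grounded"]

    def test_floating_strut_flagged(self):
        floating = Strut(np.array([[0, 0, 100.0], [30, 0, 100.0]]))
        grounded = Strut(np.array([[200, 0, 0.0], [200, 0, 50.0]]))
        report = connectivity_check([floating, grounded], base_z=0.0)
        assert report["floating_struts"] == [0]
        assert not report["all_grounded"]

    def test_component_count_matches_union_find_oracle(self, small_solid):
        spec = LatticeSpec(cell_size=120, beam_diameter=10,
                           bounding_box=((-150, -120, -30), (150, 120, 150)))
        kept = cull_struts(lattice_edges(spec), small_solid, 2.0, 5.0)
        report = connectivity_check(kept, base_z=-30.0)
        # oracle: plain union-find over quantized endpoints
        parent = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for s in kept:
            a = tuple(np.round(s.endpoints[0], 1))
            b = tuple(np.round(s.endpoints[1], 1))
            parent[find(a)] = find(b)
        n_oracle = len({find(k) for k in list(parent)})
        assert report["n_components"] == n_oracle


class TestCones:
    def test_minimum_facet_taper(self, small_solid):
        spec = ConeSupportSpec(taper_angle=15.0, tip_radius=6.0,
                               positions=((0.0, 0.0), (60.0, 0.0)))
        cones = cone_supports(spec, small_solid, base_z=0.0)
        assert cones.metadata["n_cones"] == 2
        assert min_facet_taper_deg(cones) >= 15.0

    def test_no_cone_material_in_lumen(self, small_solid, small_spec):
        spec = ConeSupportSpec(positions=((0.0, 0.0),))
        cones = cone_supports(spec, small_solid, base_z=0.0)
        d = np.linalg.norm(cones.vertices[:, 1:] - [0.0, 60.0], axis=1)
        assert d.min() >= small_spec.lumen_radius
        assert not points_inside(cones.vertices[::5], small_solid).any()

    def test_missed_anchor_reported(self, small_solid):
        spec = ConeSupportSpec(positions=((0.0, 400.0),))
        cones = cone_supports(spec, small_solid, base_z=0.0)
        assert cones.metadata["missed_anchors"] == [(0.0, 400.0)]
        assert cones.metadata["n_cones"] == 0

    def test_taper_below_15_rejected(self):
        with pytest.raises(SpecError):
            ConeSupportSpec(taper_angle=10.0)

    def test_cone_touches_capillary_underside(self, small_solid, small_spec):
        spec = ConeSupportSpec(positions=((20.0, 0.0),))
        cones = cone_supports(spec, small_solid, base_z=0.0)
        z_top = cones.vertices[:, 2].max()
        underside = 60.0 - (small_spec.lumen_radius
                            + small_spec.membrane_thickness)
        assert z_top == pytest.approx(underside, abs=0.2)
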