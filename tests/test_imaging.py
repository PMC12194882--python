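"""Registration maps, bead velocimetry, live/dead counting and fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capforge.errors import ImagingError
from capforge.imaging import (MaskPair, apply_corrections, binarize,
                              count_live_dead, estimate_velocity,
                              registration_map, render_design_mask,
                              synth_bead_movie, synth_fixtures,
                              synth_live_dead, synth_mask_pair, track_beads)


class TestBinarize:
    def test_two_level_image_exact_recovery(self):
        img = np.zeros((50, 50))
        img[10:20, 10:40] = 200.0
        mask = binarize(img, "otsu")
        assert np.array_equal(mask, img > 0)

    def test_otsu_matches_histogram_oracle_after_stretch(self):
        rng = np.random.default_rng(4)
        img = np.concatenate([rng.normal(40, 5, 2000),
                              rng.normal(180, 10, 1000)]).reshape(50, 60)
        stretched = np.clip((img - img.mean()) * 1.3 + img.mean(),
                            img.min(), img.max())
        # brute-force Otsu: maximize between-class variance over 256 bins
        hist, edges = np.histogram(stretched, bins=256)
        centres = 0.5 * (edges[:-1] + edges[1:])
        p = hist / hist.sum()
        best, thr = -1.0, centres[0]
        for i in range(1, 256):
            w0, w1 = p[:i].sum(), p[i:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (p[:i] * centres[:i]).sum() / w0
            m1 = (p[i:] * centres[i:]).sum() / w1
            v = w0 * w1 * (m0 - m1) ** 2
            if v > best:
                best, thr = v, centres[i - 1]
        mask = binarize(img, "otsu", contrast_stretch=30.0)
        oracle = stretched > thr
        assert (mask == oracle).mean() > 0.995

    def test_fixed_threshold_zero_all_foreground(self):
        img = np.ones((10, 10)) * 5.0
        assert binarize(img, "fixed", threshold=0.0).all()

    def test_constant_image_otsu_rejected(self):
        with pytest.raises(ImagingError):
            binarize(np.ones((10, 10)), "otsu")

    def test_multichannel_rejected(self):
        with pytest.raises(ImagingError):
            binarize(np.zeros((5, 5, 3)))


class TestRenderDesignMask:
    def test_cube_renders_filled_square(self):
        import trimesh
        from capforge.mesh import SurfaceMesh
        cube = SurfaceMesh.from_trimesh(trimesh.creation.box((50, 50, 50)))
        mask, info = render_design_mask(cube, pixel_size=1.0)
        rows = mask.any(axis=1).sum()
        cols = mask.any(axis=0).sum()
        assert abs(rows - 50) <= 1 and abs(cols - 50) <= 1
        assert info["pixel_size"] == 1.0

    def test_supports_excluded_by_provenance(self, small_solid):
        from capforge.mesh import SurfaceMesh
        support = SurfaceMesh(small_solid.vertices + [0, 200, 0],
                              small_solid.faces, provenance="support")
        merged = SurfaceMesh.concatenate([small_solid, support])
        mask_all, _ = render_design_mask(
            merged, 2.0, include_provenance=("membrane", "support"))
        mask_mem, _ = render_design_mask(merged, 2.0)
        assert mask_mem.sum() < mask_all.sum()

    def test_cylinder_silhouette_area(self):
        # finely tessellated straight tube seen top-down: rectangle
        # (outer diameter × length)
        import warnings

        from capforge.membrane import (CapillarySpec, cut_pores,
                                       subdivision_grid, sweep_shell, thicken)
        from capforge.pathgen import CenterlinePath
        path = CenterlinePath([[-100.0, 0.0, 60.0], [100.0, 0.0, 60.0]],
                              degree=1)
        spec = CapillarySpec(40, 2.5, 2.5, 10)
        g = subdivision_grid(path.path_length, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            solid = thicken(sweep_shell(path, g, spec))  # unpored tube
        mask, info = render_design_mask(solid, pixel_size=0.5)
        area = mask.sum() * info["pixel_size"] ** 2
        expected = 60.0 * 200.0
        assert abs(area - expected) / expected < 0.02

    def test_invalid_pixel_size(self, small_solid):
        with pytest.raises(ImagingError):
            render_design_mask(small_solid, 0.0)


class TestRegistration:
    def test_identical_masks_full_overlap(self):
        pair = synth_mask_pair(seed=0)
        _, res = registration_map(pair)
        assert res.overlap_percent == pytest.approx(100.0)
        assert res.green_fraction == 0.0 and res.red_fraction == 0.0

    def test_blank_experiment_all_missing(self):
        pair = synth_mask_pair(seed=0)
        blank = MaskPair(pair.target, np.zeros_like(pair.target))
        _, res = registration_map(blank)
        assert res.green_fraction == pytest.approx(pair.target.mean())
        assert res.yellow_fraction == 0.0

    def test_offset_squares_pixel_count_oracle(self):
        t = np.zeros((200, 200), dtype=bool)
        t[50:150, 40:140] = True
        e = np.roll(t, 20, axis=1)
        rgb, res = registration_map(MaskPair(t, e))
        n = 200 * 200
        assert res.yellow_fraction == pytest.approx(100 * 80 / n)
        assert res.green_fraction == pytest.approx(100 * 20 / n)
        assert res.red_fraction == pytest.approx(100 * 20 / n)
        # composite channels: red channel = experiment, green = target
        assert (rgb[..., 0] > 0).sum() == e.sum()
        assert (rgb[..., 1] > 0).sum() == t.sum()

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.random((40, 40)) > 0.5
        e = rng.random((40, 40)) > 0.5
        _, res = registration_map(MaskPair(t, e))
        total = (res.yellow_fraction + res.green_fraction + res.red_fraction
                 + res.black_fraction)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_overlap_invariant_under_common_shift(self):
        pair = synth_mask_pair(seed=3, erosion_px=1)
        _, a = registration_map(pair)
        t2 = np.roll(pair.target, (7, 11), axis=(0, 1))
        e2 = np.roll(pair.experiment, (7, 11), axis=(0, 1))
        _, b = registration_map(MaskPair(t2, e2))
        assert a.overlap_percent == pytest.approx(b.overlap_percent, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ImagingError):
            MaskPair(np.zeros((10, 10), bool), np.zeros((10, 12), bool))

    def test_nonbinary_mask_rejected(self):
        with pytest.raises(ImagingError):
            MaskPair(np.full((5, 5), 0.5), np.zeros((5, 5)))


class TestTracking:
    def test_single_bead_constant_displacement(self):
        frames, truth = synth_bead_movie(1.0, seed=0, n_beads=1, noise_sd=0.0)
        tracks = track_beads(frames, mode="auto")
        assert len(tracks) == 1
        assert tracks[0].mean_step_px() == pytest.approx(truth["step_px"],
                                                         rel=0.02)

    def test_crossing_beads_keep_identity(self):
        # two beads on crossing columns (laterally separated so their blobs
        # never merge); predictive linking must not swap them
        h, w, n = 64, 64, 9
        yy, xx = np.mgrid[0:h, 0:w]
        frames = []
        pos_a = [(10 + 5 * i, 28) for i in range(n)]
        pos_b = [(54 - 5 * i, 36) for i in range(n)]
        for (ay, ax), (by, bx) in zip(pos_a, pos_b):
            img = (np.exp(-((yy - ay) ** 2 + (xx - ax) ** 2) / 2.5)
                   + np.exp(-((yy - by) ** 2 + (xx - bx) ** 2) / 2.5))
            frames.append(img)
        tracks = track_beads(frames, mode="auto", max_displacement=7.0)
        long_tracks = [t for t in tracks if len(t.frames) == n]
        assert len(long_tracks) == 2
        for t in long_tracks:
            dy = np.diff(t.positions[:, 0])
            assert np.all(dy > 0) or np.all(dy < 0)  # no direction reversal

    def test_empty_frames_give_no_tracks(self):
        frames = [np.zeros((32, 32)) for _ in range(4)]
        assert track_beads(frames, mode="auto") == []

    def test_manual_mode_links_by_index(self):
        pts = [[(10, 5), (30, 40)], [(10, 15), (30, 50)], [(10, 25), (30, 60)]]
        tracks = track_beads(None, mode="manual", points=pts)
        assert len(tracks) == 2
        assert tracks[0].mean_step_px() == pytest.approx(10.0)


class TestVelocity:
    def test_exact_unit_conversion(self):
        pts = [[(10, 0)], [(10, 10)], [(10, 20)]]
        tracks = track_beads(None, mode="manual", points=pts)
        est = estimate_velocity(tracks, pixel_size=1.0, frame_interval=0.01)
        assert est.mean_velocity == pytest.approx(1.0)  # mm/s

    def test_mean_and_sample_sd(self):
        pts = [[(0, 0), (20, 0)], [(0, 10), (20, 20)], [(0, 20), (20, 40)]]
        tracks = track_beads(None, mode="manual", points=pts)
        est = estimate_velocity(tracks, 1.0, 0.01)
        assert est.mean_velocity == pytest.approx(1.5)
        assert est.sd_velocity == pytest.approx(np.std([1.0, 2.0], ddof=1))
        assert est.n_tracks == 2

    def test_scaling_linearity(self):
        pts = [[(0, 0)], [(0, 8)], [(0, 16)]]
        tracks = track_beads(None, mode="manual", points=pts)
        base = estimate_velocity(tracks, 1.0, 0.01).mean_velocity
        assert estimate_velocity(tracks, 2.0, 0.01).mean_velocity == \
            pytest.approx(2 * base)
        assert estimate_velocity(tracks, 1.0, 0.02).mean_velocity == \
            pytest.approx(base / 2)

    def test_zero_frame_interval_rejected(self):
        pts = [[(0, 0)], [(0, 8)]]
        tracks = track_beads(None, mode="manual", points=pts)
        with pytest.raises(ImagingError):
            estimate_velocity(tracks, 1.0, 0.0)

    def test_empty_tracks_rejected(self):
        with pytest.raises(ImagingError):
            estimate_velocity([], 1.0, 0.01)


class TestLiveDead:
    def test_known_disk_counts(self):
        green, red, truth = synth_live_dead(50, 10, seed=7)
        res = count_live_dead(green, red)
        assert (res.live_count, res.dead_count) == (50, 10)
        assert res.viability_percent == pytest.approx(100 * 50 / 60)

    @pytest.mark.parametrize("seed", [0, 11, 99])
    def test_exact_recovery_for_any_seed(self, seed):
        green, red, truth = synth_live_dead(30, 8, seed=seed)
        res = count_live_dead(green, red)
        assert res.live_count == truth["n_live"]
        assert res.dead_count == truth["n_dead"]

    def test_double_stained_counts_as_dead_only(self):
        green = np.zeros((100, 100))
        red = np.zeros((100, 100))
        from skimage.draw import disk
        rr, cc = disk((50, 50), 12)
        green[rr, cc] = 1.0
        rr, cc = disk((50, 50), 5)     # nucleus stain inside the green body
        red[rr, cc] = 1.0
        res = count_live_dead(green, red, min_area_px=10)
        assert (res.live_count, res.dead_count) == (0, 1)

    def test_empty_images_rejected(self):
        with pytest.raises(ImagingError):
            count_live_dead(np.zeros((50, 50)), np.zeros((50, 50)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ImagingError):
            count_live_dead(np.zeros((10, 10)), np.zeros((12, 10)))

    def test_min_area_filters_specks(self):
        green, red, _ = synth_live_dead(10, 0, seed=1, cell_radius_px=8)
        green[2, 2] = 1.0  # single-pixel noise
        res = count_live_dead(green, red + 0, min_area_px=20) if red.any() \
            else count_live_dead(green, red, min_area_px=20)
        assert res.live_count == 10


class TestCorrections:
    @pytest.fixture()
    def base_result(self):
        green, red, _ = synth_live_dead(20, 5, seed=2)
        return count_live_dead(green, red)

    def test_no_edits_identity(self, base_result):
        out = apply_corrections(base_result, [])
        assert (out.live_count, out.dead_count) == (20, 5)

    def test_add_two_live(self, base_result):
        out = apply_corrections(base_result, [((1.0, 1.0), "add_live"),
                                              ((3.0, 3.0), "add_live")])
        assert out.live_count == 22
        assert len(out.audit_log) == 2

    def test_add_then_remove_is_identity(self, base_result):
        out = apply_corrections(base_result, [((5.0, 5.0), "add_dead"),
                                              ((5.0, 5.0), "remove")])
        assert (out.live_count, out.dead_count) == (20, 5)

    def test_remove_without_detection_rejected(self, base_result):
        far = (9999.0, 9999.0)
        with pytest.raises(ImagingError):
            apply_corrections(base_result, [(far, "remove")])


class TestFixtures:
    def test_seeded_outputs_are_byte_identical(self, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        synth_fixtures("bead_movie", {"n_frames": 5}, seed=9, out_dir=a)
        synth_fixtures("bead_movie", {"n_frames": 5}, seed=9, out_dir=b)
        assert (a / "beads.tiff").read_bytes() == (b / "beads.tiff").read_bytes()

    def test_reference_speed_recovered_within_2_percent(self):
        frames, truth = synth_bead_movie(1.83, seed=5)
        tracks = track_beads(frames, mode="auto")
        est = estimate_velocity(tracks, truth["pixel_size_um"],
                                truth["frame_interval_s"])
        assert abs(est.mean_velocity - 1.83) / 1.83 < 0.02

    def test_erosion_produces_expected_missing_fraction(self):
        pair = synth_mask_pair(seed=6, erosion_px=2)
        from scipy import ndimage
        expected = (pair.target & ~ndimage.binary_erosion(
            pair.target, iterations=2)).mean()
        _, res = registration_map(pair)
        assert res.green_fraction == pytest.approx(expected, abs=0.01)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ImagingError):
            synth_fixtures("nope", {}, 0)
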