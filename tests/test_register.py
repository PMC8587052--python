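"""Rotation, cropping and mask-aware merging of quadrant images."""

import numpy as np
import pytest

from quadfluor.calib import CalibrationResult, calibrate_quadrant, detect_circles
from quadfluor.register import (
    crop_centered,
    merge_quadrants,
    register_set,
    rotate_image,
)
from quadfluor.synth import (
    IntensityTable,
    render_mark_sheet,
    render_quadrant_set,
    render_tube_quadrant,
    table3_preset,
)


def aligned_calibration(scene, qid=1):
    """A CalibrationResult built directly from generator ground truth."""
    truth = scene.ground_truth_centers()
    return CalibrationResult(
        quadrant_id=qid,
        rotation_center=tuple(truth[2, 2]),
        rotation_angle=scene.rotation_angle,
        ordered_centers=truth,
        mean_residual=0.0,
        max_residual=0.0,
        grid_spacing=scene.grid_spacing,
    )


class TestRotateImage:
    def test_zero_angle_is_identity(self, make_scene):
        img, _ = render_mark_sheet(make_scene(angle=25.0, noise_sd=2.0, seed=3))
        out = rotate_image(img, (199.5, 199.5), 0.0)
        assert np.allclose(out, img)

    def test_quarter_turn_matches_lossless_rotation(self, make_scene):
        img, _ = render_mark_sheet(make_scene(angle=25.0))
        out = rotate_image(img, (199.5, 199.5), 90.0)
        assert np.max(np.abs(out - np.rot90(img))) <= 1.0

    def test_round_trip_small_interior_error(self, make_scene):
        img, _ = render_mark_sheet(make_scene(angle=25.0))
        back = rotate_image(rotate_image(img, (199.5, 199.5), 25.0),
                            (199.5, 199.5), -25.0)
        n = img.shape[0]
        sl = slice(n // 4, 3 * n // 4)
        interior_err = np.abs(back - img)[sl, sl].mean()
        assert interior_err < 0.02 * 255

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError, match="center"):
            rotate_image(np.zeros((10, 10)), (50, 5), 10.0)


class TestCropCentered:
    def test_full_image_identity(self):
        img = np.random.default_rng(0).uniform(size=(21, 31))
        out = crop_centered(img, (15.0, 10.0), (31, 21))
        assert np.array_equal(out, img)

    def test_integer_center_odd_size_bit_exact(self):
        img = np.arange(100.0).reshape(10, 10)
        out = crop_centered(img, (4, 6), 5)
        assert np.array_equal(out, img[4:9, 2:7])

    def test_subpixel_center_lands_on_crop_center(self, make_scene):
        cfg = make_scene(angle=25.0)
        img, truth = render_mark_sheet(cfg)
        rot = rotate_image(img, truth[2, 2], cfg.rotation_angle)
        crop = crop_centered(rot, truth[2, 2], 300)
        pts = detect_circles(crop)
        center = np.array([(300 - 1) / 2.0] * 2)
        nearest = pts[np.argmin(np.linalg.norm(pts - center, axis=1))]
        assert np.linalg.norm(nearest - center) < 0.5

    def test_overflow_reports_amounts(self):
        with pytest.raises(ValueError, match="exceeds the image frame"):
            crop_centered(np.zeros((50, 50)), (5.0, 25.0), 30)


class TestMergeQuadrants:
    def test_identical_images_unchanged(self):
        img = np.random.default_rng(1).uniform(0, 255, size=(40, 40))
        merged = merge_quadrants([img] * 4)
        assert np.allclose(merged.pixels, img)
        assert merged.crop_size == (40, 40)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same shape"):
            merge_quadrants([np.zeros((4, 4)), np.zeros((5, 5))])

    def test_masked_mean_ignores_invalid_pixels(self):
        a, b = np.full((4, 4), 10.0), np.full((4, 4), 30.0)
        mb = np.zeros((4, 4), dtype=bool)
        merged = merge_quadrants([a, b], masks=[np.ones((4, 4), bool), mb])
        assert np.allclose(merged.pixels, 10.0)

    def test_mean_bounded_by_contributors(self):
        rng = np.random.default_rng(2)
        imgs = [rng.uniform(0, 255, (30, 30)) for _ in range(4)]
        masks = [rng.uniform(size=(30, 30)) > 0.3 for _ in range(4)]
        merged = merge_quadrants(imgs, masks=masks)
        stack = np.stack(imgs)
        mstack = np.stack(masks)
        covered = mstack.any(axis=0)
        lo = np.where(mstack, stack, np.inf).min(axis=0)
        hi = np.where(mstack, stack, -np.inf).max(axis=0)
        assert np.all(merged.pixels[covered] >= lo[covered] - 1e-9)
        assert np.all(merged.pixels[covered] <= hi[covered] + 1e-9)

    def test_sum_and_max_modes(self):
        a, b = np.full((3, 3), 10.0), np.full((3, 3), 30.0)
        assert np.allclose(merge_quadrants([a, b], mode="sum").pixels, 40.0)
        assert np.allclose(merge_quadrants([a, b], mode="max").pixels, 30.0)
        with pytest.raises(ValueError, match="merge mode"):
            merge_quadrants([a, b], mode="median")

    def test_four_way_mean_halves_noise(self, make_scene):
        """Background sd of a 4-image mean is ~ s/2."""
        s = 5.0
        imgs = []
        for seed in range(4):
            cfg = make_scene(angle=0.0, noise_sd=s, seed=seed,
                             background_level=50.0, bit_depth=16)
            img, _ = render_tube_quadrant(cfg, IntensityTable(np.zeros((5, 5))))
            imgs.append(img)
        merged = merge_quadrants(imgs)
        bg_sd = merged.pixels[:40, :40].std()  # tube-free corner
        assert np.isclose(bg_sd, s / 2.0, rtol=0.2)


class TestRegisterSet:
    def test_zero_angles_identical_windows_equals_mean_of_crops(self, make_scene):
        cfg = make_scene(angle=0.0, noise_sd=3.0, background_level=40.0)
        cals = [aligned_calibration(cfg, qid) for qid in (1, 2, 3, 4)]
        rng = np.random.default_rng(5)
        imgs = [rng.uniform(0, 255, (400, 400)) for _ in range(4)]
        merged = register_set(imgs, cals, crop_size=301, windows=None)
        crops = [crop_centered(im, cfg.rotation_center, 301) for im in imgs]
        assert np.allclose(merged.pixels, np.mean(crops, axis=0))
        assert sorted(merged.provenance) == [1, 2, 3, 4]

    def test_duplicate_quadrant_ids_rejected(self, make_scene):
        cfg = make_scene(angle=0.0)
        cals = [aligned_calibration(cfg, 1)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            register_set([np.zeros((400, 400))] * 2, cals, crop_size=100)

    def test_registered_centers_on_ideal_lattice(self, make_scene):
        """All 25 tube centers land within 1.5 px of the uniform lattice
        around the merged-frame center."""
        fam, ddw = table3_preset()
        qs = render_quadrant_set(fam, ddw, base_config=make_scene(noise_sd=1.0),
                                 seed=2)
        cals = [calibrate_quadrant(qs.mark_images[q], q) for q in (1, 2, 3, 4)]
        merged = register_set(qs.fam_images, cals, crop_size=301)
        pts = detect_circles(merged.pixels)
        g = np.mean([c.grid_spacing for c in cals])
        c0 = (301 - 1) / 2.0
        jj, ii = np.meshgrid(np.arange(5), np.arange(5))
        ideal = np.stack([c0 + (jj - 2) * g, c0 + (ii - 2) * g], axis=-1)
        d = np.linalg.norm(ideal.reshape(-1, 1, 2) - pts[None], axis=-1).min(axis=1)
        assert d.max() < 1.5

    def test_fam_and_ddw_composites_align(self, make_scene):
        """Tube centers agree across conditions (the two merged images
        'show an ideal match')."""
        fam, ddw = table3_preset()
        qs = render_quadrant_set(fam, ddw, base_config=make_scene(), seed=2)
        cals = [calibrate_quadrant(qs.mark_images[q], q) for q in (1, 2, 3, 4)]
        mf = register_set(qs.fam_images, cals, crop_size=301)
        md = register_set(qs.ddw_images, cals, crop_size=301)
        pf = detect_circles(mf.pixels)
        pd_ = detect_circles(md.pixels)
        d = np.linalg.norm(pf[:, None, :] - pd_[None], axis=-1).min(axis=1)
        assert d.max() < 1.5

    def test_registration_idempotent_on_aligned_set(self, make_scene):
        cfg = make_scene(angle=0.0, background_level=30.0)
        img, _ = render_mark_sheet(cfg)
        cals = [aligned_calibration(cfg, q) for q in (1, 2, 3, 4)]
        first = register_set([img] * 4, cals, crop_size=301, windows=None)
        center = first.plate_center
        recals = []
        for q in (1, 2, 3, 4):
            truth = cfg.ground_truth_centers() - np.asarray(cfg.rotation_center) \
                + np.asarray(center)
            recals.append(CalibrationResult(q, tuple(truth[2, 2]), 0.0, truth,
                                            0.0, 0.0, cfg.grid_spacing))
        second = register_set([first.pixels] * 4, recals, crop_size=301,
                              windows=None)
        assert np.abs(second.pixels - first.pixels).mean() < 0.5

    def test_rotation_does_not_bias_photometry(self, make_scene):
        """Per-tube brightness from a 25-degree scene matches the same scene
        rendered unrotated to < 1%."""
        from quadfluor.quantify import TubeGrid, extract_brightness
        fam, _ = table3_preset()
        tables = {}
        for angle in (0.0, 25.0):
            cfg = make_scene(angle=angle, visible_rows=(1, 2, 3),
                             visible_cols=(1, 2, 3))
            img, _ = render_tube_quadrant(cfg, fam)
            cal = aligned_calibration(cfg)
            rot = rotate_image(img, cal.rotation_center, cal.rotation_angle)
            crop = crop_centered(rot, cal.rotation_center, 301)
            c0 = (301 - 1) / 2.0
            jj, ii = np.meshgrid(np.arange(5), np.arange(5))
            centers = np.stack([c0 + (jj - 2) * cfg.grid_spacing, c0 + (ii - 2) * cfg.grid_spacing], axis=-1)
            grid = TubeGrid(centers, roi_size=56, avg_size=24)
            tables[angle] = extract_brightness(crop, grid).values[1:4, 1:4]
        rel = np.abs(tables[25.0] - tables[0.0]) / tables[0.0]
        assert rel.max() < 0.01
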