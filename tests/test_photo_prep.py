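"""Photograph calibration, rectification, segmentation and slice grouping."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from skimage.transform import rotate

from photorecon import (CalibratedPhoto, FiducialSet, KnownDistanceGeometry,
                        MarkerTemplate, RawPhoto, RectangleGeometry,
                        RulerArmsGeometry, SliceOrdering, TissueMask,
                        detect_fiducials, errors, fit_calibration,
                        group_components, rectify, segment_tissue,
                        to_grayscale)
from photorecon.photo_prep import PlanarCalibration


def _make_marker(seed, size=56):
    r = np.random.default_rng(seed)
    m = gaussian_filter(r.uniform(0, 1, (size, size)), 1.5)
    m = (m - m.min()) / (m.max() - m.min())
    return (m * 255).astype(np.uint8)


@pytest.fixture(scope="module")
def marker_scene():
    markers = [MarkerTemplate(image=_make_marker(s), name=f"m{s}")
               for s in range(4)]
    scene = np.full((600, 800), 30, dtype=np.uint8)
    centers = [(100, 120), (110, 640), (480, 660), (470, 140)]
    truth = []
    for mk, (r, c) in zip(markers, centers):
        h, w = mk.image.shape
        scene[r - h // 2:r - h // 2 + h, c - w // 2:c - w // 2 + w] = mk.image
        truth.append((r - h // 2 + (h - 1) / 2, c - w // 2 + (w - 1) / 2))
    return scene, markers, np.asarray(truth)


class TestDetectFiducials:
    def test_known_centers_within_two_pixels(self, marker_scene):
        scene, markers, truth = marker_scene
        fid = detect_fiducials(RawPhoto(pixels=scene), markers,
                               RectangleGeometry(100, 80))
        err = np.linalg.norm(fid.points - truth, axis=1)
        assert np.all(err < 2.0)
        assert fid.confidences is not None and len(fid.confidences) == 4

    def test_rotated_scene_recovers_rotated_centers(self, marker_scene):
        scene, markers, truth = marker_scene
        ang = 10.0
        rot_img = rotate(scene.astype(float) / 255.0, ang, preserve_range=True)
        fid = detect_fiducials(
            RawPhoto(pixels=(rot_img * 255).astype(np.uint8)), markers,
            RectangleGeometry(100, 80))
        # rotate() turns the image CCW about the center; map truth the same way
        cy, cx = (scene.shape[0] - 1) / 2, (scene.shape[1] - 1) / 2
        th = np.deg2rad(ang)
        dy, dx = truth[:, 0] - cy, truth[:, 1] - cx
        rot_truth = np.c_[cy + np.cos(th) * dy - np.sin(th) * dx,
                          cx + np.sin(th) * dy + np.cos(th) * dx]
        err = np.linalg.norm(fid.points - rot_truth, axis=1)
        assert np.all(err < 2.0)

    def test_blank_image_raises(self, marker_scene):
        _, markers, _ = marker_scene
        blank = np.zeros((400, 400), dtype=np.uint8)
        with pytest.raises(errors.MarkerNotFound):
            detect_fiducials(RawPhoto(pixels=blank), markers,
                             RectangleGeometry(100, 80))

    def test_duplicate_marker_is_ambiguous(self, marker_scene):
        scene, markers, _ = marker_scene
        twice = [markers[0], markers[0]]
        with pytest.raises(errors.AmbiguousMatch):
            detect_fiducials(RawPhoto(pixels=scene), twice,
                             KnownDistanceGeometry(10.0))


class TestFitCalibration:
    def test_axis_aligned_square(self):
        pts = np.array([[0.0, 0], [0, 100], [100, 100], [100, 0]])
        fid = FiducialSet(points=pts, template=RectangleGeometry(10, 10))
        cal = fit_calibration(fid)
        assert cal.mode == "full_perspective"
        assert cal.pixel_size == pytest.approx(0.1)
        # pure scaling: maps (r, c) -> (0.1 r, 0.1 c)
        np.testing.assert_allclose(cal.to_mm([[50.0, 30.0]]), [[5.0, 3.0]],
                                   atol=1e-9)

    def test_two_point_scale(self):
        fid = FiducialSet(points=[[10.0, 10], [10, 60]],
                          template=KnownDistanceGeometry(5.0))
        cal = fit_calibration(fid)
        assert cal.mode == "scale_only"
        assert cal.pixel_size == pytest.approx(0.1)

    def test_three_point_affine_maps_arms_to_axes(self):
        corner = np.array([200.0, 100.0])
        arm1 = corner + [0.0, 80.0]   # 80 px along +col = 8 mm
        arm2 = corner + [-60.0, 0.0]  # 60 px along -row = 6 mm
        fid = FiducialSet(points=[arm1, arm2, corner],
                          template=RulerArmsGeometry(8.0, 6.0))
        cal = fit_calibration(fid)
        assert cal.mode == "affine"
        np.testing.assert_allclose(cal.to_mm([corner])[0], [0, 0], atol=1e-9)
        np.testing.assert_allclose(cal.to_mm([arm1])[0], [0, 8], atol=1e-9)
        np.testing.assert_allclose(cal.to_mm([arm2])[0], [6, 0], atol=1e-9)

    def test_projective_roundtrip_exact(self, rng):
        """Corners forward-warped by a known homography are mapped back onto
        the physical rectangle, interior points to < 1e-6 mm."""
        w_mm, h_mm = 120.0, 80.0
        rect_mm = np.array([[0.0, 0], [0, w_mm], [h_mm, w_mm], [h_mm, 0]])
        H = np.array([[9.7, 0.3, 40.0],
                      [-0.2, 10.2, 60.0],
                      [1e-4, -8e-5, 1.0]])  # mm -> px with perspective

        def mm_to_px(p):
            q = np.c_[p, np.ones(len(p))] @ H.T
            return q[:, :2] / q[:, 2:]

        corners_px = mm_to_px(rect_mm)
        fid = FiducialSet(points=corners_px,
                          template=RectangleGeometry(w_mm, h_mm))
        cal = fit_calibration(fid)
        interior = rng.uniform([5, 5], [h_mm - 5, w_mm - 5], (20, 2))
        err = np.linalg.norm(cal.to_mm(mm_to_px(interior)) - interior, axis=1)
        assert err.max() < 1e-6

    def test_collinear_points_raise(self):
        pts = np.array([[0.0, 0], [0, 50], [0, 100], [100, 0]])
        fid = FiducialSet(points=pts, template=RectangleGeometry(10, 10))
        with pytest.raises(errors.DegenerateGeometry):
            fit_calibration(fid)

    def test_calibration_roundtrip_random_homographies(self, rng):
        """Held-out physical points recovered to < 0.05 mm at 0.1 mm/px."""
        w_mm, h_mm = 100.0, 80.0
        rect_mm = np.array([[0.0, 0], [0, w_mm], [h_mm, w_mm], [h_mm, 0]])
        worst = 0.0
        for _ in range(20):
            H = np.eye(3)
            H[:2, :2] = 10 * (np.eye(2) + rng.uniform(-0.05, 0.05, (2, 2)))
            H[:2, 2] = rng.uniform(0, 100, 2)
            H[2, :2] = rng.uniform(-1e-4, 1e-4, 2)

            def mm_to_px(p):
                q = np.c_[p, np.ones(len(p))] @ H.T
                return q[:, :2] / q[:, 2:]

            cal = fit_calibration(FiducialSet(
                points=mm_to_px(rect_mm),
                template=RectangleGeometry(w_mm, h_mm)))
            held_out = rng.uniform([0, 0], [h_mm, w_mm], (30, 2))
            err = np.linalg.norm(cal.to_mm(mm_to_px(held_out)) - held_out,
                                 axis=1)
            worst = max(worst, err.max())
        assert worst < 0.05


class TestRectify:
    def test_identity_calibration_is_exact(self, rng):
        img = (rng.uniform(0, 1, (40, 50)) * 255).astype(np.uint8)
        cal = PlanarCalibration(np.diag([0.1, 0.1, 1.0]), 0.1, "scale_only")
        out = rectify(RawPhoto(pixels=img), cal)
        np.testing.assert_allclose(out.pixels, to_grayscale(img), atol=1e-12)
        assert out.pixel_size == 0.1

    def test_checkerboard_homography_roundtrip(self):
        from photorecon._interp import bilinear

        board = np.kron((np.indices((8, 10)).sum(axis=0) % 2).astype(float),
                        np.ones((24, 24)))
        h, w = board.shape  # board pixel m sits at physical mm m * 0.1
        H_mm_px = np.array([[29.4, 1.2, 30.0], [-0.9, 30.3, 20.0],
                            [2.4e-4, -1.5e-4, 1.0]])  # mm -> raw photo px

        def mm_to_px(p):
            q = np.c_[p, np.ones(len(p))] @ H_mm_px.T
            return q[:, :2] / q[:, 2:]

        # synthesize the distorted photo (3x oversampled): the photo shows
        # the board content through the inverse homography
        Hinv = np.linalg.inv(H_mm_px)
        rows, cols = np.indices((800, 900)).astype(float)
        q = np.stack([rows, cols, np.ones_like(rows)], axis=-1) @ Hinv.T
        mm = q[..., :2] / q[..., 2:]
        photo = bilinear(board, mm[..., 0] / 0.1, mm[..., 1] / 0.1)

        corners_mm = np.array([[0.0, 0], [0, (w - 1) * 0.1],
                               [(h - 1) * 0.1, (w - 1) * 0.1],
                               [(h - 1) * 0.1, 0]])
        cal = fit_calibration(FiducialSet(
            points=mm_to_px(corners_mm),
            template=RectangleGeometry((w - 1) * 0.1, (h - 1) * 0.1)))
        rect = rectify(RawPhoto(pixels=photo), cal, target_pixel_size=0.1,
                       origin_mm=(0.0, 0.0))
        sub = rect.pixels[:h, :w]
        assert sub.shape == board.shape
        assert np.mean(np.abs(sub - board)) < 0.02

    def test_downsampling_constant_image(self):
        img = np.full((40, 60), 0.5)
        cal = PlanarCalibration(np.diag([0.1, 0.1, 1.0]), 0.1, "scale_only")
        out = rectify(RawPhoto(pixels=img), cal, target_pixel_size=0.2)
        assert out.pixels.shape == (20, 30)
        np.testing.assert_allclose(out.pixels, 0.5, atol=1e-9)

    def test_idempotent_on_rectified_photo(self, rng):
        img = rng.uniform(0, 1, (30, 30))
        cal = PlanarCalibration(np.diag([0.1, 0.1, 1.0]), 0.1, "scale_only")
        once = rectify(RawPhoto(pixels=img), cal)
        twice = rectify(RawPhoto(pixels=once.pixels), cal)
        np.testing.assert_allclose(twice.pixels, once.pixels, atol=1e-6)


class TestSegmentTissue:
    def test_bright_square(self):
        img = np.zeros((60, 60))
        img[10:40, 10:40] = 200 / 255
        photo = CalibratedPhoto(pixels=img, pixel_size=1.0)
        mask = segment_tissue(photo, threshold=100 / 255, min_area_mm2=0,
                              morph_radius_mm=0)
        assert mask.component_ids == [1]
        np.testing.assert_array_equal(mask.mask.astype(bool),
                                      img > 100 / 255)

    def test_all_zero_warns_empty(self):
        photo = CalibratedPhoto(pixels=np.zeros((30, 30)), pixel_size=1.0)
        with pytest.warns(errors.EmptyMaskWarning):
            mask = segment_tissue(photo, threshold=0.5, min_area_mm2=0)
        assert mask.component_ids == []

    def test_min_area_removes_smaller_blob(self):
        img = np.zeros((80, 80))
        img[5:25, 5:30] = 0.9    # 500 px
        img[50:75, 40:76] = 0.9  # 900 px
        photo = CalibratedPhoto(pixels=img, pixel_size=1.0)
        mask = segment_tissue(photo, threshold=0.5, min_area_mm2=600,
                              morph_radius_mm=0)
        assert len(mask.component_ids) == 1
        assert mask.mask[60, 60] == 1 and mask.mask[10, 10] == 0

    def test_invariant_to_subthreshold_background_noise(self, rng):
        img = np.zeros((60, 60))
        img[10:40, 10:40] = 0.8
        noisy = img + rng.uniform(0, 0.3, img.shape) * (img == 0)
        photo_a = CalibratedPhoto(pixels=img, pixel_size=1.0)
        photo_b = CalibratedPhoto(pixels=noisy, pixel_size=1.0)
        m_a = segment_tissue(photo_a, threshold=0.5)
        m_b = segment_tissue(photo_b, threshold=0.5)
        np.testing.assert_array_equal(m_a.mask, m_b.mask)


def _mask_with_components(n):
    comp = np.zeros((20, 10 * n), dtype=np.int32)
    for i in range(n):
        comp[5:15, 10 * i + 2:10 * i + 8] = i + 1
    return TissueMask(mask=(comp > 0).astype(np.uint8), components=comp,
                      pixel_size=1.0)


class TestGroupComponents:
    def test_one_component_per_slice(self):
        recs = group_components(_mask_with_components(3), SliceOrdering(
            order="anterior_first", slices=[[1], [2], [3]]))
        assert [r.slice_index for r in recs] == [0, 1, 2]
        assert [sorted(r.component_ids) for r in recs] == [[1], [2], [3]]

    def test_posterior_first_reverses(self):
        recs = group_components(_mask_with_components(3), SliceOrdering(
            order="posterior_first", slices=[[1], [2], [3]]))
        assert [sorted(r.component_ids) for r in recs] == [[3], [2], [1]]

    def test_multi_component_slice(self):
        recs = group_components(_mask_with_components(3), SliceOrdering(
            order="anterior_first", slices=[[1, 2], [3]]))
        assert len(recs) == 2
        assert sorted(recs[0].component_ids) == [1, 2]

    def test_partition_property(self, rng):
        mask = _mask_with_components(5)
        recs = group_components(mask, SliceOrdering(
            order="anterior_first", slices=[[2], [1, 4], [3, 5]]))
        all_ids = sorted(i for r in recs for i in r.component_ids)
        assert all_ids == mask.component_ids
        sets = [r.component_ids for r in recs]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])

    def test_unassigned_component_raises(self):
        with pytest.raises(errors.UnassignedComponent):
            group_components(_mask_with_components(3), SliceOrdering(
                order="anterior_first", slices=[[1], [3]]))

    def test_duplicate_assignment_raises(self):
        with pytest.raises(errors.DuplicateAssignment):
            group_components(_mask_with_components(2), SliceOrdering(
                order="anterior_first", slices=[[1], [1, 2]]))

    def test_unknown_component_raises(self):
        with pytest.raises(errors.UnassignedComponent):
            group_components(_mask_with_components(2), SliceOrdering(
                order="anterior_first", slices=[[1], [2, 7]]))
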