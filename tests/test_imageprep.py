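"""Alignment, resampling, normalization, discretization and ROI geometry."""

import numpy as np
import pytest

from conftest import make_ellipse_mask
from pfradiomics.imageprep import (BoundingBox, PatellaMask, Radiograph,
                                   _rotate_grid, align_patella, discretize,
                                   make_rois, mask_bbox, normalize_patella,
                                   quantize, resample_isotropic)


def _pair(mask, spacing=(0.5, 0.5)):
    rng = np.random.default_rng(0)
    img = Radiograph(rng.normal(0, 1, mask.shape) + 3.0 * mask, spacing)
    return img, PatellaMask(mask)


class TestAlignPatella:
    def test_axis_aligned_ellipse_needs_no_rotation(self):
        img, msk = _pair(make_ellipse_mask(a=40, b=25))
        _, _, angle = align_patella(img, msk)
        assert angle == 0.0

    @pytest.mark.parametrize("phi", [17.0, -11.5])
    def test_recovers_forward_rotation(self, phi):
        # the mask satisfies |R(phi) p / (a,b)| <= 1, i.e. the 40x25 ellipse
        # rotated by -phi on the pixel grid; undoing it takes angle +phi
        rr, cc = np.mgrid[0:160, 0:160].astype(float)
        t = np.deg2rad(phi)
        u = np.cos(t) * (rr - 80) - np.sin(t) * (cc - 80)
        v = np.sin(t) * (rr - 80) + np.cos(t) * (cc - 80)
        mask = (u / 40.0) ** 2 + (v / 25.0) ** 2 <= 1.0
        img, msk = _pair(mask)
        _, _, angle = align_patella(img, msk)
        assert abs(angle - phi) <= 1.0

    @pytest.mark.parametrize("phi", [5.0, 25.0, -23.0, 9.5])
    def test_recovery_across_angles_within_wobble(self, phi):
        # pixel quantisation leaves ~1.5 deg of irreducible wobble on the
        # bbox-ratio criterion for masks of this size
        rr, cc = np.mgrid[0:160, 0:160].astype(float)
        t = np.deg2rad(phi)
        u = np.cos(t) * (rr - 80) - np.sin(t) * (cc - 80)
        v = np.sin(t) * (rr - 80) + np.cos(t) * (cc - 80)
        mask = (u / 40.0) ** 2 + (v / 25.0) ** 2 <= 1.0
        img, msk = _pair(mask)
        _, _, angle = align_patella(img, msk)
        assert abs(angle - phi) <= 2.0

    def test_disc_ties_resolve_to_zero(self):
        img, msk = _pair(make_ellipse_mask(a=30, b=30))
        _, _, angle = align_patella(img, msk)
        assert angle == 0.0

    def test_alignment_is_idempotent(self):
        # an analytically aligned mask re-aligns at exactly 0; a raster
        # produced by the aligner itself re-aligns within the pixel wobble
        img, msk = _pair(make_ellipse_mask(a=40, b=25))
        _, _, angle0 = align_patella(img, msk)
        assert angle0 == 0.0
        rr, cc = np.mgrid[0:160, 0:160].astype(float)
        t = np.deg2rad(9.0)
        u = np.cos(t) * (rr - 80) - np.sin(t) * (cc - 80)
        v = np.sin(t) * (rr - 80) + np.cos(t) * (cc - 80)
        rot = (u / 40.0) ** 2 + (v / 25.0) ** 2 <= 1.0
        img, msk = _pair(rot)
        img2, msk2, _ = align_patella(img, msk)
        _, _, angle2 = align_patella(img2, msk2)
        assert abs(angle2) <= 2.0

    def test_empty_and_degenerate_masks_error(self):
        img, msk = _pair(make_ellipse_mask())
        one_px = np.zeros((128, 128), bool)
        one_px[5, 5] = True
        with pytest.raises(ValueError):
            align_patella(img, PatellaMask(one_px))
        with pytest.raises(ValueError):
            PatellaMask(np.zeros((128, 128), bool))


class TestResample:
    def test_identity_at_target_spacing(self):
        img, msk = _pair(make_ellipse_mask(), spacing=(0.5, 0.5))
        out_img, out_msk = resample_isotropic(img, msk, 0.5)
        assert out_img.shape == img.shape
        np.testing.assert_allclose(out_img.pixels, img.pixels, atol=1e-9)

    def test_doubling_resolution(self):
        img, msk = _pair(make_ellipse_mask(), spacing=(1.0, 1.0))
        out_img, _ = resample_isotropic(img, msk, 0.5)
        assert abs(out_img.shape[0] - 2 * img.shape[0]) <= 1
        assert abs(out_img.shape[1] - 2 * img.shape[1]) <= 1
        assert out_img.spacing_mm == (0.5, 0.5)

    def test_constant_image_stays_constant(self):
        msk = make_ellipse_mask()
        img = Radiograph(np.full(msk.shape, 7.0), (0.7, 0.7))
        out_img, _ = resample_isotropic(img, PatellaMask(msk), 0.5)
        np.testing.assert_allclose(out_img.pixels, 7.0)


class TestNormalize:
    def test_zscore_inside_bbox(self):
        rng = np.random.default_rng(1)
        img = Radiograph(rng.normal(10, 3, (60, 60)), (0.5, 0.5))
        bbox = BoundingBox(10, 50, 10, 50)
        out = normalize_patella(img, bbox)
        region = out.pixels[bbox.slices()]
        assert abs(region.mean()) < 1e-10
        assert abs(region.std() - 1.0) < 1e-10

    def test_clipping_at_six_sd(self):
        img_arr = np.zeros((20, 20))
        img_arr[:10] = 1.0
        img_arr[0, 0] = 100.0      # far outlier outside the bbox
        img = Radiograph(img_arr, (0.5, 0.5))
        out = normalize_patella(img, BoundingBox(2, 18, 2, 18))
        assert out.pixels.max() == 6.0
        assert out.pixels.min() >= -6.0

    def test_degenerate_region_errors(self):
        img = Radiograph(np.ones((20, 20)), (0.5, 0.5))
        with pytest.raises(ValueError):
            normalize_patella(img, BoundingBox(0, 10, 0, 10))


class TestDiscretize:
    def test_extremes_map_to_first_and_last_level(self):
        vals = np.array([[0.0, 1.0], [0.0, 1.0]])
        lv = quantize(vals, 32)
        assert set(lv.ravel()) == {1, 32}

    def test_uniform_ramp_balanced_counts(self):
        vals = np.linspace(0, 1, 3200).reshape(32, 100)
        lv = quantize(vals, 32)
        counts = np.bincount(lv.ravel(), minlength=33)[1:]
        assert np.all(np.abs(counts - 100) <= 1)

    def test_constant_region_errors(self):
        with pytest.raises(ValueError):
            quantize(np.ones((4, 4)), 32)

    def test_discretize_operates_on_bbox(self):
        img = Radiograph(np.arange(100.0).reshape(10, 10), (0.5, 0.5))
        lv = discretize(img, BoundingBox(0, 10, 0, 10), n_bins=4)
        assert lv.min() == 1 and lv.max() == 4


class TestMakeRois:
    def test_committed_geometry_90x90(self):
        bbox = BoundingBox(100, 190, 100, 190)
        rois = make_rois(bbox, "left")
        for _, box in rois.items():
            assert box.width == 90 and box.height == 30
        # anterior edge sits on the posterior-third line of the bbox
        assert rois.roi_sup.col_min == 190 - 30
        assert rois.roi_inf.row_max == 190

    def test_equal_size_and_disjoint_for_random_bboxes(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            r0, c0 = rng.integers(0, 50, 2)
            h = rng.integers(9, 120)
            w = rng.integers(9, 120)
            rois = make_rois(BoundingBox(r0, r0 + h, c0, c0 + w), "left")
            boxes = [b for _, b in rois.items()]
            assert len({(b.height, b.width) for b in boxes}) == 1
            assert boxes[0].row_max <= boxes[1].row_min
            assert boxes[1].row_max <= boxes[2].row_min

    def test_right_knee_mirrors_exactly(self):
        n_cols = 300
        bbox = BoundingBox(40, 130, 100, 163)
        left = make_rois(bbox, "left")
        flipped_bbox = BoundingBox(40, 130, n_cols - 163, n_cols - 100)
        right = make_rois(flipped_bbox, "right")
        for (_, lb), (_, rb) in zip(left.items(), right.items()):
            assert (lb.row_min, lb.row_max) == (rb.row_min, rb.row_max)
            assert (n_cols - lb.col_max, n_cols - lb.col_min) == \
                (rb.col_min, rb.col_max)

    def test_out_of_bounds_extension_errors(self):
        bbox = BoundingBox(10, 100, 10, 100)
        with pytest.raises(ValueError, match="pad"):
            make_rois(bbox, "left", image_shape=(120, 120))


def test_bbox_of_mask():
    m = np.zeros((10, 12), bool)
    m[2:5, 3:9] = True
    assert mask_bbox(m).as_list() == [2, 5, 3, 9]
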