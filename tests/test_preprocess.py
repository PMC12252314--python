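"""Contrast enhancement, segmentation, box normalisation and rotation pairs."""

import numpy as np
import pytest

from torsionlab.errors import (ConfigurationError, InputError,
                               SegmentationError)
from torsionlab.preprocess import (IrisMask, enhance_contrast,
                                   extract_iris_box, make_rotation_samples,
                                   rotate_box, segment_iris)
from torsionlab.synthetic import render_eye_frame

from helpers import registration_oracle


class TestEnhanceContrast:
    def test_constant_image_stays_constant(self):
        img = np.full((64, 64), 128, dtype=np.uint8)
        out = enhance_contrast(img)
        assert out.shape == img.shape and out.dtype == np.uint8
        assert np.ptp(out) <= 1

    def test_output_within_8bit_range(self, frame0):
        out = enhance_contrast(frame0[0])
        assert out.min() >= 0 and out.max() <= 255

    def test_low_contrast_gradient_gains_spread(self):
        grad = np.tile(np.linspace(100, 110, 96, dtype=np.uint8), (96, 1))
        out = enhance_contrast(grad)
        assert out.astype(float).std() > grad.astype(float).std()

    def test_rgb_path_preserves_shape(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, size=(48, 48, 3), dtype=np.uint8)
        out = enhance_contrast(img)
        assert out.shape == img.shape and out.dtype == np.uint8

    def test_empty_image_rejected(self):
        with pytest.raises(InputError):
            enhance_contrast(np.empty((0, 0), dtype=np.uint8))


class TestSegmentIris:
    def test_oracle_passes_mask_through(self, frame0):
        img, mask = frame0
        out = segment_iris(img, "oracle", oracle_mask=mask)
        assert np.array_equal(out.mask, mask)

    def test_all_black_image_fails_classical(self):
        with pytest.raises(SegmentationError) as exc:
            segment_iris(np.zeros((64, 64), dtype=np.uint8), "classical",
                         frame_index=17)
        assert exc.value.frame_index == 17

    def test_classical_matches_oracle_iou(self, frame0):
        img, mask = frame0
        out = segment_iris(img, "classical")
        inter = (out.mask & mask).sum()
        union = (out.mask | mask).sum()
        assert inter / union >= 0.7

    def test_unknown_strategy_rejected(self, frame0):
        with pytest.raises(ConfigurationError):
            segment_iris(frame0[0], "unet")


class TestExtractIrisBox:
    @staticmethod
    def _disk(shape, cx, cy, r):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        return np.hypot(yy - cy, xx - cx) <= r

    def test_centered_radius32_disk_is_identity_crop(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, size=(224, 224), dtype=np.uint8)
        mask = self._disk((224, 224), 112, 112, 32)
        box = extract_iris_box(img, IrisMask(mask, (224, 224)))
        assert box.pixels.shape == (64, 64)
        assert np.allclose(box.pixels, img[80:144, 80:144] / 255.0, atol=1e-6)
        assert box.diameter_src == pytest.approx(64, abs=1)

    def test_radius16_disk_scales_up_by_two(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 255, size=(224, 224), dtype=np.uint8)
        mask = self._disk((224, 224), 100, 120, 16)
        box = extract_iris_box(img, IrisMask(mask, (224, 224)))
        assert box.pixels.shape == (64, 64)
        assert box.diameter_src == pytest.approx(32, abs=1)
        assert box.center[0] == pytest.approx(100, abs=1)
        assert box.center[1] == pytest.approx(120, abs=1)

    def test_border_disk_zero_padded(self):
        img = np.full((128, 128), 200, dtype=np.uint8)
        mask = self._disk((128, 128), 10, 64, 20)
        box = extract_iris_box(img, IrisMask(mask, (128, 128)))
        assert box.pixels.shape == (64, 64)
        # the square leaves the image on the left: padded pixels are zero
        assert box.pixels[:, 0].max() == 0.0
        assert box.pixels[32, 32] > 0.5


class TestRotateBox:
    def test_zero_rotation_is_identity(self):
        rng = np.random.default_rng(2)
        b = rng.random((64, 64)).astype(np.float32)
        assert np.array_equal(rotate_box(b, 0.0), b)

    def test_inverse_pair_recovers_box(self, small_box_set):
        # band-limit the box first: the bound is a property of bilinear
        # rotation, which loses accuracy only at above-Nyquist edges
        from scipy.ndimage import gaussian_filter

        b = gaussian_filter(small_box_set[0].pixels, 1.0)
        back = rotate_box(rotate_box(b, 10.0), -10.0)
        yy, xx = np.mgrid[0:64, 0:64]
        inner = np.hypot(yy - 31.5, xx - 31.5) <= 28
        mae = np.abs(back[inner] - b[inner]).mean() * 255.0
        assert mae <= 2.0

    def test_sign_convention_counterclockwise_on_screen(self):
        # bright pixel right of centre; +90 deg must move it above centre
        b = np.zeros((64, 64), dtype=np.float32)
        b[32, 42] = 1.0
        out = rotate_box(b, 90.0)
        r, c = np.unravel_index(np.argmax(out), out.shape)
        assert abs(r - 22) <= 1 and abs(c - 32) <= 1

    def test_mean_intensity_conserved_inside_inscribed_circle(
            self, small_box_set):
        yy, xx = np.mgrid[0:64, 0:64]
        inner = np.hypot(yy - 31.5, xx - 31.5) <= 28
        for theta in (-15.0, -7.0, 7.0, 15.0):
            b = small_box_set[1].pixels
            r = rotate_box(b, theta)
            assert r[inner].mean() == pytest.approx(b[inner].mean(), rel=0.02)


class TestMakeRotationSamples:
    def test_stride_three_grouping(self, small_box_set):
        samples = make_rotation_samples(small_box_set[:9], 3, seed=0)
        assert len(samples) == 3
        for i, s in enumerate(samples):
            for k in range(3):
                assert np.array_equal(s.original[k],
                                      small_box_set[3 * i + k].pixels)

    def test_grid_sampler_yields_integer_angles(self, small_box_set):
        samples = make_rotation_samples(small_box_set, 4,
                                        angle_sampler="grid_1deg", seed=1)
        for s in samples:
            assert s.theta_gt == int(s.theta_gt)
            assert -15 <= s.theta_gt <= 15

    def test_same_seed_same_angles(self, small_box_set):
        a = make_rotation_samples(small_box_set, 4, seed=9)
        b = make_rotation_samples(small_box_set, 4, seed=9)
        assert [s.theta_gt for s in a] == [s.theta_gt for s in b]

    def test_rotated_stack_matches_rotate_box(self, small_box_set):
        s = make_rotation_samples(small_box_set, 1, seed=2)[0]
        for k in range(3):
            assert np.array_equal(s.rotated[k],
                                  rotate_box(s.original[k], s.theta_gt))

    def test_too_few_boxes_rejected(self, small_box_set):
        with pytest.raises(ConfigurationError):
            make_rotation_samples(small_box_set[:2], 1, seed=0)


class TestRoundTrip:
    def test_box_registration_recovers_rendered_theta(self, scene):
        """Render at theta, segment with the oracle, crop, then register the
        crop against the theta=0 crop: the angle must survive the pipeline."""
        img0, mask0, _ = render_eye_frame(scene, 0.0)
        m0 = segment_iris(img0, "oracle", oracle_mask=mask0)
        box0 = extract_iris_box(img0, m0)
        yy, xx = np.mgrid[0:64, 0:64]
        inner = np.hypot(yy - 31.5, xx - 31.5) <= 29
        for theta in (-12.0, 6.0):
            imgt, maskt, _ = render_eye_frame(scene, theta)
            mt = segment_iris(imgt, "oracle", oracle_mask=maskt)
            boxt = extract_iris_box(imgt, mt)
            rec = registration_oracle(box0.pixels, boxt.pixels, inner)
            assert abs(rec - theta) <= 0.5
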