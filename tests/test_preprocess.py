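"""Preprocessing chain: smoothing, grayscale, thresholding, box extraction,
crop-resize, and determinism of the whole pipeline."""

import numpy as np
import pytest
from scipy import ndimage

from plumvision.preprocess import (
    BoundingBox,
    NoObjectError,
    adaptive_binarize,
    crop_resize,
    extract_fruit_box,
    gaussian_smooth,
    preprocess_image,
    to_grayscale,
)
from plumvision.preprocess import _gaussian_kernel_1d

from conftest import draw_ellipse_image


class TestGaussianSmooth:
    def test_constant_image_preserved(self):
        img = np.full((40, 50, 3), 128, np.uint8)
        assert np.array_equal(gaussian_smooth(img, 11), img)

    def test_impulse_reproduces_kernel(self):
        """Brute-force 2-D convolution oracle on a single impulse."""
        img = np.zeros((31, 31), np.float64)
        img[15, 15] = 1.0
        k1 = _gaussian_kernel_1d(11)
        expected = np.outer(k1, k1)
        out = gaussian_smooth(img, 11)
        assert np.allclose(out[10:21, 10:21], expected, atol=1e-12)
        # oracle: full dense convolution
        dense = ndimage.convolve(img, np.outer(k1, k1), mode="reflect")
        assert np.allclose(out, dense, atol=1e-12)

    def test_kernel_size_one_is_identity(self):
        img = np.arange(60, dtype=np.uint8).reshape(4, 5, 3)
        assert np.array_equal(gaussian_smooth(img, 1), img)

    @pytest.mark.parametrize("k", [0, 2, 4, -3])
    def test_even_or_nonpositive_kernel_rejected(self, k):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((5, 5, 3), np.uint8), k)


class TestGrayscale:
    @pytest.mark.parametrize("rgb,expected", [
        ((255, 255, 255), 255),
        ((255, 0, 0), 76),       # round(0.299 * 255)
        ((0, 255, 0), 150),      # round(0.587 * 255)
        ((17, 17, 17), 17),      # weights sum to 1
    ])
    def test_luminance_values(self, rgb, expected):
        img = np.full((3, 3, 3), 0, np.uint8)
        img[:] = rgb
        assert np.all(to_grayscale(img) == expected)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((5, 5), np.uint8))


class TestAdaptiveBinarize:
    def test_constant_image_gives_empty_mask(self):
        img = np.full((30, 30), 90, np.uint8)
        assert not adaptive_binarize(img, 11, 5.0).any()

    def test_huge_negative_offset_marks_everything(self):
        img = np.full((30, 30), 90, np.uint8)
        assert adaptive_binarize(img, 11, -256.0).all()

    def test_matches_brute_force_local_mean(self, rng):
        """Oracle: explicit local-mean loop with reflected borders."""
        img = rng.integers(0, 256, size=(20, 24)).astype(np.uint8)
        block, offset = 5, 3.0
        out = adaptive_binarize(img, block, offset)
        pad = block // 2
        ref = np.pad(img.astype(float), pad, mode="symmetric")
        for y in range(20):
            for x in range(24):
                m = ref[y:y + block, x:x + block].mean()
                expected = 255 if img[y, x] > m + offset else 0
                assert out[y, x] == expected

    def test_bright_disk_mask_isolates_boundary_region(self):
        img, _ = draw_ellipse_image(128, 128, 60, 60)
        gray = to_grayscale(img)
        mask = adaptive_binarize(gray, 51, 5.0)
        ys, xs = np.nonzero(mask)
        rad = np.hypot(ys - 128, xs - 128)
        assert mask.any()
        assert rad.max() <= 62            # inside the disk
        assert rad.min() >= 25            # not the disk centre

    def test_even_block_size_rejected(self):
        with pytest.raises(ValueError):
            adaptive_binarize(np.zeros((10, 10), np.uint8), 10, 1.0)


class TestExtractFruitBox:
    def test_ellipse_box_within_two_pixels(self, rng):
        for _ in range(15):
            cy, cx = rng.uniform(90, 160, 2)
            b, a = rng.uniform(40, 80, 2)
            img, (x0, y0, x1, y1) = draw_ellipse_image(cy, cx, b, a)
            box = extract_fruit_box(img)
            assert abs(box.x - x0) <= 2
            assert abs(box.y - y0) <= 2
            assert abs(box.x + box.w - 1 - x1) <= 2
            assert abs(box.y + box.h - 1 - y1) <= 2

    def test_all_black_image_raises_no_object(self):
        with pytest.raises(NoObjectError) as exc:
            extract_fruit_box(np.zeros((100, 100, 3), np.uint8))
        assert exc.value.stage in ("adaptive_binarize", "canny")

    def test_larger_of_two_blobs_wins(self):
        img = np.zeros((256, 256, 3), np.uint8)
        yy, xx = np.mgrid[0:256, 0:256]
        img[np.hypot(yy - 80, xx - 70) <= 50] = (90, 150, 70)    # large
        img[np.hypot(yy - 190, xx - 190) <= 22] = (90, 150, 70)  # small
        box = extract_fruit_box(img)
        # oracle: connected-component extents of the large disk
        assert abs(box.x - 20) <= 3 and abs(box.y - 30) <= 3
        assert abs(box.w - 101) <= 4 and abs(box.h - 101) <= 4


class TestCropResize:
    def test_exact_crop_when_box_is_output_sized(self, rng):
        img = rng.integers(0, 256, size=(300, 300, 3)).astype(np.uint8)
        box = BoundingBox(x=40, y=60, w=100, h=100)
        out = crop_resize(img, box)
        assert np.array_equal(out, img[60:160, 40:140])

    def test_constant_box_resizes_to_constant(self):
        img = np.full((300, 300, 3), 77, np.uint8)
        out = crop_resize(img, BoundingBox(0, 0, 200, 200))
        assert out.shape == (100, 100, 3)
        assert np.all(out == 77)

    def test_checkerboard_downsample_preserves_mean(self):
        img = np.zeros((200, 200, 3), np.uint8)
        img[(np.add.outer(np.arange(200), np.arange(200)) % 2) == 0] = 255
        out = crop_resize(img, BoundingBox(0, 0, 200, 200))
        assert abs(out.mean() - img.mean()) <= 255 / 255.0 + 0.5

    def test_box_outside_image_rejected(self):
        img = np.zeros((50, 50, 3), np.uint8)
        with pytest.raises(ValueError):
            crop_resize(img, BoundingBox(x=10, y=10, w=45, h=45))

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(x=0, y=0, w=0, h=5)


class TestChainContracts:
    def test_chain_is_deterministic(self, rng):
        img, _ = draw_ellipse_image(120, 130, 55, 70)
        noise = rng.integers(0, 20, size=img.shape).astype(np.uint8)
        img = np.clip(img.astype(int) + noise, 0, 255).astype(np.uint8)
        out1 = preprocess_image(img)
        out2 = preprocess_image(img.copy())
        assert np.array_equal(out1, out2)

    @pytest.mark.parametrize("size", [(256, 256), (180, 320)])
    def test_output_is_always_100x100x3(self, size):
        h, w = size
        img, _ = draw_ellipse_image(h // 2, w // 2, h // 3, w // 3, size=max(h, w))
        out = preprocess_image(img[:h, :w])
        assert out.shape == (100, 100, 3)
        assert out.dtype == np.uint8
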