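"""Morphological operators against a brute-force oracle and their algebra."""

import numpy as np
import pytest
from scipy import ndimage

from mcnn.morphology import (
    StructuringElement,
    binarize_filter,
    close_,
    dilate,
    erode,
    morphological_layer,
    open_,
    residual,
)


def brute_erode(image, mask, pad=1.0):
    """Double-loop sliding-window minimum over active cells, same padding."""
    k = mask.shape[0]
    half = k // 2
    h, w = image.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            vals = []
            for i in range(k):
                for j in range(k):
                    if mask[i, j]:
                        rr, cc = r + i - half, c + j - half
                        vals.append(image[rr, cc] if 0 <= rr < h and 0 <= cc < w else pad)
            out[r, c] = min(vals)
    return out


def brute_dilate(image, mask, pad=0.0):
    """Sliding-window maximum over the reflected element, same padding."""
    k = mask.shape[0]
    half = k // 2
    h, w = image.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            vals = []
            for i in range(k):
                for j in range(k):
                    if mask[i, j]:
                        rr, cc = r - (i - half), c - (j - half)
                        vals.append(image[rr, cc] if 0 <= rr < h and 0 <= cc < w else pad)
            out[r, c] = max(vals)
    return out


def random_se(rng, size=5, ensure_center=False):
    mask = (rng.random((size, size)) > 0.5).astype(np.uint8)
    if ensure_center or not mask.any():
        mask[size // 2, size // 2] = 1
    return StructuringElement(mask)


# ----------------------------------------------------------------------
# binarization
# ----------------------------------------------------------------------
class TestBinarizeFilter:
    def test_midpoint_threshold(self):
        # min 0.2, max 0.9 -> only values with (v - 0.2)/0.7 >= 0.5 survive:
        # 0.5 -> 0.43 (off), 0.9 -> 1.0 (on), 0.4 and below -> off
        weights = np.full((5, 5), 0.4)
        weights[0, 0], weights[1, 1], weights[2, 2] = 0.2, 0.9, 0.5
        weights[3, 3] = 0.56  # normalized 0.514 -> on
        se = binarize_filter(weights)
        expected = np.zeros((5, 5), dtype=np.uint8)
        expected[1, 1] = expected[3, 3] = 1
        np.testing.assert_array_equal(se.mask, expected)

    def test_constant_filter_degenerates_to_center(self):
        se = binarize_filter(np.full((5, 5), 0.7))
        assert se.active_count == 1
        assert se.mask[2, 2] == 1

    def test_non_5x5_rejected(self):
        with pytest.raises(ValueError, match="5x5"):
            binarize_filter(np.zeros((4, 4)))

    def test_random_filters_always_usable(self, rng):
        # min-max normalization puts the max at 1 (active) and the min at 0
        # (inactive), so non-constant filters have both kinds of cells
        for _ in range(100):
            weights = rng.normal(size=(5, 5))
            se = binarize_filter(weights)
            assert se.active_count >= 1
            assert se.active_count <= 24  # at least one zero for non-constant


# ----------------------------------------------------------------------
# operator correctness
# ----------------------------------------------------------------------
class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(25))
    def test_erode_dilate_match_brute_force(self, trial):
        rng = np.random.default_rng(1000 + trial)
        image = rng.random((8, 8))
        for size in (3, 5):
            se = random_se(rng, size)
            np.testing.assert_array_equal(erode(image, se), brute_erode(image, se.mask))
            np.testing.assert_array_equal(dilate(image, se), brute_dilate(image, se.mask))

    @pytest.mark.parametrize("trial", range(10))
    def test_open_close_are_the_compositions(self, trial):
        rng = np.random.default_rng(2000 + trial)
        image = rng.random((8, 8))
        se = random_se(rng)
        np.testing.assert_array_equal(open_(image, se), dilate(erode(image, se), se))
        np.testing.assert_array_equal(close_(image, se), erode(dilate(image, se), se))

    def test_matches_scipy_grey_morphology(self, rng):
        # independent C implementation as a second oracle
        for _ in range(20):
            image = rng.random((12, 12))
            se = random_se(rng)
            fp = se.mask.astype(bool)
            np.testing.assert_array_equal(
                erode(image, se),
                ndimage.grey_erosion(image, footprint=fp, mode="constant", cval=1.0),
            )
            np.testing.assert_array_equal(
                dilate(image, se),
                ndimage.grey_dilation(image, footprint=fp, mode="constant", cval=0.0),
            )

    def test_full_3x3_se_on_random_image(self):
        rng = np.random.default_rng(7)
        image = rng.random((8, 8))
        se = StructuringElement(np.ones((3, 3), dtype=np.uint8))
        np.testing.assert_array_equal(erode(image, se), brute_erode(image, se.mask))


class TestOperatorAlgebra:
    def test_constant_image_fixed_point(self, rng):
        image = np.full((10, 10), 0.6)
        se = random_se(rng)
        np.testing.assert_array_equal(erode(image, se), image)
        np.testing.assert_array_equal(dilate(image, se), image)

    def test_center_only_se_is_identity(self, rng):
        image = rng.random((9, 9))
        se = StructuringElement.center_only()
        for op in (erode, dilate, open_, close_):
            np.testing.assert_array_equal(op(image, se), image)

    @pytest.mark.parametrize("trial", range(10))
    def test_duality(self, trial):
        # dilation is the complement of erosion by the reflected element
        rng = np.random.default_rng(3000 + trial)
        image = rng.random((8, 8))
        se = random_se(rng)
        np.testing.assert_allclose(
            dilate(image, se), 1.0 - erode(1.0 - image, se.reflect()), atol=1e-12
        )

    def test_monotonicity(self, rng):
        x = rng.random((8, 8))
        y = np.clip(x + rng.random((8, 8)) * 0.3, 0, 1)  # y >= x
        for _ in range(10):
            se = random_se(rng)
            assert (erode(x, se) <= erode(y, se)).all()
            assert (dilate(x, se) <= dilate(y, se)).all()

    @pytest.mark.parametrize("trial", range(10))
    def test_idempotence_and_ordering_chain(self, trial):
        rng = np.random.default_rng(4000 + trial)
        image = rng.random((8, 8))
        se = random_se(rng, ensure_center=True)
        opened, closed = open_(image, se), close_(image, se)
        np.testing.assert_allclose(open_(opened, se), opened, atol=1e-12)
        np.testing.assert_allclose(close_(closed, se), closed, atol=1e-12)
        eps = 1e-12
        assert (erode(image, se) <= opened + eps).all()
        assert (opened <= image + eps).all()
        assert (image <= closed + eps).all()
        assert (closed <= dilate(image, se) + eps).all()

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            erode(np.empty((0, 0)), StructuringElement.center_only())


# ----------------------------------------------------------------------
# residual and the four-map layer
# ----------------------------------------------------------------------
class TestResidualAndLayer:
    def test_residual_of_erosion_nonnegative(self, rng):
        # erosion <= X pointwise whenever the element contains its center
        image = rng.random((8, 8))
        se = random_se(rng, ensure_center=True)
        res = residual(image, erode(image, se))
        assert (res >= -1e-12).all()

    def test_residual_identity_and_constant_cases(self, rng):
        image = rng.random((8, 8))
        np.testing.assert_array_equal(residual(image, image), np.zeros_like(image))
        const = np.full((8, 8), 0.3)
        np.testing.assert_array_equal(
            residual(const, erode(const, random_se(rng))), np.zeros_like(const)
        )

    def test_residual_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            residual(rng.random((8, 8)), rng.random((7, 8)))

    def test_layer_produces_four_same_shape_maps(self, rng):
        image = rng.random((16, 16))
        filters = rng.normal(size=(4, 5, 5))
        stack = morphological_layer(image, filters)
        assert stack.maps.shape == (16, 16, 4)

    def test_layer_on_constant_input(self, rng):
        image = np.full((12, 12), 0.4)
        stack = morphological_layer(image, rng.normal(size=(4, 5, 5)))
        np.testing.assert_array_equal(stack["erosion"], image)
        np.testing.assert_array_equal(stack["dilation"], image)
        np.testing.assert_array_equal(stack["opening"], image)
        np.testing.assert_array_equal(stack["residual"], np.zeros_like(image))

    def test_layer_residual_uses_its_own_filter(self, rng):
        # each operation has its own learned filter; the residual map is the
        # input minus the erosion computed with the fourth filter
        image = rng.random((16, 16))
        filters = rng.normal(size=(4, 5, 5))
        stack = morphological_layer(image, filters)
        expected = image - erode(image, binarize_filter(filters[3]))
        np.testing.assert_allclose(stack["residual"], expected, atol=1e-12)

    def test_layer_wrong_filter_count(self, rng):
        with pytest.raises(ValueError, match="4 filters"):
            morphological_layer(rng.random((8, 8)), rng.normal(size=(3, 5, 5)))


class TestStructuringElement:
    def test_validation(self):
        with pytest.raises(ValueError):
            StructuringElement(np.zeros((5, 5)))  # all-zero
        with pytest.raises(ValueError):
            StructuringElement(np.ones((4, 4)))  # even side
        with pytest.raises(ValueError):
            StructuringElement(np.full((5, 5), 0.5))  # non-binary

    def test_reflect_involution(self, rng):
        se = random_se(rng)
        np.testing.assert_array_equal(se.reflect().reflect().mask, se.mask)
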