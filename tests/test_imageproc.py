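"""Preprocessing operators: flat-fielding, opening background, thresholding,
labeling and the elaboration filters, checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cytomorph import (
    flatfield_correct,
    label_regions,
    merge_elaborated,
    north_shadow,
    opening_background,
    subtract_background,
    threshold_mask,
)
from cytomorph.imageproc import (
    NORTH_SHADOW_KERNEL,
    convolve2d,
    convolve_colorize,
    load_kernel,
)
from cytomorph.scenegen import render_scene

from conftest import small_scene


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_convolve(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct double-loop true convolution with replicate padding."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(image.astype(float), ((ph, ph), (pw, pw)), mode="edge")
    out = np.zeros_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    acc += kernel[a, b] * padded[i + kh - 1 - a, j + kw - 1 - b]
            out[i, j] = acc
    return out


def brute_force_opening(image: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Erosion then dilation via explicit min/max over the neighborhood."""
    offs = np.argwhere(footprint) - np.array(footprint.shape) // 2

    def scan(img, reducer):
        h, w = img.shape
        out = np.empty_like(img, dtype=float)
        for i in range(h):
            for j in range(w):
                vals = []
                for dr, dc in offs:
                    r = min(max(i + dr, 0), h - 1)  # replicate padding
                    c = min(max(j + dc, 0), w - 1)
                    vals.append(img[r, c])
                out[i, j] = reducer(vals)
        return out

    return scan(scan(image.astype(float), min), max)


# ---------------------------------------------------------------------------


class TestFlatfield:
    def test_constant_image_is_identity(self):
        img = np.full((64, 64), 37.0)
        assert np.allclose(flatfield_correct(img, 10), img)

    def test_removes_synthetic_shading_bump(self):
        # pure shading times a constant: correction recovers the constant
        cfg = small_scene(n_cells=0, noise_gaussian_sd=0.0, shading_amplitude=0.3)
        channels, truth = render_scene(cfg)
        img = channels["phalloidin"].astype(float)
        corrected = flatfield_correct(img, 100.0)
        assert np.all(np.abs(corrected - cfg.background_level) / cfg.background_level < 0.02)

    def test_preserves_global_mean(self):
        cfg = small_scene(seed=4, shading_amplitude=0.3)
        channels, _ = render_scene(cfg)
        img = channels["phalloidin"].astype(float)
        corrected = flatfield_correct(img, 100.0)
        assert corrected.mean() == pytest.approx(img.mean(), rel=1e-3)

    def test_removes_at_least_90pct_of_shading_amplitude(self):
        cfg = small_scene(n_cells=0, noise_gaussian_sd=0.0, shading_amplitude=0.3)
        channels, _ = render_scene(cfg)
        img = channels["phalloidin"].astype(float)
        corrected = flatfield_correct(img, 100.0)
        injected = np.ptp(img) / img.mean()
        residual = np.ptp(corrected) / corrected.mean()
        assert residual <= 0.1 * injected

    def test_all_zero_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = flatfield_correct(np.zeros((32, 32)), 10)
        assert not out.any()


class TestOpeningBackground:
    def test_constant_image_unchanged(self):
        img = np.full((40, 40), 11.0)
        assert np.array_equal(opening_background(img, 5).image, img)

    def test_single_bright_pixel_removed(self):
        img = np.zeros((31, 31))
        img[15, 15] = 100.0
        assert not opening_background(img, 5).image.any()

    @pytest.mark.parametrize("diameter", [3, 5, 9])
    def test_matches_brute_force_oracle(self, diameter, rng):
        from skimage.morphology import disk

        img = rng.integers(0, 256, size=(32, 32)).astype(float)
        expected = brute_force_opening(img, disk(diameter // 2))
        assert np.array_equal(opening_background(img, diameter).image, expected)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arrays(np.uint8, (24, 24), elements=st.integers(0, 255)),
        st.sampled_from([3, 7, 11]),
    )
    def test_anti_extensive_and_idempotent(self, img, diameter):
        opened = opening_background(img.astype(float), diameter).image
        assert np.all(opened <= img)  # anti-extensivity
        reopened = opening_background(opened, diameter).image
        assert np.array_equal(reopened, opened)  # idempotence

    def test_tiny_disk_rejected(self):
        with pytest.raises(ValueError):
            opening_background(np.zeros((5, 5)), 2)


class TestSubtractBackground:
    def test_self_subtraction_is_zero(self):
        img = np.arange(16.0).reshape(4, 4)
        assert not subtract_background(img, img).any()

    def test_zero_background_is_identity(self):
        img = np.arange(16.0).reshape(4, 4)
        assert np.array_equal(subtract_background(img, np.zeros_like(img)), img)

    def test_output_clamped_nonnegative(self, rng):
        img = rng.normal(size=(16, 16))
        bg = rng.normal(size=(16, 16))
        assert np.all(subtract_background(img, bg) >= 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((4, 4)), np.zeros((5, 5)))


class TestThreshold:
    def test_two_level_image_split_exactly(self):
        img = np.full((20, 20), 10.0)
        img[5:15, 5:15] = 200.0
        res = threshold_mask(img)
        assert np.array_equal(res.mask, img == 200.0)
        assert 10 < res.threshold < 200

    def test_constant_image_is_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            threshold_mask(np.full((10, 10), 3.0))

    def test_noise_free_scene_masks_match_ground_truth(self):
        cfg = small_scene(seed=6, noise_gaussian_sd=0.0, shading_amplitude=0.0)
        channels, truth = render_scene(cfg)
        res = threshold_mask(channels["phalloidin"].astype(float))
        labels = label_regions(res.mask, 100)
        for cell in truth.cells:
            overlap = labels[cell.cell_mask]
            lab = np.bincount(overlap[overlap > 0]).argmax()
            comp = labels == lab
            iou = (comp & cell.cell_mask).sum() / (comp | cell.cell_mask).sum()
            assert iou >= 0.9

    def test_manual_threshold(self):
        img = np.arange(9.0).reshape(3, 3)
        res = threshold_mask(img, method=4.0)
        assert res.mask.sum() == 4 and res.method == "manual"


class TestLabelRegions:
    def test_two_disjoint_squares(self):
        mask = np.zeros((20, 20), bool)
        mask[2:6, 2:6] = True
        mask[10:14, 10:14] = True
        assert label_regions(mask).max() == 2

    def test_min_area_filter_removes_small(self):
        mask = np.zeros((10, 10), bool)
        mask[0:3, 0:3] = True  # 9 px
        assert label_regions(mask, min_area_px=10).max() == 0

    def test_diagonal_touch_is_one_component(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[1, 1] = True
        assert label_regions(mask).max() == 1


class TestElaborationFilters:
    def test_north_shadow_fixes_constants(self):
        img = np.full((16, 16), 42.0)
        assert np.allclose(north_shadow(img), img)

    def test_step_edge_response_is_signed_and_local(self):
        img = np.zeros((20, 20))
        img[10:, :] = 100.0  # horizontal step edge
        out = north_shadow(img)
        assert np.allclose(out[:5], 0.0) and np.allclose(out[15:], 100.0)
        band = out[8:12]
        assert band.max() > 100.0 or band.min() < 0.0

    def test_matches_brute_force_convolution(self, rng):
        img = rng.random((16, 16)) * 255
        assert np.allclose(
            north_shadow(img), brute_force_convolve(img, NORTH_SHADOW_KERNEL)
        )

    def test_convolution_is_linear(self, rng):
        x = rng.random((12, 12))
        y = rng.random((12, 12))
        lhs = convolve2d(2.5 * x + 0.5 * y, NORTH_SHADOW_KERNEL)
        rhs = 2.5 * convolve2d(x, NORTH_SHADOW_KERNEL) + 0.5 * convolve2d(
            y, NORTH_SHADOW_KERNEL
        )
        assert np.allclose(lhs, rhs)

    def test_colorize_identity_kernel(self, rng):
        img = rng.random((10, 10)) * 100
        ident = np.zeros((3, 3))
        ident[1, 1] = 1.0
        rgb = convolve_colorize(img, ident, "green")
        assert np.allclose(rgb[..., 1], img)
        assert not rgb[..., 0].any() and not rgb[..., 2].any()

    def test_colorize_zero_image_is_black(self):
        rgb = convolve_colorize(np.zeros((8, 8)), np.ones((3, 3)), "red")
        assert not rgb.any()

    def test_colorize_sharpen_matches_oracle(self, rng):
        img = rng.random((16, 16)) * 255
        sharpen = np.array([[0, -1, 0], [-1, 5, -1], [0, -1, 0]], dtype=float)
        expected = np.clip(brute_force_convolve(img, sharpen), 0, None)
        assert np.allclose(convolve_colorize(img, sharpen, "blue")[..., 2], expected)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            convolve2d(np.zeros((8, 8)), np.ones((2, 2)))

    def test_merge_black_colorized_keeps_shadow(self, rng):
        shadow = rng.random((8, 8)) * 200
        merged = merge_elaborated(shadow, np.zeros((8, 8, 3)))
        assert np.allclose(merged, np.repeat(shadow[..., None], 3, axis=-1))

    def test_merge_both_black(self):
        assert not merge_elaborated(np.zeros((8, 8)), np.zeros((8, 8, 3))).any()

    def test_merge_deterministic(self, rng):
        a = rng.random((8, 8)) * 100
        b = convolve_colorize(a, NORTH_SHADOW_KERNEL, "green")
        assert np.array_equal(merge_elaborated(a, b), merge_elaborated(a, b))


def test_kernel_loading_from_text(tmp_path):
    path = tmp_path / "kernel.txt"
    path.write_text("0 -1 0\n-1 5 -1\n0 -1 0\n")
    k = load_kernel(path)
    assert k.shape == (3, 3) and k[1, 1] == 5
    bad = tmp_path / "bad.txt"
    bad.write_text("1 2\n3 4\n")
    with pytest.raises(ValueError):
        load_kernel(bad)
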