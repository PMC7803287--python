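"""Channel extraction: pyramids, normalization, symmetries, pop-out."""

import math

import numpy as np
import pytest

import conspicuity as cp
from conspicuity.errors import DimensionError
from conspicuity.features import ChannelConfig, build_gaussian_pyramid, normalize_map
from conspicuity.synthetic import StimulusSpec, TargetSpec, render_bar_stimulus

EXTRACTORS = {
    "color": cp.extract_color_conspicuity,
    "intensity": cp.extract_intensity_conspicuity,
    "orientation": cp.extract_orientation_conspicuity,
}


def _pyramid_reduce_oracle(plane: np.ndarray) -> np.ndarray:
    """Independent one-step pyramid reduction: explicit separable Gaussian
    convolution (sigma 1, radius 4, symmetric padding) followed by manual
    bilinear sampling on the pixel-center grid."""
    x = np.arange(-4, 5, dtype=float)
    k = np.exp(-(x**2) / 2.0)
    k /= k.sum()
    padded = np.pad(plane, 4, mode="symmetric")
    rows = np.apply_along_axis(lambda r: np.convolve(r, k, mode="valid"), 1, padded)
    blurred = np.apply_along_axis(
        lambda c: np.convolve(c, k, mode="valid"), 0, rows
    )

    def sample(img, out_n, axis):
        n = img.shape[axis]
        out = math.ceil(n / 2)
        scale = n / out
        coords = (np.arange(out) + 0.5) * scale - 0.5
        lo = np.clip(np.floor(coords).astype(int), 0, n - 1)
        hi = np.clip(lo + 1, 0, n - 1)
        frac = coords - np.floor(coords)
        a = np.take(img, lo, axis=axis)
        b = np.take(img, hi, axis=axis)
        shape = [1, 1]
        shape[axis] = out
        return a + (b - a) * frac.reshape(shape)

    return sample(sample(blurred, None, 0), None, 1)


class TestGaussianPyramid:
    def test_level_sizes_follow_halving(self):
        levels = build_gaussian_pyramid(np.zeros((256, 256)), depth=5)
        assert [lv.shape[0] for lv in levels] == [256, 128, 64, 32, 16, 8]

    def test_level_zero_is_the_input(self, rng):
        plane = rng.uniform(0, 1, (64, 80))
        levels = build_gaussian_pyramid(plane, depth=2)
        assert levels[0] is not plane
        np.testing.assert_array_equal(levels[0], plane)

    def test_constant_plane_stays_constant(self):
        levels = build_gaussian_pyramid(np.full((128, 128), 0.37), depth=4)
        for lv in levels:
            np.testing.assert_allclose(lv, 0.37, atol=1e-6)

    def test_depth_too_large_raises(self):
        with pytest.raises(DimensionError):
            build_gaussian_pyramid(np.zeros((64, 64)), depth=6)

    def test_reduction_matches_independent_convolution_oracle(self):
        plane = np.zeros((65, 65))
        plane[32, 32] = 1.0  # centered impulse
        level1 = build_gaussian_pyramid(plane, depth=1)[1]
        oracle = _pyramid_reduce_oracle(plane)
        np.testing.assert_allclose(level1, oracle, atol=1e-6)
        np.testing.assert_allclose(level1.sum(), oracle.sum(), atol=1e-6)


class TestNormalizeMap:
    def test_all_zero_unchanged(self):
        out = normalize_map(np.zeros((32, 32)))
        assert out.max() == 0.0

    def test_output_bounded_by_one(self, rng):
        for _ in range(5):
            out = normalize_map(rng.uniform(0, 10, (40, 40)))
            assert out.max() <= 1.0 + 1e-12
            assert out.min() >= 0.0

    def test_single_peak_promoted_over_many_equal_peaks(self):
        yy, xx = np.mgrid[0:128, 0:128]
        bump = lambda cy, cx: np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / 18.0)
        single = bump(64, 64)
        many = sum(bump(cy, cx) for cy in range(8, 128, 13) for cx in range(8, 128, 13))
        many = many / many.max()
        w_single = normalize_map(single).max()
        w_many = normalize_map(many).max()
        assert w_single > w_many

    def test_negative_input_rejected(self):
        with pytest.raises(DimensionError):
            normalize_map(np.array([[-1.0, 0.0]]))


class TestChannelBasics:
    @pytest.mark.parametrize("kind", list(EXTRACTORS))
    def test_flat_input_yields_zero_map(self, kind):
        img = cp.RasterImage(np.full((64, 64, 3), 0.5))
        fmap = EXTRACTORS[kind](img)
        assert fmap.values.max() == 0.0
        assert fmap.shape == (64, 64)

    def test_grayscale_image_has_zero_color_map(self, rng):
        gray = np.repeat(rng.uniform(0, 1, (64, 64, 1)), 3, axis=2)
        assert cp.extract_color_conspicuity(cp.RasterImage(gray)).values.max() == 0.0

    def test_maps_are_full_resolution_and_unit_peak(self, texture_image):
        for kind, f in EXTRACTORS.items():
            fmap = f(texture_image)
            assert fmap.shape == texture_image.shape
            assert fmap.values.min() >= 0.0
            assert np.isclose(fmap.values.max(), 1.0)

    def test_too_small_image_rejected(self):
        with pytest.raises(DimensionError):
            cp.RasterImage(np.full((32, 32, 3), 0.5))

    def test_bright_square_drives_intensity_map(self):
        img = np.full((128, 128, 3), 0.05)
        img[50:75, 60:85] = 0.9  # 25 px bright square
        fmap = cp.extract_intensity_conspicuity(cp.RasterImage(img))
        r, c = np.unravel_index(fmap.values.argmax(), fmap.shape)
        assert 40 <= r <= 84 and 50 <= c <= 94  # box dilated by 10 px


class TestChannelSymmetries:
    def test_mirror_image_gives_mirrored_intensity_map(self, rng):
        img = rng.uniform(0, 1, (128, 160, 3))
        a = cp.extract_intensity_conspicuity(cp.RasterImage(img))
        b = cp.extract_intensity_conspicuity(cp.RasterImage(img[:, ::-1]))
        assert np.abs(a.values[:, ::-1] - b.values).max() < 1e-6

    def test_swapping_red_green_planes_preserves_color_map(self, rng):
        img = rng.uniform(0, 1, (96, 96, 3))
        a = cp.extract_color_conspicuity(cp.RasterImage(img))
        b = cp.extract_color_conspicuity(cp.RasterImage(img[..., [1, 0, 2]]))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_orientation_bank_closed_under_quarter_rotation(self, rng):
        img = rng.uniform(0, 1, (128, 128, 3))
        a = cp.extract_orientation_conspicuity(cp.RasterImage(img))
        b = cp.extract_orientation_conspicuity(
            cp.RasterImage(np.rot90(img).copy())
        )
        assert np.abs(np.rot90(a.values) - b.values).max() < 1e-4

    def test_translation_covariance_of_intensity_argmax(self):
        base = np.full((160, 160, 3), 0.1)
        base[40:56, 40:56] = 0.9
        shifted = np.roll(base, (24, 16), axis=(0, 1))
        a = cp.extract_intensity_conspicuity(cp.RasterImage(base)).values
        b = cp.extract_intensity_conspicuity(cp.RasterImage(shifted)).values
        ra, ca = np.unravel_index(a.argmax(), a.shape)
        rb, cb = np.unravel_index(b.argmax(), b.shape)
        assert abs(rb - ra - 24) <= 4 and abs(cb - ca - 16) <= 4


def _small_stimulus(kind: str, seed: int, bar_level: int = 2) -> "cp.SyntheticScene":
    return render_bar_stimulus(
        StimulusSpec(
            canvas=(256, 256),
            bar_level=bar_level,
            grid_shape=(5, 5),
            targets=(TargetSpec(kind),),
            seed=seed,
        )
    )


class TestPopOutLocalization:
    @pytest.mark.parametrize("kind", list(EXTRACTORS))
    @pytest.mark.parametrize("bar_level", [5, 10])
    def test_deviant_channel_peaks_at_target(self, kind, bar_level):
        scene = render_bar_stimulus(
            StimulusSpec(targets=(TargetSpec(kind),), bar_level=bar_level, seed=3)
        )
        fmap = EXTRACTORS[kind](scene.image)
        r, c = np.unravel_index(fmap.values.argmax(), fmap.shape)
        tx, ty = scene.target_positions[0]
        assert math.hypot(c - tx, r - ty) <= 10.0

    def test_feature_isolation_on_color_stimulus(self):
        """Orientation responses of target vs distractor glyphs agree while
        the color channel singles the target out."""
        scene = _small_stimulus("color", seed=5)
        omap = cp.extract_orientation_conspicuity(scene.image).values
        cmap = cp.extract_color_conspicuity(scene.image).values
        tx, ty = scene.target_positions[0]
        r, c = np.unravel_index(cmap.argmax(), cmap.shape)
        assert math.hypot(c - tx, r - ty) <= 10.0
        # orientation response at target is comparable to typical glyph response
        win = 8
        t_resp = omap[int(ty) - win : int(ty) + win, int(tx) - win : int(tx) + win].max()
        assert t_resp <= omap.max() * 1.0 + 1e-9
        assert abs(t_resp - np.percentile(omap[omap > 0.1], 75)) <= 0.4


class TestCombineSaliency:
    def test_single_channel_weight_recovers_that_map(self, bundle10):
        maps = bundle10.scenes[0].maps
        s = cp.combine_saliency(maps, (1.0, 0.0, 0.0))
        np.testing.assert_allclose(s.values, maps["color"].values, atol=1e-12)

    def test_zero_weights_give_zero_map(self, bundle10):
        maps = bundle10.scenes[0].maps
        s = cp.combine_saliency(maps, (0.0, 0.0, 0.0))
        assert s.values.max() == 0.0

    def test_equal_weights_match_pixelwise_mean(self, bundle10):
        maps = bundle10.scenes[0].maps
        s = cp.combine_saliency(maps, (1 / 3, 1 / 3, 1 / 3), rescale=False)
        expected = (
            maps["color"].values + maps["intensity"].values + maps["orientation"].values
        ) / 3.0
        np.testing.assert_allclose(s.values, expected, atol=1e-12)

    def test_shape_mismatch_rejected(self, bundle10, texture_image):
        maps = dict(bundle10.scenes[0].maps)
        maps["color"] = cp.FeatureMap("color", np.zeros((64, 64)))
        with pytest.raises(DimensionError):
            cp.combine_saliency(maps, (1, 1, 1))


class TestChannelConfig:
    def test_duplicate_gabor_angles_rejected(self):
        with pytest.raises(ValueError):
            ChannelConfig(gabor_orientations_deg=(0.0, 0.0, 90.0))

    def test_depth_without_any_pair_rejected(self):
        cfg = ChannelConfig(pyramid_depth=3)
        with pytest.raises(DimensionError):
            cfg.resolved_depth((256, 256))
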