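"""Unit and oracle tests for the 17 pixel-level features."""

import numpy as np
import pytest

from visrep import pixel_features as pf
from visrep.pixel_features import (
    FEATURE_NAMES,
    PixelFeatureExtractor,
    brightness,
    channel_stats,
    colorfulness,
    contrast,
    extract_features,
    hue_peak_count,
    naturalness,
    rgb_contrast,
    sharpness,
)

from _oracle import oracle_all_features, oracle_sharpness
from conftest import uniform_image


class TestChannelStats:
    def test_uniform_gray_is_constant(self):
        stats = channel_stats(uniform_image(128, 128, 128))
        for name in ("red", "green", "blue", "value"):
            assert stats[f"{name}_mean"] == pytest.approx(128.0)
            assert stats[f"{name}_variance"] == 0.0
        assert stats["saturation_mean"] == 0.0
        assert stats["saturation_variance"] == 0.0

    def test_black_white_pair_population_variance(self):
        img = np.array([[[0, 0, 0], [255, 255, 255]]], dtype=np.uint8)
        stats = channel_stats(img)
        assert stats["red_mean"] == pytest.approx(127.5)
        assert stats["red_variance"] == pytest.approx(16256.25)

    def test_pure_red_saturation_and_value(self):
        stats = channel_stats(uniform_image(255, 0, 0))
        assert stats["saturation_mean"] == pytest.approx(255.0)
        assert stats["value_mean"] == pytest.approx(255.0)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            channel_stats(np.zeros((0, 0, 3), dtype=np.uint8))


class TestScalarFeatures:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((255, 255, 255), 255.0), ((0, 0, 0), 0.0), ((0, 255, 0), 149.685)],
    )
    def test_brightness_closed_form(self, rgb, expected):
        assert brightness(uniform_image(*rgb)) == pytest.approx(expected)

    def test_colorfulness_closed_forms(self):
        assert colorfulness(uniform_image(100, 100, 100)) == 0.0
        # uniform pure red: 0.3 * sqrt(255^2 + 127.5^2)
        assert colorfulness(uniform_image(255, 0, 0)) == pytest.approx(
            0.3 * np.sqrt(255.0**2 + 127.5**2), rel=1e-12
        )
        half = np.zeros((2, 2, 3), dtype=np.uint8)
        half[0, :, 0] = 255  # red row
        half[1, :, 1] = 255  # green row
        assert colorfulness(half) == pytest.approx(293.25)

    def test_contrast_modes(self):
        img = np.array([[[0, 0, 0], [255, 255, 255]]], dtype=np.uint8)
        assert contrast(img, mode="sd") == pytest.approx(127.5)
        assert contrast(img, mode="literal") == pytest.approx(63.75)
        assert contrast(uniform_image(7, 7, 7)) == 0.0
        with pytest.raises(ValueError):
            contrast(img, mode="bogus")

    def test_rgb_contrast_half_black_half_white(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[1] = 255
        assert rgb_contrast(img) == pytest.approx(np.sqrt(3) * 127.5)
        assert rgb_contrast(uniform_image(42, 1, 200)) == 0.0

    def test_naturalness_range_and_degenerate(self):
        assert naturalness(uniform_image(128, 128, 128)) == 0.0  # nothing qualifies
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        assert 0.0 <= naturalness(img) <= 1.0

    def test_naturalness_sky_at_natural_saturation_is_one(self):
        # sky hue 220 deg, saturation 0.43 -> group score exp(0) = 1
        from matplotlib.colors import hsv_to_rgb

        rgb = np.round(hsv_to_rgb([220 / 360, 0.43, 0.55]) * 255).astype(np.uint8)
        img = uniform_image(*rgb)
        lum = 0.299 * rgb[0] + 0.587 * rgb[1] + 0.114 * rgb[2]
        assert 20.0 <= lum / 255 * 100 <= 80.0  # pixel qualifies
        assert naturalness(img) == pytest.approx(1.0, abs=1e-3)


class TestSharpness:
    def test_uniform_image_is_zero(self):
        assert sharpness(uniform_image(200, 200, 200)) == 0.0

    def test_single_white_pixel_matches_hand_oracle(self):
        img = np.zeros((3, 3, 3), dtype=np.uint8)
        img[1, 1] = 255
        assert sharpness(img) == pytest.approx(oracle_sharpness(img), rel=1e-12)

    def test_sum_equals_mean_times_pixels(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, size=(6, 5, 3), dtype=np.uint8)
        assert sharpness(img, "sum") == pytest.approx(sharpness(img, "mean") * 30)


class TestHuePeaks:
    def test_uniform_saturated_red_has_one_mode(self):
        assert hue_peak_count(uniform_image(255, 0, 0)) == 1

    def test_red_and_green_halves_have_two_modes(self):
        img = np.zeros((2, 4, 3), dtype=np.uint8)
        img[0, :, 0] = 255
        img[1, :, 1] = 255
        assert hue_peak_count(img) == 2

    def test_gray_image_has_no_modes(self):
        assert hue_peak_count(uniform_image(90, 90, 90)) == 0


class TestOracleEquivalence:
    def test_random_images_match_loop_reference(self):
        """All 17 features agree with a literal loop-based reference on
        100 random 8x8 images to 1e-9 relative tolerance."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            img = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
            got = extract_features(img).to_dict()
            want = oracle_all_features(img)
            for name in FEATURE_NAMES:
                assert got[name] == pytest.approx(
                    want[name], rel=1e-9, abs=1e-9
                ), name

    def test_uniform_gray_composite(self):
        vec = extract_features(uniform_image(128, 128, 128)).to_dict()
        for name in FEATURE_NAMES:
            if name.endswith("_mean") and name not in ("saturation_mean",):
                continue
            if name == "brightness":
                continue
            assert vec[name] == 0.0, name


class TestInvariancesAndExtractor:
    def test_pixel_duplication_leaves_intensive_features_unchanged(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        doubled = np.repeat(img, 2, axis=1)
        a = extract_features(img).to_dict()
        b = extract_features(doubled).to_dict()
        intensive = [
            n
            for n in FEATURE_NAMES
            if n.endswith(("_mean", "_variance"))
            or n in ("brightness", "colorfulness", "naturalness", "contrast", "hue_peaks")
        ]
        for name in intensive:
            assert b[name] == pytest.approx(a[name], rel=1e-9), name

    def test_adding_saturated_pixels_does_not_decrease_colorfulness(self):
        gray = np.full((8, 8, 3), 128, dtype=np.uint8)
        prev = colorfulness(gray)
        img = gray.copy()
        for k in (4, 16, 32):
            img.reshape(-1, 3)[:k] = (255, 0, 0)
            cur = colorfulness(img)
            assert cur >= prev - 1e-12
            prev = cur

    def test_extractor_transform_is_deterministic_and_ordered(self):
        rng = np.random.default_rng(1)
        imgs = [rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8) for _ in range(3)]
        ex = PixelFeatureExtractor()
        out1 = ex.fit_transform(imgs)
        out2 = ex.fit_transform(imgs)
        assert out1.shape == (3, 17)
        np.testing.assert_array_equal(out1, out2)
        assert list(ex.get_feature_names_out()) == list(FEATURE_NAMES)

    def test_grayscale_and_alpha_inputs_are_coerced(self):
        gray2d = np.full((8, 8), 77, dtype=np.uint8)
        rgba = np.dstack([np.full((8, 8, 3), 77, dtype=np.uint8), np.full((8, 8), 9, np.uint8)])
        assert pf.as_rgb_array(gray2d).shape == (8, 8, 3)
        assert brightness(rgba) == pytest.approx(77.0)

    def test_extractor_sklearn_param_interface(self):
        ex = PixelFeatureExtractor().set_params(contrast_mode="literal")
        assert ex.get_params()["contrast_mode"] == "literal"
        with pytest.raises(ValueError):
            ex.set_params(nonsense=1)
        with pytest.raises(ValueError):
            PixelFeatureExtractor(contrast_mode="bogus").fit([])
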