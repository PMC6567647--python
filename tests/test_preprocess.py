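import numpy as np
import pytest
from scipy import ndimage

from cryopick.errors import DegenerateInputError, InvalidConfigError
from cryopick.io import Micrograph
from cryopick.preprocess import (PreprocessConfig, StepToggles, StretchLimits,
                                 adjust_intensity, clahe, equalize_histogram,
                                 guided_filter, midrange_stretch, morph_close,
                                 preprocess, stretch_limits, wiener_restore,
                                 with_toggles)


def fisher_separation(pixels, particle_mask):
    fg = pixels[particle_mask]
    bg = pixels[~particle_mask]
    return (bg.mean() - fg.mean()) ** 2 / (bg.var() + fg.var())


class TestStretchLimits:
    def test_ramp_hits_percentile_values(self, ramp_micrograph):
        # sort-and-index oracle on the flattened pixels
        v = np.sort(ramp_micrograph.pixels, axis=None)
        n = v.size
        expected_low = v[int(np.ceil(0.02 * n)) - 1]
        expected_high = v[int(np.ceil(0.98 * n)) - 1]
        lims = stretch_limits(ramp_micrograph, 0.02, 0.02)
        assert lims.low == pytest.approx(expected_low)
        assert lims.high == pytest.approx(expected_high)

    def test_constant_image_falls_back(self):
        img = Micrograph(pixels=np.full((32, 32), 0.5))
        with pytest.warns(UserWarning, match="degenerate"):
            lims = stretch_limits(img)
        assert (lims.low, lims.high) == (0.0, 1.0)

    def test_interior_limits_representable(self):
        lims = StretchLimits(0.2, 0.8)
        assert lims.low == 0.2 and lims.high == 0.8


class TestMidrangeStretch:
    def test_divides_by_max(self):
        img = Micrograph(pixels=np.array([[0.2, 0.4]]))
        np.testing.assert_allclose(midrange_stretch(img).pixels, [[0.5, 1.0]])

    def test_identity_when_max_is_one(self):
        img = Micrograph(pixels=np.array([[0.3, 1.0]]))
        np.testing.assert_allclose(midrange_stretch(img).pixels, img.pixels)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            midrange_stretch(Micrograph(pixels=np.zeros((8, 8))))


class TestAdjustIntensity:
    @pytest.mark.parametrize("value,expected", [
        (0.5, 0.5),          # midpoint maps to midpoint
        (0.1, 0.0),          # below low clips to 0
        (0.65, 0.75),        # (0.65 - 0.2) / 0.6
        (0.9, 1.0),          # above high clips to 1
    ])
    def test_linear_map_with_clipping(self, value, expected):
        img = Micrograph(pixels=np.full((4, 4), value))
        out = adjust_intensity(img, StretchLimits(0.2, 0.8))
        np.testing.assert_allclose(out.pixels, expected, atol=1e-12)

    def test_monotone_nondecreasing(self, ramp_micrograph):
        out = adjust_intensity(ramp_micrograph, StretchLimits(0.1, 0.7))
        row = out.pixels[0]
        assert np.all(np.diff(row) >= 0)


class TestEqualizeHistogram:
    def test_two_level_image_maps_to_cdf(self):
        pixels = np.zeros((32, 32))
        pixels[:, 16:] = 1.0
        out = equalize_histogram(Micrograph(pixels=pixels))
        # CDF(0) = 0.5, CDF(1) = 1.0
        np.testing.assert_allclose(np.unique(out.pixels), [0.5, 1.0],
                                   atol=1e-6)

    def test_uniform_input_near_identity(self, ramp_micrograph):
        # CDF convention shifts each level upward by its own bin mass, so
        # the pointwise change is bounded by ~1.5 bin widths on a ramp
        out = equalize_histogram(ramp_micrograph, n_bins=256)
        assert np.abs(out.pixels - ramp_micrograph.pixels).max() < 1.5 / 256

    def test_flattens_skewed_histogram(self):
        rng = np.random.default_rng(0)
        img = Micrograph(pixels=rng.beta(5, 2, size=(128, 128)))
        out = equalize_histogram(img)

        def cv(pixels):
            counts, _ = np.histogram(pixels, bins=32, range=(0, 1))
            return counts.std() / counts.mean()

        assert cv(out.pixels) < cv(img.pixels)


class TestWienerRestore:
    def test_constant_image_unchanged(self):
        img = Micrograph(pixels=np.full((32, 32), 0.4))
        np.testing.assert_allclose(wiener_restore(img).pixels, 0.4)

    def test_reduces_noise_variance(self):
        rng = np.random.default_rng(1)
        img = Micrograph(pixels=np.clip(
            0.5 + rng.normal(0, 0.05, size=(128, 128)), 0, 1))
        out = wiener_restore(img, window=5)
        assert out.pixels.var() < img.pixels.var()

    def test_step_edge_stays_put(self):
        # 1D-profile oracle: the 50% crossing must stay within 1 px
        pixels = np.zeros((33, 64))
        pixels[:, 32:] = 1.0
        out = wiener_restore(Micrograph(pixels=pixels), window=5)
        profile = out.pixels[16]
        crossing = np.argmax(profile >= 0.5)
        assert abs(crossing - 32) <= 1


class TestClahe:
    def test_constant_image_stays_constant(self):
        img = Micrograph(pixels=np.full((64, 64), 0.3))
        out = clahe(img)
        assert np.ptp(out.pixels) < 1e-9

    def test_single_tile_no_clip_matches_global_equalization(self):
        rng = np.random.default_rng(2)
        img = Micrograph(pixels=rng.beta(2, 5, size=(128, 128)))
        local = clahe(img, tiles=(1, 1), clip=1.0, n_bins=256)
        global_ = equalize_histogram(img, n_bins=256)
        assert np.abs(local.pixels - global_.pixels).max() < 2 / 256

    def test_boosts_local_contrast_of_dim_disk(self, dim_disk_micrograph):
        img, truth = dim_disk_micrograph
        p = truth.particles[0]
        y, x = int(p.center[0]), int(p.center[1])
        sl = (slice(max(y - 16, 0), y + 16), slice(max(x - 16, 0), x + 16))
        out = clahe(img)
        assert out.pixels[sl].std() > img.pixels[sl].std()

    def test_tile_grid_larger_than_image_rejected(self):
        img = Micrograph(pixels=np.zeros((32, 32)))
        with pytest.raises(InvalidConfigError):
            clahe(img, tiles=(64, 64))


class TestGuidedFilter:
    def test_constant_unchanged(self):
        img = Micrograph(pixels=np.full((32, 32), 0.7))
        np.testing.assert_allclose(guided_filter(img).pixels, 0.7, atol=1e-9)

    def test_large_eps_limit_is_double_box_mean(self):
        # closed form: a -> 0, b -> window mean, averaged over windows
        rng = np.random.default_rng(3)
        img = Micrograph(pixels=rng.uniform(0, 1, size=(64, 64)))
        out = guided_filter(img, window=5, eps=1e6)
        expected = ndimage.uniform_filter(
            ndimage.uniform_filter(img.pixels, size=5, mode="reflect"),
            size=5, mode="reflect")
        assert np.abs(out.pixels - expected).max() < 1e-3

    def test_edge_preserved_while_flat_region_smooths(self):
        rng = np.random.default_rng(4)
        pixels = np.zeros((33, 64))
        pixels[:, 32:] = 1.0
        noisy = np.clip(pixels + rng.normal(0, 0.05, pixels.shape), 0, 1)
        out = guided_filter(Micrograph(pixels=noisy), window=5, eps=1e-3)
        profile = out.pixels[16]
        edge_contrast = profile[40:60].mean() - profile[4:24].mean()
        assert edge_contrast >= 0.8  # >= 80% of the unit step retained
        flat_in = noisy[4:29, 4:24].var()
        flat_out = out.pixels[4:29, 4:24].var()
        assert flat_out < flat_in

    def test_nonpositive_eps_rejected(self):
        img = Micrograph(pixels=np.zeros((16, 16)))
        with pytest.raises(InvalidConfigError):
            guided_filter(img, eps=0.0)


class TestMorphClose:
    def test_idempotent(self):
        rng = np.random.default_rng(5)
        img = Micrograph(pixels=rng.uniform(0, 1, size=(48, 48)))
        once = morph_close(img, se_size=5)
        twice = morph_close(once, se_size=5)
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_removes_isolated_dark_pixel(self):
        pixels = np.ones((7, 7))
        pixels[3, 3] = 0.0
        out = morph_close(Micrograph(pixels=pixels), se_size=5)
        assert out.pixels[3, 3] == 1.0

    def test_constant_unchanged(self):
        img = Micrograph(pixels=np.full((16, 16), 0.2))
        np.testing.assert_array_equal(morph_close(img).pixels, img.pixels)


class TestFullChain:
    def test_all_toggles_off_is_identity(self, dim_disk_micrograph):
        img, _ = dim_disk_micrograph
        cfg = PreprocessConfig(step_toggles=StepToggles.none())
        np.testing.assert_array_equal(preprocess(img, cfg).pixels, img.pixels)

    def test_deterministic(self, dim_disk_micrograph):
        img, _ = dim_disk_micrograph
        a = preprocess(img, PreprocessConfig())
        b = preprocess(img, PreprocessConfig())
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_output_in_unit_interval(self, dim_disk_micrograph):
        img, _ = dim_disk_micrograph
        out = preprocess(img, PreprocessConfig())
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_separation_improves_over_raw_and_over_adjust_alone(
            self, dim_disk_micrograph):
        img, truth = dim_disk_micrograph
        full = preprocess(img, PreprocessConfig())
        adjust_only = preprocess(img, with_toggles(
            PreprocessConfig(step_toggles=StepToggles.none()), adjust=True))
        raw_sep = fisher_separation(img.pixels, truth.particle_mask)
        adj_sep = fisher_separation(adjust_only.pixels, truth.particle_mask)
        full_sep = fisher_separation(full.pixels, truth.particle_mask)
        assert full_sep > raw_sep
        assert full_sep >= adj_sep

    def test_step_errors_name_the_step(self):
        img = Micrograph(pixels=np.zeros((32, 32)))  # all-zero: adjust fails
        with pytest.raises(DegenerateInputError, match="intensity_adjust"):
            preprocess(img, PreprocessConfig())
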