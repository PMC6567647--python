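import math

import numpy as np
import pytest

from cht_oracle import brute_accumulator, brute_candidates
from conftest import rasterize_disk, rasterize_square
from cryopick.clean import CleaningParams
from cryopick.detect import (DetectParams, PipelineConfig, boundary_pixels,
                             cht_accumulator, cht_detect, feret_square_refine,
                             pick, square_detect)
from cryopick.errors import InvalidConfigError
from cryopick.synthetic import SceneSpec, generate_scene


class TestBoundaryPixels:
    def test_filled_5x5_square_has_16(self):
        mask = rasterize_square((9, 9), (2, 2), 5)
        assert len(boundary_pixels(mask)) == 16

    def test_single_pixel(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 4] = True
        np.testing.assert_array_equal(boundary_pixels(mask), [[3, 4]])

    def test_empty(self):
        assert len(boundary_pixels(np.zeros((8, 8), dtype=bool))) == 0

    def test_image_border_counts_as_background(self):
        mask = np.ones((5, 5), dtype=bool)
        assert len(boundary_pixels(mask)) == 16  # the 5x5 frame


class TestChtDetect:
    def test_single_disk_recovered(self):
        mask = rasterize_disk((64, 64), (32, 32), 10)
        (cand,) = cht_detect(mask, 5, 15)
        assert math.hypot(cand.center[0] - 32, cand.center[1] - 32) <= 1.0
        assert abs(cand.radius_or_halfside - 10) <= 1.0

    def test_two_disks_40px_apart(self):
        mask = rasterize_disk((96, 96), (30, 25), 10) \
            | rasterize_disk((96, 96), (30, 65), 10)
        cands = cht_detect(mask, 5, 15)
        assert len(cands) == 2
        centers = sorted((round(c.center[1]),) for c in cands)
        assert centers == [(25,), (65,)]

    def test_empty_mask(self):
        assert cht_detect(np.zeros((64, 64), dtype=bool), 5, 12) == []

    def test_oversized_radius_rejected(self):
        with pytest.raises(InvalidConfigError):
            cht_detect(np.zeros((64, 64), dtype=bool), 5, 40)

    def test_accumulator_matches_brute_force(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((48, 48), dtype=bool)
        for _ in range(2):
            cy, cx = rng.integers(12, 36, size=2)
            mask |= rasterize_disk(mask.shape, (cy, cx), rng.integers(5, 11))
        np.testing.assert_array_equal(cht_accumulator(mask, 4, 12),
                                      brute_accumulator(mask, 4, 12))

    @pytest.mark.parametrize("n_disks,seed", [(0, 1), (1, 2), (2, 3), (3, 4)])
    def test_candidates_equal_brute_force(self, n_disks, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((64, 64), dtype=bool)
        for _ in range(n_disks):
            cy, cx = rng.integers(14, 50, size=2)
            mask |= rasterize_disk(mask.shape, (cy, cx), rng.integers(5, 13))
        r_min, r_max, frac, sep = 4, 12, 0.35, 4.0
        _acc, expected = brute_candidates(mask, r_min, r_max, frac, sep)
        got = {(int(round(c.center[0])), int(round(c.center[1])),
                int(c.radius_or_halfside))
               for c in cht_detect(mask, r_min, r_max, frac, sep)}
        assert got == expected

    @pytest.mark.parametrize("r", [5, 8, 12, 17, 21, 26, 30])
    def test_parameter_recovery_noiseless(self, r):
        # +-20% radius band, as the pipeline derives it from expected size
        n = 2 * r + 31
        c = n // 2
        mask = rasterize_disk((n, n), (c, c), r)
        p = DetectParams.for_expected_radius(r)
        cands = cht_detect(mask, p.r_min, p.r_max)
        assert len(cands) == 1
        assert abs(cands[0].radius_or_halfside - r) <= 1.0
        assert math.hypot(cands[0].center[0] - c, cands[0].center[1] - c) <= 1.0

    def test_translation_equivariance(self):
        base = np.zeros((96, 96), dtype=bool)
        base |= rasterize_disk(base.shape, (30, 30), 9)
        base |= rasterize_disk(base.shape, (60, 55), 7)
        shifted = np.roll(base, (5, -7), axis=(0, 1))
        a = sorted((round(c.center[0], 3), round(c.center[1], 3))
                   for c in cht_detect(base, 5, 12))
        b = sorted((round(c.center[0], 3), round(c.center[1], 3))
                   for c in cht_detect(shifted, 5, 12))
        for (ya, xa), (yb, xb) in zip(a, b):
            assert yb - ya == pytest.approx(5, abs=1e-9)
            assert xb - xa == pytest.approx(-7, abs=1e-9)

    def test_min_separation_enforced(self):
        rng = np.random.default_rng(5)
        mask = np.zeros((128, 128), dtype=bool)
        for _ in range(5):
            cy, cx = rng.integers(15, 113, size=2)
            mask |= rasterize_disk(mask.shape, (cy, cx), 9)
        sep = 12.0
        cands = cht_detect(mask, 5, 12, min_separation=sep)
        for i, a in enumerate(cands):
            for b in cands[i + 1:]:
                d = math.hypot(a.center[0] - b.center[0],
                               a.center[1] - b.center[1])
                assert d >= sep - 1.0  # sub-pixel refinement can shave < 1 px


class TestSquareDetect:
    def test_20x20_square(self):
        mask = rasterize_square((64, 64), (20, 20), 20)
        (cand,) = square_detect(mask, side_min=10, side_max=40)
        assert cand.radius_or_halfside == pytest.approx(10, abs=0.5)
        assert cand.center == pytest.approx((29.5, 29.5))
        assert cand.score == 1.0

    def test_too_small_component_skipped(self):
        mask = rasterize_square((32, 32), (10, 10), 5)
        assert square_detect(mask, side_min=10, side_max=40) == []

    def test_empty(self):
        assert square_detect(np.zeros((16, 16), dtype=bool), 5, 20) == []


class TestFeretRefine:
    def test_axis_aligned_square_halfside(self):
        mask = rasterize_square((40, 40), (15, 15), 10)
        rough = square_detect(mask, 5, 20)
        refined = feret_square_refine(mask, rough, smooth_sigma=0.0)
        assert len(refined) == 1
        # feret = 9*sqrt(2) -> halfside 4.5
        assert refined[0].radius_or_halfside == pytest.approx(4.5)

    def test_merged_component_dropped_as_outlier(self):
        mask = np.zeros((80, 120), dtype=bool)
        for i in range(3):
            mask |= rasterize_square(mask.shape, (10, 8 + 36 * i), 14)
        merged = rasterize_square(mask.shape, (45, 20), 14) \
            | rasterize_square(mask.shape, (45, 33), 14)  # two fused squares
        mask |= merged
        rough = square_detect(mask, 8, 40)
        assert len(rough) == 4
        refined = feret_square_refine(mask, rough, outlier_factor=1.5)
        assert len(refined) == 3
        assert all(c.radius_or_halfside < 10 for c in refined)

    def test_single_candidate_is_its_own_median(self):
        mask = rasterize_square((40, 40), (12, 12), 12)
        refined = feret_square_refine(mask, square_detect(mask, 5, 20))
        assert len(refined) == 1


class TestEndToEndPick:
    def test_circle_only_mode_yields_circles(self):
        spec = SceneSpec(height=256, width=256, n_circles=5,
                         radius_range=(10, 12), n_squares=3,
                         side_range=(18, 24), noise_sigma=0.05,
                         min_separation=8.0, seed=11)
        img, _ = generate_scene(spec)
        cfg = PipelineConfig(clean=CleaningParams.for_expected_radius(11),
                             detect=DetectParams.for_expected_radius(
                                 11, shape="circle"))
        ps = pick(img, cfg)
        assert len(ps) > 0
        assert all(p.shape == "circle" for p in ps)

    def test_mixed_fixture_yields_both_shapes(self):
        spec = SceneSpec(height=320, width=320, n_circles=5,
                         radius_range=(10, 12), n_squares=4,
                         side_range=(20, 26), noise_sigma=0.08,
                         min_separation=8.0, seed=12)
        img, _ = generate_scene(spec)
        cfg = PipelineConfig(
            clean=CleaningParams.for_expected_radius(11),
            detect=DetectParams.for_expected_radius(
                11, shape="both", side_min=14, side_max=34))
        shapes = {p.shape for p in pick(img, cfg)}
        assert shapes == {"circle", "square"}

    def test_deterministic_with_interval_clustering(self):
        spec = SceneSpec(height=256, width=256, n_circles=6,
                         radius_range=(10, 12), noise_sigma=0.1,
                         min_separation=8.0, seed=13)
        img, _ = generate_scene(spec)
        cfg = PipelineConfig(clean=CleaningParams.for_expected_radius(11),
                             detect=DetectParams.for_expected_radius(11))
        a, b = pick(img, cfg), pick(img, cfg)
        assert [p.to_record() for p in a] == [p.to_record() for p in b]
        assert a.params_fingerprint == b.params_fingerprint
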