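"""Spot-detection stages: filtering, extrema, prominence, areas, composition."""

import numpy as np
import pytest

from conftest import brute_force_extrema, flood_fill_components
from pidspot.detection import (
    DetectionParams,
    ExtremumPoint,
    apply_noise_tolerance,
    binarize,
    clamp_nonnegative,
    detect,
    find_local_extrema,
    high_pass,
    integrate_spots,
    label_spot_areas,
    match_nearest_minimum,
)
from pidspot.image_io import Image12
from pidspot.synthetic import SceneParams, generate_image


class TestHighPass:
    def test_constant_image_maps_to_zero(self):
        out = clamp_nonnegative(high_pass(np.full((20, 20), 500.0), sigma=2.0))
        assert np.allclose(out, 0.0)

    def test_impulse_preserved_but_attenuated(self):
        img = np.zeros((21, 21))
        img[10, 10] = 4095
        out = high_pass(img, sigma=2.0)
        assert out[10, 10] == np.max(out)
        assert 0 < out[10, 10] < 4095

    def test_linear_ramp_interior_near_zero(self):
        # a symmetric blur leaves a linear ramp invariant away from borders
        ramp = np.tile(np.linspace(0, 4095, 200), (50, 1))
        out = high_pass(ramp, sigma=2.0)
        assert np.abs(out[10:-10, 10:-10]).max() <= 2.0

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            high_pass(np.zeros((5, 5)), sigma=0)


class TestFindLocalExtrema:
    def test_constant_image_has_no_extrema(self):
        maxima, minima = find_local_extrema(np.full((10, 10), 7.0))
        assert maxima == [] and minima == []

    def test_single_peak(self):
        img = np.zeros((5, 5))
        img[2, 2] = 100
        maxima, minima = find_local_extrema(img)
        assert maxima == [ExtremumPoint(x=2, y=2, value=100.0, kind="maximum")]
        assert minima == []  # zero plateau: ties are never minima

    def test_border_pixels_never_extrema(self):
        img = np.zeros((5, 5))
        img[0, 2] = 50  # brightest pixel, but on the border
        maxima, _ = find_local_extrema(img)
        assert all(p.y != 0 for p in maxima)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="3x3"):
            find_local_extrema(np.zeros((2, 5)))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            img = rng.integers(0, 50, (16, 16)).astype(float)
            maxima, minima = find_local_extrema(img)
            bmax, bmin = brute_force_extrema(img)
            assert {(p.x, p.y, p.value) for p in maxima} == set(bmax)
            assert {(p.x, p.y, p.value) for p in minima} == set(bmin)

    def test_no_two_maxima_adjacent(self, rng):
        # strict inequality makes 8-adjacent maxima impossible
        img = rng.integers(0, 100, (30, 30)).astype(float)
        maxima, _ = find_local_extrema(img)
        pts = [(p.x, p.y) for p in maxima]
        for i, (x1, y1) in enumerate(pts):
            for x2, y2 in pts[i + 1 :]:
                assert max(abs(x1 - x2), abs(y1 - y2)) > 1


def _mx(x, y, v):
    return ExtremumPoint(x=x, y=y, value=v, kind="maximum")


def _mn(x, y, v):
    return ExtremumPoint(x=x, y=y, value=v, kind="minimum")


class TestMatchNearestMinimum:
    def test_picks_closer_minimum(self):
        m = match_nearest_minimum(_mx(0, 0, 100), [_mn(3, 0, 5), _mn(5, 0, 1)], 10)
        assert (m.x, m.y) == (3, 0)

    def test_distance_tie_broken_by_lower_value(self):
        m = match_nearest_minimum(_mx(0, 0, 100), [_mn(3, 0, 9), _mn(-3, 0, 4)], 10)
        assert m.value == 4

    def test_full_tie_broken_by_y_then_x(self):
        # all candidates at distance 3 with value 4: smallest y wins, then smallest x
        m = match_nearest_minimum(
            _mx(0, 0, 100), [_mn(0, 3, 4), _mn(3, 0, 4), _mn(-3, 0, 4)], 10
        )
        assert (m.x, m.y) == (-3, 0)

    def test_none_outside_radius(self):
        assert match_nearest_minimum(_mx(0, 0, 100), [_mn(20, 0, 5)], 10) is None

    def test_matches_exhaustive_search(self, rng):
        for _ in range(200):
            mx = _mx(int(rng.integers(0, 30)), int(rng.integers(0, 30)), 100)
            minima = [
                _mn(int(rng.integers(0, 30)), int(rng.integers(0, 30)), float(rng.integers(0, 50)))
                for _ in range(rng.integers(0, 15))
            ]
            got = match_nearest_minimum(mx, minima, 8.0)
            best = None
            for m in minima:
                d2 = (m.x - mx.x) ** 2 + (m.y - mx.y) ** 2
                if d2 > 64:
                    continue
                key = (d2, m.value, m.y, m.x)
                if best is None or key < best[0]:
                    best = (key, m)
            assert got == (best[1] if best else None)


class TestNoiseTolerance:
    def test_difference_below_tolerance_rejected(self):
        kept = apply_noise_tolerance([_mx(5, 5, 100)], [_mn(7, 5, 69)], 32, 10)
        assert kept == []

    def test_difference_above_tolerance_accepted(self):
        kept = apply_noise_tolerance([_mx(5, 5, 200)], [_mn(7, 5, 100)], 32, 10)
        assert len(kept) == 1

    def test_boundary_exactly_tolerance_accepted(self):
        kept = apply_noise_tolerance([_mx(5, 5, 132)], [_mn(7, 5, 100)], 32, 10)
        assert len(kept) == 1

    def test_unmatched_maximum_compared_to_zero_background(self):
        assert apply_noise_tolerance([_mx(5, 5, 31)], [], 32, 10) == []
        assert len(apply_noise_tolerance([_mx(5, 5, 32)], [], 32, 10)) == 1

    def test_raising_tolerance_never_gains_points(self, rng):
        maxima = [
            _mx(int(x), int(y), float(v))
            for x, y, v in zip(
                rng.integers(0, 50, 40), rng.integers(0, 50, 40), rng.integers(1, 300, 40)
            )
        ]
        minima = [
            _mn(int(x), int(y), float(v))
            for x, y, v in zip(
                rng.integers(0, 50, 20), rng.integers(0, 50, 20), rng.integers(0, 100, 20)
            )
        ]
        counts = [
            len(apply_noise_tolerance(maxima, minima, tol, 10))
            for tol in (8, 16, 32, 64, 128)
        ]
        assert counts == sorted(counts, reverse=True)


class TestBinarizeAndLabel:
    def test_threshold_boundary_inclusive(self):
        mask = binarize(np.array([[15.0, 16.0, 17.0]] * 3), 16)
        assert mask[0].tolist() == [False, True, True]

    def test_all_zero_empty_mask(self):
        assert not binarize(np.zeros((5, 5)), 16).any()

    def test_foreground_monotone_in_threshold(self, rng):
        img, _ = generate_image(SceneParams(seed=3, n_spots=30))
        hp = clamp_nonnegative(high_pass(img, 2.0))
        areas = [binarize(hp, t).sum() for t in (8, 16, 32)]
        assert areas[0] >= areas[1] >= areas[2]

    def test_diagonal_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(label_spot_areas(mask, connectivity=8)) == 1
        assert len(label_spot_areas(mask, connectivity=4)) == 2

    def test_empty_mask_no_regions(self):
        assert label_spot_areas(np.zeros((5, 5), bool)) == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_components_match_flood_fill_oracle(self, rng, connectivity):
        for _ in range(20):
            mask = rng.random((15, 15)) < 0.4
            regions = label_spot_areas(mask, connectivity)
            got = {frozenset(zip(r.ys.tolist(), r.xs.tolist())) for r in regions}
            assert got == set(flood_fill_components(mask, connectivity))


class TestIntegrateSpots:
    def _setup(self):
        filtered = np.zeros((10, 10))
        filtered[2:4, 2:4] = 20.0  # region A
        filtered[7, 7] = 50.0  # region B
        mask = binarize(filtered, 16)
        return filtered, label_spot_areas(mask)

    def test_region_without_positive_point_dropped(self):
        filtered, regions = self._setup()
        spots = integrate_spots([_mx(7, 7, 50.0)], regions, filtered)
        assert len(spots) == 1
        assert spots[0].area_px == 1 and spots[0].integrated_signal == 50.0

    def test_two_maxima_in_one_region_merge_to_one_spot(self):
        filtered, regions = self._setup()
        spots = integrate_spots([_mx(2, 2, 20.0), _mx(3, 3, 20.0)], regions, filtered)
        assert len(spots) == 1
        assert spots[0].n_positive_maxima == 2
        assert spots[0].area_px == 4
        assert spots[0].integrated_signal == pytest.approx(80.0)

    def test_point_outside_all_regions_dropped(self):
        filtered, regions = self._setup()
        assert integrate_spots([_mx(0, 0, 99.0)], regions, filtered) == []

    def test_every_region_pixel_at_least_threshold(self):
        img, _ = generate_image(SceneParams(seed=5))
        params = DetectionParams()
        hp = clamp_nonnegative(high_pass(img, params.highpass_sigma))
        mask = binarize(hp, params.binarize_threshold)
        for reg in label_spot_areas(mask):
            assert (hp[reg.ys, reg.xs] >= params.binarize_threshold).all()


class TestDetect:
    def test_all_zero_image_empty(self):
        assert detect(Image12(np.zeros((20, 20), dtype=np.uint16))) == []

    def test_deterministic(self):
        img, _ = generate_image(SceneParams(seed=7))
        assert detect(img) == detect(img)

    def test_dc_offset_invariance(self):
        img, _ = generate_image(
            SceneParams(seed=8, background_mean_adu=300, n_spots=20)
        )
        shifted = Image12(np.clip(img.pixels.astype(int) + 300, 0, 4095))
        from conftest import assert_spot_lists_close

        assert_spot_lists_close(detect(shifted), detect(img))

    def test_translation_equivariance(self):
        params = SceneParams(seed=9, n_spots=15, width=200, height=150,
                             border_margin_px=30)
        img, _ = generate_image(params)
        dx, dy = 7, 5
        moved = np.full_like(img.pixels, 400)
        moved[dy:, dx:] = img.pixels[:-dy, :-dx]
        base = detect(img)
        shifted = detect(Image12(moved))
        base_c = sorted((s.centroid_x, s.centroid_y) for s in base)
        shift_c = sorted((s.centroid_x - dx, s.centroid_y - dy) for s in shifted)
        # interior spots must translate exactly; allow border-sourced diffs
        matched = 0
        for (x1, y1) in base_c:
            if any(abs(x1 - x2) < 0.25 and abs(y1 - y2) < 0.25 for x2, y2 in shift_c):
                matched += 1
        assert matched >= len(base_c) - 1

    def test_planted_spots_recovered_without_confusers(self):
        params = SceneParams(
            seed=11, n_spots=50, width=600, height=400,
            background_amplitude_adu=0, read_noise_sd=0, shot_noise=False,
        )
        img, truth = generate_image(params)
        spots = detect(img)
        assert len(spots) == 50
        det = sorted((s.centroid_x, s.centroid_y) for s in spots)
        for x, y in zip(truth.xs, truth.ys):
            assert min((dx - x) ** 2 + (dy - y) ** 2 for dx, dy in det) <= 4.0

    def test_raising_binarize_threshold_never_gains_spots(self):
        img, _ = generate_image(SceneParams(seed=13))
        n = [
            len(detect(img, DetectionParams(binarize_threshold=t)))
            for t in (8, 16, 32, 64)
        ]
        assert n == sorted(n, reverse=True)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(noise_tolerance=0)
        with pytest.raises(ValueError):
            DetectionParams(connectivity=6)
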