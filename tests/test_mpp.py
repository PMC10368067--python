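"""Unit and property tests for the marked-point-process detector."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octquant.mpp import (
    Configuration,
    MPPParams,
    Rectangle,
    brute_force_minimize,
    candidate_data_terms,
    configuration_energy,
    contrast_statistic,
    detect_slice,
    greedy_minimize,
    minimize_energy,
    overlaps,
    quality,
    rasterize,
    rectangle_energy,
)

from conftest import vitreous_roi


class TestContrastStatistic:
    def test_constant_image_gives_zero(self):
        img = np.full((20, 20), 0.3)
        assert contrast_statistic(img, Rectangle(10, 10, 4, 4), 2) == 0.0

    def test_hand_computed_value(self):
        # interior {10,10,12,12}: mean 11, population var 1;
        # crown (width-1 ring of 12 px) six 3s and six 7s: mean 5, var 4
        # -> x = (11-5)^2 / (1+4) = 7.2
        img = np.zeros((10, 10))
        img[4:6, 4:6] = [[10, 10], [12, 12]]
        ring = [(3, 3), (3, 4), (3, 5), (3, 6), (4, 3), (5, 3), (4, 6), (5, 6), (6, 3), (6, 4), (6, 5), (6, 6)]
        for k, (r, c) in enumerate(ring):
            img[r, c] = 3 if k % 2 == 0 else 7
        x = contrast_statistic(img, Rectangle(5, 5, 2, 2), 1)
        assert x == pytest.approx(7.2, abs=1e-12)

    def test_zero_variance_unequal_means_is_infinite(self):
        img = np.zeros((12, 12))
        img[4:8, 4:8] = 1.0
        assert math.isinf(contrast_statistic(img, Rectangle(6, 6, 4, 4), 2))

    def test_rectangle_filling_image_has_no_crown(self):
        img = np.ones((6, 6))
        with pytest.raises(ValueError, match="crown"):
            contrast_statistic(img, Rectangle(3, 3, 6, 6), 2)

    def test_rectangle_outside_image_rejected(self):
        with pytest.raises(ValueError):
            contrast_statistic(np.ones((8, 8)), Rectangle(0, 0, 6, 6), 1)


class TestQuality:
    @pytest.mark.parametrize("form", ["printed", "corrected"])
    def test_zero_contrast_is_one(self, form):
        assert quality(0.0, 3.0, form) == 1.0

    def test_boundary_values(self):
        # at x = x0 the printed form jumps to exp(0)=1, the corrected form is 0
        assert quality(5.0, 5.0, "printed") == pytest.approx(1.0)
        assert quality(5.0, 5.0, "corrected") == pytest.approx(0.0)

    def test_corrected_at_twice_threshold(self):
        assert quality(8.0, 4.0, "corrected") == pytest.approx(math.exp(-1) - 1)

    def test_printed_discontinuity_at_threshold(self):
        x0 = 2.0
        below = quality(x0 - 1e-9, x0, "printed")
        at = quality(x0, x0, "printed")
        assert below == pytest.approx(0.0, abs=1e-8)
        assert at == pytest.approx(1.0)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            quality(1.0, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x1=st.floats(0, 100, allow_nan=False),
        x2=st.floats(0, 100, allow_nan=False),
        x0=st.floats(0.1, 20, allow_nan=False),
    )
    def test_corrected_form_is_monotone_nonincreasing(self, x1, x2, x0):
        a, b = sorted((x1, x2))
        assert quality(a, x0, "corrected") >= quality(b, x0, "corrected") - 1e-12


class TestRectangleEnergy:
    def test_constant_image(self, mpp_params):
        img = np.full((30, 30), 0.5)
        assert rectangle_energy(img, Rectangle(15, 15, 4, 4), mpp_params) == 1.0

    def test_planted_rectangle_matches_quality_composition(self):
        params = MPPParams(x0=6.0, bright_only=True)
        rng = np.random.default_rng(0)
        img = 0.1 * rng.gamma(50, 1 / 50, (40, 40))
        img[18:22, 18:22] = 0.9
        rect = Rectangle(20, 20, 4, 4)
        x = contrast_statistic(img, rect, params.crown_width)
        assert rectangle_energy(img, rect, params) == pytest.approx(quality(x, params.x0))

    def test_bright_only_gates_dark_rectangles(self):
        params = MPPParams(bright_only=True)
        img = np.ones((30, 30))
        img[10:14, 10:14] = 0.0  # strongly contrasted but dark
        assert rectangle_energy(img, Rectangle(12, 12, 4, 4), params) == 1.0
        permissive = MPPParams(bright_only=False)
        assert rectangle_energy(img, Rectangle(12, 12, 4, 4), permissive) < 0


class TestOverlap:
    def test_identical_rectangles_overlap(self):
        r = Rectangle(10, 10, 4, 4)
        assert overlaps(r, r)

    def test_disjoint_quadrants(self):
        assert not overlaps(Rectangle(5, 5, 4, 4), Rectangle(50, 50, 4, 4))

    def test_edge_sharing_is_not_overlap(self):
        # columns [10,14) and [14,18): half-open footprints only touch
        a = Rectangle(10, 12, 4, 4)
        b = Rectangle(10, 16, 4, 4)
        assert a.col1 == b.col0
        assert not overlaps(a, b)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(5, 50), st.integers(5, 50), st.integers(5, 50), st.integers(5, 50))
    def test_symmetry(self, r1, c1, r2, c2):
        a, b = Rectangle(r1, c1, 4, 6), Rectangle(r2, c2, 5, 3)
        assert overlaps(a, b) == overlaps(b, a)


class TestConfigurationEnergy:
    def test_empty_configuration_is_zero(self, mpp_params):
        assert configuration_energy(np.ones((20, 20)), Configuration([]), mpp_params) == 0.0

    def test_single_rectangle_equals_data_term(self, mpp_params):
        rng = np.random.default_rng(1)
        img = rng.random((30, 30))
        rect = Rectangle(15, 15, 4, 4)
        cfg = Configuration([rect])
        assert configuration_energy(img, cfg, mpp_params) == pytest.approx(
            rectangle_energy(img, rect, mpp_params)
        )

    def test_sum_of_two_disjoint_planted_rectangles(self):
        params = MPPParams(x0=6.0)
        rng = np.random.default_rng(2)
        img = 0.1 * rng.gamma(50, 1 / 50, (60, 60))
        img[10:14, 10:14] = 0.9
        img[40:44, 40:44] = 0.9
        r1, r2 = Rectangle(12, 12, 4, 4), Rectangle(42, 42, 4, 4)
        total = configuration_energy(img, Configuration([r1, r2]), params)
        expected = rectangle_energy(img, r1, params) + rectangle_energy(img, r2, params)
        assert total == pytest.approx(expected)

    def test_overlapping_pair_is_inadmissible(self, mpp_params):
        cfg = Configuration([Rectangle(10, 10, 4, 4), Rectangle(11, 11, 4, 4)])
        with pytest.raises(ValueError, match="inadmissible"):
            configuration_energy(np.ones((30, 30)), cfg, mpp_params)


class TestBruteForce:
    def test_all_positive_candidates_give_empty_configuration(self, mpp_params):
        img = np.full((30, 30), 0.5)
        cands = [Rectangle(10, 10, 4, 4), Rectangle(20, 20, 4, 4)]
        assert len(brute_force_minimize(img, cands, mpp_params)) == 0

    def test_overlapping_candidates_keep_the_better_one(self):
        # two overlapping planted bright squares: the stronger one wins alone
        params = MPPParams(x0=6.0)
        rng = np.random.default_rng(3)
        img = 0.1 * rng.gamma(50, 1 / 50, (40, 40))
        img[18:24, 18:24] = 0.9
        a = Rectangle(21, 21, 6, 6)  # full particle
        b = Rectangle(20, 20, 4, 4)  # offset sub-box, overlapping a
        assert overlaps(a, b)
        da = rectangle_energy(img, a, params)
        db = rectangle_energy(img, b, params)
        best = brute_force_minimize(img, [a, b], params)
        assert list(best) == [a if da < db else b]

    def test_disjoint_negative_candidates_all_selected(self):
        params = MPPParams(x0=6.0)
        rng = np.random.default_rng(4)
        img = 0.1 * rng.gamma(50, 1 / 50, (60, 60))
        rects = []
        for r, c in [(10, 10), (10, 40), (40, 25)]:
            img[r - 2 : r + 2, c - 2 : c + 2] = 0.9
            rects.append(Rectangle(r, c, 4, 4))
        best = brute_force_minimize(img, rects, params)
        assert sorted(best) == sorted(rects)

    def test_candidate_cap(self, mpp_params):
        cands = [Rectangle(5 + i, 5, 3, 3) for i in range(25)]
        with pytest.raises(ValueError, match="capped"):
            brute_force_minimize(np.ones((64, 64)), cands, mpp_params)


class TestMinimizeEnergy:
    def test_constant_image_yields_empty_configuration(self, mpp_params):
        cfg = minimize_energy(np.full((64, 64), 0.4), mpp_params)
        assert len(cfg) == 0

    def test_matches_brute_force_on_small_instances(self, small_instance_factory):
        for seed in range(8):
            img, cands, params = small_instance_factory(seed)
            e_bf = configuration_energy(img, brute_force_minimize(img, cands, params), params)
            cfg = minimize_energy(img, params, candidates=cands)
            e = configuration_energy(img, cfg, params)
            assert e == pytest.approx(e_bf, abs=1e-9)

    def test_never_worse_than_greedy(self, small_instance_factory):
        for seed in range(5):
            img, cands, params = small_instance_factory(seed + 100)
            energies = np.array([rectangle_energy(img, r, params) for r in cands])
            e_greedy = configuration_energy(img, greedy_minimize(cands, energies), params)
            e = configuration_energy(img, minimize_energy(img, params, candidates=cands), params)
            assert e <= e_greedy + 1e-12

    def test_returned_configuration_is_admissible(self, default_phantom):
        z = 3
        img = default_phantom.volume[z]
        roi = vitreous_roi(default_phantom, z)
        cfg, _ = detect_slice(img, MPPParams(seed=1), roi_mask=roi)
        assert cfg.is_admissible()

    def test_recovers_planted_particles(self, default_phantom):
        from octquant.metrics import match_centroids

        z = 5
        cfg, _ = detect_slice(
            default_phantom.volume[z], MPPParams(seed=2), roi_mask=vitreous_roi(default_phantom, z)
        )
        gt = np.array([[r.row, r.col] for r in default_phantom.gt_rectangles[z]]).reshape(-1, 2)
        pred = np.array([[r.row, r.col] for r in cfg]).reshape(-1, 2)
        score = match_centroids(gt, pred, tolerance=7)
        assert score.recall >= 0.9

    def test_translation_equivariance(self):
        rng = np.random.default_rng(9)
        base = 0.1 * rng.gamma(40, 1 / 40, (48, 48))
        base[20:24, 20:24] = 0.9
        shifted = np.roll(np.roll(base, 5, axis=0), -3, axis=1)
        params = MPPParams(seed=5, x0=6.0)
        c0 = minimize_energy(base, params)
        c1 = minimize_energy(shifted, params)
        centers0 = sorted((r.row + 5, r.col - 3, r.w, r.l) for r in c0)
        centers1 = sorted((r.row, r.col, r.w, r.l) for r in c1)
        assert centers0 == centers1


class TestDetectSlice:
    def test_empty_roi_gives_empty_configuration(self, default_phantom, mpp_params):
        cfg, mask = detect_slice(default_phantom.volume[0], mpp_params, roi_mask=np.zeros((256, 256), bool))
        assert len(cfg) == 0 and not mask.any()

    def test_mask_pixel_count_is_additive(self, default_phantom):
        z = 2
        cfg, mask = detect_slice(
            default_phantom.volume[z], MPPParams(seed=3), roi_mask=vitreous_roi(default_phantom, z)
        )
        assert mask.sum() == sum(r.area for r in cfg)

    def test_roi_shape_mismatch_rejected(self, default_phantom, mpp_params):
        with pytest.raises(ValueError, match="shape"):
            detect_slice(default_phantom.volume[0], mpp_params, roi_mask=np.zeros((10, 10), bool))


def test_candidate_data_terms_match_scalar_energies(default_phantom):
    """Vectorized grid energies agree with the per-rectangle reference."""
    params = MPPParams(seed=0)
    z = 1
    img = default_phantom.volume[z]
    roi = vitreous_roi(default_phantom, z)
    rects, energies = candidate_data_terms(img, params, roi_mask=roi)
    assert len(rects) > 0
    for r, e in list(zip(rects, energies))[:50]:
        assert rectangle_energy(img, r, params) == pytest.approx(e, abs=1e-9)


def test_rasterize_matches_footprints():
    cfg = Configuration([Rectangle(5, 5, 3, 4), Rectangle(20, 20, 5, 2)])
    mask = rasterize(cfg, (32, 32))
    assert mask.sum() == 12 + 10
    assert mask[3:7, 4:7].all()
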