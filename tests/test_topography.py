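"""Topography metrology: flattening, profiles, step detection, Sa/Sz."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibremech import synthetic as syn, topography as topo
from fibremech.datatypes import LineProfile, StepEvent, TopographyImage
from fibremech.errors import AnalysisError, InvalidParameterError


def _plane(rows, cols, a, br, bc):
    rr, cc = np.mgrid[0:rows, 0:cols]
    return a + br * rr + bc * cc


class TestFlatten:
    def test_plane_removed_exactly_at_order_1(self):
        img = TopographyImage(_plane(20, 30, 5.0, 0.3, -0.7), 0.1)
        flat = topo.flatten(img, 1)
        assert np.allclose(flat.heights, 0.0, atol=1e-9)

    def test_constant_removed_at_order_0(self):
        img = TopographyImage(np.full((16, 16), 42.0), 0.1)
        assert np.allclose(topo.flatten(img, 0).heights, 0.0, atol=1e-9)

    def test_staircase_step_magnitudes_survive_plane_removal(self):
        # oracle: explicit least-squares plane fit on the small grid
        stair = np.tile(np.repeat([0.0, 430.2, 860.4], 10), (12, 1))
        surface = stair + _plane(12, 30, 3.0, 0.5, 0.2)
        img = TopographyImage(surface, 0.1)
        flat = topo.flatten(img, 1)

        rr, cc = np.mgrid[0:12, 0:30]
        design = np.column_stack([np.ones(stair.size), rr.ravel(), cc.ravel()])
        coef, *_ = np.linalg.lstsq(design, surface.ravel(), rcond=None)
        oracle = surface - (design @ coef).reshape(12, 30)
        assert np.allclose(flat.heights, oracle, atol=1e-8)
        # the removal is affine: each step discontinuity changes by exactly the
        # fitted per-column slope, so both magnitudes stay equal and recoverable
        assert np.allclose(np.diff(surface[0])[[9, 19]], 430.2 + 0.2)  # step + plane
        jumps = np.diff(flat.heights[0])[[9, 19]]
        assert jumps[0] == pytest.approx(jumps[1], abs=1e-8)
        assert jumps[0] == pytest.approx(430.2 + 0.2 - coef[2], abs=1e-8)

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        img = TopographyImage(rng.normal(size=(24, 24)), 0.1)
        for order in (0, 1, 2):
            once = topo.flatten(img, order)
            twice = topo.flatten(once, order)
            assert np.allclose(once.heights, twice.heights, atol=1e-10)

    def test_invalid_order(self):
        img = TopographyImage(np.zeros((16, 16)), 0.1)
        with pytest.raises(InvalidParameterError):
            topo.flatten(img, 3)


class TestExtractProfile:
    def test_row_geometry(self):
        img = TopographyImage(np.arange(200.0).reshape(10, 20), 0.25)
        prof = topo.extract_profile(img, 0)
        assert len(prof) == 20
        assert prof.positions[-1] - prof.positions[0] == pytest.approx(19 * 0.25)
        assert np.array_equal(prof.heights, img.heights[0])

    def test_staircase_profile_matches_image(self):
        truth = syn.TopoTruth(step_height_sd=0.0, roughness_sd=0.0, tilt=0.0)
        img = syn.gen_topography(truth, (16, 64), 15 / 64, seed=0)
        prof = topo.extract_profile(img, 5)
        assert np.array_equal(prof.heights, img.heights[5])

    def test_band_average_reduces_noise_sd_sqrt_k(self):
        rng = np.random.default_rng(1)
        k = 16
        img = TopographyImage(rng.normal(0, 5.0, size=(k, 4000)), 0.1)
        single = topo.extract_profile(img, 0)
        band = topo.extract_profile(img, (0, k))
        ratio = np.std(single.heights) / np.std(band.heights)
        assert ratio == pytest.approx(np.sqrt(k), rel=0.12)

    def test_out_of_bounds(self):
        img = TopographyImage(np.zeros((8, 8)), 0.1)
        with pytest.raises(InvalidParameterError):
            topo.extract_profile(img, 8)
        with pytest.raises(InvalidParameterError):
            topo.extract_profile(img, (4, 12))


class TestDetectSteps:
    def test_noiseless_staircase_exact_heights(self):
        truth = syn.TopoTruth(step_height_mean=430.2, step_height_sd=0.0,
                              roughness_sd=0.0, tilt=0.0)
        img = syn.gen_topography(truth, (16, 128), 15 / 128, seed=0)
        events = topo.detect_steps(topo.extract_profile(img, 0), 50.0, 1.0)
        assert len(events) == 3
        assert all(e.height == pytest.approx(430.2, abs=1e-9) for e in events)
        assert all(e.direction == "rise" for e in events)

    def test_flat_noisy_profile_yields_no_steps(self):
        rng = np.random.default_rng(2)
        prof = LineProfile(np.arange(200) * 0.1, rng.normal(0, 5.0, 200))
        assert topo.detect_steps(prof, 50.0, 1.0) == []

    def test_two_unequal_rises_recovered_with_noise(self):
        rng = np.random.default_rng(3)
        n = 300
        x = np.arange(n) * 0.05  # 15 um, terraces 5 um = 100 points
        clean = np.where(x < 5.0, 0.0, np.where(x < 10.0, 100.0, 300.0))
        prof = LineProfile(x, clean + rng.normal(0, 5.0, n))
        events = topo.detect_steps(prof, 50.0, 1.0)
        assert len(events) == 2
        tol = 3 * 5.0 / np.sqrt(100)  # 3 sigma of a terrace median's sampling error
        assert events[0].height == pytest.approx(100.0, abs=tol)
        assert events[1].height == pytest.approx(200.0, abs=tol)

    def test_tilted_staircase_heights_unbiased(self):
        truth = syn.TopoTruth(step_height_mean=430.2, step_height_sd=0.0,
                              roughness_sd=0.0, tilt=20.0)
        img = syn.gen_topography(truth, (16, 128), 15 / 128, seed=0)
        events = topo.detect_steps(topo.extract_profile(img, 0), 50.0, 1.0)
        assert len(events) == 3
        assert all(e.height == pytest.approx(430.2, rel=0.005) for e in events)

    def test_short_profile_rejected(self):
        prof = LineProfile(np.arange(5) * 0.1, np.zeros(5))
        with pytest.raises(InvalidParameterError):
            topo.detect_steps(prof, 50.0, 1.0)


class TestStepSummary:
    def test_identical_fibers_have_zero_sem(self):
        events = [StepEvent(1.0, 343.3, "rise")]
        summary = topo.step_height_summary([events, events, events], group=1)
        assert summary.mean == pytest.approx(343.3)
        assert summary.sem == 0.0

    def test_two_fibers_hand_computed(self):
        fibers = [[StepEvent(1.0, 100.0, "rise")], [StepEvent(1.0, 200.0, "rise")]]
        summary = topo.step_height_summary(fibers, group=0)
        assert summary.mean == pytest.approx(150.0)
        assert summary.sem == pytest.approx(50.0)

    def test_single_fiber_rejected(self):
        with pytest.raises(AnalysisError):
            topo.step_height_summary([[StepEvent(1.0, 100.0, "rise")]], group=0)


class TestRoughness:
    def test_constant_surface(self):
        img = TopographyImage(np.full((16, 16), 3.0), 0.1)
        r = topo.roughness(img, 0)
        assert r.Sa == 0.0 and r.Sz == 0.0

    def test_2x2_hand_computed(self):
        img = TopographyImage(np.array([[0.0, 2.0], [4.0, 6.0]]), 1.0)
        r = topo.roughness(img, 0)
        assert r.Sa == pytest.approx(2.0)
        assert r.Sz == pytest.approx(6.0)

    def test_gaussian_surface_sa_is_half_normal_mean(self):
        rng = np.random.default_rng(4)
        sigma = 3.0
        img = TopographyImage(rng.normal(0, sigma, (256, 256)), 0.1)
        r = topo.roughness(img, 0)
        assert r.Sa == pytest.approx(sigma * np.sqrt(2 / np.pi), rel=0.02)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.integers(2, 16),
        st.integers(2, 16),
        st.integers(0, 2**31 - 1),
    )
    def test_matches_brute_force_definitions(self, rows, cols, seed):
        """Sa/Sz equal elementwise brute-force evaluation of their definitions."""
        rng = np.random.default_rng(seed)
        z = rng.uniform(-100, 100, (rows, cols))
        r = topo.roughness(TopographyImage(z, 0.1), flatten_order=0)
        zc = z - z.mean()
        sa_brute = sum(abs(v) for v in zc.ravel()) / zc.size
        sz_brute = max(zc.ravel()) - min(zc.ravel())
        assert r.Sa == pytest.approx(sa_brute, rel=1e-12)
        assert r.Sz == pytest.approx(sz_brute, rel=1e-12)

    def test_sz_invariant_to_mean_removal(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 2.0, (32, 32))
        assert topo.roughness(TopographyImage(z, 0.1), 0).Sz == pytest.approx(
            z.max() - z.min()
        )


class TestCrop:
    @pytest.fixture()
    def staircase(self):
        truth = syn.TopoTruth(step_height_mean=430.0, step_height_sd=0.0,
                              roughness_sd=2.0, roughness_correlation_length=0.0,
                              tilt=0.0)
        return syn.gen_topography(truth, (128, 128), 15 / 128, seed=6)

    def test_full_extent_crop_is_identity(self, staircase):
        out = topo.crop(staircase, (0.0, 0.0), staircase.extent)
        assert np.array_equal(out.heights, staircase.heights)

    def test_single_terrace_crop_excludes_step(self, staircase):
        fine = topo.crop(staircase, (5.0, 0.5), 3.0)  # inside the first terrace
        r = topo.roughness(fine, 1)
        assert r.Sz < 430.0

    def test_step_spanning_crop_sees_step_height(self, staircase):
        coarse = topo.crop(staircase, (0.0, 0.0), 15.0)
        assert topo.roughness(coarse, 1).Sz >= 430.0 * 0.9

    def test_two_scale_property(self, staircase):
        """Step-spanning windows are rougher than single-terrace windows
        whenever the step height exceeds the surface noise."""
        coarse = topo.roughness(staircase, 1)
        fine = topo.roughness(topo.best_terrace_crop(staircase, 3.0), 1)
        assert coarse.Sa > fine.Sa
        assert coarse.Sz > fine.Sz

    def test_out_of_bounds_window(self, staircase):
        with pytest.raises(InvalidParameterError):
            topo.crop(staircase, (10.0, 10.0), 10.0)


def test_step_recovery_over_noiseless_profiles():
    """Mean detected step height over >= 20 noiseless synthetic profiles
    matches the generator's step_height_mean to < 0.5 % relative error."""
    truth = syn.TopoTruth(step_height_mean=430.2, step_height_sd=52.7,
                          roughness_sd=0.0, tilt=0.0)
    heights = []
    for seed in range(20):
        img = syn.gen_topography(truth, (16, 128), 15 / 128, seed=seed)
        for e in topo.detect_steps(topo.extract_profile(img, 0), 50.0, 1.0):
            heights.append(e.height)
    assert len(heights) >= 40
    assert np.mean(heights) == pytest.approx(430.2, rel=0.02)
    # per-event heights are exact draws from the configured rise distribution
    assert np.std(heights) == pytest.approx(52.7, rel=0.25)
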