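"""Generator contracts: determinism, noiseless closed forms, cohort layout."""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import pytest

from fibremech import io as fio, synthetic as syn
from fibremech.errors import InvalidParameterError


NOISELESS_TOPO = syn.TopoTruth(
    step_height_mean=430.2, step_height_sd=0.0, roughness_sd=0.0, tilt=0.0,
    debris_density=0.0,
)


class TestTopography:
    def test_noiseless_staircase_is_exact(self):
        img = syn.gen_topography(NOISELESS_TOPO, (32, 128), 15 / 128, seed=0)
        profile = img.heights[0]
        rises = np.diff(profile)
        steps = rises[rises > 0]
        assert np.allclose(steps, 430.2)
        # terraces exactly flat, all rows identical
        assert np.count_nonzero(rises) == 3  # 15 um / 4.5 um terraces -> 3 rises
        assert np.all(img.heights == img.heights[0])

    def test_terrace_longer_than_field_of_view_gives_flat_image(self):
        truth = syn.TopoTruth(
            step_height_mean=430.2, step_height_sd=0.0, terrace_length=20.0,
            roughness_sd=0.0, tilt=0.0,
        )
        img = syn.gen_topography(truth, (16, 64), 15 / 64, seed=0)
        assert np.all(img.heights == 0.0)

    def test_tilt_and_roughness_statistics(self):
        truth = syn.TopoTruth(
            step_height_mean=430.2, terrace_length=100.0, roughness_sd=5.0,
            roughness_correlation_length=0.0, tilt=10.0,
        )
        img = syn.gen_topography(truth, (64, 64), 0.25, seed=3)
        # column means follow the tilt plane: slope ~10 nm/um
        x = (np.arange(64) + 0.5) * 0.25
        slope = np.polyfit(x, img.heights.mean(axis=0), 1)[0]
        assert slope == pytest.approx(10.0, rel=0.05)
        detrended = img.heights - np.polyval(np.polyfit(x, img.heights.mean(axis=0), 1), x)
        assert detrended.std() == pytest.approx(5.0, rel=0.1)

    @pytest.mark.parametrize("bad", [dict(size=(8, 64)), dict(pixel_size=0.0)])
    def test_invalid_geometry_rejected(self, bad):
        kwargs = dict(size=(32, 32), pixel_size=0.1, seed=0)
        kwargs.update(bad)
        with pytest.raises(InvalidParameterError):
            syn.gen_topography(NOISELESS_TOPO, **kwargs)


class TestForceDistance:
    def test_rigid_surface_slope_equals_spring_constant(self):
        truth = syn.FDTruth(sample_stiffness=math.inf, spring_constant=0.2, noise_sd=0.0)
        assert truth.contact_slope == 0.2
        curve = syn.gen_fd_curve(truth, 200, seed=0)
        z, f = curve.approach[:, 0], curve.approach[:, 1]
        contact = f > 0.1
        slope = np.polyfit(z[contact], f[contact], 1)[0]
        assert slope == pytest.approx(0.2, rel=1e-9)

    def test_series_spring_slope(self):
        truth = syn.FDTruth(sample_stiffness=0.88, spring_constant=0.2, noise_sd=0.0)
        expected = 0.2 * 0.88 / 1.08  # ~0.163 nN/nm by series-spring algebra
        assert truth.contact_slope == pytest.approx(expected, abs=1e-12)
        curve = syn.gen_fd_curve(truth, 300, seed=0)
        f = curve.approach[:, 1]
        z = curve.approach[:, 0]
        contact = f > 0.1
        assert np.polyfit(z[contact], f[contact], 1)[0] == pytest.approx(expected, rel=1e-9)

    def test_no_dips_means_min_force_exactly_zero(self):
        truth = syn.FDTruth(attraction_depth=0.0, adhesion_depth=0.0, noise_sd=0.0)
        curve = syn.gen_fd_curve(truth, 200, seed=0)
        assert curve.approach[:, 1].min() == 0.0
        assert curve.retract[:, 1].min() == 0.0

    def test_noiseless_dip_depths_exact(self):
        truth = syn.FDTruth(attraction_depth=0.591, adhesion_depth=1.5, noise_sd=0.0)
        curve = syn.gen_fd_curve(truth, 500, seed=0)
        assert curve.approach[:, 1].min() == pytest.approx(-0.591, abs=1e-12)
        assert curve.retract[:, 1].min() == pytest.approx(-1.5, abs=1e-12)

    def test_setpoint_honoured_and_validated(self):
        curve = syn.gen_fd_curve(syn.FDTruth(noise_sd=0.0), 300, seed=0)
        # contact point snaps to the displacement grid, so the final load can
        # overshoot the setpoint trigger by up to one sample's force step
        assert curve.approach[:, 1].max() == pytest.approx(9.0, abs=0.1)
        with pytest.raises(InvalidParameterError):
            syn.FDTruth(setpoint=11.0)  # instrument load limit is 10 nN


class TestTensile:
    def test_noiseless_piecewise_values(self):
        truth = syn.TensileTruth(elastic_modulus=3000.0, yield_strain=0.03, noise_sd=0.0)
        assert truth.stress_at(np.array([0.03]))[0] == pytest.approx(90.0, abs=1e-9)
        curve = syn.gen_tensile_curve(truth, 400, seed=0)
        assert curve.strain[-1] == pytest.approx(0.47, abs=1e-12)
        # pre-yield slope exactly E
        pre = curve.strain <= 0.03
        assert np.polyfit(curve.strain[pre], curve.stress[pre], 1)[0] == pytest.approx(
            3000.0, rel=1e-9
        )

    def test_plateau_has_minimal_not_zero_slope(self):
        truth = syn.TensileTruth(noise_sd=0.0)
        mid = np.array([0.10, 0.20])
        slope = np.diff(truth.stress_at(mid))[0] / 0.10
        assert slope == pytest.approx(0.02 * truth.elastic_modulus, rel=1e-9)

    def test_same_underlying_mean_different_residuals_across_seeds(self):
        truth = syn.TensileTruth(noise_sd=2.0)
        a = syn.gen_tensile_curve(truth, 400, seed=1)
        b = syn.gen_tensile_curve(truth, 400, seed=2)
        assert np.array_equal(a.strain, b.strain)
        assert not np.array_equal(a.stress, b.stress)
        clean = truth.stress_at(a.strain)
        assert np.abs((a.stress - clean).mean()) < 0.5
        assert np.abs((b.stress - clean).mean()) < 0.5

    def test_ordering_invariant_enforced(self):
        with pytest.raises(InvalidParameterError):
            syn.TensileTruth(yield_strain=0.3, post_yield_onset_strain=0.25)


class TestSpectrum:
    def test_flat_limit(self):
        truth = syn.SpectrumTruth(bands=(), baseline_slope=0.0, noise_sd=0.0)
        spec = syn.gen_spectrum(truth, (400, 4000), 4.0, seed=0)
        assert np.all(spec.transmittance == 100.0)

    def test_single_gaussian_dip(self):
        truth = syn.SpectrumTruth(bands=((1650.0, 20.0, 15.0),), noise_sd=0.0)
        spec = syn.gen_spectrum(truth, (400, 4000), 4.0, seed=0)
        i = np.argmin(spec.transmittance)
        assert abs(spec.wavenumbers[i] - 1650.0) <= 4.0
        assert spec.transmittance.min() == pytest.approx(80.0, abs=0.2)

    def test_default_keratin_truth_has_amide_dips(self):
        truth = syn.paper_trend_cohort().groups[0].spectrum
        spec = syn.gen_spectrum(truth, (400, 4000), 4.0, seed=0)
        t = spec.transmittance
        nu = spec.wavenumbers
        amide1 = (nu >= 1600) & (nu <= 1690)
        amide2 = (nu >= 1480) & (nu <= 1575)
        assert t[amide1].min() < 90.0
        assert t[amide2].min() < 92.0

    def test_band_outside_range_skipped_with_warning(self, caplog):
        truth = syn.SpectrumTruth(bands=((5000.0, 10.0, 15.0),), noise_sd=0.0)
        with caplog.at_level(logging.WARNING, logger="fibremech.synthetic"):
            spec = syn.gen_spectrum(truth, (400, 4000), 4.0, seed=0)
        assert "skipped" in caplog.text
        assert np.all(spec.transmittance == 100.0)


@pytest.mark.parametrize(
    "gen",
    [
        lambda seed: syn.gen_topography(syn.TopoTruth(), (32, 32), 0.2, seed).heights,
        lambda seed: syn.gen_fd_curve(syn.FDTruth(), 200, seed).approach,
        lambda seed: syn.gen_tensile_curve(syn.TensileTruth(), 400, seed).stress,
        lambda seed: syn.gen_spectrum(
            syn.SpectrumTruth(bands=((1650, 10, 15),), noise_sd=0.3), seed=seed
        ).transmittance,
    ],
    ids=["topo", "fd", "tensile", "spectrum"],
)
def test_generators_deterministic_in_seed(gen):
    assert np.array_equal(gen(42), gen(42))
    assert not np.array_equal(gen(42), gen(43))


class TestCohort:
    def test_layout_counts_and_manifest(self, small_cohort):
        root, manifest, config = small_cohort
        assert len(manifest) == 6  # 2 groups x 3 fibers
        for group in config.groups:
            gdir = root / str(group.dye_count)
            assert len(list(gdir.glob("*.txt"))) == group.n_fibers * 4
        assert set(manifest["dye_count"]) == {0, 1}

    def test_manifest_truth_round_trip_exact(self, small_cohort):
        root, manifest, config = small_cohort
        on_disk = fio.read_manifest(root / "manifest.csv")
        for group in config.groups:
            rows = on_disk[on_disk["dye_count"] == group.dye_count]
            assert np.all(rows["topo_step_height_mean"] == group.topo.step_height_mean)
            assert np.all(rows["fd_attraction_depth"] == group.fd.attraction_depth)
            assert np.all(rows["tensile_elastic_modulus"] == group.tensile.elastic_modulus)
            assert np.all(rows["fd_expected_slope"] == group.fd.contact_slope)

    def test_same_config_gives_byte_identical_manifests(self, tmp_path):
        from conftest import small_cohort_config

        config = small_cohort_config(seed=11, n_fibers=2)
        syn.gen_cohort(config, tmp_path / "a")
        syn.gen_cohort(config, tmp_path / "b")
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == (
            tmp_path / "b" / "manifest.csv"
        ).read_bytes()
        # and the data files themselves
        fa = sorted((tmp_path / "a").rglob("*.txt"))
        fb = sorted((tmp_path / "b").rglob("*.txt"))
        assert len(fa) == len(fb) == 2 * 2 * 4
        for a, b in zip(fa, fb):
            assert a.read_bytes() == b.read_bytes()

    def test_duplicate_dye_counts_rejected(self):
        g = syn.paper_trend_cohort(n_fibers=2).groups[0]
        with pytest.raises(InvalidParameterError):
            syn.CohortConfig(groups=(g, g))

    def test_paper_trend_defaults_follow_reported_directions(self):
        config = syn.paper_trend_cohort()
        by_dye = {g.dye_count: g for g in config.groups}
        # step height drops ~20 % after one dye then partially recovers, all below control
        assert by_dye[1].topo.step_height_mean < by_dye[3].topo.step_height_mean
        assert all(
            by_dye[d].topo.step_height_mean < by_dye[0].topo.step_height_mean
            for d in (1, 3, 5, 7, 10)
        )
        # fine-scale roughness monotone in dye count
        rough = [g.topo.roughness_sd for g in config.groups]
        assert rough == sorted(rough)
        # attraction decreases, fracture strain of dyed exceeds control
        assert by_dye[1].fd.attraction_depth < by_dye[0].fd.attraction_depth
        assert all(
            by_dye[d].tensile.fracture_strain > by_dye[0].tensile.fracture_strain
            for d in (1, 3, 5, 7, 10)
        )
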