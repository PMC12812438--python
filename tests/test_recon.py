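"""Reconstruction: background, contrast, resonance, OT/dOT, Beer-Lambert, RI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpm import optics, phantoms, recon, render
from fpm.optics import LaserLine, free_spectral_range, interference_order
from fpm.recon import (
    beer_lambert_mu,
    delta_ot_map,
    estimate_background,
    max_contrast_map,
    ot_map,
    physical_thickness_map,
    refractive_index_map,
    resonance_map,
    unwrap_delta_ot,
    weber_contrast,
    weber_contrast_stack,
    wfm_baseline,
    wrap_delta_ot,
)
from fpm.stack_io import WavelengthStack


def synthetic_stack(ot_um, wavelengths, shape=(6, 6), fwhm=0.29, r=0.68):
    """Noiseless uniform-OT stack rendered directly from the cavity model."""
    line = LaserLine(fwhm_nm=fwhm)
    frames = np.stack([
        np.full(shape, optics.effective_transmission(ot_um, line.at(l), r))
        for l in wavelengths])
    return WavelengthStack(frames, np.asarray(wavelengths, dtype=float))


class TestBackground:
    def test_constant_frame(self):
        assert estimate_background(np.full((16, 16), 0.37)) == pytest.approx(0.37)

    def test_median_ignores_sparse_outliers(self, rng):
        frame = np.full((32, 32), 0.2)
        idx = rng.choice(frame.size, size=10, replace=False)
        frame.ravel()[idx] = 5.0
        assert estimate_background(frame) == pytest.approx(0.2)

    def test_rendered_background_matches_theory(self, cavity, line):
        scene = phantoms.empty_scene((8, 8))
        stack = render.render_stack(scene, cavity, line, [516.2])
        level = optics.effective_transmission(66.5, line.at(516.2), 0.68)
        assert estimate_background(stack.frames[0]) == pytest.approx(level, abs=1e-9)

    def test_contaminated_roi_warns(self):
        frame = np.full((32, 32), 0.2) + np.linspace(0, 0.001, 32)
        frame[8:24, 8:24] = 3.0
        with pytest.warns(UserWarning, match="contaminated"):
            estimate_background(frame, roi=(0, 32, 0, 32))

    def test_local_mode_tracks_gradient(self):
        ny = nx = 64
        ramp = np.linspace(0.2, 0.6, nx)[None, :] * np.ones((ny, 1))
        field = estimate_background(ramp, mode="local", tile=16)
        assert field.shape == ramp.shape
        # tile medians extrapolate at the borders: allow a half-tile of drift
        assert np.max(np.abs(field - ramp)) < 0.4 * 8 / 64 + 1e-9

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            estimate_background(np.ones((8, 8)), roi=(4, 4, 0, 8))


class TestWeberContrast:
    @pytest.mark.parametrize("i, ib, expected", [
        (0.5, 0.5, 0.0),     # sample equals background
        (1.0, 0.5, 1.0),     # twice the background
        (0.0, 0.5, 1.0),     # full extinction, absolute contrast
    ])
    def test_values(self, i, ib, expected):
        assert weber_contrast(np.array([[i]]), ib)[0, 0] == pytest.approx(expected)

    def test_degenerate_background_rejected(self):
        with pytest.raises(ValueError):
            weber_contrast(np.ones((4, 4)), 0.0)

    def test_stack_backgrounds_estimated_per_frame(self, cavity, line):
        scene = phantoms.empty_scene((8, 8))
        stack = render.render_stack(scene, cavity, line, [515.5, 516.5, 517.5])
        contrast, backgrounds = weber_contrast_stack(stack)
        assert contrast.shape == (3, 8, 8)
        np.testing.assert_allclose(contrast, 0.0, atol=1e-12)
        assert len(backgrounds) == 3


class TestMaxContrastMap:
    def test_single_frame_identity(self):
        c = np.random.default_rng(0).random((1, 8, 8))
        m = max_contrast_map(c, [516.0])
        np.testing.assert_array_equal(m.values, c[0])

    def test_dominates_every_frame(self, rng):
        c = rng.random((7, 16, 16))
        m = max_contrast_map(c, np.linspace(515, 519, 7))
        assert np.all(m.values[None] >= c - 1e-15)

    def test_frame_order_invariance(self, rng):
        c = rng.random((5, 8, 8))
        lam = np.linspace(515, 519, 5)
        perm = rng.permutation(5)
        a = max_contrast_map(c, lam)
        b = max_contrast_map(c[perm], lam[perm])
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.argmax_wavelength_nm, b.argmax_wavelength_nm)

    def test_ties_take_lowest_wavelength(self):
        c = np.ones((3, 2, 2))
        m = max_contrast_map(c, [517.0, 515.0, 519.0])
        assert np.all(m.argmax_wavelength_nm == 515.0)


class TestWfmBaseline:
    def test_constant_stack(self):
        stack = WavelengthStack(np.full((5, 4, 4), 0.3), np.linspace(515, 517, 5))
        np.testing.assert_allclose(wfm_baseline(stack, 2.0), 0.3)

    def test_pure_phase_object_vanishes(self, cavity, line):
        scene = phantoms.cell_scene(body_radius_um=40, body_delta_ot_nm=100,
                                    shape=(64, 64))
        fsr = free_spectral_range(515.0, 66.5)
        lam = np.linspace(515.0, 515.0 + fsr, 41)[:-1]
        stack = render.render_stack(scene, cavity, line, lam)
        baseline = stack.frames.mean(axis=0)
        c = weber_contrast(baseline, estimate_background(baseline, (0, 8, 0, 8)))
        assert c.max() < 0.02

    def test_absorption_survives_averaging(self, line):
        cav = optics.CavitySpec(reflectivity=1e-12)
        scene = phantoms.cell_scene(body_radius_um=20, attenuation=0.2, shape=(48, 48))
        stack = render.render_stack(scene, cav, line)
        baseline = wfm_baseline(stack, free_spectral_range(515.0, 66.5))
        np.testing.assert_allclose(baseline, (1 - scene.atten_map) ** 2, atol=1e-9)

    def test_short_scan_warns(self):
        stack = WavelengthStack(np.ones((3, 4, 4)), [515.0, 515.2, 515.4])
        with pytest.warns(UserWarning, match="below one FSR"):
            wfm_baseline(stack, 2.0)


class TestResonanceMap:
    def test_uniform_background_resonance(self, cavity, line):
        scene = phantoms.empty_scene((8, 8))
        stack = render.render_stack(scene, cavity, line)
        rm = resonance_map(stack)
        assert np.ptp(rm.lambda_max_nm) < 1e-9  # uniform across pixels
        lam = float(rm.lambda_max_nm[0, 0])
        n = interference_order(1.33, 50.0, lam)
        assert n * lam * 1e-3 / 2 == pytest.approx(66.5, abs=2e-3)

    def test_peak_on_sample_returned_exactly(self):
        lam = np.linspace(515.0, 517.0, 9)
        frames = np.zeros((9, 2, 2))
        frames[4] = 1.0  # symmetric discrete peak: vertex at the sample
        rm = resonance_map(WavelengthStack(frames, lam))
        assert rm.lambda_max_nm[0, 0] == pytest.approx(lam[4])

    @pytest.mark.parametrize("frac", [0.5, 0.25])
    def test_substep_accuracy(self, frac):
        step = 4.0 / 34
        lam_true = 516.0 + frac * step
        ot = 258 * lam_true * 1e-3 / 2
        grid = np.arange(515.2, 517.0, step)  # sub-FSR window, single peak
        stack = synthetic_stack(ot, grid)
        rm = resonance_map(stack)
        assert abs(rm.lambda_max_nm[0, 0] - lam_true) < step / 10

    def test_edge_peak_flagged(self):
        lam = np.linspace(515.0, 517.0, 9)
        frames = np.tile(np.linspace(1.0, 0.1, 9)[:, None, None], (1, 2, 2))
        rm = resonance_map(WavelengthStack(frames, lam))
        assert rm.unrefined.all()
        assert rm.lambda_max_nm[0, 0] == lam[0]

    def test_flat_trace_flagged(self):
        stack = WavelengthStack(np.ones((5, 3, 3)), np.linspace(515, 517, 5))
        rm = resonance_map(stack)
        assert rm.flat.all()

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            resonance_map(WavelengthStack(np.ones((2, 3, 3)), [515.0, 516.0]))


class TestOtMaps:
    def test_ot_from_resonance(self):
        rm = recon.ResonanceMap(np.full((2, 2), 515.5), np.ones((2, 2)),
                                np.zeros((2, 2), bool), np.zeros((2, 2), bool))
        otm = ot_map(rm, 258)
        assert otm.ot_um[0, 0] == pytest.approx(66.4995)

    def test_first_order_half_wave(self):
        rm = recon.ResonanceMap(np.full((1, 1), 1000.0), np.ones((1, 1)),
                                np.zeros((1, 1), bool), np.zeros((1, 1), bool))
        assert ot_map(rm, 1).ot_um[0, 0] == pytest.approx(0.5)

    def test_background_round_trip_within_limit(self, cavity, line):
        scene = phantoms.empty_scene((8, 8))
        stack = render.render_stack(scene, cavity, line)
        rm = resonance_map(stack)
        lam0 = float(rm.lambda_max_nm[0, 0])
        n = interference_order(1.33, 50.0, lam0)
        otm = ot_map(rm, n)
        limit_um = optics.ot_resolution_limit(n, line.fwhm_nm) * 1e-3
        assert abs(otm.ot_um[0, 0] - 66.5) < limit_um

    def test_delta_ot_empty_scene(self, cavity, line):
        scene = phantoms.empty_scene((8, 8))
        stack = render.render_stack(scene, cavity, line)
        otm = delta_ot_map(ot_map(resonance_map(stack), 258), (0, 4, 0, 4))
        np.testing.assert_allclose(otm.delta_ot_um, 0.0, atol=1e-6)
        assert not otm.wrapped.any()

    def test_bead_center_flagged_wrapped(self):
        # dOT of 0.84 um is far outside the +-lambda/4 unambiguous window
        ot = np.full((8, 8), 66.5)
        ot[4, 4] = 66.5 + 0.84
        otm = delta_ot_map(recon.OTMap(ot, 258), (0, 2, 0, 8), wavelength_nm=516.0)
        assert otm.wrapped[4, 4]
        assert not otm.wrapped[0, 0]

    @given(st.floats(-3.0, 3.0))
    @settings(deadline=None, derandomize=True)
    def test_wrap_into_principal_window(self, dot):
        lam = 516.0
        w = wrap_delta_ot(np.array([dot]), lam)[0]
        half = lam * 1e-3 / 2
        assert -half / 2 <= w < half / 2
        # wrapping preserves the value modulo lambda/2
        assert abs((dot - w) / half - round((dot - w) / half)) < 1e-9

    def test_unwrap_recovers_smooth_field(self):
        lam = 516.0
        yy, xx = np.mgrid[0:64, 0:64]
        true = 0.9 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / 150.0)
        wrapped = wrap_delta_ot(true, lam)
        rec = unwrap_delta_ot(wrapped, lam, background_roi=(0, 8, 0, 8))
        np.testing.assert_allclose(rec, true, atol=1e-9)


class TestBeerLambert:
    def test_natural_convention(self):
        assert beer_lambert_mu(5.0, 50.0) == pytest.approx(0.1)
        assert beer_lambert_mu(0.0, 50.0) == 0.0

    def test_decadic_convention(self):
        assert beer_lambert_mu(1.0, 50.0, "decadic") == pytest.approx(0.04605, abs=1e-5)

    def test_conventions_differ_by_ln10(self):
        a, d = 2.7, 31.0
        assert (beer_lambert_mu(a, d, "decadic")
                == pytest.approx(beer_lambert_mu(a, d) * np.log(10.0)))

    def test_physical_thickness_inversion(self):
        assert physical_thickness_map(np.array([[0.5]]), 0.5, 0.1)[0][0, 0] == 0.0
        pt, _ = physical_thickness_map(np.array([[0.5 * np.exp(0.7)]]), 0.5, 0.1)
        assert pt[0, 0] == pytest.approx(7.0)

    def test_negative_thickness_clipped_and_flagged(self):
        pt, clipped = physical_thickness_map(np.array([[0.3, 0.6]]), 0.5, 0.1)
        assert pt[0, 0] == 0.0
        assert clipped[0, 0] and not clipped[0, 1]

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            physical_thickness_map(np.ones((2, 2)), -1.0, 0.1)
        with pytest.raises(ValueError):
            physical_thickness_map(np.ones((2, 2)), 1.0, 0.0)
        with pytest.raises(ValueError):
            beer_lambert_mu(1.0, 50.0, "unknown")


class TestRefractiveIndex:
    def test_bead_reference_values(self):
        ri = refractive_index_map(np.array([[0.84]]), np.array([[7.0]]), 1.33)
        assert ri.n_map[0, 0] == pytest.approx(1.45)

    def test_zero_dot_gives_medium(self):
        ri = refractive_index_map(np.zeros((2, 2)), np.full((2, 2), 3.0), 1.33)
        np.testing.assert_allclose(ri.n_map, 1.33)

    def test_thin_regions_masked(self):
        ri = refractive_index_map(np.array([[0.1, 0.1]]), np.array([[0.2, 2.0]]),
                                  1.33, min_pt_um=0.5)
        assert np.isnan(ri.n_map[0, 0]) and not ri.defined[0, 0]
        assert ri.defined[0, 1]


class TestEndToEnd:
    def test_delta_ot_recovery_within_spectral_sampling(self, cavity, line):
        """Noiseless render -> reconstruction recovers dOT to within the
        N*dstep/2 spectral-sampling bound (and in practice far better)."""
        scene = phantoms.cell_scene(body_radius_um=30, body_delta_ot_nm=100,
                                    organelles=[((8.0, 4.0), 3.0, 25.0)],
                                    shape=(72, 72))
        stack = render.render_stack(scene, cavity, line)
        rm = resonance_map(stack)
        n = interference_order(1.33, 50.0, float(stack.wavelengths_nm[0]))
        otm = delta_ot_map(ot_map(rm, n), (0, 8, 0, 8),
                           wavelength_nm=float(np.mean(stack.wavelengths_nm)))
        rec = wrap_delta_ot(otm.delta_ot_um, 516.0)
        true = scene.ground_truth["delta_ot_um"]
        step = np.diff(stack.wavelengths_nm).mean()
        bound_um = n * step / 2 * 1e-3
        assert np.max(np.abs(rec - true)) <= bound_um

    def test_recovery_error_shrinks_with_more_steps(self, cavity):
        scene = phantoms.cell_scene(body_radius_um=8, body_delta_ot_nm=80,
                                    shape=(48, 48))
        true = scene.ground_truth["delta_ot_um"]
        errs = []
        for steps in (9, 35):
            ln = LaserLine(n_steps=steps)
            stack = render.render_stack(scene, cavity, ln)
            rm = resonance_map(stack)
            otm = delta_ot_map(ot_map(rm, 258), (0, 6, 0, 6))
            rec = wrap_delta_ot(otm.delta_ot_um, 516.0)
            errs.append(np.max(np.abs(rec - true)))
        assert errs[1] < errs[0]
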