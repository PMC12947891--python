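"""Unit tests for the RICS core: model evaluation, data ACFs, and fits."""

import numpy as np
import pytest

from tfpop import (
    Acf2D,
    AcquisitionGeometry,
    ImageStack,
    NuclearMask,
    PsfModel,
    amplitude_to_concentration,
    autofluorescence_factor,
    compute_acf2d,
    concentration_to_amplitude,
    fit_fast_axis,
    fit_three_component,
    fit_two_component,
    model_acf,
    model_acf_multi,
    segment_nuclei,
    slow_axis_profile,
    subtract_background,
)
from tfpop.rics import BackgroundSubtractionError, positive_quadrant
from tfpop.synthetic import (
    NoiseProtocol,
    SpeciesSpec,
    simulate_acf_study,
    simulate_raster_stack,
    three_component_baseline,
    two_component_baseline,
)


def naive_acf_value(dx, dy, amplitude, d, geom, psf):
    """Independent term-by-term evaluation of the single-species ACF."""
    tau = geom.dwell * dx + geom.line_time * dy
    lateral = 1.0 / (1.0 + 4.0 * d * tau / psf.w0**2)
    axial = (1.0 + 4.0 * d * tau / psf.wz**2) ** -0.5
    gauss = np.exp(
        -((dx**2 + dy**2) * geom.pixel_size**2) / (psf.w0**2 + 4.0 * d * tau)
    )
    return amplitude * lateral * axial * gauss


class TestModelAcf:
    def test_zero_shift_equals_amplitude(self, geometry_case1, psf):
        acf = model_acf(0.02, 3.0, geometry_case1, psf)
        iy, ix = acf.zero_index
        assert acf.values[iy, ix] == pytest.approx(0.02)

    def test_immobile_limit_is_spatial_gaussian(self, geometry_case1, psf):
        acf = model_acf(0.015, 0.0, geometry_case1, psf)
        dxg, dyg = np.meshgrid(acf.dx_shifts, acf.dy_shifts)
        expected = 0.015 * np.exp(
            -(dxg**2 + dyg**2) * geometry_case1.pixel_size**2 / psf.w0**2
        )
        np.testing.assert_allclose(acf.values, expected, rtol=1e-12)

    @pytest.mark.parametrize("case", ["case-1", "case-2"])
    def test_matches_independent_evaluation(self, case, psf):
        from tfpop.synthetic import case_geometry

        geom = case_geometry(case)
        acf = model_acf(0.02, 3.0, geom, psf)
        for dx, dy in [(0, 0), (5, 0), (0, 7), (13, 3), (64, 32)]:
            iy = int(np.flatnonzero(acf.dy_shifts == dy)[0])
            ix = int(np.flatnonzero(acf.dx_shifts == dx)[0])
            assert acf.values[iy, ix] == pytest.approx(
                naive_acf_value(dx, dy, 0.02, 3.0, geom, psf), rel=1e-12
            )

    def test_mixture_is_linear_combination(self, geometry_case1, psf):
        a = 0.02
        mix = model_acf_multi(a, [0.75, 0.25], [0.0, 3.0], geometry_case1, psf)
        g0 = model_acf(1.0, 0.0, geometry_case1, psf)
        g1 = model_acf(1.0, 3.0, geometry_case1, psf)
        np.testing.assert_allclose(
            mix.values, a * (0.75 * g0.values + 0.25 * g1.values), rtol=1e-12
        )

    def test_invalid_inputs(self, geometry_case1, psf):
        with pytest.raises(ValueError):
            model_acf(-0.1, 3.0, geometry_case1, psf)
        with pytest.raises(ValueError):
            model_acf_multi(0.02, [0.5, 0.4], [0, 3], geometry_case1, psf)


class TestAmplitudeConversion:
    def test_round_trip_identity(self, psf):
        a = concentration_to_amplitude(100.0, psf)
        assert amplitude_to_concentration(a, psf) == pytest.approx(100.0)

    def test_hand_arithmetic(self):
        # gamma = 2^(-3/2), w0 = 0.25 um, wz = 1.5 um, c = 100 nM:
        # V = pi^1.5 * 0.0625 * 1.5 = 0.52219 um^3;
        # density = 60.22 um^-3; A = 0.35355 / (0.52219 * 60.22)
        psf = PsfModel(w0=0.25, wz=1.5)
        v = np.pi**1.5 * 0.25**2 * 1.5
        expected_a = 2.0**-1.5 / (v * 100 * 0.6022)
        assert concentration_to_amplitude(100.0, psf) == pytest.approx(expected_a)

    def test_inverse_proportionality(self, psf):
        a1 = concentration_to_amplitude(60.0, psf)
        a2 = concentration_to_amplitude(120.0, psf)
        assert a1 == pytest.approx(2 * a2)

    def test_rejects_nonpositive(self, psf):
        with pytest.raises(ValueError):
            amplitude_to_concentration(0.0, psf)


class TestAutofluorescence:
    @pytest.mark.parametrize(
        "i, i0, expected",
        [(100.0, 0.0, 1.0), (100.0, 2.0, 0.9604), (100.0, 50.0, 0.25)],
    )
    def test_factor_values(self, i, i0, expected):
        assert autofluorescence_factor(i, i0) == pytest.approx(expected)

    def test_rejects_background_above_signal(self):
        with pytest.raises(ValueError):
            autofluorescence_factor(1.0, 2.0)


class TestBackgroundSubtraction:
    def test_recovers_offset_from_simulation(self, geometry_small, psf):
        sim = simulate_raster_stack(
            [SpeciesSpec(0.0, 90.0)],
            geometry_small,
            psf,
            offset_mean=100.0,
            offset_sd=10.0,
            n_frames=2,
            nucleus_radius_um=1.2,
            seed=3,
        )
        sub, mean, sd = subtract_background(sim.green)
        assert mean == pytest.approx(100.0, abs=1.0)
        assert sd == pytest.approx(10.0, abs=2.0)
        # far from the nucleus (beyond the PSF halo) only the offset remains
        dr = geometry_small.pixel_size
        yy, xx = np.mgrid[:128, :128]
        r = np.hypot((xx + 0.5) * dr - 128 * dr / 2, (yy + 0.5) * dr - 128 * dr / 2)
        far = r > 1.2 + 3 * psf.w0
        assert abs(sub.data[0][far].mean()) < 1.0
        assert sub.offset_subtracted

    def test_zero_offset_leaves_stack_unchanged(self, geometry_small, rng):
        data = np.abs(rng.normal(0.0, 1.0, (2, 128, 128)))
        stack = ImageStack(data, geometry_small)
        sub, mean, _ = subtract_background(stack)
        assert abs(mean) < 0.5
        np.testing.assert_allclose(sub.data, data - mean)

    def test_constant_frame_raises(self, geometry_small):
        stack = ImageStack(np.full((1, 128, 128), 4095.0), geometry_small)
        with pytest.raises(BackgroundSubtractionError):
            subtract_background(stack)

    def test_rejects_double_subtraction(self, geometry_small, rng):
        stack = ImageStack(
            rng.normal(100, 10, (1, 128, 128)), geometry_small,
            offset_subtracted=True,
        )
        with pytest.raises(ValueError):
            subtract_background(stack)


class TestComputeAcf2d:
    def test_constant_image_gives_zero(self, geometry_small):
        stack = ImageStack(
            np.full((2, 128, 128), 50.0), geometry_small, offset_subtracted=True
        )
        acfs = compute_acf2d(stack, group_size=2, max_dx=16, max_dy=8)
        vals = acfs[0].values
        np.testing.assert_allclose(vals[np.isfinite(vals)], 0.0, atol=1e-12)

    def test_white_noise_has_zero_lag_peak_only(self, geometry_small, rng):
        stack = ImageStack(
            rng.normal(100.0, 10.0, (4, 128, 128)),
            geometry_small,
            offset_subtracted=True,
        )
        acf = compute_acf2d(stack, group_size=4, max_dx=16, max_dy=8)[0]
        iy, ix = acf.zero_index
        g00 = acf.values[iy, ix]
        assert g00 > 0
        off = acf.values.copy()
        off[iy, ix] = np.nan
        # uncorrelated pixels: off-lag correlations are pure noise around 0
        noise_floor = g00 / np.sqrt(128 * 128)
        assert np.nanmax(np.abs(off)) < 3 * noise_floor * 3

    def test_immobile_species_fast_axis_matches_psf(self, psf):
        # average ACFs over independent fields: a static pattern never
        # refreshes within one acquisition, so replication sets the precision
        geom = AcquisitionGeometry(
            pixel_size=0.03195, dwell=2.06e-6, line_time=5e-3,
            frame_time=192 * 5e-3, n_rows=192, n_cols=192,
        )
        vals = []
        for seed in range(4):
            sim = simulate_raster_stack(
                [SpeciesSpec(0.0, 90.0)], geom, psf, n_frames=1,
                nucleus_radius_um=2.6, seed=seed,
            )
            sub, *_ = subtract_background(sim.green)
            acf = compute_acf2d(sub, sim.analysis_mask, group_size=1)[0]
            vals.append(acf.values)
        mean_acf = acf.copy_with(np.mean(vals, axis=0))
        fit = fit_fast_axis(mean_acf, psf)
        assert fit.converged
        assert fit.w0 == pytest.approx(psf.w0, rel=0.12)

    def test_masked_acf_equals_subregion_acf(self, geometry_small, rng):
        # smooth random field so there is spatial correlation to estimate
        from scipy import ndimage

        frame = ndimage.gaussian_filter(rng.normal(0, 1, (128, 128)), 3) + 10
        stack = ImageStack(frame[None], geometry_small, offset_subtracted=True)
        half = np.zeros((128, 128), dtype=bool)
        half[:, :64] = True
        masked = compute_acf2d(
            stack, NuclearMask(half), group_size=1, max_dx=12, max_dy=8
        )[0]
        sub_geom = AcquisitionGeometry(
            pixel_size=geometry_small.pixel_size,
            dwell=geometry_small.dwell,
            line_time=geometry_small.line_time,
            frame_time=geometry_small.frame_time,
            n_rows=128,
            n_cols=64,
        )
        cropped_stack = ImageStack(
            frame[None, :, :64], sub_geom, offset_subtracted=True
        )
        cropped = compute_acf2d(cropped_stack, group_size=1, max_dx=12, max_dy=8)[0]
        both = np.isfinite(masked.values) & np.isfinite(cropped.values)
        np.testing.assert_allclose(
            masked.values[both], cropped.values[both], rtol=1e-9, atol=1e-12
        )

    def test_gain_invariance_of_acf_and_phi(self, geometry_small, psf, rng):
        from scipy import ndimage

        data = np.stack(
            [ndimage.gaussian_filter(rng.normal(0, 1, (128, 128)), 2) + 5
             for _ in range(3)]
        )
        stack = ImageStack(data, geometry_small, offset_subtracted=True)
        acf1 = compute_acf2d(stack, group_size=3, max_dx=16, max_dy=8)[0]
        acf2 = compute_acf2d(stack.scaled(7.3), group_size=3, max_dx=16, max_dy=8)[0]
        np.testing.assert_allclose(acf1.values, acf2.values, rtol=1e-10)
        a = fit_fast_axis(acf1, psf).amplitude
        f1 = fit_two_component(acf1, a, 3.0, psf)
        f2 = fit_two_component(acf2, a, 3.0, psf)
        assert f1.phi == pytest.approx(f2.phi, abs=1e-9)

    def test_small_mask_rejected(self, geometry_small, rng):
        stack = ImageStack(
            rng.normal(10, 1, (1, 128, 128)), geometry_small, offset_subtracted=True
        )
        tiny = np.zeros((128, 128), dtype=bool)
        tiny[:10, :10] = True
        with pytest.raises(ValueError):
            compute_acf2d(stack, NuclearMask(tiny))


class TestFastAxisFit:
    def test_exact_recovery_noise_free(self, geometry_case1, psf):
        acf = model_acf(0.02, 0.0, geometry_case1, psf)
        fit = fit_fast_axis(acf, psf)
        assert fit.amplitude == pytest.approx(0.02, rel=1e-6)
        assert fit.w0 == pytest.approx(psf.w0, rel=1e-6)
        assert abs(fit.background) < 1e-8
        assert not fit.background_pinned

    def test_large_offset_pins_background(self, geometry_case1, psf):
        acf = model_acf(0.02, 0.0, geometry_case1, psf)
        shifted = acf.copy_with(acf.values + 1e-2)
        with pytest.warns(UserWarning, match="pinned"):
            fit = fit_fast_axis(shifted, psf)
        assert fit.background_pinned
        assert abs(fit.background) == pytest.approx(1e-3)


class TestTwoComponentFit:
    def test_noise_free_baseline_recovery(self, geometry_case1, psf):
        base = two_component_baseline(psf)
        study = simulate_acf_study(
            "two", geometry_case1, base, NoiseProtocol(1, 0.0, 0.0, 0)
        )
        fit = fit_two_component(study.acfs[0], base.amplitude, 3.0, psf)
        assert fit.phi == pytest.approx(0.75, abs=1e-6)
        assert not fit.at_boundary

    def test_pure_free_diffusion_hits_boundary(self, geometry_case1, psf):
        acf = model_acf(0.02, 3.0, geometry_case1, psf)
        fit = fit_two_component(acf, 0.02, 3.0, psf)
        assert fit.phi == pytest.approx(0.0, abs=1e-6)
        assert fit.at_boundary

    def test_jittered_study_mean_recovers_baseline(self, geometry_case1, psf):
        base = two_component_baseline(psf)
        study = simulate_acf_study(
            "two", geometry_case1, base, NoiseProtocol(20, 0.10, 0.02, 5)
        )
        phis = np.array(
            [fit_two_component(a, base.amplitude, 3.0, psf).phi for a in study.acfs]
        )
        se = phis.std(ddof=1) / np.sqrt(len(phis))
        assert abs(phis.mean() - 0.75) < max(2 * se, 0.02)


class TestThreeComponentFit:
    def test_noise_free_baseline_recovery(self, geometry_case1, psf):
        base = three_component_baseline(psf)
        study = simulate_acf_study(
            "three", geometry_case1, base, NoiseProtocol(1, 0.0, 0.0, 0)
        )
        fit = fit_three_component(
            study.acfs[0], base.amplitude, 0.25, (0.0, 0.1, 3.0), psf
        )
        assert fit.phi1 == pytest.approx(0.50, abs=1e-6)

    def test_zero_cluster_truth_returns_boundary_zero(self, geometry_case1, psf):
        base = two_component_baseline(psf)  # no cluster component
        study = simulate_acf_study(
            "two", geometry_case1, base, NoiseProtocol(1, 0.0, 0.0, 0)
        )
        fit = fit_three_component(
            study.acfs[0], base.amplitude, 0.75, (0.0, 0.1, 3.0), psf
        )
        assert fit.phi1 == pytest.approx(0.0, abs=1e-6)
        assert fit.at_boundary

    def test_infeasible_phi0_rejected(self, geometry_case1, psf):
        acf = model_acf(0.02, 0.0, geometry_case1, psf)
        with pytest.raises(ValueError):
            fit_three_component(acf, 0.02, 1.5)

    def test_noise_free_self_consistency_all_orders(self, geometry_case1, psf):
        """Free-parameter recovery to <0.1% for one-, two-, three-component."""
        a = 0.02
        one = model_acf(a, 0.0, geometry_case1, psf)
        assert fit_fast_axis(one, psf).amplitude == pytest.approx(a, rel=1e-3)
        base2 = two_component_baseline(psf)
        acf2 = simulate_acf_study(
            "two", geometry_case1, base2, NoiseProtocol(1, 0.0, 0.0, 0)
        ).acfs[0]
        assert fit_two_component(acf2, base2.amplitude, 3.0, psf).phi == pytest.approx(
            0.75, rel=1e-3
        )
        base3 = three_component_baseline(psf)
        acf3 = simulate_acf_study(
            "three", geometry_case1, base3, NoiseProtocol(1, 0.0, 0.0, 0)
        ).acfs[0]
        assert fit_three_component(
            acf3, base3.amplitude, 0.25, (0.0, 0.1, 3.0), psf
        ).phi1 == pytest.approx(0.50, rel=1e-3)


class TestSlowAxisProfile:
    @pytest.mark.parametrize("case", ["case-1", "case-2"])
    def test_two_component_stays_inside_psf(self, case, psf):
        from tfpop.synthetic import case_geometry

        geom = case_geometry(case)
        base = two_component_baseline(psf)
        study = simulate_acf_study("two", geom, base, NoiseProtocol(20, 0.1, 0.02, 42))
        mean_acf = study.acfs[0].copy_with(
            np.mean([a.values for a in study.acfs], axis=0)
        )
        prof = slow_axis_profile(
            mean_acf, psf, noise_sd=0.02 * base.amplitude / np.sqrt(20)
        )
        assert not prof.exceeds_psf

    @pytest.mark.parametrize("case", ["case-1", "case-2"])
    def test_three_component_extends_past_psf(self, case, psf):
        from tfpop.synthetic import case_geometry

        geom = case_geometry(case)
        base = three_component_baseline(psf)
        study = simulate_acf_study(
            "three", geom, base, NoiseProtocol(20, 0.1, 0.02, 42)
        )
        mean_acf = study.acfs[0].copy_with(
            np.mean([a.values for a in study.acfs], axis=0)
        )
        prof = slow_axis_profile(
            mean_acf, psf, noise_sd=0.02 * base.amplitude / np.sqrt(20)
        )
        assert prof.exceeds_psf

    def test_immobile_profile_equals_psf(self, geometry_case1, psf):
        acf = model_acf(0.02, 0.0, geometry_case1, psf)
        prof = slow_axis_profile(acf, psf, noise_sd=1e-9)
        np.testing.assert_allclose(prof.profile, prof.psf_reference, atol=1e-12)
        assert not prof.exceeds_psf


class TestSegmentation:
    def test_bright_disks_recovered(self, geometry_small, rng):
        yy, xx = np.mgrid[:128, :128]
        truth = ((yy - 40) ** 2 + (xx - 40) ** 2 < 20**2) | (
            (yy - 90) ** 2 + (xx - 90) ** 2 < 18**2
        )
        frame = rng.normal(100, 10, (2, 128, 128))
        frame[:, truth] += 300
        mask = segment_nuclei(ImageStack(frame, geometry_small))
        got = mask.for_frame(0)
        jaccard = (got & truth).sum() / (got | truth).sum()
        assert jaccard > 0.9

    def test_uniform_frame_raises(self, geometry_small):
        stack = ImageStack(np.full((1, 128, 128), 7.0), geometry_small)
        with pytest.raises(ValueError):
            segment_nuclei(stack)

    def test_full_frame_override(self, geometry_small):
        mask = NuclearMask.full_frame(geometry_small)
        assert mask.mask.all()


def test_positive_quadrant_folding(geometry_small):
    dxs = np.arange(-2, 3)
    dys = np.arange(-1, 2)
    vals = np.arange(15, dtype=float).reshape(3, 5)
    acf = Acf2D(vals, dxs, dys, geometry_small)
    folded = positive_quadrant(acf)
    assert folded.dx_shifts.tolist() == [0, 1, 2]
    # G(1, 0): average of values at (+-1, 0)
    assert folded.values[0, 1] == pytest.approx((vals[1, 3] + vals[1, 1]) / 2)
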