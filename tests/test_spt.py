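"""Unit tests for step-size-distribution analysis and defocalization."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from tfpop import (
    ImageStack,
    StepSet,
    TrajectoryTable,
    calibrate_localization,
    compute_snr,
    effective_axial_range,
    extract_steps,
    fit_ssd,
    msd_analysis,
    rayleigh_mixture_pdf,
    zcorr,
)
from tfpop.spt import axial_survival_probability
from tfpop.synthetic import (
    StepMixtureSpec,
    mixture_90ms,
    mixture_500ms,
    sample_steps_defocalized,
    sample_steps_rayleigh,
    simulate_trajectories,
)


def mc_slab_survival(d, dt, dz, n=100_000, substeps=256, seed=0):
    """Brute-force absorbing-slab survival: fine random walk with a
    Brownian-bridge crossing test per substep (independent oracle)."""
    rng = np.random.default_rng(seed)
    half = dz / 2.0
    z = rng.uniform(-half, half, n)
    alive = np.ones(n, dtype=bool)
    dts = dt / substeps
    sd = np.sqrt(2 * d * dts)
    var = 2 * d * dts
    for _ in range(substeps):
        zn = z + rng.normal(0, 1, n) * sd
        esc = np.abs(zn) >= half
        p_up = np.exp(-2 * (half - z) * (half - zn) / var)
        p_dn = np.exp(-2 * (half + z) * (half + zn) / var)
        cross = rng.uniform(0, 1, n) < np.clip(p_up + p_dn - p_up * p_dn, 0, 1)
        alive &= ~(esc | cross)
        z = zn
    return alive.mean()


class TestTrajectoryTable:
    def test_short_trajectories_discarded(self):
        df = pd.DataFrame(
            {
                "particle": [0] * 3 + [1] * 5,
                "frame": [0, 1, 2, 0, 1, 2, 3, 4],
                "x_um": 0.0,
                "y_um": 0.0,
            }
        )
        table = TrajectoryTable(df, frame_interval=0.09)
        # particle 0 has only 2 steps -> dropped; particle 1 (4 steps) kept
        assert table.n_trajectories == 1
        assert set(table.data["particle"]) == {1}

    def test_duplicate_frames_rejected(self):
        df = pd.DataFrame(
            {"particle": [0] * 4, "frame": [0, 1, 1, 3], "x_um": 0.0, "y_um": 0.0}
        )
        with pytest.raises(ValueError):
            TrajectoryTable(df, frame_interval=0.09)


class TestExtractSteps:
    def test_step_count_and_gaps(self):
        df = pd.DataFrame(
            {
                "particle": [0] * 5 + [1] * 5,
                "frame": [0, 1, 2, 3, 4, 0, 1, 2, 4, 5],
                "x_um": np.arange(10, dtype=float),
                "y_um": 0.0,
            }
        )
        table = TrajectoryTable(df, frame_interval=0.09)
        steps = extract_steps(table)
        # particle 0: 4 consecutive steps; particle 1: frames 2->4 is a gap
        assert steps.steps.size == 4 + 3
        np.testing.assert_allclose(steps.steps, 1.0)

    def test_stationary_particle_mean_square_is_4_sigma2(self):
        sigma2 = 4.5e-4
        mix = StepMixtureSpec(((0.0, 1.0),), localization_variance=sigma2)
        traj = simulate_trajectories(mix, 400, 30, seed=1)
        assert traj.n_trajectories == 400  # no axial loss
        steps = extract_steps(traj)
        assert np.mean(steps.steps**2) == pytest.approx(4 * sigma2, rel=0.05)


class TestSnr:
    def _spot_stack(self, geometry, rng, amplitude=100.0, sd=10.0):
        data = rng.normal(0.0, sd, (1, 128, 128))
        spots = [(30, 30), (70, 90), (100, 50)]
        for r, c in spots:
            data[0, r, c] += amplitude
        stack = ImageStack(data + 200.0, geometry, offset_subtracted=False)
        det = np.array([[0, r, c] for r, c in spots])
        return stack, det

    def test_snr_of_synthetic_spots(self, geometry_small, rng):
        stack, det = self._spot_stack(geometry_small, rng)
        snr = compute_snr(stack, det)
        assert snr == pytest.approx(100.0 / 10.0 + 200.0 / 10.0, rel=0.2)

    def test_gain_invariance(self, geometry_small, rng):
        stack, det = self._spot_stack(geometry_small, rng)
        s1 = compute_snr(stack, det)
        s2 = compute_snr(stack.scaled(3.0), det)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_uniform_image_raises(self, geometry_small):
        stack = ImageStack(np.full((1, 128, 128), 5.0), geometry_small)
        with pytest.raises(ValueError):
            compute_snr(stack, np.array([[0, 10, 10]]))

    def test_out_of_bounds_detection_rejected(self, geometry_small, rng):
        stack = ImageStack(rng.normal(0, 1, (1, 128, 128)), geometry_small)
        with pytest.raises(ValueError):
            compute_snr(stack, np.array([[0, 500, 10]]))


class TestLocalizationCalibration:
    def test_exact_recovery(self):
        a, b = 2e-3, 5e-3
        snr = np.array([2.0, 5.0, 10.0, 20.0, 50.0])
        pts = list(zip(snr, a / snr + b / snr**2))
        cal = calibrate_localization(pts)
        assert cal.a_bg == pytest.approx(a, rel=1e-8)
        assert cal.b_shot == pytest.approx(b, rel=1e-8)

    def test_high_snr_limit(self):
        cal = calibrate_localization([(2, 1e-3), (5, 4e-4), (10, 2e-4)])
        assert cal.predict(1e9) == pytest.approx(0.0, abs=1e-10)

    def test_held_out_prediction(self, rng):
        # bead-like calibration at 8 laser powers with measurement noise
        a, b = 1.5e-3, 8e-3
        snr = np.array([2.0, 3.0, 4.5, 6.0, 8.0, 12.0, 18.0, 25.0])
        s2 = (a / snr + b / snr**2) * rng.normal(1.0, 0.03, snr.size)
        held = 4
        pts = [(s, v) for i, (s, v) in enumerate(zip(snr, s2)) if i != held]
        cal = calibrate_localization(pts)
        truth = a / snr[held] + b / snr[held] ** 2
        assert cal.predict(snr[held]) == pytest.approx(truth, rel=0.15)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            calibrate_localization([(5, 1e-3), (5, 1e-3), (5, 1e-3)])


class TestEffectiveAxialRange:
    def test_zero_diffusivity(self):
        assert effective_axial_range(0.7, 0.0) == pytest.approx(0.7)

    def test_square_root_arithmetic(self):
        # 0.7 + 0.21 * sqrt(0.1) = 0.7 + 0.21 * 0.31623
        assert effective_axial_range(0.7, 0.1) == pytest.approx(0.76641, abs=1e-4)

    def test_monotone_in_diffusivity(self):
        vals = [effective_axial_range(0.7, d) for d in (0.0, 0.05, 0.1, 1.0)]
        assert np.all(np.diff(vals) > 0)


class TestZcorr:
    def test_limits_are_unity(self):
        assert zcorr(0.0, 0.09, 0.7) == 1.0
        assert zcorr(3.0, 0.0, 0.7) == 1.0

    def test_against_monte_carlo(self):
        d, dt, dz = 3.0, 0.09, 1.06
        mc = mc_slab_survival(d, dt, dz, n=150_000)
        se = np.sqrt(mc * (1 - mc) / 150_000)
        assert abs(zcorr(d, dt, dz) - mc) < max(3 * se, 0.01 * mc)

    def test_against_eigenfunction_series(self):
        # independent closed form: uniform-start survival of the absorbing
        # slab, S(t) = sum_odd 8/(pi k)^2 exp(-(k pi)^2 D t / dz^2)
        d, dt, dz = 0.5, 0.1, 0.9
        ks = np.arange(1, 200, 2)
        s = np.sum(8.0 / (np.pi * ks) ** 2 * np.exp(-((ks * np.pi) ** 2) * d * dt / dz**2))
        assert zcorr(d, dt, dz) == pytest.approx(s, rel=1e-6)

    def test_monotone_decreasing_in_time(self):
        vals = [zcorr(0.1, t, 0.766) for t in (0.01, 0.05, 0.09, 0.5)]
        assert np.all(np.diff(vals) < 0)

    def test_survival_probability_bounds(self):
        z = np.linspace(-0.35, 0.35, 11)
        s = axial_survival_probability(z, 0.1, 0.09, 0.7)
        assert np.all((s >= 0) & (s <= 1))
        assert s[5] == s.max()  # center of the slab survives best


class TestRayleighMixturePdf:
    @pytest.mark.parametrize(
        "mix",
        [mixture_90ms(), mixture_500ms(),
         StepMixtureSpec(((0.5, 0.2), (0.05, 0.3), (0.001, 0.5)))],
    )
    def test_density_normalizes(self, mix):
        val, _ = quad(
            lambda r: rayleigh_mixture_pdf(
                r, mix.weights, mix.diffusivities, mix.localization_variance,
                mix.frame_interval,
            ),
            0,
            np.inf,
            limit=200,
        )
        assert val == pytest.approx(1.0, abs=1e-6)


class TestFitSsd:
    def test_weights_sum_to_one(self):
        steps = sample_steps_rayleigh(mixture_90ms(), 20_000, seed=0)
        for k in (1, 2, 3):
            fit = fit_ssd(steps, k=k)
            assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_loglik_nondecreasing_in_k(self):
        steps = sample_steps_rayleigh(mixture_90ms(), 20_000, seed=1)
        lls = [fit_ssd(steps, k=k).log_likelihood for k in (1, 2, 3)]
        assert lls[1] >= lls[0] - 1e-6
        assert lls[2] >= lls[1] - 1e-6

    def test_recovery_bias_over_replicates(self):
        """Each recovered diffusivity is within 10% of truth on average."""
        mix = mixture_90ms()
        recovered = []
        for seed in range(20):
            steps = sample_steps_rayleigh(mix, 50_000, seed=seed)
            fit = fit_ssd(steps, k=2)
            recovered.append(fit.diffusivities)
        mean_d = np.mean(recovered, axis=0)
        np.testing.assert_allclose(mean_d, [0.1, 0.01], rtol=0.10)

    def test_corrected_fit_recovers_true_fractions(self):
        dz = effective_axial_range(0.7, 0.1)
        mix = mixture_90ms(axial_range=dz)
        steps = sample_steps_defocalized(mix, 50_000, seed=3)
        fit = fit_ssd(steps, k=2, correction=True, dz=dz)
        assert fit.corrected
        assert fit.diffusivities[0] == pytest.approx(0.1, rel=0.15)
        assert fit.weights[1] == pytest.approx(0.66, abs=0.05)
        # raw step-mixture weights over-represent the slow component
        assert fit.observed_weights[1] > fit.weights[1]

    def test_correction_requires_slab(self):
        steps = sample_steps_rayleigh(mixture_90ms(), 1000, seed=0)
        with pytest.raises(ValueError):
            fit_ssd(steps, k=2, correction=True)
        with pytest.raises(ValueError):
            fit_ssd(steps, k=3, correction=True, dz=0.7)

    def test_k_bounds(self):
        steps = sample_steps_rayleigh(mixture_90ms(), 1000, seed=0)
        with pytest.raises(ValueError):
            fit_ssd(steps, k=4)

    def test_overfit_of_single_component_adds_no_evidence(self):
        mix = StepMixtureSpec(((0.05, 1.0),))
        steps = sample_steps_rayleigh(mix, 20_000, seed=5)
        f1 = fit_ssd(steps, k=1)
        f2 = fit_ssd(steps, k=2)
        # one true component: the second component carries no statistical
        # support (likelihood-ratio statistic far below the 2-dof threshold)
        assert 2 * (f2.log_likelihood - f1.log_likelihood) < 9.2


class TestMsd:
    def _table(self, xy, dt=0.09):
        frames = np.arange(xy.shape[1])
        rows = []
        for p in range(xy.shape[0]):
            rows.append(
                pd.DataFrame(
                    {"particle": p, "frame": frames,
                     "x_um": xy[p, :, 0], "y_um": xy[p, :, 1]}
                )
            )
        return TrajectoryTable(pd.concat(rows), frame_interval=dt)

    def test_free_brownian_slope_near_one(self, rng):
        d, dt = 0.1, 0.09
        steps = rng.normal(0, np.sqrt(2 * d * dt), (200, 29, 2))
        xy = np.concatenate([np.zeros((200, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
        res = msd_analysis(self._table(xy), max_lag=8)
        assert res.loglog_slope == pytest.approx(1.0, abs=0.1)

    def test_confined_motion_is_subdiffusive(self, rng):
        d, dt, box = 0.1, 0.09, 0.15  # confinement much smaller than free range
        xy = np.zeros((200, 30, 2))
        for t in range(1, 30):
            step = rng.normal(0, np.sqrt(2 * d * dt), (200, 2))
            xy[:, t] = np.clip(xy[:, t - 1] + step, -box, box)
        res = msd_analysis(self._table(xy), max_lag=8)
        assert res.loglog_slope < 1.0
        assert res.msd_over_t_slope_sign < 0

    def test_immobile_with_noise_is_flat(self, rng):
        sigma2 = 4.5e-4
        xy = rng.normal(0, np.sqrt(sigma2), (100, 20, 2))
        res = msd_analysis(self._table(xy), max_lag=6)
        np.testing.assert_allclose(res.msd, 4 * sigma2, rtol=0.15)

    def test_too_few_trajectories_rejected(self, rng):
        xy = rng.normal(0, 0.01, (5, 20, 2))
        with pytest.raises(ValueError):
            msd_analysis(self._table(xy))


class TestStepSet:
    def test_rejects_negative_steps(self):
        with pytest.raises(ValueError):
            StepSet(np.array([0.1, -0.2]), 0.09)

    def test_rejects_nonpositive_lag(self):
        with pytest.raises(ValueError):
            StepSet(np.array([0.1]), 0.0)
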