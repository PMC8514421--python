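"""Arc length, quintic smoothing spline, derivatives, peaks and averaging."""

import math

import numpy as np
import pytest

from trapjaw.io import CalibratedTrajectory, calibrate
from trapjaw.kinematics import (
    DisplacementSeries,
    analyze_track,
    average_chelicerae,
    cumulative_arc_length,
    differentiate,
    fit_quintic_spline,
    strike_window,
)
from trapjaw.simulate import StrikeSimConfig, simulate_strike


def _traj(points_mm, times=None, L=1.0):
    points_mm = np.asarray(points_mm, dtype=float)
    if times is None:
        times = np.arange(len(points_mm)) / 1000.0
    return CalibratedTrajectory(
        times=np.asarray(times, float), points_mm=points_mm, cheliceral_length_mm=L
    )


def _series(times, theta, L=1.0):
    times = np.asarray(times, float)
    theta = np.asarray(theta, float)
    return DisplacementSeries(
        times=times, s_mm=theta * L, theta_rad=theta, cheliceral_length_mm=L
    )


class TestArcLength:
    def test_stationary_point_gives_zero_displacement(self):
        series = cumulative_arc_length(_traj(np.ones((5, 2))))
        np.testing.assert_array_equal(series.s_mm, 0.0)

    def test_three_four_five_chord(self):
        series = cumulative_arc_length(_traj([[0.0, 0.0], [3.0, 4.0]]))
        np.testing.assert_allclose(series.s_mm, [0.0, 5.0])

    def test_quarter_circle_chord_sum_error_below_half_thousandth_percent(self):
        # 91 points at 1 degree spacing on a unit-radius quarter circle;
        # the per-step chord deficit is 1 - sinc(delta/2) ~ 1.3e-5
        ang = np.radians(np.arange(91.0))
        pts = np.column_stack([np.cos(ang), np.sin(ang)])
        series = cumulative_arc_length(_traj(pts))
        assert series.s_mm[-1] == pytest.approx(math.pi / 2, rel=5e-5)

    def test_theta_is_arc_length_over_L(self):
        pts = np.column_stack([np.linspace(0, 2, 7), np.zeros(7)])
        series = cumulative_arc_length(_traj(pts, L=0.5))
        np.testing.assert_allclose(series.theta_rad, series.s_mm / 0.5)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            cumulative_arc_length(_traj(np.ones((5, 2)), L=-1.0))


class TestSplineFit:
    def test_constant_displacement_gives_zero_velocity(self):
        t = np.linspace(0, 1, 30)
        fit = fit_quintic_spline(_series(t, np.full_like(t, 2.5)))
        assert np.max(np.abs(fit.omega(t))) < 1e-8

    def test_linear_displacement_reproduced_with_constant_velocity(self):
        t = np.linspace(0, 0.02, 40)
        b = 130.0
        fit = fit_quintic_spline(_series(t, b * t))
        np.testing.assert_allclose(fit.omega(t), b, rtol=1e-6)

    def test_noiseless_quintic_polynomial_reproduced_exactly(self):
        # a degree-5 polynomial lies in the spline space; GCV drives the
        # penalty to (near) zero and the fit reproduces it to solver tolerance
        t = np.linspace(0, 1, 60)
        y = 1 + 2 * t - 3 * t**2 + 4 * t**3 - 2 * t**4 + 0.5 * t**5
        fit = fit_quintic_spline(_series(t, y))
        np.testing.assert_allclose(fit.theta(t), y, atol=1e-8)

    def test_smoothstep_peak_velocity_recovered_within_one_percent(self, clean_sim):
        series = cumulative_arc_length(calibrate(clean_sim.tracks["R"]))
        fit = fit_quintic_spline(series)
        grid = np.linspace(fit.t_start, fit.t_end, 5000)
        peak = np.max(fit.omega(grid))
        assert peak == pytest.approx(clean_sim.truth.peak_omega, rel=0.01)

    def test_spline_derivatives_match_finite_differences_of_fit(self, noisy_sim):
        # independent oracle: central differences of the fitted displacement
        series = cumulative_arc_length(calibrate(noisy_sim.tracks["L"]))
        fit = fit_quintic_spline(series)
        grid = np.linspace(fit.t_start, fit.t_end, 1200)[100:-100]
        h = (grid[1] - grid[0]) / 10.0
        fd_omega = (fit.theta(grid + h) - fit.theta(grid - h)) / (2 * h)
        fd_alpha = (fit.theta(grid + h) - 2 * fit.theta(grid) + fit.theta(grid - h)) / h**2
        np.testing.assert_allclose(fit.omega(grid), fd_omega,
                                   rtol=1e-3, atol=1e-3 * np.max(np.abs(fd_omega)))
        np.testing.assert_allclose(fit.alpha(grid), fd_alpha,
                                   rtol=1e-3, atol=1e-3 * np.max(np.abs(fd_alpha)))

    def test_df_override_controls_effective_degrees_of_freedom(self, noisy_sim):
        series = cumulative_arc_length(calibrate(noisy_sim.tracks["R"]))
        fit = fit_quintic_spline(series, df=8.0)
        assert fit.edf == pytest.approx(8.0, abs=0.05)

    def test_too_few_or_degenerate_times_rejected(self):
        t = np.linspace(0, 1, 5)
        with pytest.raises(ValueError, match="at least 6"):
            fit_quintic_spline(_series(t, t))
        t = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            fit_quintic_spline(_series(t, t))

    def test_evaluation_outside_fitted_interval_rejected(self):
        t = np.linspace(0, 1, 30)
        fit = fit_quintic_spline(_series(t, t**2))
        with pytest.raises(ValueError, match="outside fitted interval"):
            fit.omega(np.array([1.5]))


class TestDifferentiate:
    def test_linear_theta_gives_zero_acceleration(self):
        t = np.linspace(0, 0.02, 40)
        fit = fit_quintic_spline(_series(t, 200.0 * t))
        profile = differentiate(fit, n_input=40)
        assert np.max(np.abs(profile.alpha)) < 1e-3 * 200.0 / 0.02

    def test_smoothstep_peak_acceleration_recovered_within_three_percent(self, clean_sim):
        profile = analyze_track(clean_sim.tracks["R"])
        assert profile.peak_alpha == pytest.approx(clean_sim.truth.peak_alpha, rel=0.03)

    def test_linear_peaks_are_omega_alpha_times_L(self, noisy_sim):
        profile = analyze_track(noisy_sim.tracks["R"])
        L_m = profile.cheliceral_length_mm * 1e-3
        assert profile.peak_v == pytest.approx(profile.peak_omega * L_m, rel=1e-12)
        assert profile.peak_a == pytest.approx(profile.peak_alpha * L_m, rel=1e-12)

    def test_mean_study_scale_linear_velocity(self):
        # unit bookkeeping: 384.25 rad/s at a 0.46 mm chelicera is 0.177 m/s
        assert 384.25 * 0.46e-3 == pytest.approx(0.1768, abs=5e-4)

    def test_sweep_matches_gape_on_clean_simulation(self, clean_sim):
        profile = analyze_track(clean_sim.tracks["L"])
        assert profile.sweep_rad == pytest.approx(clean_sim.truth.gape_rad, rel=0.005)


class TestStrikeWindow:
    def test_default_duration_is_first_to_last_frame(self, clean_sim):
        series = cumulative_arc_length(calibrate(clean_sim.tracks["R"]))
        t0, t1, dur = strike_window(series)
        assert (t0, t1) == (series.times[0], series.times[-1])
        assert dur == pytest.approx(0.012, abs=1e-12)

    def test_thresholded_window_is_inside_strike_and_symmetric(self, clean_sim):
        series = cumulative_arc_length(calibrate(clean_sim.tracks["R"]))
        t0, t1, dur = strike_window(series, threshold_frac=0.02)
        T = clean_sim.truth.duration_s
        assert 0.0 <= t0 < t1 <= T
        # smoothstep velocity is symmetric about T/2
        assert (t0 + t1) / 2 == pytest.approx(T / 2, abs=0.02 * T)

    def test_threshold_outside_unit_interval_rejected(self, clean_sim):
        series = cumulative_arc_length(calibrate(clean_sim.tracks["R"]))
        with pytest.raises(ValueError):
            strike_window(series, threshold_frac=1.5)

    def test_single_frame_series_rejected(self):
        series = _series([0.0], [0.0])
        with pytest.raises(ValueError):
            strike_window(series)


class TestAverageChelicerae:
    def test_identical_profiles_average_to_themselves(self, clean_sim):
        p = analyze_track(clean_sim.tracks["R"])
        avg = average_chelicerae(p, p)
        assert avg.peak_omega == pytest.approx(p.peak_omega, rel=1e-12)
        np.testing.assert_allclose(avg.omega, np.interp(avg.times, p.times, p.omega))

    def test_scalar_summaries_are_arithmetic_means(self, clean_sim):
        a = analyze_track(clean_sim.tracks["L"])
        b = analyze_track(clean_sim.tracks["R"])
        a.peak_omega, b.peak_omega = 100.0, 200.0
        avg = average_chelicerae(a, b)
        assert avg.peak_omega == 150.0

    def test_missing_chelicera_passes_through_flagged(self, clean_sim):
        p = analyze_track(clean_sim.tracks["L"])
        avg = average_chelicerae(p, None)
        assert avg.averaged_from_single_chelicera
        assert avg.peak_omega == p.peak_omega

    def test_mismatched_strike_ids_rejected(self, clean_sim):
        a = analyze_track(clean_sim.tracks["L"])
        b = analyze_track(clean_sim.tracks["R"])
        b.strike_id = "other"
        with pytest.raises(ValueError, match="mismatched strike identity"):
            average_chelicerae(a, b)


class TestParameterRecovery:
    def test_recovery_error_orders_with_noise_level(self):
        # digitization noise is the dominant error source: tripling it must
        # not improve the median recovery error
        medians = []
        for noise in (0.25, 0.75, 2.25):
            errs = []
            for seed in range(25):
                sim = simulate_strike(StrikeSimConfig(noise_px=noise, seed=seed,
                                                      digitize_every=4))
                p = analyze_track(sim.tracks["R"])
                errs.append(abs(p.peak_omega / sim.truth.peak_omega - 1))
            medians.append(np.median(errs))
        assert medians[0] <= medians[1] <= medians[2]
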