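"""Synthetic strike generator: closed-form peaks, geometry, determinism, round-trip."""

import math

import numpy as np
import pytest

from trapjaw.io import read_tracks
from trapjaw.simulate import (
    StrikeSimConfig,
    digitization_stride,
    digitized_frame_indices,
    make_angle_profile,
    simulate_strike,
    simulate_study,
    simulate_track,
    write_fixture,
)


class TestAngleProfile:
    def test_smoothstep_peaks_match_closed_forms(self):
        # Theta = pi, T = 1: peak omega = 1.875*pi, peak alpha = (10/sqrt 3)*pi
        cfg = StrikeSimConfig(gape_deg=180.0, duration_s=1.0)
        truth = make_angle_profile(cfg)
        assert truth.peak_omega == pytest.approx(1.875 * math.pi, rel=1e-12)
        assert truth.peak_alpha == pytest.approx(10.0 / math.sqrt(3.0) * math.pi, rel=1e-12)

    def test_closed_forms_agree_with_dense_grid_maximization(self):
        cfg = StrikeSimConfig(gape_deg=172.4, duration_s=0.012)
        truth = make_angle_profile(cfg)
        t = np.linspace(0.0, cfg.duration_s, 2_000_001)
        assert np.max(truth.omega_of_t(t)) == pytest.approx(truth.peak_omega, rel=1e-6)
        assert np.max(np.abs(truth.alpha_of_t(t))) == pytest.approx(truth.peak_alpha, rel=1e-6)

    def test_profile_boundary_conditions(self):
        cfg = StrikeSimConfig(gape_deg=150.0, duration_s=0.01)
        truth = make_angle_profile(cfg)
        T = cfg.duration_s
        assert truth.theta_of_t(0.0) == pytest.approx(0.0, abs=1e-15)
        assert truth.theta_of_t(T) == pytest.approx(truth.gape_rad, rel=1e-12)
        t = np.linspace(0, T, 1001)
        assert np.all(np.diff(truth.theta_of_t(t)) >= -1e-12)     # nondecreasing

    def test_peaks_scale_linearly_in_gape(self):
        small = make_angle_profile(StrikeSimConfig(gape_deg=1.0, duration_s=1.0))
        big = make_angle_profile(StrikeSimConfig(gape_deg=100.0, duration_s=1.0))
        assert big.peak_omega == pytest.approx(100 * small.peak_omega, rel=1e-12)
        assert big.peak_alpha == pytest.approx(100 * small.peak_alpha, rel=1e-12)

    def test_doubling_duration_halves_omega_quarters_alpha(self):
        t1 = make_angle_profile(StrikeSimConfig(gape_deg=160.0, duration_s=0.01))
        t2 = make_angle_profile(StrikeSimConfig(gape_deg=160.0, duration_s=0.02))
        assert t2.peak_omega == pytest.approx(t1.peak_omega / 2, rel=1e-12)
        assert t2.peak_alpha == pytest.approx(t1.peak_alpha / 4, rel=1e-12)

    @pytest.mark.parametrize("bad", [{"gape_deg": -10.0}, {"gape_deg": 200.0},
                                     {"duration_s": 0.0}, {"fps": -1.0}])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            StrikeSimConfig(**bad)


class TestSimulatedTracks:
    def test_noise_free_points_lie_on_circle_of_radius_L(self, clean_sim):
        cfg = clean_sim.config
        for track in clean_sim.tracks.values():
            radii = np.linalg.norm(track.points_px, axis=1)
            expected = cfg.cheliceral_length_mm / cfg.scale_mm_per_px
            np.testing.assert_allclose(radii, expected, rtol=1e-12)

    def test_same_seed_reproduces_identical_tracks(self):
        cfg = StrikeSimConfig(noise_px=0.5, seed=42)
        a = simulate_strike(cfg)
        b = simulate_strike(cfg)
        for side in ("L", "R"):
            np.testing.assert_array_equal(a.tracks[side].points_px, b.tracks[side].points_px)

    def test_digitized_frame_count_matches_counting_oracle(self):
        # floor(T * fps / stride) + 1 frames at stride k: 0, k, 2k, ...
        cfg = StrikeSimConfig(duration_s=0.012, fps=10_000.0, digitize_every=4)
        idx = digitized_frame_indices(cfg)
        oracle = len([k for k in range(0, 10**6, 4) if k / cfg.fps <= cfg.duration_s])
        assert len(idx) == oracle == 31
        assert len(idx) == math.floor(cfg.duration_s * cfg.fps / 4) + 1

    def test_chelicerae_are_synchronous_and_mirrored(self, clean_sim):
        left, right = clean_sim.tracks["L"], clean_sim.tracks["R"]
        np.testing.assert_array_equal(left.times, right.times)
        np.testing.assert_allclose(left.points_px[:, 0], -right.points_px[:, 0], atol=1e-9)
        np.testing.assert_allclose(left.points_px[:, 1], right.points_px[:, 1], atol=1e-9)

    def test_too_few_digitized_frames_rejected(self):
        cfg = StrikeSimConfig(duration_s=0.0004, fps=10_000.0)   # 5 frames only
        with pytest.raises(ValueError, match="at least 6"):
            simulate_track(make_angle_profile(cfg), cfg)

    def test_drift_translates_points_and_reference_alike(self):
        cfg = StrikeSimConfig(noise_px=0.0, drift_mm_per_s=(5.0, -2.0), seed=3)
        still = simulate_strike(StrikeSimConfig(noise_px=0.0, seed=3))
        moving = simulate_strike(cfg)
        shift = np.outer(moving.tracks["R"].times,
                         np.array([5.0, -2.0]) / cfg.scale_mm_per_px)
        np.testing.assert_allclose(
            moving.tracks["R"].points_px, still.tracks["R"].points_px + shift, atol=1e-9
        )
        np.testing.assert_allclose(moving.body_reference.points_px, shift, atol=1e-9)


class TestDigitizationProtocol:
    @pytest.mark.parametrize("fps,stride", [(1000, 1), (2500, 1), (5000, 2), (10_000, 4)])
    def test_stride_keeps_effective_rate_near_target(self, fps, stride):
        assert digitization_stride(fps) == stride


class TestFixtureIO:
    def test_write_then_read_round_trips(self, tmp_path, noisy_sim):
        paths = write_fixture(noisy_sim, tmp_path / "strike")
        tracks = read_tracks(paths["tracks"], paths["config"])
        assert len(tracks) == 2
        by_side = {t.side: t for t in tracks}
        for side in ("L", "R"):
            np.testing.assert_allclose(
                by_side[side].points_px, noisy_sim.tracks[side].points_px, rtol=1e-9
            )
            np.testing.assert_array_equal(
                by_side[side].frame_index, noisy_sim.tracks[side].frame_index
            )

    def test_empty_path_rejected(self, noisy_sim):
        with pytest.raises(ValueError, match="empty"):
            write_fixture(noisy_sim, "")


class TestStudyGeneration:
    def test_study_draws_respect_observed_ranges(self):
        sims = simulate_study(n_strikes=16, seed=11)
        assert len(sims) == 16
        for sim in sims:
            assert 152.62 <= sim.config.gape_deg <= 179.78
            assert 0.0034 <= sim.config.duration_s <= 0.0363
            assert 0.43 <= sim.config.cheliceral_length_mm <= 0.48

    def test_strikes_of_same_individual_share_cheliceral_length(self):
        sims = simulate_study(n_strikes=16, n_individuals=10, seed=5)
        lengths = {}
        for sim in sims:
            L = sim.config.cheliceral_length_mm
            lengths.setdefault(sim.config.specimen_id, L)
            assert lengths[sim.config.specimen_id] == L
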