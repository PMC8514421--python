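"""Synthetic cheliceral strikes with analytic ground truth.

The generator emulates what a high-speed camera and a human digitizer
produce: a point on a circular arc of radius equal to the cheliceral length,
swept through the gape angle by a smooth sigmoidal closure profile, sampled
at the camera frame rate, optionally digitized only every k-th frame,
translated by a constant-velocity body lunge, and corrupted by isotropic
Gaussian pixel noise of the digitizing click.

The default closure profile is the quintic smoothstep

    theta(t) = Theta * (10 tau^3 - 15 tau^4 + 6 tau^5),   tau = t / T,

which is C^2 at both ends and has closed-form extrema:

    peak omega = 1.875 * Theta / T          (at tau = 1/2)
    peak alpha = (10 / sqrt(3)) * Theta / T^2

so every downstream derivative estimate can be checked against an exact
answer. All randomness flows from a single integer seed through
``numpy.random.default_rng`` (PCG64).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from trapjaw.io import TrackedStrike, write_config, write_tracks

#: peak angular velocity coefficient of the quintic smoothstep, Theta/T units
SMOOTHSTEP_PEAK_OMEGA_COEF = 1.875
#: peak angular acceleration coefficient, Theta/T^2 units
SMOOTHSTEP_PEAK_ALPHA_COEF = 10.0 / math.sqrt(3.0)


@dataclass
class StrikeSimConfig:
    """Parameters of one simulated strike and its camera/digitizer model.

    Defaults are the study conditions of the species analysed here: a
    ~172 degree gape closed in 12 ms by a chelicera of length 0.46 mm,
    filmed at 10 kHz and digitized with half-pixel click noise.
    """

    gape_deg: float = 172.4          # total angular sweep Theta, degrees
    duration_s: float = 0.012        # closure time T, seconds
    cheliceral_length_mm: float = 0.46
    fps: float = 10_000.0
    scale_mm_per_px: float = 0.005
    noise_px: float = 0.5            # sd of digitization noise per coordinate
    drift_mm_per_s: tuple[float, float] = (0.0, 0.0)   # body-lunge velocity
    digitize_every: int = 1          # frame stride of the digitizer
    seed: int = 0
    profile: str = "smoothstep"
    specimen_id: str = "sim01"
    strike_id: str = "A"
    sex: str = "F"

    def __post_init__(self) -> None:
        if not 0.0 < self.gape_deg <= 180.0:
            raise ValueError(f"gape_deg must be in (0, 180], got {self.gape_deg}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.cheliceral_length_mm <= 0:
            raise ValueError("cheliceral_length_mm must be positive")
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale_mm_per_px must be positive")
        if self.noise_px < 0:
            raise ValueError("noise_px must be nonnegative")
        if int(self.digitize_every) != self.digitize_every or self.digitize_every < 1:
            raise ValueError("digitize_every must be an integer >= 1")

    @property
    def gape_rad(self) -> float:
        return math.radians(self.gape_deg)


@dataclass
class SimTruth:
    """Ground-truth closure profile with analytic peak kinematics."""

    theta_of_t: object               # callable t -> angular displacement, rad
    omega_of_t: object               # callable t -> rad/s
    alpha_of_t: object               # callable t -> rad/s^2
    peak_omega: float                # rad/s
    peak_alpha: float                # rad/s^2
    gape_rad: float
    duration_s: float
    profile: str = "smoothstep"


@dataclass
class SimulatedStrike:
    """Left/right digitized tracks plus the truth that generated them."""

    truth: SimTruth
    tracks: dict[str, TrackedStrike]          # keyed "L" / "R"
    config: StrikeSimConfig
    body_reference: TrackedStrike | None = None   # digitized pivot/body point

    @property
    def metadata(self) -> dict:
        c = self.config
        return {
            "fps": c.fps,
            "scale_mm_per_px": c.scale_mm_per_px,
            "cheliceral_length_mm": c.cheliceral_length_mm,
            "digitize_every": int(c.digitize_every),
            "sex": c.sex,
        }


def make_angle_profile(config: StrikeSimConfig) -> SimTruth:
    """Build the closure profile theta(t) and its analytic peak kinematics."""
    if config.profile != "smoothstep":
        raise ValueError(f"unknown profile family {config.profile!r}")
    theta_total = config.gape_rad
    T = config.duration_s

    def theta(t):
        tau = np.clip(np.asarray(t, dtype=float) / T, 0.0, 1.0)
        return theta_total * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)

    def omega(t):
        tau = np.asarray(t, dtype=float) / T
        inside = (tau >= 0) & (tau <= 1)
        tau = np.clip(tau, 0.0, 1.0)
        return np.where(inside, theta_total / T * 30 * tau**2 * (1 - tau) ** 2, 0.0)

    def alpha(t):
        tau = np.asarray(t, dtype=float) / T
        inside = (tau >= 0) & (tau <= 1)
        tau = np.clip(tau, 0.0, 1.0)
        return np.where(inside, theta_total / T**2 * (60 * tau - 180 * tau**2 + 120 * tau**3), 0.0)

    return SimTruth(
        theta_of_t=theta,
        omega_of_t=omega,
        alpha_of_t=alpha,
        peak_omega=SMOOTHSTEP_PEAK_OMEGA_COEF * theta_total / T,
        peak_alpha=SMOOTHSTEP_PEAK_ALPHA_COEF * theta_total / T**2,
        gape_rad=theta_total,
        duration_s=T,
        profile=config.profile,
    )


def digitized_frame_indices(config: StrikeSimConfig) -> np.ndarray:
    """Frame indices the digitizer marks: 0, k, 2k, ... while t <= T."""
    last_frame = int(math.floor(config.duration_s * config.fps))
    idx = np.arange(0, last_frame + 1, int(config.digitize_every))
    return idx


def simulate_track(truth: SimTruth, config: StrikeSimConfig) -> SimulatedStrike:
    """Render the truth profile into digitized left/right pixel tracks.

    The pivot sits at the origin; the chelicerae open symmetrically about the
    midline (the +y axis) to a half-gape of Theta/2 each, and closure sweeps
    each tracked point toward the midline. The left chelicera is the mirror
    image of the right. Both chelicerae share timestamps (synchronous strike).
    Deterministic for a fixed seed.
    """
    idx = digitized_frame_indices(config)
    if len(idx) < 6:
        raise ValueError(
            f"only {len(idx)} digitized frames fall inside the strike; "
            f"at least 6 are required (spline degree + 1)"
        )
    t = idx / config.fps
    theta = truth.theta_of_t(t)
    L = config.cheliceral_length_mm
    half_gape = truth.gape_rad / 2.0
    # angle of the tracked point measured from the midline (+y axis)
    phi = half_gape - theta
    right_mm = np.column_stack([L * np.sin(phi), L * np.cos(phi)])
    left_mm = np.column_stack([-L * np.sin(phi), L * np.cos(phi)])
    drift = np.outer(t, np.asarray(config.drift_mm_per_s, dtype=float))
    pivot_mm = drift                       # pivot starts at the origin

    rng = np.random.default_rng(config.seed)
    tracks: dict[str, TrackedStrike] = {}
    for side, pts_mm in (("L", left_mm), ("R", right_mm)):
        px = (pts_mm + drift) / config.scale_mm_per_px
        if config.noise_px > 0:
            px = px + rng.normal(0.0, config.noise_px, size=px.shape)
        tracks[side] = TrackedStrike(
            specimen_id=config.specimen_id,
            strike_id=config.strike_id,
            side=side,
            frame_index=idx,
            times=t,
            points_px=px,
            fps=config.fps,
            scale_mm_per_px=config.scale_mm_per_px,
            cheliceral_length_mm=L,
            sex=config.sex,
        )
    ref_px = pivot_mm / config.scale_mm_per_px
    if config.noise_px > 0:
        ref_px = ref_px + rng.normal(0.0, config.noise_px, size=ref_px.shape)
    body_reference = TrackedStrike(
        specimen_id=config.specimen_id,
        strike_id=config.strike_id,
        side="R",     # side code is irrelevant for a body point; reuse a valid code
        frame_index=idx,
        times=t,
        points_px=ref_px,
        fps=config.fps,
        scale_mm_per_px=config.scale_mm_per_px,
        cheliceral_length_mm=L,
        sex=config.sex,
    )
    return SimulatedStrike(truth=truth, tracks=tracks, config=config,
                           body_reference=body_reference)


def simulate_strike(config: StrikeSimConfig) -> SimulatedStrike:
    """Convenience: profile + track rendering in one call."""
    return simulate_track(make_angle_profile(config), config)


def write_fixture(sim: SimulatedStrike, path) -> dict[str, Path]:
    """Write one simulated strike as the track CSV + YAML metadata pair.

    Returns the written file paths. Round-trips losslessly at the CSV print
    precision (10 significant digits).
    """
    if str(path) == "":
        raise ValueError("empty output path")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tracks_csv = path / "tracks.csv"
    config_yaml = path / "config.yaml"
    truth_yaml = path / "truth.yaml"
    write_tracks([sim.tracks["L"], sim.tracks["R"]], tracks_csv)
    write_config(sim.metadata, config_yaml)
    with open(truth_yaml, "w") as fh:
        yaml.safe_dump(
            {
                "gape_rad": float(sim.truth.gape_rad),
                "duration_s": float(sim.truth.duration_s),
                "peak_omega_rad_s": float(sim.truth.peak_omega),
                "peak_alpha_rad_s2": float(sim.truth.peak_alpha),
                "profile": sim.truth.profile,
            },
            fh,
        )
    return {"tracks": tracks_csv, "config": config_yaml, "truth": truth_yaml}


# --- digitization protocol --------------------------------------------------

#: effective rate at which a human digitizer marks points. Above this frame
#: rate the inter-frame motion falls below the click-noise floor, so points
#: are digitized at set frame intervals instead of every frame (every 4th
#: frame at 10 kHz); below it every frame is digitized.
DIGITIZATION_RATE_HZ = 2500.0


def digitization_stride(fps: float, target_rate_hz: float = DIGITIZATION_RATE_HZ) -> int:
    """Frame stride of the digitization protocol for a recording at ``fps``."""
    return max(1, round(fps / target_rate_hz))


# --- study-level generation -------------------------------------------------

#: study conditions: distribution of strike parameters across the recorded
#: individuals (means +/- sd and ranges of gape, closure duration and
#: cheliceral length observed for this species)
STUDY_GAPE_MEAN_DEG = 172.4
STUDY_GAPE_SD_DEG = 7.9
STUDY_GAPE_RANGE_DEG = (152.62, 179.78)
STUDY_DURATION_MEAN_S = 0.012
STUDY_DURATION_SD_S = 0.009
STUDY_DURATION_RANGE_S = (0.0034, 0.0363)
STUDY_LENGTH_MEAN_MM = 0.46
STUDY_LENGTH_SD_MM = 0.019
STUDY_LENGTH_RANGE_MM = (0.43, 0.48)
STUDY_N_STRIKES = 16
STUDY_N_INDIVIDUALS = 10


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Draw from N(mean, sd) conditioned on [lo, hi] by resampling."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = (out < lo) | (out > hi)
    return out


def simulate_study(
    n_strikes: int = STUDY_N_STRIKES,
    n_individuals: int = STUDY_N_INDIVIDUALS,
    seed: int = 0,
    fps: float = 10_000.0,
    noise_px: float = 0.5,
    scale_mm_per_px: float = 0.005,
    digitize_every: int | None = None,
) -> list[SimulatedStrike]:
    """Simulate a whole recording campaign of synchronous two-chelicera strikes.

    Gape, closure duration and cheliceral length are drawn per strike from
    truncated normal distributions matching the observed species-level
    means, SDs and ranges; cheliceral length is a per-individual property so
    strikes of the same individual share it. Durations are lognormal on the
    observed range to reproduce the strong right skew of strike durations.
    """
    if n_strikes < 1:
        raise ValueError("n_strikes must be >= 1")
    if digitize_every is None:
        digitize_every = digitization_stride(fps)
    rng = np.random.default_rng(seed)
    lengths = _truncated_normal(
        rng, STUDY_LENGTH_MEAN_MM, STUDY_LENGTH_SD_MM, *STUDY_LENGTH_RANGE_MM,
        size=n_individuals,
    )
    # lognormal parameters matched to the observed duration mean and sd
    mu = math.log(STUDY_DURATION_MEAN_S**2
                  / math.sqrt(STUDY_DURATION_MEAN_S**2 + STUDY_DURATION_SD_S**2))
    sig = math.sqrt(math.log(1 + (STUDY_DURATION_SD_S / STUDY_DURATION_MEAN_S) ** 2))
    sims = []
    for k in range(n_strikes):
        individual = k % n_individuals
        gape = float(_truncated_normal(
            rng, STUDY_GAPE_MEAN_DEG, STUDY_GAPE_SD_DEG, *STUDY_GAPE_RANGE_DEG))
        dur = float(np.exp(rng.normal(mu, sig)))
        dur = min(max(dur, STUDY_DURATION_RANGE_S[0]), STUDY_DURATION_RANGE_S[1])
        cfg = StrikeSimConfig(
            gape_deg=gape,
            duration_s=dur,
            cheliceral_length_mm=float(lengths[individual]),
            fps=fps,
            scale_mm_per_px=scale_mm_per_px,
            noise_px=noise_px,
            digitize_every=digitize_every,
            seed=int(rng.integers(0, 2**31 - 1)),
            specimen_id=f"sim{individual + 1:02d}",
            strike_id=f"S{k + 1:02d}",
        )
        sims.append(simulate_strike(cfg))
    return sims
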