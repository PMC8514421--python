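"""Reading, validation, calibration and drift correction of tracked-point data.

Input tracks are CSV tables with one row per digitized frame per chelicera
(columns: ``specimen_id, strike_id, side, frame_index, time_s, x_px, y_px``)
plus a per-recording metadata config (YAML) holding the frame rate, the
mm-per-pixel scale, the cheliceral length and the digitization stride.
Frame indexing is 0-based and the first digitized frame of a strike defines
t = 0, so times of later frames are ``frame_index / fps``.

Coordinates are planar: recordings are made with the camera perpendicular to
the plane of cheliceral movement, so no 3D reconstruction is attempted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: columns required in a track CSV, in canonical order
TRACK_COLUMNS = ["specimen_id", "strike_id", "side", "frame_index", "time_s", "x_px", "y_px"]

#: metadata keys required in the per-recording config
CONFIG_KEYS = ["fps", "scale_mm_per_px", "cheliceral_length_mm"]

_SIDES = {"L", "R"}

# tolerance for time_s vs frame_index / fps consistency, seconds
_TIME_TOL_S = 1e-9


class TrackValidationError(ValueError):
    """A track file or object violates the schema; message names the offending rows."""


@dataclass
class TrackedStrike:
    """Raw digitized point series for one chelicera in one strike.

    The tracked point is the distal anteriomesal edge of the chelicera,
    digitized frame by frame (possibly at a stride > 1) over the course of
    cheliceral closure.
    """

    specimen_id: str
    strike_id: str
    side: str                      # "L" | "R"
    frame_index: np.ndarray        # int, 0-based, strictly increasing
    times: np.ndarray              # seconds, strictly increasing, times = frame_index / fps
    points_px: np.ndarray          # (n, 2) pixel coordinates
    fps: float                     # frames per second
    scale_mm_per_px: float         # mm per pixel
    cheliceral_length_mm: float    # L, mm
    sex: str = "unknown"

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.points_px = np.asarray(self.points_px, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.times)
        if n < 6:
            raise TrackValidationError(
                f"track {self.specimen_id}/{self.strike_id}/{self.side}: "
                f"{n} samples; at least 6 digitized points are required "
                f"(quintic spline degree + 1)"
            )
        if self.side not in _SIDES:
            raise TrackValidationError(f"unknown side code {self.side!r}; expected 'L' or 'R'")
        if self.points_px.shape != (n, 2):
            raise TrackValidationError(
                f"points_px shape {self.points_px.shape} does not match {n} timestamps"
            )
        if np.any(np.diff(self.times) <= 0):
            bad = int(np.nonzero(np.diff(self.times) <= 0)[0][0]) + 1
            raise TrackValidationError(f"times not strictly increasing at sample {bad}")
        if np.any(np.diff(self.frame_index) <= 0):
            bad = int(np.nonzero(np.diff(self.frame_index) <= 0)[0][0]) + 1
            raise TrackValidationError(f"frame_index not strictly increasing at sample {bad}")
        if self.fps <= 0:
            raise TrackValidationError("fps must be positive")
        if self.scale_mm_per_px <= 0:
            raise TrackValidationError("scale_mm_per_px must be positive")
        if self.cheliceral_length_mm <= 0:
            raise TrackValidationError("cheliceral_length_mm must be positive")
        # first digitized frame defines t = 0
        expected = (self.frame_index - self.frame_index[0]) / self.fps
        if np.max(np.abs(self.times - expected)) > _TIME_TOL_S:
            bad = int(np.argmax(np.abs(self.times - expected)))
            raise TrackValidationError(
                f"time_s inconsistent with frame_index/fps at sample {bad}: "
                f"{self.times[bad]!r} vs expected {expected[bad]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def key(self) -> tuple[str, str, str]:
        return (self.specimen_id, self.strike_id, self.side)


@dataclass
class CalibratedTrajectory:
    """Pixel track converted to millimetres, with calibration provenance."""

    times: np.ndarray              # s
    points_mm: np.ndarray          # (n, 2) mm
    cheliceral_length_mm: float
    specimen_id: str = ""
    strike_id: str = ""
    side: str = ""
    provenance: list[str] = field(default_factory=list)


def _load_config(config) -> dict:
    """Accept a dict or a YAML path; check required metadata keys."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise TrackValidationError("config must be a mapping or a YAML file containing one")
    missing = [k for k in CONFIG_KEYS if k not in config]
    if missing:
        raise TrackValidationError(f"config missing required keys: {missing}")
    return config


def read_tracks(path, config) -> list[TrackedStrike]:
    """Read a track CSV into one :class:`TrackedStrike` per (specimen, strike, side).

    Rows are sorted by frame within each group. Malformed input raises
    :class:`TrackValidationError` naming the offending column or row —
    validation never passes silently.
    """
    config = _load_config(config)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackValidationError(f"{path}: missing columns {missing}")
    tracks: list[TrackedStrike] = []
    for (specimen, strike, side), grp in df.groupby(
        ["specimen_id", "strike_id", "side"], sort=True
    ):
        grp = grp.sort_values("frame_index")
        dup = grp["frame_index"].duplicated()
        if dup.any():
            rows = [int(i) for i in grp.index[dup]]
            raise TrackValidationError(
                f"{path}: duplicated frame_index for {specimen}/{strike}/{side} "
                f"at CSV rows {rows}"
            )
        tracks.append(
            TrackedStrike(
                specimen_id=str(specimen),
                strike_id=str(strike),
                side=str(side),
                frame_index=grp["frame_index"].to_numpy(),
                times=grp["time_s"].to_numpy(),
                points_px=grp[["x_px", "y_px"]].to_numpy(),
                fps=float(config["fps"]),
                scale_mm_per_px=float(config["scale_mm_per_px"]),
                cheliceral_length_mm=float(config["cheliceral_length_mm"]),
                sex=str(config.get("sex", "unknown")),
            )
        )
    return tracks


def write_tracks(tracks: list[TrackedStrike], path) -> None:
    """Write tracks back to the canonical CSV schema (inverse of :func:`read_tracks`)."""
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "specimen_id": tr.specimen_id,
                    "strike_id": tr.strike_id,
                    "side": tr.side,
                    "frame_index": tr.frame_index,
                    "time_s": tr.times,
                    "x_px": tr.points_px[:, 0],
                    "y_px": tr.points_px[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def calibrate(track: TrackedStrike) -> CalibratedTrajectory:
    """Convert pixel coordinates to mm by the recording's mm-per-pixel scale.

    Calibration is a type transition (pixels in, millimetres out), so a
    second application is rejected rather than silently rescaling.
    """
    if isinstance(track, CalibratedTrajectory):
        raise TypeError("trajectory is already calibrated (points are in mm)")
    if track.scale_mm_per_px <= 0:
        raise ValueError("scale_mm_per_px must be positive")
    return CalibratedTrajectory(
        times=track.times.copy(),
        points_mm=track.points_px * track.scale_mm_per_px,
        cheliceral_length_mm=track.cheliceral_length_mm,
        specimen_id=track.specimen_id,
        strike_id=track.strike_id,
        side=track.side,
        provenance=[f"calibrated at {track.scale_mm_per_px} mm/px"],
    )


def remove_drift(track: TrackedStrike, reference) -> TrackedStrike:
    """Subtract a tracked body-reference point to isolate cheliceral rotation.

    ``reference`` is any object with ``times`` and ``points_px`` sampled at
    exactly the same instants as ``track`` (e.g. a digitized carapace point).
    The reference displacement relative to its first frame is subtracted
    frame-wise, so a stationary reference leaves the track unchanged up to a
    constant offset of zero.
    """
    ref_times = np.asarray(reference.times, dtype=float)
    ref_points = np.asarray(reference.points_px, dtype=float)
    if ref_times.shape != track.times.shape or np.max(np.abs(ref_times - track.times)) > _TIME_TOL_S:
        raise TrackValidationError("reference series not sampled at the track's times")
    corrected = track.points_px - (ref_points - ref_points[0])
    out = dataclasses.replace(track, points_px=corrected)
    return out


def write_results(df: pd.DataFrame, path, units: dict[str, str] | None = None) -> None:
    """Write a results table with a leading comment block naming units."""
    path = Path(path)
    with open(path, "w") as fh:
        if units:
            for col, unit in units.items():
                fh.write(f"# {col}: {unit}\n")
        df.to_csv(fh, index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
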