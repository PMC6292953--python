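"""Kinematic outcomes: movement units, cumulative 3D distance, average velocity.

Movement units (MUs) quantify how segmented a movement is: one MU is one
acceleration-then-deceleration pulse of the tangential speed profile.  The
segmentation follows the classic extremum-merging operationalization:
alternating local minima and maxima of the speed series are simplified by
repeatedly merging the adjacent extremum pair with the smallest speed
difference until every remaining rise and fall is at least ``dv_min``
(default 20 mm/s); each surviving maximum is then a candidate unit and must
additionally contain an acceleration and a deceleration extremum of
magnitude at least ``da_min`` (default 5 mm/s^2).

All three outcomes are evaluated over the first-six-taps window
``[trial start, time of sixth successful tap)`` and composited per leg as
the unweighted mean of the knee, ankle and toe marker values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mocap_io import Config, MarkerTrajectory, SteppingTrial

__all__ = [
    "SpeedSeries",
    "MovementUnit",
    "KinematicSummary",
    "tangential_speed",
    "count_movement_units",
    "cumulative_distance",
    "average_velocity",
    "summarize_leg",
]


@dataclass
class SpeedSeries:
    """Per-frame tangential speed (mm/s) and its derivative (mm/s^2)."""

    speed: np.ndarray
    accel: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        if len(self.speed) != len(self.accel):
            raise ValueError("speed and accel must have equal length")
        if (self.speed < 0).any():
            raise ValueError("speed must be non-negative")

    def window(self, f0: int, f1: int) -> "SpeedSeries":
        return SpeedSeries(self.speed[f0:f1], self.accel[f0:f1], self.sampling_rate_hz)


@dataclass(frozen=True)
class MovementUnit:
    start_frame: int
    peak_frame: int
    end_frame: int
    velocity_rise_mm_s: float
    velocity_fall_mm_s: float
    peak_accel_mm_s2: float
    peak_decel_mm_s2: float


@dataclass
class KinematicSummary:
    """Per-leg composite outcomes over the first-six-taps window."""

    leg: str
    mu_count: float
    distance_mm: float
    velocity_mm_s: float
    window_s: tuple[float, float]
    per_marker: dict[str, dict[str, float]]
    incomplete: bool = False


def tangential_speed(traj: MarkerTrajectory) -> SpeedSeries:
    """Speed as the norm of the central-difference velocity of the positions.

    Endpoints use one-sided differences (``np.gradient`` semantics); the
    acceleration is the central difference of the speed itself.
    """
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames to differentiate")
    if traj.missing.any():
        raise ValueError("speed requires a gap-free trajectory")
    dt = 1.0 / traj.sampling_rate_hz
    vel = np.gradient(traj.positions, dt, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    accel = np.gradient(speed, dt)
    return SpeedSeries(speed, accel, traj.sampling_rate_hz)


def _alternating_extrema(v: np.ndarray) -> tuple[list[int], list[int]]:
    """Indices and kinds (+1 max / -1 min) of alternating extrema.

    Both endpoints are included; plateaus collapse to their last frame.  The
    kind of the endpoints follows from alternation with the interior extrema
    (an initially rising series starts on a minimum).
    """
    n = len(v)
    if n == 0:
        return [], []
    idx = [0]
    last_sign = 0
    first_sign = 0
    for i in range(1, n):
        d = v[i] - v[i - 1]
        s = 0 if d == 0 else (1 if d > 0 else -1)
        if s == 0:
            continue
        if last_sign != 0 and s != last_sign:
            idx.append(i - 1)
        last_sign = s
        if first_sign == 0:
            first_sign = s
    if idx[-1] != n - 1:
        idx.append(n - 1)
    if len(idx) == 1:
        return idx, [1]
    # first extremum is a minimum iff the series initially rises
    k0 = -1 if first_sign >= 0 else 1
    kinds = [k0 * (-1) ** j for j in range(len(idx))]
    return idx, kinds


def count_movement_units(
    series: SpeedSeries, cfg: Config
) -> tuple[int, list[MovementUnit]]:
    """Count movement units of a speed series by iterative extremum merging.

    Algorithm: (1) list alternating speed extrema including the endpoints;
    (2) repeatedly delete the adjacent *interior* extremum pair with the
    smallest absolute speed difference while that difference is below
    ``dv_min`` (ties break on the earlier pair); (3) every surviving maximum
    flanked by two lower extrema whose rise and fall both reach ``dv_min``
    is a candidate unit; (4) a candidate is kept only if the acceleration
    within it reaches ``+da_min`` and ``-da_min``.  Units are returned in
    time order.
    """
    v = np.asarray(series.speed, dtype=float)
    if len(v) == 0:
        return 0, []
    dv_min = cfg.mu.dv_min_mm_s
    da_min = cfg.mu.da_min_mm_s2

    idx, kinds = _alternating_extrema(v)
    vals = [float(v[i]) for i in idx]

    while len(idx) > 2:
        best_j = -1
        best_d = dv_min
        # pairs (j, j+1) with both members interior
        for j in range(1, len(idx) - 2):
            d = abs(vals[j + 1] - vals[j])
            if d < best_d:
                best_d = d
                best_j = j
        if best_j < 0:
            break
        del idx[best_j : best_j + 2]
        del vals[best_j : best_j + 2]
        del kinds[best_j : best_j + 2]

    units: list[MovementUnit] = []
    accel = series.accel
    for j in range(1, len(idx) - 1):
        if kinds[j] != 1:
            continue
        rise = vals[j] - vals[j - 1]
        fall = vals[j] - vals[j + 1]
        if rise < dv_min or fall < dv_min:
            continue
        a = accel[idx[j - 1] : idx[j + 1] + 1]
        if len(a) == 0 or a.max() < da_min or a.min() > -da_min:
            continue
        units.append(
            MovementUnit(
                start_frame=idx[j - 1],
                peak_frame=idx[j],
                end_frame=idx[j + 1],
                velocity_rise_mm_s=rise,
                velocity_fall_mm_s=fall,
                peak_accel_mm_s2=float(a.max()),
                peak_decel_mm_s2=float(a.min()),
            )
        )
    return len(units), units


def cumulative_distance(
    traj: MarkerTrajectory, window_s: tuple[float, float] | None = None
) -> float:
    """Summed frame-to-frame 3D displacement (mm) over a half-open window."""
    f0, f1 = _window_frames(traj, window_s)
    pos = traj.positions[f0:f1]
    if len(pos) < 2:
        return 0.0
    if traj.missing[f0:f1].any():
        raise ValueError("cumulative distance requires a gap-free window")
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


def average_velocity(
    traj: MarkerTrajectory, window_s: tuple[float, float] | None = None
) -> float:
    """Cumulative distance divided by the window duration (mm/s)."""
    f0, f1 = _window_frames(traj, window_s)
    dur = (f1 - f0) / traj.sampling_rate_hz
    if dur <= 0:
        raise ValueError("zero-length analysis window")
    return cumulative_distance(traj, window_s) / dur


def _window_frames(traj: MarkerTrajectory, window_s) -> tuple[int, int]:
    if window_s is None:
        return 0, traj.n_frames
    fs = traj.sampling_rate_hz
    f0 = max(0, int(np.ceil(window_s[0] * fs - 1e-9)))
    f1 = min(traj.n_frames, int(np.ceil(window_s[1] * fs - 1e-9)))
    return f0, f1


def summarize_leg(
    trial: SteppingTrial,
    taps,
    cfg: Config,
) -> dict[str, KinematicSummary]:
    """Kinematic summaries of both legs over the first-six-taps window.

    ``taps`` is the detected tap list (time-ordered).  The analysis window is
    ``[0, time of the sixth tap)``.  With fewer than six taps the summaries
    are flagged incomplete (and excluded from statistics downstream).  The
    composite of each outcome is the unweighted mean over the knee, ankle and
    toe markers.
    """
    out: dict[str, KinematicSummary] = {}
    incomplete = len(taps) < 6
    t6 = taps[5].time_s if not incomplete else trial.trial_length_s
    window = (0.0, t6)
    for side in "LR":
        per_marker: dict[str, dict[str, float]] = {}
        for part in ("toe", "ankle", "knee"):
            label = f"{side}_{part}"
            traj = trial.markers[label]
            f0, f1 = _window_frames(traj, window)
            series = tangential_speed(traj).window(f0, f1)
            n_mu, _ = count_movement_units(series, cfg)
            per_marker[label] = {
                "mu_count": float(n_mu),
                "distance_mm": cumulative_distance(traj, window),
                "velocity_mm_s": average_velocity(traj, window),
            }
        vals = list(per_marker.values())
        out[side] = KinematicSummary(
            leg=side,
            mu_count=float(np.mean([m["mu_count"] for m in vals])),
            distance_mm=float(np.mean([m["distance_mm"] for m in vals])),
            velocity_mm_s=float(np.mean([m["velocity_mm_s"] for m in vals])),
            window_s=window,
            per_marker=per_marker,
            incomplete=incomplete,
        )
    return out
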