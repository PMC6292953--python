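"""Data cleaning: gap classification and filling, trial validation, smoothing.

The cleaning rules mirror the study's preprocessing: marker gaps shorter than
10 frames are filled automatically, gaps of up to 20 frames are filled only
under an explicit accept policy (standing in for the human judgement of
whether a manual fill is reliable), and anything longer is unfillable.  A leg
whose knee, ankle or toe marker keeps an unfillable gap inside the analysis
window invalidates the whole trial for kinematics.  Smoothing is a
second-order low-pass Butterworth applied forward and backward (zero phase,
effective fourth order); the cutoff names the per-pass -3 dB point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .mocap_io import Config, MarkerTrajectory, SteppingTrial, MARKER_ROLES

__all__ = [
    "Gap",
    "GapReport",
    "TrialValidation",
    "find_gaps",
    "fill_gaps",
    "validate_trial",
    "lowpass_filter",
    "filter_trial",
]

#: valid frames used on each side of a gap for the cubic fill
_FILL_SUPPORT = 4


@dataclass(frozen=True)
class Gap:
    start_frame: int
    length: int
    action: str  # "auto_filled" | "manual_filled" | "unfillable"

    @property
    def end_frame(self) -> int:  # exclusive
        return self.start_frame + self.length


@dataclass
class GapReport:
    """All gaps of one marker and what was done about them."""

    label: str
    gaps: tuple[Gap, ...]

    @property
    def unfillable(self) -> tuple[Gap, ...]:
        return tuple(g for g in self.gaps if g.action == "unfillable")


@dataclass
class TrialValidation:
    """Per-marker / per-leg / per-trial inclusion decision with reasons."""

    trial_id: str
    marker_valid: dict[str, bool]
    leg_valid: dict[str, bool]
    included: bool
    reasons: tuple[str, ...]


def find_gaps(traj: MarkerTrajectory) -> list[tuple[int, int]]:
    """Runs of missing frames as (start, length) pairs."""
    m = traj.missing
    if not m.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], m.view(np.int8), [0]))))
    starts, ends = idx[0::2], idx[1::2]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def fill_gaps(traj: MarkerTrajectory, cfg: Config) -> tuple[MarkerTrajectory, GapReport]:
    """Classify and fill the marker's gaps.

    Gaps strictly shorter than ``auto_fill_max_frames`` are filled
    automatically; lengths up to ``manual_fill_max_frames`` are filled only
    when ``manual_policy == "accept"``; longer gaps, and gaps touching the
    trajectory boundary, stay missing and are reported unfillable.  Filling
    interpolates each coordinate with a cubic spline through the valid frames
    flanking the gap; observed frames are never modified.
    """
    out = traj.copy()
    report: list[Gap] = []
    for start, length in find_gaps(traj):
        boundary = start == 0 or start + length == traj.n_frames
        if boundary or length > cfg.gaps.manual_fill_max_frames:
            action = "unfillable"
        elif length < cfg.gaps.auto_fill_max_frames:
            action = "auto_filled"
        elif cfg.gaps.manual_policy == "accept":
            action = "manual_filled"
        else:
            action = "unfillable"
        if action != "unfillable":
            _fill_one(out, start, length)
        report.append(Gap(start, length, action))
    return out, GapReport(traj.label, tuple(report))


def _fill_one(traj: MarkerTrajectory, start: int, length: int) -> None:
    valid = np.flatnonzero(~traj.missing)
    left = valid[valid < start][-_FILL_SUPPORT:]
    right = valid[valid >= start + length][:_FILL_SUPPORT]
    support = np.concatenate([left, right])
    gap_idx = np.arange(start, start + length)
    if len(left) >= 2 and len(right) >= 2:
        spline = CubicSpline(support, traj.positions[support])
        traj.positions[gap_idx] = spline(gap_idx)
    else:  # single flanking frame on one side: fall back to linear
        traj.positions[gap_idx] = np.array(
            [np.interp(gap_idx, support, traj.positions[support][:, k]) for k in range(3)]
        ).T
    traj.missing[gap_idx] = False


def validate_trial(
    trial: SteppingTrial,
    gap_reports: dict[str, GapReport],
    cfg: Config,
    window_s: tuple[float, float] | None = None,
) -> TrialValidation:
    """Apply the inclusion rules given the gap reports.

    A marker is invalid if any unfillable gap overlaps the analysis window
    ``[t0, t1)`` (the whole trial when ``window_s`` is None); a leg is invalid
    if any of its three markers is; the trial is excluded from kinematics if
    either leg is invalid.
    """
    fs = trial.sampling_rate_hz
    if window_s is None:
        f0, f1 = 0, trial.n_frames
    else:
        f0, f1 = int(window_s[0] * fs), int(np.ceil(window_s[1] * fs))
    marker_valid: dict[str, bool] = {}
    reasons: list[str] = []
    for role in MARKER_ROLES:
        rep = gap_reports.get(role)
        bad = [
            g
            for g in (rep.unfillable if rep else ())
            if g.start_frame < f1 and g.end_frame > f0
        ]
        marker_valid[role] = not bad
        for g in bad:
            reasons.append(
                f"{role}: unfillable gap of {g.length} frames at frame {g.start_frame}"
            )
    leg_valid = {
        side: all(marker_valid[f"{side}_{part}"] for part in ("toe", "ankle", "knee"))
        for side in "LR"
    }
    included = leg_valid["L"] and leg_valid["R"]
    return TrialValidation(trial.trial_id, marker_valid, leg_valid, included, tuple(reasons))


def lowpass_filter(traj: MarkerTrajectory, cfg: Config) -> MarkerTrajectory:
    """Zero-phase low-pass smoothing of one marker trajectory.

    Applies a Butterworth filter of ``cfg.filter.order`` at
    ``cfg.filter.cutoff_hz`` forward and backward over each coordinate with
    reflective edge padding of three times the filter order.  Missing frames
    must have been filled (or the trial excluded) first.
    """
    if traj.missing.any():
        raise ValueError(
            f"{traj.label}: cannot filter a trajectory with missing frames; "
            "fill gaps or exclude the trial first"
        )
    order, cutoff = cfg.filter.order, cfg.filter.cutoff_hz
    nyq = traj.sampling_rate_hz / 2.0
    if cutoff >= nyq:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if traj.n_frames < 10 * order:
        raise ValueError("trajectory too short to filter")
    b, a = butter(order, cutoff / nyq)
    if cfg.filter.dual_pass:
        smoothed = filtfilt(b, a, traj.positions, axis=0, padtype="even", padlen=3 * order)
    else:
        from scipy.signal import lfilter

        smoothed = lfilter(b, a, traj.positions, axis=0)
    return MarkerTrajectory(traj.label, smoothed, traj.sampling_rate_hz)


def filter_trial(trial: SteppingTrial, cfg: Config) -> SteppingTrial:
    """Low-pass every body marker of a trial (targets are static and untouched)."""
    markers = {role: lowpass_filter(m, cfg) for role, m in trial.markers.items()}
    return SteppingTrial(
        participant_id=trial.participant_id,
        group=trial.group,
        test=trial.test,
        trial_index=trial.trial_index,
        digit_series=trial.digit_series,
        markers=markers,
        targets=trial.targets,
        trial_length_s=trial.trial_length_s,
    )
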