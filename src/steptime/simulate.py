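"""Synthetic stepping-task trials, 2x2 cohorts, and metronome sessions.

The generator provides ground truth that the real study could not: every
trial records its planted tap times, tap targets, per-move movement-unit
counts and noiseless path lengths, so the whole downstream measurement chain
is testable without any recorded data.

Geometry and timing emulate the stepping task: the player stands at the
centre of a circle of six tennis balls (digits 1/3/5 on the left half for the
left foot, 2/4/6 on the right half for the right foot) and taps them in the
order of a digit series shown on a screen, repeating the series cyclically
for the 20 s trial.  Each point-to-point foot transport follows a
minimum-jerk profile, i.e. a single bell-shaped speed pulse, which makes the
planted movement-unit count exactly one per clean move.  Optional
"sub-movements" are small corrective minimum-jerk adjustment steps executed
right after target arrival: each adds exactly one further speed pulse
(separated from the transport pulse by a near-zero dip), so the planted MU
count per move is ``1 + submovements_per_move`` while the first-contact time
is untouched.

Sensor noise is i.i.d. Gaussian per axis (default 1 mm, the optoelectronic
system's quoted positional accuracy) and marker dropout is planted as
explicit gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mocap_io import MarkerTrajectory, SteppingTrial, required_foot

__all__ = [
    "TrajectoryParams",
    "CohortDesign",
    "GroundTruth",
    "DIGIT_SERIES_POOL",
    "generate_trial",
    "generate_cohort",
    "generate_cohort_outcomes",
    "generate_im_session",
    "inject_gaps",
    "minimum_jerk_position",
]

#: the eight digit series presented in randomized order during a test session
DIGIT_SERIES_POOL: tuple[tuple[int, ...], ...] = (
    (1, 6, 5, 2, 3, 4),
    (2, 3, 6, 5, 4, 1),
    (3, 2, 1, 6, 5, 4),
    (4, 1, 2, 5, 6, 3),
    (5, 4, 3, 2, 1, 6),
    (6, 5, 2, 1, 4, 3),
    (1, 4, 5, 6, 3, 2),
    (2, 5, 6, 3, 4, 1),
)

# target layout: digit -> angle (degrees) on the circle; odd digits (left
# foot) on the left half-plane (x < 0), even digits on the right
_TARGET_ANGLE_DEG = {1: 120.0, 3: 180.0, 5: 240.0, 2: 60.0, 4: 0.0, 6: 300.0}

#: relative movement amplitude of each marker in a leg cluster
_MARKER_SCALE = {"toe": 1.0, "ankle": 0.85, "knee": 0.35}
#: resting height (mm) of each marker above the floor
_MARKER_HEIGHT = {"toe": 35.0, "ankle": 70.0, "knee": 450.0}
#: peak height (mm) of the toe lift arc during a transport move
_LIFT_MM = 60.0
#: lateral stance offset (mm) of each foot from the circle centre
_STANCE_OFFSET_MM = 100.0


@dataclass
class TrajectoryParams:
    """Timing, geometry, noise and dropout parameters of one simulated trial."""

    sampling_rate_hz: float = 120.0
    circle_radius_mm: float = 550.0
    movement_duration_s: float = 0.75
    dwell_s: float = 0.2
    trial_length_s: float = 20.0
    noise_sd_mm: float = 1.0
    submovements_per_move: int = 0
    submovement_amplitude_mm_s: float = 120.0
    submovement_duration_s: float = 0.2
    #: marker dropout: (marker_label, start_frame, length_frames)
    gap_spec: tuple[tuple[str, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.circle_radius_mm <= 0 or self.movement_duration_s <= 0:
            raise ValueError("geometry and movement duration must be positive")
        if self.dwell_s < 0 or self.noise_sd_mm < 0:
            raise ValueError("dwell_s and noise_sd_mm must be non-negative")
        if self.submovements_per_move < 0:
            raise ValueError("submovements_per_move must be non-negative")
        if any(length < 1 for _, _, length in self.gap_spec):
            raise ValueError("all gap lengths must be >= 1")
        budget = self.movement_duration_s + 2 * self.dwell_s
        if self.submovements_per_move * self.submovement_duration_s > budget:
            raise ValueError(
                "planted sub-movements do not fit into the foot's idle time between moves"
            )


@dataclass
class CohortDesign:
    """A 2 (group) x 2 (test) cohort with configurable interaction effects.

    The effect fields are the post-minus-pre shift applied to the SMT group
    only (the group-by-test interaction); negative asynchrony/duration shifts
    mean improvement.  Defaults mirror the study's design size (12 players per
    group, 8 trials of 20 s per test occasion).
    """

    n_per_group: int = 12
    trials_per_test: int = 8
    trial_length_s: float = 20.0
    groups: tuple[str, str] = ("SMT", "CTRL")
    tests: tuple[str, str] = ("pre", "post")
    effect_asynchrony_ms: float = 0.0
    effect_correct_taps: float = 0.0
    effect_duration_s: float = 0.0
    between_subject_sd: float = 2.5
    within_subject_sd: float = 2.0
    #: baseline outcome levels (pre-test population means)
    baseline_asynchrony_ms: float = 90.0
    baseline_correct_taps: float = 14.0
    baseline_duration_s: float = 6.5
    asynchrony_between_sd_ms: float = 20.0
    asynchrony_within_sd_ms: float = 12.0
    duration_between_sd_s: float = 0.8
    duration_within_sd_s: float = 0.6
    #: trials to corrupt with an unrecoverable (>20 frame) marker gap
    n_corrupt_trials: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.trials_per_test < 1:
            raise ValueError("trials_per_test must be >= 1")
        for sd in (
            self.between_subject_sd,
            self.within_subject_sd,
            self.asynchrony_between_sd_ms,
            self.asynchrony_within_sd_ms,
            self.duration_between_sd_s,
            self.duration_within_sd_s,
        ):
            if sd <= 0:
                raise ValueError("all standard deviations must be positive")

    @property
    def n_trials_total(self) -> int:
        return 2 * self.n_per_group * len(self.tests) * self.trials_per_test


@dataclass
class GroundTruth:
    """Planted truth for one trial (or the planted effects of a cohort)."""

    true_tap_times_s: tuple[float, ...] = ()
    true_tap_targets: tuple[int, ...] = ()
    true_tap_feet: tuple[str, ...] = ()
    #: per executed move: (leg, start_frame, end_frame_excl, planted MU count);
    #: the window spans transport onset to arrival plus planted sub-movements
    true_move_windows: tuple[tuple[str, int, int, int], ...] = ()
    #: noiseless cumulative path length (mm) per marker over the whole trial
    true_path_length_mm: dict = field(default_factory=dict)
    true_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = self.true_tap_times_s
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("planted tap times must be strictly increasing")
        if any(n < 1 for *_, n in self.true_move_windows):
            raise ValueError("every executed move plants at least one movement unit")


def minimum_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile, clipped to [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def target_positions(circle_radius_mm: float) -> dict[int, np.ndarray]:
    """Ball-centre positions of the six targets on the circle (z = ball height)."""
    out = {}
    for digit, ang in _TARGET_ANGLE_DEG.items():
        a = np.deg2rad(ang)
        out[digit] = np.array(
            [circle_radius_mm * np.cos(a), circle_radius_mm * np.sin(a), _MARKER_HEIGHT["toe"]]
        )
    return out


def _executed_schedule(
    digit_series: Sequence[int], params: TrajectoryParams
) -> list[tuple[int, float]]:
    """Cyclic (digit, move_start_s) schedule filling the trial length."""
    slot = params.movement_duration_s + params.dwell_s
    sched = []
    k = 0
    while k * slot + params.movement_duration_s <= params.trial_length_s:
        sched.append((int(digit_series[k % len(digit_series)]), k * slot))
        k += 1
    return sched


def generate_trial(
    digit_series: Sequence[int],
    params: TrajectoryParams,
    *,
    participant_id: str = "P00",
    group: str = "SMT",
    test: str = "pre",
    trial_index: int = 0,
    executed_digits: Sequence[int] | None = None,
) -> tuple[SteppingTrial, GroundTruth]:
    """Simulate one stepping trial and its ground truth.

    The planned ``digit_series`` is repeated cyclically to fill the trial; by
    default the execution is flawless.  ``executed_digits`` overrides the
    executed tap sequence (used by the cohort generator to plant insertion
    errors) while scoring remains against the planned series.
    """
    digit_series = tuple(int(d) for d in digit_series)
    if not digit_series:
        raise ValueError("digit_series must be nonempty")
    for d in digit_series:
        if not 1 <= d <= 6:
            raise ValueError(f"invalid digit in series: {d}")

    fs = params.sampling_rate_hz
    n_frames = int(round(params.trial_length_s * fs))
    rng = np.random.default_rng(params.seed)
    targets = target_positions(params.circle_radius_mm)

    if executed_digits is None:
        schedule = _executed_schedule(digit_series, params)
    else:
        slot = params.movement_duration_s + params.dwell_s
        schedule = [
            (int(d), k * slot)
            for k, d in enumerate(executed_digits)
            if k * slot + params.movement_duration_s <= params.trial_length_s
        ]

    homes = {
        "L": np.array([-_STANCE_OFFSET_MM, 0.0, _MARKER_HEIGHT["toe"]]),
        "R": np.array([_STANCE_OFFSET_MM, 0.0, _MARKER_HEIGHT["toe"]]),
    }
    t = np.arange(n_frames) / fs

    # toe paths are built per foot chronologically: held positions,
    # minimum-jerk transports with a sinusoidal lift arc, then corrective
    # sub-movement steps; every transport re-lands exactly on its target
    toe = {side: np.tile(homes[side], (n_frames, 1)) for side in "LR"}
    cur = {side: homes[side].copy() for side in "LR"}

    tap_times: list[float] = []
    tap_targets: list[int] = []
    tap_feet: list[str] = []
    move_windows: list[tuple[str, int, int, int]] = []

    T = params.movement_duration_s
    n_sub = params.submovements_per_move
    sub_T = params.submovement_duration_s
    sub_amp_mm = params.submovement_amplitude_mm_s * sub_T / 1.875  # one-way step length

    def _write_segment(side: str, t0: float, dur: float, start: np.ndarray,
                       dest: np.ndarray, lift: float) -> None:
        tau = (t - t0) / dur
        s = minimum_jerk_position(tau)
        seg = start + np.outer(s, dest - start)
        # lift arc parameterized by path fraction, so every velocity component
        # vanishes at both ends of the transport (single speed peak)
        seg[:, 2] += lift * np.sin(np.pi * s)
        sel = t >= t0
        toe[side][sel] = seg[sel]

    for digit, t0 in schedule:
        side = required_foot(digit)
        dest = targets[digit]
        _write_segment(side, t0, T, cur[side], dest, _LIFT_MM)
        cur[side] = dest.copy()

        arrival = t0 + T
        tap_times.append(arrival)
        tap_targets.append(digit)
        tap_feet.append(side)

        # corrective sub-movements: one-way minimum-jerk steps right after
        # arrival, alternating between the x and y axes; the net offset stays
        # well inside the contact radius and the next transport starts from it.
        # pulses that would not complete before the trial ends are not planted
        n_planted = 0
        for k in range(n_sub):
            if arrival + (k + 1) * sub_T > params.trial_length_s:
                break
            direction = np.array([1.0, 0.0, 0.0]) if k % 2 == 0 else np.array([0.0, 1.0, 0.0])
            nxt = cur[side] + sub_amp_mm * direction
            _write_segment(side, arrival + k * sub_T, sub_T, cur[side], nxt, 0.0)
            cur[side] = nxt
            n_planted += 1

        w0 = int(round(t0 * fs))
        w1 = int(round((arrival + n_planted * sub_T) * fs))
        move_windows.append((side, w0, min(w1, n_frames), 1 + n_planted))

    markers: dict[str, MarkerTrajectory] = {}
    truth_path: dict[str, float] = {}
    for side in "LR":
        disp = toe[side] - homes[side]
        for part in ("toe", "ankle", "knee"):
            label = f"{side}_{part}"
            base = homes[side].copy()
            base[2] = _MARKER_HEIGHT[part]
            scale = _MARKER_SCALE[part]
            pos = base + scale * disp
            truth_path[label] = float(
                np.linalg.norm(np.diff(pos, axis=0), axis=1).sum()
            )
            noisy = pos + rng.normal(0.0, params.noise_sd_mm, pos.shape)
            markers[label] = MarkerTrajectory(label, noisy, fs)

    trial = SteppingTrial(
        participant_id=participant_id,
        group=group,
        test=test,
        trial_index=trial_index,
        digit_series=digit_series,
        markers=markers,
        targets=targets,
        trial_length_s=params.trial_length_s,
    )
    for label, start, length in params.gap_spec:
        if label not in trial.markers:
            raise ValueError(f"gap_spec names unknown marker {label!r}")
        trial.markers[label] = inject_gaps(trial.markers[label], [(start, length)])

    truth = GroundTruth(
        true_tap_times_s=tuple(tap_times),
        true_tap_targets=tuple(tap_targets),
        true_tap_feet=tuple(tap_feet),
        true_move_windows=tuple(move_windows),
        true_path_length_mm=truth_path,
    )
    return trial, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def generate_cohort_outcomes(design: CohortDesign) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a cohort's behavioural outcomes from the additive model.

    The outcome model per trial is ``participant intercept + interaction
    (SMT post only) + trial noise``; per-participant metronome asynchrony is
    generated once per test occasion.  Returns a tidy trial-level table with
    columns ``participant_id, group, test, trial_index, correct_taps,
    duration_six_s, asynchrony_ms`` and the echoed planted effects.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for group in design.groups:
        for i in range(design.n_per_group):
            pid = f"{group}{i:02d}"
            b_taps = rng.normal(0.0, design.between_subject_sd)
            b_dur = rng.normal(0.0, design.duration_between_sd_s)
            b_asyn = rng.normal(0.0, design.asynchrony_between_sd_ms)
            for test in design.tests:
                smt_post = group == design.groups[0] and test == design.tests[1]
                asyn = (
                    design.baseline_asynchrony_ms
                    + b_asyn
                    + (design.effect_asynchrony_ms if smt_post else 0.0)
                    + rng.normal(0.0, design.asynchrony_within_sd_ms)
                )
                for j in range(design.trials_per_test):
                    taps = (
                        design.baseline_correct_taps
                        + b_taps
                        + (design.effect_correct_taps if smt_post else 0.0)
                        + rng.normal(0.0, design.within_subject_sd)
                    )
                    dur = (
                        design.baseline_duration_s
                        + b_dur
                        + (design.effect_duration_s if smt_post else 0.0)
                        + rng.normal(0.0, design.duration_within_sd_s)
                    )
                    rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "test": test,
                            "trial_index": j,
                            "correct_taps": taps,
                            "duration_six_s": dur,
                            "asynchrony_ms": asyn,
                        }
                    )
    truth = GroundTruth(
        true_effects={
            "effect_asynchrony_ms": design.effect_asynchrony_ms,
            "effect_correct_taps": design.effect_correct_taps,
            "effect_duration_s": design.effect_duration_s,
        }
    )
    return pd.DataFrame(rows), truth


def generate_cohort(
    design: CohortDesign, params: TrajectoryParams | None = None
) -> tuple[list[tuple[SteppingTrial, GroundTruth]], GroundTruth]:
    """Generate a full cohort of trajectory-level trials.

    Behavioural targets are drawn from the same additive outcome model as
    :func:`generate_cohort_outcomes` and realized mechanically: the per-trial
    first-six duration sets the transport tempo, and correct-tap deficits are
    planted as insertion errors (an extra tap of a wrong same-side ball before
    a planned digit).  ``design.n_corrupt_trials`` trials additionally get an
    unrecoverable (>20 frame) gap planted in one body marker.
    """
    params = params or TrajectoryParams()
    outcomes, truth = generate_cohort_outcomes(design)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xC0]))
    series_order = [
        DIGIT_SERIES_POOL[k % len(DIGIT_SERIES_POOL)] for k in range(design.trials_per_test)
    ]

    n_total = len(outcomes)
    corrupt_rows = (
        set(rng.choice(n_total, size=design.n_corrupt_trials, replace=False).tolist())
        if design.n_corrupt_trials
        else set()
    )

    trials: list[tuple[SteppingTrial, GroundTruth]] = []
    for rownum, rec in enumerate(outcomes.to_dict("records")):
        series = series_order[int(rec["trial_index"])]
        dwell = params.dwell_s
        # tempo from the drawn first-six duration: tap6 = 6 T + 5 dwell
        T = max(0.35, (float(rec["duration_six_s"]) - 5 * dwell) / 6.0)
        p = TrajectoryParams(
            sampling_rate_hz=params.sampling_rate_hz,
            circle_radius_mm=params.circle_radius_mm,
            movement_duration_s=T,
            dwell_s=dwell,
            trial_length_s=design.trial_length_s,
            noise_sd_mm=params.noise_sd_mm,
            submovements_per_move=params.submovements_per_move,
            submovement_amplitude_mm_s=params.submovement_amplitude_mm_s,
            submovement_duration_s=params.submovement_duration_s,
            seed=int(rng.integers(2**31 - 1)),
        )
        slot = T + dwell
        n_moves = int((design.trial_length_s - T) // slot) + 1
        planned = [series[k % len(series)] for k in range(n_moves)]
        deficit = max(0, int(round(n_moves - float(rec["correct_taps"]))))
        executed = _plant_insertions(planned, deficit, rng)[:n_moves]
        trial, gt = generate_trial(
            series,
            p,
            participant_id=rec["participant_id"],
            group=rec["group"],
            test=rec["test"],
            trial_index=int(rec["trial_index"]),
            executed_digits=executed,
        )
        if rownum in corrupt_rows:
            label = "L_toe"
            start = int(rng.integers(100, trial.n_frames - 200))
            trial.markers[label] = inject_gaps(trial.markers[label], [(start, 30)])
        trials.append((trial, gt))
    return trials, truth


def _plant_insertions(planned: list[int], k: int, rng: np.random.Generator) -> list[int]:
    """Insert ``k`` wrong same-side taps before randomly chosen planned taps."""
    out = list(planned)
    for _ in range(k):
        pos = int(rng.integers(len(out)))
        digit = out[pos]
        side = required_foot(digit)
        wrong = [d for d in (1, 3, 5) if side == "L" and d != digit] or [
            d for d in (2, 4, 6) if d != digit
        ]
        out.insert(pos, int(rng.choice(wrong)))
    return out


# ---------------------------------------------------------------------------
# metronome sessions and gaps
# ---------------------------------------------------------------------------


def generate_im_session(
    true_mean_asynchrony_ms: float,
    asynchrony_sd_ms: float,
    n_beats: int,
    ioi_ms: float = 1100.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Simulate one synchronization test: one response per metronome beat.

    Responses fall at ``beat + N(true_mean, sd)`` milliseconds.  Returns a
    response log with ``beats_ms`` and ``responses_ms`` arrays.
    """
    if n_beats < 2:
        raise ValueError("n_beats must be >= 2")
    if asynchrony_sd_ms < 0:
        raise ValueError("asynchrony_sd_ms must be non-negative")
    rng = np.random.default_rng(seed)
    beats = np.arange(n_beats, dtype=float) * ioi_ms
    responses = beats + true_mean_asynchrony_ms + rng.normal(0.0, asynchrony_sd_ms, n_beats)
    return {"beats_ms": beats, "responses_ms": responses, "ioi_ms": float(ioi_ms)}


def inject_gaps(
    traj: MarkerTrajectory, gap_spec: Iterable[tuple[int, int]]
) -> MarkerTrajectory:
    """Mask frame runs as missing; untouched frames stay bit-identical."""
    out = traj.copy()
    seen: list[tuple[int, int]] = []
    for start, length in gap_spec:
        if length < 1:
            raise ValueError("gap length must be >= 1")
        if start < 0 or start + length > out.n_frames:
            raise ValueError(f"gap ({start}, {length}) exceeds trajectory frame range")
        for s0, l0 in seen:
            if start < s0 + l0 and s0 < start + length:
                raise ValueError("overlapping gaps are not allowed")
        seen.append((start, length))
        out.missing[start : start + length] = True
        out.positions[start : start + length] = np.nan
    return out
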