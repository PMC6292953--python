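"""Tap detection and scoring, first-six-taps duration, metronome metrics.

A tap is a contact of the toe marker with a target ball: the toe-to-target
distance dips below the contact radius (default 60 mm, roughly the ball
radius plus boot clearance).  One tap is reported per continuous contact
episode, timed at the first local minimum of the distance after entry; a new
tap on the same target additionally requires the refractory interval to have
passed.  Taps are scored against the trial's digit series with a greedy
pointer that advances only on correct taps (correct = expected digit tapped
with the digit's required foot; the series repeats cyclically).

Metronome (synchronization-test) metrics: *timing ability* is the mean
absolute asynchrony between each response and its beat; *rhythmic ability*
is the mean absolute deviation of the inter-response interval from the
inter-onset interval (IOI, 1100 ms at 54 bpm).  Training feedback classifies
a response as on-beat within 15 ms of the beat, early at 16 ms or more
before it, late at 16 ms or more after it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mocap_io import Config, SteppingTrial, required_foot

__all__ = [
    "TapEvent",
    "IMMetrics",
    "detect_taps",
    "score_taps",
    "first_six_duration",
    "im_metrics",
    "classify_response",
]


@dataclass
class TapEvent:
    time_s: float
    target: int
    foot: str  # "L" or "R"
    correct: bool = False
    matched_position: int | None = None


@dataclass
class IMMetrics:
    timing_ability_ms: float
    rhythmic_ability_ms: float
    asynchronies_ms: np.ndarray
    classifications: tuple[str, ...]


def detect_taps(trial: SteppingTrial, cfg: Config) -> list[TapEvent]:
    """Detect target contacts of both toe markers.

    For each (toe, target) pair, contact episodes are maximal frame runs with
    distance below ``contact_radius_mm``.  Each episode yields one tap at its
    first local distance minimum; an episode starting within ``refractory_s``
    of the previous tap on the same target by the same foot is suppressed.
    Events are returned sorted by time.
    """
    radius = cfg.tap.contact_radius_mm
    refractory = cfg.tap.refractory_s
    fs = trial.sampling_rate_hz
    events: list[TapEvent] = []
    for side in "LR":
        toe = trial.markers[f"{side}_toe"]
        if toe.missing.any():
            raise ValueError(f"{side}_toe has missing frames; fill or exclude first")
        for digit, target in trial.targets.items():
            d = np.linalg.norm(toe.positions - target, axis=1)
            inside = d < radius
            if not inside.any():
                continue
            edges = np.flatnonzero(np.diff(np.concatenate(([0], inside.view(np.int8), [0]))))
            last_time = -np.inf
            for e0, e1 in zip(edges[0::2], edges[1::2]):
                tap_frame = _first_local_min(d, e0, e1)
                tap_time = tap_frame / fs
                if tap_time - last_time < refractory:
                    continue
                events.append(TapEvent(tap_time, digit, side))
                last_time = tap_time
    events.sort(key=lambda e: e.time_s)
    return events


def _first_local_min(d: np.ndarray, e0: int, e1: int) -> int:
    """First frame in [e0, e1) that is not above its successor."""
    for i in range(e0, e1 - 1):
        if d[i] <= d[i + 1]:
            return i
    return e1 - 1


def score_taps(taps: list[TapEvent], digit_series) -> tuple[int, int]:
    """Score taps against the cyclically repeating digit series.

    The expected digit starts at series position 0; a tap is correct iff its
    target equals the expected digit *and* its foot is that digit's required
    foot, in which case the pointer advances.  Incorrect taps count toward
    ``n_taps`` but do not advance the pointer.  Mutates the ``correct`` and
    ``matched_position`` fields of the events.  Returns ``(n_correct,
    n_taps)``.
    """
    series = tuple(int(d) for d in digit_series)
    if not series:
        raise ValueError("digit series must be nonempty")
    pointer = 0
    n_correct = 0
    for tap in taps:
        expected = series[pointer % len(series)]
        if tap.target == expected and tap.foot == required_foot(expected):
            tap.correct = True
            tap.matched_position = pointer
            pointer += 1
            n_correct += 1
        else:
            tap.correct = False
            tap.matched_position = None
    return n_correct, len(taps)


def first_six_duration(taps: list[TapEvent], trial_start_s: float = 0.0) -> float:
    """Time from trial start to the sixth successful tap (seconds).

    Raises ``ValueError`` when fewer than six taps exist (incomplete trial).
    """
    if len(taps) < 6:
        raise ValueError(f"only {len(taps)} taps; first-six duration undefined")
    return taps[5].time_s - trial_start_s


def im_metrics(
    responses_ms: np.ndarray, beats_ms: np.ndarray, cfg: Config | None = None
) -> IMMetrics:
    """Timing and rhythmic ability of one synchronization-test session.

    Responses are paired to beats greedily by nearest beat, each beat used at
    most once.  Asynchrony is signed (response minus beat, ms); timing
    ability is the mean absolute asynchrony, rhythmic ability the mean
    absolute deviation of successive inter-response intervals from the IOI
    inferred from the beat schedule.
    """
    cfg = cfg or Config()
    responses = np.sort(np.asarray(responses_ms, dtype=float))
    beats = np.asarray(beats_ms, dtype=float)
    if len(responses) < 2:
        raise ValueError("need at least 2 responses")
    if len(beats) < 2:
        raise ValueError("need at least 2 beats")

    used = np.zeros(len(beats), dtype=bool)
    asyn = np.empty(len(responses))
    for i, r in enumerate(responses):
        order = np.argsort(np.abs(beats - r))
        for j in order:
            if not used[j]:
                used[j] = True
                asyn[i] = r - beats[j]
                break
        else:
            raise ValueError("more responses than beats")

    ioi = float(np.median(np.diff(beats)))
    iri = np.diff(responses)
    timing = float(np.mean(np.abs(asyn)))
    rhythmic = float(np.mean(np.abs(iri - ioi)))
    labels = tuple(classify_response(a, cfg) for a in asyn)
    return IMMetrics(timing, rhythmic, asyn, labels)


def classify_response(asynchrony_ms: float, cfg: Config | None = None) -> str:
    """Classify a signed asynchrony as ``on_beat``, ``early`` or ``late``.

    Integer-millisecond boundary semantics: within 15 ms of the beat is
    on-beat; 16 ms or earlier is early; 16 ms or later is late.  Fractional
    asynchronies strictly between 15 and 16 ms round toward zero before
    classification.
    """
    cfg = cfg or Config()
    if not math.isfinite(asynchrony_ms):
        raise ValueError("asynchrony must be finite")
    w = cfg.im.on_beat_window_ms
    t = math.trunc(asynchrony_ms)
    if abs(t) <= w:
        return "on_beat"
    return "early" if t < 0 else "late"
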