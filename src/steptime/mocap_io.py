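"""Reading and writing of trajectory files, trial metadata, configuration and summaries.

This module is the single source of truth for the data model and its
conventions.  All quantities are exchanged in millimetres, mm/s, mm/s**2,
seconds and milliseconds; no other module rescales silently.

Conventions
-----------
* Right-handed lab frame, ``z`` vertical, coordinates in millimetres.
* Frames are 0-based; frame ``i`` of a trajectory sampled at ``f`` Hz is at
  time ``i / f`` seconds.  Time windows are half-open ``[t0, t1)``.
* Missing samples are encoded as empty cells in files (``NaN`` literals are
  also accepted) and as ``True`` entries of :attr:`MarkerTrajectory.missing`.

Trajectory file dialect (tab separated)::

    FREQUENCY <hz>
    MARKERS <label> <label> ...
    x y z x y z ...          # one row per frame, 3 columns per marker

Trial metadata is a comma-separated table keyed by trial id; analysis
configuration is a YAML mapping mirroring :class:`Config`.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, fields as _dc_fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MarkerTrajectory",
    "SteppingTrial",
    "Config",
    "FilterConfig",
    "GapConfig",
    "MuConfig",
    "TapConfig",
    "ImConfig",
    "StatsConfig",
    "MARKER_ROLES",
    "LEFT_DIGITS",
    "RIGHT_DIGITS",
    "required_foot",
    "load_config",
    "read_trial",
    "write_trial",
    "read_metadata",
    "write_metadata",
    "write_summary",
    "read_summary",
]

#: the six body-marker roles used in the kinematic analysis
MARKER_ROLES = ("L_toe", "L_ankle", "L_knee", "R_toe", "R_ankle", "R_knee")

#: digits assigned to each foot in the stepping task
LEFT_DIGITS = frozenset({1, 3, 5})
RIGHT_DIGITS = frozenset({2, 4, 6})


def required_foot(digit: int) -> str:
    """Foot prescribed for a target digit: left for 1/3/5, right for 2/4/6."""
    if digit in LEFT_DIGITS:
        return "L"
    if digit in RIGHT_DIGITS:
        return "R"
    raise ValueError(f"digit must be in 1..6, got {digit}")


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class MarkerTrajectory:
    """Per-frame 3D positions (mm) of one labelled marker.

    ``positions`` has shape ``(n_frames, 3)``; frames flagged in ``missing``
    hold ``NaN`` and are ignored by every computation until filled.
    """

    label: str
    positions: np.ndarray
    sampling_rate_hz: float
    missing: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_frames, 3)")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.missing is None:
            self.missing = np.isnan(self.positions).any(axis=1)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != (len(self.positions),):
            raise ValueError("missing mask length must equal frame count")
        obs = self.positions[~self.missing]
        if obs.size and not np.isfinite(obs).all():
            raise ValueError("non-missing frames must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate_hz

    def copy(self) -> "MarkerTrajectory":
        return MarkerTrajectory(
            self.label, self.positions.copy(), self.sampling_rate_hz, self.missing.copy()
        )


@dataclass
class SteppingTrial:
    """One 20 s stepping trial: six body markers, six targets and metadata."""

    participant_id: str
    group: str  # "SMT" or "CTRL"
    test: str  # "pre" or "post"
    trial_index: int
    digit_series: tuple[int, ...]
    markers: dict[str, MarkerTrajectory]
    targets: dict[int, np.ndarray]  # digit -> (3,) position, mm
    trial_length_s: float = 20.0

    def __post_init__(self) -> None:
        self.digit_series = tuple(int(d) for d in self.digit_series)
        if not self.digit_series:
            raise ValueError("digit_series must be nonempty")
        for d in self.digit_series:
            if not 1 <= d <= 6:
                raise ValueError(f"digit series entries must be in 1..6, got {d}")
        missing_roles = [r for r in MARKER_ROLES if r not in self.markers]
        if missing_roles:
            raise ValueError(f"trial is missing marker role(s): {missing_roles}")
        n = {m.n_frames for m in self.markers.values()}
        fs = {m.sampling_rate_hz for m in self.markers.values()}
        if len(n) != 1 or len(fs) != 1:
            raise ValueError("all markers must share frame count and sampling rate")
        if sorted(self.targets) != [1, 2, 3, 4, 5, 6]:
            raise ValueError("targets must be labelled 1..6 uniquely")
        self.targets = {int(k): np.asarray(v, dtype=float) for k, v in self.targets.items()}

    @property
    def sampling_rate_hz(self) -> float:
        return next(iter(self.markers.values())).sampling_rate_hz

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).n_frames

    @property
    def trial_id(self) -> str:
        return f"{self.participant_id}_{self.test}_t{self.trial_index:02d}"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterConfig:
    order: int = 2
    cutoff_hz: float = 10.0
    dual_pass: bool = True


@dataclass(frozen=True)
class GapConfig:
    #: gaps strictly shorter than this are filled automatically
    auto_fill_max_frames: int = 10
    #: gaps up to this length are filled only under ``manual_policy="accept"``
    manual_fill_max_frames: int = 20
    manual_policy: str = "accept"  # "accept" or "reject"


@dataclass(frozen=True)
class MuConfig:
    #: minimum speed rise/fall of a movement unit, mm/s
    dv_min_mm_s: float = 20.0
    #: minimum acceleration and deceleration magnitude inside a unit, mm/s^2
    da_min_mm_s2: float = 5.0


@dataclass(frozen=True)
class TapConfig:
    contact_radius_mm: float = 60.0
    refractory_s: float = 0.25


@dataclass(frozen=True)
class ImConfig:
    ioi_ms: float = 1100.0
    on_beat_window_ms: float = 15.0


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    #: analysis unit for the stepping/kinematic outcomes ("trial" or "participant")
    analysis_unit: str = "trial"


@dataclass(frozen=True)
class Config:
    filter: FilterConfig = field(default_factory=FilterConfig)
    gaps: GapConfig = field(default_factory=GapConfig)
    mu: MuConfig = field(default_factory=MuConfig)
    tap: TapConfig = field(default_factory=TapConfig)
    im: ImConfig = field(default_factory=ImConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def __post_init__(self) -> None:
        if self.filter.order < 1 or self.filter.cutoff_hz <= 0:
            raise ValueError("filter order and cutoff must be positive")
        if self.gaps.auto_fill_max_frames <= 0 or self.gaps.manual_fill_max_frames <= 0:
            raise ValueError("gap thresholds must be positive")
        if self.gaps.auto_fill_max_frames >= self.gaps.manual_fill_max_frames:
            raise ValueError("auto_fill_max_frames must be < manual_fill_max_frames")
        if self.gaps.manual_policy not in ("accept", "reject"):
            raise ValueError("manual_policy must be 'accept' or 'reject'")
        if self.mu.dv_min_mm_s <= 0 or self.mu.da_min_mm_s2 <= 0:
            raise ValueError("movement-unit thresholds must be positive")
        if self.tap.contact_radius_mm <= 0 or self.tap.refractory_s <= 0:
            raise ValueError("tap thresholds must be positive")
        if self.im.ioi_ms <= 0 or self.im.on_beat_window_ms <= 0:
            raise ValueError("metronome parameters must be positive")
        if not 0 < self.stats.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.stats.analysis_unit not in ("trial", "participant"):
            raise ValueError("analysis_unit must be 'trial' or 'participant'")

    def to_dict(self) -> dict:
        out: dict = {}
        for f in _dc_fields(self):
            sec = getattr(self, f.name)
            out[f.name] = {sf.name: getattr(sec, sf.name) for sf in _dc_fields(sec)}
        return out


_SECTIONS = {
    "filter": FilterConfig,
    "gaps": GapConfig,
    "mu": MuConfig,
    "tap": TapConfig,
    "im": ImConfig,
    "stats": StatsConfig,
}


def load_config(source: str | Path | None = None) -> Config:
    """Load a :class:`Config` from a YAML file, filling unspecified keys with defaults.

    Unknown sections or keys raise ``ValueError`` so that typos cannot silently
    fall back to defaults.  ``source=None`` (or an empty file) yields all
    defaults.
    """
    if source is None:
        return Config()
    data = yaml.safe_load(Path(source).read_text())
    if data is None:
        return Config()
    if not isinstance(data, Mapping):
        raise ValueError("config file must contain a mapping")
    kwargs = {}
    for section, payload in data.items():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section: {section!r}")
        cls = _SECTIONS[section]
        valid = {f.name for f in _dc_fields(cls)}
        payload = payload or {}
        unknown = set(payload) - valid
        if unknown:
            raise ValueError(f"unknown key(s) in config section {section!r}: {sorted(unknown)}")
        kwargs[section] = cls(**payload)
    return Config(**kwargs)


# ---------------------------------------------------------------------------
# trajectory files
# ---------------------------------------------------------------------------


def write_trial(trial: SteppingTrial, path: str | Path) -> None:
    """Write a trial's marker and target trajectories in the TSV dialect.

    Targets are written as static markers ``T1``..``T6`` after the body
    markers, mirroring reflective markers attached to the balls themselves.
    """
    labels = list(MARKER_ROLES) + [f"T{d}" for d in range(1, 7)]
    n = trial.n_frames
    cols: list[np.ndarray] = []
    for role in MARKER_ROLES:
        m = trial.markers[role]
        pos = m.positions.copy()
        pos[m.missing] = np.nan
        cols.append(pos)
    for d in range(1, 7):
        cols.append(np.broadcast_to(trial.targets[d], (n, 3)))
    data = np.hstack(cols)
    buf = _io.StringIO()
    buf.write(f"FREQUENCY\t{trial.sampling_rate_hz:g}\n")
    buf.write("MARKERS\t" + "\t".join(labels) + "\n")
    for row in data:
        buf.write("\t".join("" if np.isnan(v) else f"{v:.6f}" for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_trial(trajectory_file: str | Path, metadata_record: Mapping) -> SteppingTrial:
    """Read one trial from a trajectory file plus its metadata record.

    The metadata record must provide ``participant_id``, ``group``, ``test``,
    ``trial_index`` and ``digit_series`` (digits as a string like ``"165234"``
    or an iterable of ints); ``trial_length_s`` is optional.
    """
    path = Path(trajectory_file)
    lines = path.read_text().splitlines()
    if len(lines) < 2 or not lines[0].startswith("FREQUENCY"):
        raise ValueError(f"{path}: first line must declare FREQUENCY")
    fs = float(lines[0].split("\t")[1])
    if not lines[1].startswith("MARKERS"):
        raise ValueError(f"{path}: second line must declare MARKERS")
    labels = lines[1].split("\t")[1:]
    ncol = 3 * len(labels)
    rows = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip("\t "):
            continue
        parts = line.split("\t")
        if len(parts) != ncol:
            raise ValueError(
                f"{path}:{lineno}: expected {ncol} columns (3 per marker), got {len(parts)}"
            )
        rows.append([np.nan if p.strip() in ("", "nan", "NaN") else float(p) for p in parts])
    data = np.asarray(rows, dtype=float)

    markers: dict[str, MarkerTrajectory] = {}
    targets: dict[int, np.ndarray] = {}
    for j, label in enumerate(labels):
        pos = data[:, 3 * j : 3 * j + 3]
        if label.startswith("T") and label[1:].isdigit():
            targets[int(label[1:])] = np.nanmedian(pos, axis=0)
        else:
            markers[label] = MarkerTrajectory(label, pos, fs)
    missing_roles = [r for r in MARKER_ROLES if r not in markers]
    if missing_roles:
        raise ValueError(f"{path}: missing required marker role(s): {missing_roles}")

    series = metadata_record["digit_series"]
    if isinstance(series, str):
        series = tuple(int(c) for c in series if c.strip())
    return SteppingTrial(
        participant_id=str(metadata_record["participant_id"]),
        group=str(metadata_record["group"]),
        test=str(metadata_record["test"]),
        trial_index=int(metadata_record["trial_index"]),
        digit_series=tuple(series),
        markers=markers,
        targets=targets,
        trial_length_s=float(metadata_record.get("trial_length_s", 20.0)),
    )


# ---------------------------------------------------------------------------
# metadata and summary tables
# ---------------------------------------------------------------------------

_METADATA_COLUMNS = [
    "trial_id",
    "participant_id",
    "group",
    "test",
    "trial_index",
    "digit_series",
    "trial_length_s",
    "trajectory_file",
]


def write_metadata(records: Sequence[Mapping], path: str | Path) -> None:
    df = pd.DataFrame(list(records))
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata records lack column(s): {missing}")
    df[_METADATA_COLUMNS].to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"digit_series": str, "participant_id": str})
    return df.set_index("trial_id", drop=False)


def write_summary(records: Sequence[Mapping], path: str | Path) -> pd.DataFrame:
    """Write per-trial/leg summary records as a deterministic CSV table.

    All records must share one schema; columns keep the order of the first
    record and floats are rendered with six decimals so that rewriting the
    same records is byte-identical.
    """
    records = list(records)
    if records:
        schema = list(records[0].keys())
        for r in records[1:]:
            if list(r.keys()) != schema:
                raise ValueError("summary records have mixed schemas")
        df = pd.DataFrame(records, columns=schema)
    else:
        df = pd.DataFrame()
    df.to_csv(path, index=False, float_format="%.6f")
    return df


def read_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
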