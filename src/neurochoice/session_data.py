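"""Canonical data model for 2AUC task sessions.

A trial of the two-alternative unforced-choice (2AUC) task presents grating
stimuli of independent contrast on a left and a right screen; the animal
responds Left, Right, or NoGo (holding the wheel still).  Sessions bundle
trials recorded from one subject in one sitting, together with optional
per-trial region-activity estimates used by the neurometric and decoding
modules.

Trial and activity tables are plain delimited text (UTF-8 CSV with a header
row); missing values are empty fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHOICES",
    "REGIONS",
    "REGION_COORDS_MM",
    "TrialRecord",
    "Session",
    "ActivityMatrix",
    "ValidationReport",
    "SchemaError",
    "TrialParseError",
    "load_trial_table",
    "write_trial_table",
    "sessions_to_frame",
    "load_activity_table",
    "write_activity_table",
    "validate_session",
    "rewarded_choices",
    "is_correct",
]

CHOICES = ("Left", "Right", "NoGo")

#: Fixed region order used throughout the package for activity vectors f.
REGIONS = ("VISp_L", "VISp_R", "MOs_L", "MOs_R")

#: Canonical stereotaxic coordinates (AP, ML) in mm from bregma for named
#: laser targets (ML sign: left hemisphere negative).
REGION_COORDS_MM: Mapping[str, tuple[float, float]] = {
    "VISp_L": (-4.0, -2.0),
    "VISp_R": (-4.0, 2.0),
    "MOs_L": (2.0, -0.5),
    "MOs_R": (2.0, 0.5),
    "MOp_L": (-0.5, -1.0),
    "MOp_R": (-0.5, 1.0),
}

TRIAL_COLUMNS = (
    "trial_id",
    "session_id",
    "subject_id",
    "contrast_left",
    "contrast_right",
    "choice",
    "reaction_time",
    "laser_on",
    "laser_region",
    "laser_ap_mm",
    "laser_ml_mm",
    "laser_power_mw",
    "laser_onset_s",
)

REQUIRED_COLUMNS = (
    "trial_id",
    "session_id",
    "subject_id",
    "contrast_left",
    "contrast_right",
    "choice",
)


class SchemaError(ValueError):
    """A required column is missing or the table layout is malformed."""


class TrialParseError(ValueError):
    """A row holds a value outside its domain (bad category, bad range)."""


@dataclass(slots=True)
class TrialRecord:
    """One behavioral trial.

    Contrasts are fractions in [0, 1]; percent values (1, 100] on input are
    divided by 100.  ``reaction_time`` is movement-onset time in seconds from
    stimulus onset and is NaN for NoGo trials.  Laser metadata is all-or-none:
    ``laser_region``/``laser_coord`` are set iff ``laser_on``.
    """

    trial_id: int
    session_id: str
    subject_id: str
    contrast_left: float
    contrast_right: float
    choice: str | None  # None only transiently, before choice simulation
    reaction_time: float = math.nan
    laser_on: bool = False
    laser_region: str | None = None
    laser_coord: tuple[float, float] | None = None  # (AP, ML) mm from bregma
    laser_power_mw: float = 0.0
    laser_onset_s: float = math.nan
    reward: float | None = None

    def __post_init__(self) -> None:
        self.contrast_left = _as_contrast(self.contrast_left, "contrast_left")
        self.contrast_right = _as_contrast(self.contrast_right, "contrast_right")
        if self.choice is not None and self.choice not in CHOICES:
            raise TrialParseError(
                f"choice must be one of {CHOICES}, got {self.choice!r}"
            )
        if not self.laser_on and (
            self.laser_region is not None or self.laser_coord is not None
        ):
            raise TrialParseError(
                "laser_region/laser_coord set on a trial with laser_on=False"
            )
        if self.laser_on and self.laser_region is None and self.laser_coord is None:
            raise TrialParseError("laser_on trial needs laser_region or laser_coord")
        if self.laser_region is not None and self.laser_coord is None:
            self.laser_coord = REGION_COORDS_MM.get(self.laser_region)


def _as_contrast(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise TrialParseError(f"{name} must be finite, got {value}")
    if 1.0 < value <= 100.0:  # percent on input
        value = value / 100.0
    if not 0.0 <= value <= 1.0:
        raise TrialParseError(f"{name} must lie in [0, 1], got {value}")
    return value


@dataclass
class Session:
    """Ordered trials from one subject in one recording session."""

    session_id: str
    subject_id: str
    trials: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.trials:
            if t.session_id != self.session_id or t.subject_id != self.subject_id:
                raise TrialParseError(
                    f"trial {t.trial_id} carries ids {t.session_id}/{t.subject_id},"
                    f" session is {self.session_id}/{self.subject_id}"
                )
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise TrialParseError(f"duplicate trial_ids in session {self.session_id}")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def condition_table(self) -> list[tuple[float, float]]:
        """Distinct (contrast_left, contrast_right) pairs present, sorted."""
        return sorted({(t.contrast_left, t.contrast_right) for t in self.trials})

    def to_frame(self) -> pd.DataFrame:
        return sessions_to_frame([self])


@dataclass
class ActivityMatrix:
    """Per-trial x per-region (x time-window) scalar activity.

    ``values`` has shape (n_trials, n_regions, n_windows) and holds the
    activity vector f: estimated population firing rate (spikes/s after
    calibration) or a dF/F-derivative signal before calibration.
    """

    trial_ids: np.ndarray
    regions: tuple[str, ...]
    windows: tuple[tuple[float, float], ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        self.regions = tuple(self.regions)
        self.windows = tuple((float(a), float(b)) for a, b in self.windows)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        expected = (len(self.trial_ids), len(self.regions), len(self.windows))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != {expected} implied by "
                "trial_ids/regions/windows"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity values must be finite")
        for a, b in self.windows:
            if not a < b:
                raise ValueError(f"window bounds must satisfy start < end: {(a, b)}")

    def rates(self, window: int = 0) -> np.ndarray:
        """(n_trials, n_regions) slice for one window."""
        return self.values[:, :, window]

    def for_trials(self, trial_ids: Sequence[int]) -> np.ndarray:
        """Rows of ``rates(0)`` aligned to ``trial_ids`` (all must be present)."""
        index = {tid: i for i, tid in enumerate(self.trial_ids.tolist())}
        missing = [tid for tid in trial_ids if tid not in index]
        if missing:
            raise ValueError(f"activity missing for trial ids {missing}")
        rows = np.array([index[tid] for tid in trial_ids], dtype=int)
        return self.values[rows, :, 0]


# ---------------------------------------------------------------------------
# Trial-table IO
# ---------------------------------------------------------------------------


def sessions_to_frame(sessions: Iterable[Session]) -> pd.DataFrame:
    rows = []
    any_reward = False
    for sess in sessions:
        for t in sess.trials:
            ap, ml = t.laser_coord if t.laser_coord is not None else (math.nan, math.nan)
            rows.append(
                {
                    "trial_id": t.trial_id,
                    "session_id": t.session_id,
                    "subject_id": t.subject_id,
                    "contrast_left": t.contrast_left,
                    "contrast_right": t.contrast_right,
                    "choice": t.choice,
                    "reaction_time": t.reaction_time,
                    "laser_on": t.laser_on,
                    "laser_region": t.laser_region if t.laser_region else "",
                    "laser_ap_mm": ap,
                    "laser_ml_mm": ml,
                    "laser_power_mw": t.laser_power_mw,
                    "laser_onset_s": t.laser_onset_s,
                    "reward": t.reward,
                }
            )
            any_reward = any_reward or t.reward is not None
    frame = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS) + ["reward"])
    if not any_reward:
        frame = frame.drop(columns=["reward"])
    return frame


def write_trial_table(sessions: Iterable[Session], path) -> None:
    """Write sessions as a delimited trial table; inverse of load_trial_table."""
    sessions_to_frame(sessions).to_csv(path, index=False)


def load_trial_table(path, schema: Mapping[str, str] | None = None) -> list[Session]:
    """Read a trial table into validated Sessions.

    Parameters
    ----------
    path : file path or buffer of a comma-separated table with a header row.
    schema : optional map {canonical name -> column name in the file}.

    Returns one Session per distinct ``session_id`` (in order of first
    appearance), trials ordered by ``trial_id``.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if schema:
        frame = frame.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"trial table is missing required columns: {missing}")
    return frame_to_sessions(frame)


def frame_to_sessions(frame: pd.DataFrame) -> list[Session]:
    sessions: dict[str, Session] = {}
    for pos, row in enumerate(frame.itertuples(index=False), start=1):
        rec = row._asdict()
        try:
            trial = _trial_from_row(rec)
        except TrialParseError as err:
            raise TrialParseError(f"row {pos}: {err}") from err
        sess = sessions.get(trial.session_id)
        if sess is None:
            sess = Session(trial.session_id, trial.subject_id, [])
            sessions[trial.session_id] = sess
        sess.trials.append(trial)
    out = []
    for sess in sessions.values():
        sess.trials.sort(key=lambda t: t.trial_id)
        out.append(Session(sess.session_id, sess.subject_id, sess.trials))
    return out


def _opt_float(value) -> float:
    if value is None or (isinstance(value, str) and value.strip() == ""):
        return math.nan
    value = float(value)
    return value


def _trial_from_row(rec: Mapping) -> TrialRecord:
    laser_on = bool(rec.get("laser_on", False))
    if isinstance(rec.get("laser_on"), str):
        laser_on = rec["laser_on"].strip().lower() in {"true", "1", "yes"}
    region = rec.get("laser_region")
    if region is None or (isinstance(region, float) and math.isnan(region)):
        region = None
    else:
        region = str(region).strip()
        if region in {"", "none"}:
            region = None
    ap = _opt_float(rec.get("laser_ap_mm"))
    ml = _opt_float(rec.get("laser_ml_mm"))
    coord = (ap, ml) if math.isfinite(ap) and math.isfinite(ml) else None
    reward = rec.get("reward")
    if reward is not None:
        reward = _opt_float(reward)
        if math.isnan(reward):
            reward = None
    power = _opt_float(rec.get("laser_power_mw"))
    return TrialRecord(
        trial_id=int(rec["trial_id"]),
        session_id=str(rec["session_id"]),
        subject_id=str(rec["subject_id"]),
        contrast_left=rec["contrast_left"],
        contrast_right=rec["contrast_right"],
        choice=str(rec["choice"]),
        reaction_time=_opt_float(rec.get("reaction_time")),
        laser_on=laser_on,
        laser_region=region if laser_on else None,
        laser_coord=coord if laser_on else None,
        laser_power_mw=0.0 if math.isnan(power) else power,
        laser_onset_s=_opt_float(rec.get("laser_onset_s")),
        reward=reward,
    )


# ---------------------------------------------------------------------------
# Activity-table IO
# ---------------------------------------------------------------------------


def write_activity_table(activity: ActivityMatrix, path) -> None:
    rows = []
    for i, tid in enumerate(activity.trial_ids.tolist()):
        for r, region in enumerate(activity.regions):
            for w, (a, b) in enumerate(activity.windows):
                rows.append((tid, region, a, b, activity.values[i, r, w]))
    pd.DataFrame(
        rows, columns=["trial_id", "region", "window_start_s", "window_end_s", "value"]
    ).to_csv(path, index=False)


def load_activity_table(path) -> ActivityMatrix:
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"trial_id", "region", "window_start_s", "window_end_s", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"activity table is missing columns: {sorted(missing)}")
    trial_ids = list(dict.fromkeys(frame["trial_id"].astype(int)))
    regions = tuple(dict.fromkeys(frame["region"].astype(str)))
    windows = tuple(
        dict.fromkeys(zip(frame["window_start_s"], frame["window_end_s"]))
    )
    t_index = {tid: i for i, tid in enumerate(trial_ids)}
    r_index = {r: i for i, r in enumerate(regions)}
    w_index = {w: i for i, w in enumerate(windows)}
    values = np.full((len(trial_ids), len(regions), len(windows)), np.nan)
    for row in frame.itertuples(index=False):
        values[
            t_index[int(row.trial_id)],
            r_index[str(row.region)],
            w_index[(row.window_start_s, row.window_end_s)],
        ] = row.value
    if np.isnan(values).any():
        raise SchemaError("activity table does not cover trial x region x window grid")
    return ActivityMatrix(np.array(trial_ids), regions, windows, values)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def rewarded_choices(contrast_left: float, contrast_right: float) -> tuple[str, ...]:
    """Choices rewarded under the task rules for one stimulus condition.

    Higher contrast side wins; equal non-zero contrast rewards Left or Right
    (randomly, 50% each); no stimulus rewards NoGo.
    """
    if contrast_left == 0.0 and contrast_right == 0.0:
        return ("NoGo",)
    if contrast_left > contrast_right:
        return ("Left",)
    if contrast_right > contrast_left:
        return ("Right",)
    return ("Left", "Right")


def is_correct(trial: TrialRecord) -> bool:
    return trial.choice in rewarded_choices(trial.contrast_left, trial.contrast_right)


def is_easy(trial: TrialRecord, high_contrast: float = 0.5) -> bool:
    """Easy trial: one side at high contrast (>= 0.5), the other blank."""
    lo = min(trial.contrast_left, trial.contrast_right)
    hi = max(trial.contrast_left, trial.contrast_right)
    return lo == 0.0 and hi >= high_contrast


@dataclass
class ValidationReport:
    session_id: str
    violations: list[str]
    excluded: list[tuple[int, str]]  # (trial_id, reason)

    @property
    def ok(self) -> bool:
        return not self.violations

    @property
    def excluded_ids(self) -> set[int]:
        return {tid for tid, _ in self.excluded}


def validate_session(
    session: Session, warmup_trials: int = 5, high_contrast: float = 0.5
) -> ValidationReport:
    """Report invariant violations and standard trial exclusions.

    Exclusions flagged (never applied in place):
    * the first ``warmup_trials`` trials of the session (settling-in period);
    * the second and further consecutive errors on easy trials (high contrast
      vs. zero), which typically reflect disengagement.
    """
    violations: list[str] = []
    excluded: list[tuple[int, str]] = []
    for t in session.trials:
        if t.choice is None:
            violations.append(f"trial {t.trial_id}: choice is unset")
            continue
        if t.choice == "NoGo" and math.isfinite(t.reaction_time):
            violations.append(f"trial {t.trial_id}: NoGo trial has a reaction time")
        if t.choice != "NoGo" and not math.isfinite(t.reaction_time):
            # tolerated (not recorded), but worth surfacing
            pass
        if t.laser_on and t.laser_region is None and t.laser_coord is None:
            violations.append(f"trial {t.trial_id}: laser_on without site")
    for t in session.trials[:warmup_trials]:
        excluded.append((t.trial_id, "warmup"))
    prev_easy_error = False
    for t in session.trials:
        easy_error = is_easy(t, high_contrast) and not is_correct(t)
        if easy_error and prev_easy_error:
            excluded.append((t.trial_id, "repeated_easy_error"))
        prev_easy_error = easy_error
    return ValidationReport(session.session_id, violations, excluded)


def exclude_trials(session: Session, report: ValidationReport) -> Session:
    """Copy of ``session`` without the trials flagged in ``report``."""
    keep = [t for t in session.trials if t.trial_id not in report.excluded_ids]
    return replace(session, trials=[replace(t) for t in keep])
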