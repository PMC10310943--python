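"""Core domain types: recordings, schedules, and per-subject parameter rows.

Conventions fixed package-wide: screen-center origin, rightward/upward
positive, gaze in degrees of visual angle, times in seconds from recording
start. Recordings are stored as numpy arrays (one recording = one task run,
possibly many trials) with a per-sample trial index.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Task",
    "GazeRecording",
    "Trial",
    "TrialSchedule",
    "SubjectParameters",
    "CANONICAL_PARAMETERS",
    "FIXATION_PARAMETERS",
    "PROSACCADE_PARAMETERS",
    "ANTISACCADE_PARAMETERS",
    "DataError",
    "FormatError",
]

MAX_GAZE_DEG = 60.0  # sanity bound on |x|, |y|


class DataError(ValueError):
    """Raised when on-disk or in-memory data violates a domain invariant."""


class FormatError(ValueError):
    """Raised when a file does not conform to the expected dialect."""


class Task(str, enum.Enum):
    FIXATION = "fixation"
    PROSACCADE = "prosaccade"
    ANTISACCADE = "antisaccade"


# Canonical per-subject parameter names: 5 fixation + 7 x 2 pro-saccade
# eccentricity classes + 5 anti-saccade = 24.
FIXATION_PARAMETERS = (
    "fix_bcea68",
    "fix_bcea95",
    "fix_sd_h",
    "fix_sd_v",
    "fix_intrusion_rate",
)
_PRO_BASE = (
    "latency",
    "time_to_target",
    "mean_velocity",
    "peak_velocity",
    "first_gain",
    "first_gain_error",
    "n_saccades",
)
PROSACCADE_PARAMETERS = tuple(
    f"pro_{ecc}_{name}" for ecc in ("short", "large") for name in _PRO_BASE
)
ANTISACCADE_PARAMETERS = (
    "anti_error_rate",
    "anti_corrected_rate",
    "anti_recognition_rate",
    "anti_correct_latency",
    "anti_incorrect_latency",
)
CANONICAL_PARAMETERS = FIXATION_PARAMETERS + PROSACCADE_PARAMETERS + ANTISACCADE_PARAMETERS
assert len(CANONICAL_PARAMETERS) == 24


@dataclass
class GazeRecording:
    """One task run of 2-D gaze samples in degrees of visual angle.

    ``valid`` marks tracker-reported sample validity; invalid samples are
    carried through I/O untouched so that preprocessing, not parsing,
    decides their fate.
    """

    subject_id: str
    task: Task
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    trial_id: np.ndarray
    sample_rate: float = 60.0

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.trial_id = np.asarray(self.trial_id, dtype=int)
        n = self.t.size
        if n < 2:
            raise DataError("a gaze recording needs at least 2 samples")
        for name in ("x", "y", "valid", "trial_id"):
            if getattr(self, name).size != n:
                raise DataError(f"column '{name}' length mismatch with t")
        dt = np.diff(self.t)
        if np.any(dt < 0):
            idx = int(np.argmax(dt < 0)) + 1
            raise DataError(f"time not non-decreasing at sample index {idx}")
        v = self.valid
        if np.any(np.abs(self.x[v]) > MAX_GAZE_DEG) or np.any(np.abs(self.y[v]) > MAX_GAZE_DEG):
            raise DataError(f"valid gaze sample outside the +/-{MAX_GAZE_DEG} deg sanity bound")
        if not (np.isfinite(self.sample_rate) and self.sample_rate > 0):
            raise DataError("sample_rate must be a positive frequency in Hz")
        med = float(np.median(dt[dt > 0])) if np.any(dt > 0) else math.inf
        nominal = 1.0 / self.sample_rate
        if not (0.8 * nominal <= med <= 1.2 * nominal):
            raise DataError(
                f"median inter-sample interval {med:.4f}s deviates >20% from "
                f"nominal {nominal:.4f}s"
            )

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def copy(self) -> "GazeRecording":
        return GazeRecording(
            subject_id=self.subject_id,
            task=self.task,
            t=self.t.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            valid=self.valid.copy(),
            trial_id=self.trial_id.copy(),
            sample_rate=self.sample_rate,
        )


@dataclass
class Trial:
    """Stimulus geometry and timing for one trial.

    Times are absolute seconds within the task recording. The anti-saccade
    fields (``arrow_*``, ``response_window``) are None for the other tasks.
    """

    trial_id: int
    target_x: float
    target_y: float
    fixation_onset: float
    target_onset: float
    target_duration: float
    eccentricity_class: str = "n/a"  # short | large | n/a
    arrow_direction: Optional[str] = None  # left | right | up | down
    arrow_onset: Optional[float] = None
    arrow_duration: Optional[float] = None
    response_window: Optional[float] = None

    @property
    def end(self) -> float:
        if self.response_window is not None and self.arrow_onset is not None:
            return self.arrow_onset + (self.arrow_duration or 0.0) + self.response_window
        return self.target_onset + self.target_duration


@dataclass
class TrialSchedule:
    task: Task
    trials: list[Trial] = field(default_factory=list)
    sample_rate: float = 60.0

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        prev_end = -math.inf
        for tr in self.trials:
            if tr.fixation_onset < prev_end - 1e-9:
                raise DataError(f"trial {tr.trial_id} overlaps the previous trial")
            prev_end = tr.end

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class SubjectParameters:
    """One subject's extracted oculomotor parameters plus demographics.

    ``parameters`` maps each of the 24 canonical names to a float; missing
    values are NaN (explicit, never silently absent).
    """

    subject_id: str
    group: str  # "PD" | "HC"
    age: float
    sex: str  # "M" | "F"
    updrs3: Optional[float]
    parameters: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.parameters) != set(CANONICAL_PARAMETERS):
            missing = set(CANONICAL_PARAMETERS) - set(self.parameters)
            extra = set(self.parameters) - set(CANONICAL_PARAMETERS)
            raise DataError(
                "parameter map must contain exactly the 24 canonical names; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        if self.group not in ("PD", "HC"):
            raise DataError(f"group must be 'PD' or 'HC', got {self.group!r}")
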