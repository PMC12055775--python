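"""Task protocol: trial timing, domain types, units, and file formats.

Conventions used throughout the package:

* gaze angles in degrees of visual angle, rightward/upward positive,
  0 = central fixation;
* pupil diameters in millimetres;
* all event times in seconds from recording start;
* trial windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TaskType",
    "Side",
    "Eye",
    "Group",
    "TrialSpec",
    "StimulusSchedule",
    "GazeRecording",
    "build_schedule",
    "trial_windows",
    "write_events_csv",
    "read_events_csv",
    "write_recording_csv",
    "read_recording_csv",
    "FIXATION_S",
    "STIMULUS_S",
    "REST_S",
    "TRIAL_S",
    "TRIALS_PER_SIDE",
    "TRIALS_PER_TASK",
    "DEFAULT_SAMPLE_RATE_HZ",
    "DEFAULT_ECCENTRICITY_DEG",
]

#: Trial phase durations in seconds: 1 s central fixation, 1.2 s lateral
#: stimulus, 2 s rest.
FIXATION_S = 1.0
STIMULUS_S = 1.2
REST_S = 2.0
TRIAL_S = FIXATION_S + STIMULUS_S + REST_S  # 4.2 s

TRIALS_PER_SIDE = 20
TRIALS_PER_TASK = 2 * TRIALS_PER_SIDE  # 40

#: Sample rate is not fixed by the protocol; 120 Hz is a typical VR tracker
#: rate and its Nyquist frequency (60 Hz) comfortably covers the 19 Hz
#: spectral cutoff.
DEFAULT_SAMPLE_RATE_HZ = 120.0
DEFAULT_ECCENTRICITY_DEG = 10.0


class TaskType(str, enum.Enum):
    """The two saccade task variants."""

    PRO = "pro_saccade"
    ANTI = "anti_saccade"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"

    @property
    def sign(self) -> int:
        """Horizontal sign of this side (right positive)."""
        return 1 if self is Side.RIGHT else -1


class Eye(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Group(str, enum.Enum):
    PD = "PD"
    CONTROL = "control"


@dataclass(frozen=True)
class TrialSpec:
    """Timing and stimulus geometry for one trial.

    Phase boundaries obey the protocol: stimulus onset 1.0 s after fixation
    onset, stimulus visible for 1.2 s, followed by a 2.0 s rest.
    """

    index: int
    fixation_onset_s: float
    stimulus_onset_s: float
    stimulus_offset_s: float
    rest_end_s: float
    side: Side
    target_eccentricity_deg: float

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("trial index must be >= 0")
        if self.target_eccentricity_deg <= 0:
            raise ValueError("target eccentricity must be positive")
        for got, want, name in [
            (self.stimulus_onset_s - self.fixation_onset_s, FIXATION_S, "fixation"),
            (self.stimulus_offset_s - self.stimulus_onset_s, STIMULUS_S, "stimulus"),
            (self.rest_end_s - self.stimulus_offset_s, REST_S, "rest"),
        ]:
            if abs(got - want) > 1e-9:
                raise ValueError(f"{name} phase duration {got:.6f}s != {want}s")

    @property
    def target_deg(self) -> float:
        """Signed stimulus position (degrees, rightward positive)."""
        return self.side.sign * self.target_eccentricity_deg

    @property
    def window(self) -> tuple[float, float]:
        return (self.fixation_onset_s, self.rest_end_s)


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered trials for one task run."""

    task: TaskType
    trials: tuple[TrialSpec, ...]

    def __post_init__(self) -> None:
        prev_end = None
        for tr in self.trials:
            if prev_end is not None and tr.fixation_onset_s < prev_end - 1e-9:
                raise ValueError("overlapping trial windows")
            prev_end = tr.rest_end_s

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def duration_s(self) -> float:
        return self.trials[-1].rest_end_s if self.trials else 0.0

    def side_counts(self) -> dict[Side, int]:
        counts = {Side.LEFT: 0, Side.RIGHT: 0}
        for tr in self.trials:
            counts[tr.side] += 1
        return counts


@dataclass
class GazeRecording:
    """Uniformly sampled gaze + pupil time series for one subject and task."""

    subject_id: str
    group: Group
    task: TaskType
    sample_rate_hz: float
    t: np.ndarray
    gaze_x_deg: np.ndarray
    gaze_y_deg: np.ndarray
    pupil_left_mm: np.ndarray
    pupil_right_mm: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def pupil(self, eye: Eye) -> np.ndarray:
        return self.pupil_left_mm if eye is Eye.LEFT else self.pupil_right_mm

    def valid(self, eye: Eye) -> np.ndarray:
        return self.valid_left if eye is Eye.LEFT else self.valid_right

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        n = len(self.t)
        arrays = [
            self.gaze_x_deg,
            self.gaze_y_deg,
            self.pupil_left_mm,
            self.pupil_right_mm,
            self.valid_left,
            self.valid_right,
        ]
        if any(len(a) != n for a in arrays):
            raise ValueError("signal arrays must all share the time grid length")
        dt = np.diff(self.t)
        if n > 1:
            if not np.all(dt > 0):
                raise ValueError("t must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.sample_rate_hz)) > 1e-9:
                raise ValueError("t spacing must equal 1/sample_rate within 1e-9")
        for pupil, valid in [(self.pupil_left_mm, self.valid_left), (self.pupil_right_mm, self.valid_right)]:
            if np.any(pupil[np.asarray(valid, bool)] <= 0):
                raise ValueError("valid pupil samples must be positive")


def build_schedule(
    task: TaskType,
    eccentricity_deg: float = DEFAULT_ECCENTRICITY_DEG,
    seed: int = 0,
) -> StimulusSchedule:
    """Build the 40-trial schedule for one task.

    Twenty trials per side, side order a seeded random permutation; trial
    ``k`` spans ``[4.2 k, 4.2 (k+1))`` seconds.
    """
    if eccentricity_deg <= 0:
        raise ValueError("eccentricity must be positive")
    rng = np.random.default_rng(seed)
    pool = [Side.LEFT] * TRIALS_PER_SIDE + [Side.RIGHT] * TRIALS_PER_SIDE
    sides = [pool[i] for i in rng.permutation(TRIALS_PER_TASK)]
    trials = []
    for k, side in enumerate(sides):
        t0 = k * TRIAL_S
        trials.append(
            TrialSpec(
                index=k,
                fixation_onset_s=t0,
                stimulus_onset_s=t0 + FIXATION_S,
                stimulus_offset_s=t0 + FIXATION_S + STIMULUS_S,
                rest_end_s=(k + 1) * TRIAL_S,  # exact: equals the next fixation onset
                side=side,
                target_eccentricity_deg=eccentricity_deg,
            )
        )
    return StimulusSchedule(task=task, trials=tuple(trials))


def trial_windows(schedule: StimulusSchedule) -> list[tuple[float, float]]:
    """Half-open ``[fixation_onset, rest_end)`` interval per trial."""
    return [tr.window for tr in schedule.trials]


# ---------------------------------------------------------------------------
# Interchange formats (CSV)
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "subject_id",
    "task",
    "trial_index",
    "side",
    "fixation_onset_s",
    "stimulus_onset_s",
    "stimulus_offset_s",
    "rest_end_s",
    "target_eccentricity_deg",
]


def write_events_csv(schedule: StimulusSchedule, subject_id: str, path: str | Path) -> None:
    rows = [
        {
            "subject_id": subject_id,
            "task": schedule.task.value,
            "trial_index": tr.index,
            "side": tr.side.value,
            "fixation_onset_s": tr.fixation_onset_s,
            "stimulus_onset_s": tr.stimulus_onset_s,
            "stimulus_offset_s": tr.stimulus_offset_s,
            "rest_end_s": tr.rest_end_s,
            "target_eccentricity_deg": tr.target_eccentricity_deg,
        }
        for tr in schedule.trials
    ]
    # %.17g guarantees exact float64 text round-trip
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_events_csv(path: str | Path) -> StimulusSchedule:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events file missing columns: {sorted(missing)}")
    tasks = df["task"].unique()
    if len(tasks) != 1:
        raise ValueError("events file must contain exactly one task")
    df = df.sort_values("trial_index")
    trials = tuple(
        TrialSpec(
            index=int(r.trial_index),
            fixation_onset_s=float(r.fixation_onset_s),
            stimulus_onset_s=float(r.stimulus_onset_s),
            stimulus_offset_s=float(r.stimulus_offset_s),
            rest_end_s=float(r.rest_end_s),
            side=Side(r.side),
            target_eccentricity_deg=float(r.target_eccentricity_deg),
        )
        for r in df.itertuples()
    )
    return StimulusSchedule(task=TaskType(tasks[0]), trials=trials)


def write_recording_csv(rec: GazeRecording, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t": rec.t,
            "gaze_x_deg": rec.gaze_x_deg,
            "gaze_y_deg": rec.gaze_y_deg,
            "pupil_left_mm": rec.pupil_left_mm,
            "pupil_right_mm": rec.pupil_right_mm,
            "valid_left": rec.valid_left.astype(int),
            "valid_right": rec.valid_right.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_recording_csv(
    path: str | Path,
    subject_id: str,
    group: Group,
    task: TaskType,
    sample_rate_hz: float | None = None,
) -> GazeRecording:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["t"].to_numpy(float)
    if sample_rate_hz is None:
        if len(t) < 2:
            raise ValueError("cannot infer sample rate from fewer than 2 samples")
        sample_rate_hz = 1.0 / float(np.median(np.diff(t)))
    rec = GazeRecording(
        subject_id=subject_id,
        group=group,
        task=task,
        sample_rate_hz=float(sample_rate_hz),
        t=t,
        gaze_x_deg=df["gaze_x_deg"].to_numpy(float),
        gaze_y_deg=df["gaze_y_deg"].to_numpy(float),
        pupil_left_mm=df["pupil_left_mm"].to_numpy(float),
        pupil_right_mm=df["pupil_right_mm"].to_numpy(float),
        valid_left=df["valid_left"].to_numpy(bool),
        valid_right=df["valid_right"].to_numpy(bool),
    )
    rec.validate()
    return rec
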