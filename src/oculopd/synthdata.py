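"""Synthetic cohorts of saccade-task recordings with known generating truth.

Saccades use a minimum-jerk position profile, whose closed-form
peak-velocity relation ``duration = 1.875 * |amplitude| / peak_velocity``
makes generator truth recoverable by the detector. Pupil traces are a
baseline plus stimulus-locked constriction dips, stationary band-limited
sinusoids, and white noise. All randomness flows from one root seed via
deterministically spawned child seeds.

Default group profiles are centred on published group-level summary values
for early-stage PD patients versus healthy controls (saccade dynamics and
pupil-oscillation amplitude scale); they are illustrative of the reported
group contrasts, not a claim of fidelity to individual subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from oculopd.protocol import (
    DEFAULT_ECCENTRICITY_DEG,
    DEFAULT_SAMPLE_RATE_HZ,
    GazeRecording,
    Group,
    Side,
    StimulusSchedule,
    TaskType,
    build_schedule,
)

__all__ = [
    "MeanSD",
    "GroupProfile",
    "CohortConfig",
    "SubjectData",
    "CohortData",
    "synth_saccade_waveform",
    "minimum_jerk_duration_s",
    "synth_pupil_signal",
    "simulate_subject",
    "simulate_cohort",
    "default_pd_profile",
    "default_control_profile",
]

MeanSD = tuple[float, float]

#: Minimum-jerk peak-velocity factor: v_peak = 1.875 * amplitude / duration.
_MINJERK_FACTOR = 1.875

# Fixed micro-parameters of the behavioural model (not group-dependent).
_LATENCY_CLIP_S = (0.10, 0.60)
_GAIN_CLIP = (0.50, 1.30)
_MIN_PEAK_VELOCITY_DPS = 120.0
_CORRECTIVE_ISI_S = (0.15, 0.03)  # inter-saccadic interval before a refixation
_RECENTER_BEFORE_REST_END_S = 0.45
_BLINK_DUR_RANGE_S = (0.10, 0.30)

# Profile SDs describe between-subject spread (the scale on which group
# summaries are reported); trial-to-trial jitter within a subject is a
# fixed fraction of that spread.
_WITHIN_SD_FRAC = 0.35
_SUBJECT_PROB_SD = {"pro_correct": 0.12, "anti_error": 0.15, "anti_correction": 0.25}
_BAND_AMP_TRACE_SD_FRAC = 0.2
_BASELINE_TRACE_SD_MM = 0.05
_CONSTRICTION_TRACE_SD_MM = 0.02


def _draw(rng: np.random.Generator, ms: MeanSD, lo: float | None = None, hi: float | None = None) -> float:
    v = rng.normal(ms[0], ms[1]) if ms[1] > 0 else ms[0]
    if lo is not None or hi is not None:
        v = float(np.clip(v, lo, hi))
    return float(v)


@dataclass(frozen=True)
class GroupProfile:
    """Generating parameters for one diagnostic group.

    ``latency_ms`` etc. are (mean, sd) pairs; ``band_osc_amp_mm`` maps
    oscillation frequency (Hz, must lie in [0, 19]) to an amplitude
    (mean, sd) pair in millimetres.
    """

    latency_ms: MeanSD
    peak_velocity_dps: MeanSD
    gain: MeanSD
    pro_correct_prob: float
    anti_error_prob: float
    anti_correction_prob: float
    correction_delay_ms: MeanSD
    pupil_baseline_mm: MeanSD
    constriction_amp_mm: MeanSD
    band_osc_amp_mm: dict[float, MeanSD] = field(default_factory=dict)
    noise_sd_mm: float = 0.02
    blink_rate_hz: float = 0.05

    def __post_init__(self) -> None:
        for name in ("latency_ms", "peak_velocity_dps", "gain", "correction_delay_ms", "pupil_baseline_mm", "constriction_amp_mm"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} SD must be >= 0")
        for p in (self.pro_correct_prob, self.anti_error_prob, self.anti_correction_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for f, ms in self.band_osc_amp_mm.items():
            if not 0.0 <= f <= 19.0:
                raise ValueError("band oscillation frequencies must lie in [0, 19] Hz")
            if ms[1] < 0:
                raise ValueError("band oscillation amplitude SD must be >= 0")
        if self.noise_sd_mm < 0 or self.blink_rate_hz < 0:
            raise ValueError("noise_sd_mm and blink_rate_hz must be >= 0")


def default_pd_profile() -> GroupProfile:
    return GroupProfile(
        latency_ms=(270.0, 115.0),
        peak_velocity_dps=(420.0, 150.0),
        gain=(0.82, 0.12),
        pro_correct_prob=0.85,
        anti_error_prob=0.55,
        anti_correction_prob=0.27,
        correction_delay_ms=(250.0, 120.0),
        pupil_baseline_mm=(3.5, 0.3),
        constriction_amp_mm=(0.5, 0.1),
        band_osc_amp_mm={2.1: (0.47, 0.10), 11.8: (0.10, 0.03), 17.4: (0.07, 0.02)},
        noise_sd_mm=0.02,
        blink_rate_hz=0.05,
    )


def default_control_profile() -> GroupProfile:
    return GroupProfile(
        latency_ms=(283.0, 100.0),
        peak_velocity_dps=(540.0, 140.0),
        gain=(0.95, 0.07),
        pro_correct_prob=0.93,
        anti_error_prob=0.60,
        anti_correction_prob=0.45,
        correction_delay_ms=(310.0, 120.0),
        pupil_baseline_mm=(3.5, 0.3),
        constriction_amp_mm=(0.5, 0.1),
        band_osc_amp_mm={2.1: (0.30, 0.10), 11.8: (0.16, 0.04), 17.4: (0.12, 0.03)},
        noise_sd_mm=0.02,
        blink_rate_hz=0.05,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort sizes, group profiles, and acquisition parameters."""

    n_pd: int = 43
    n_control: int = 25
    pd_profile: GroupProfile = field(default_factory=default_pd_profile)
    control_profile: GroupProfile = field(default_factory=default_control_profile)
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    eccentricity_deg: float = DEFAULT_ECCENTRICITY_DEG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pd < 1 or self.n_control < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.eccentricity_deg <= 0:
            raise ValueError("eccentricity must be positive")

    def profile(self, group: Group) -> GroupProfile:
        return self.pd_profile if group is Group.PD else self.control_profile


def minimum_jerk_duration_s(amplitude_deg: float, peak_velocity_dps: float) -> float:
    """Closed-form minimum-jerk saccade duration, 1.875 |A| / v_peak."""
    return _MINJERK_FACTOR * abs(amplitude_deg) / peak_velocity_dps


def synth_saccade_waveform(
    amplitude_deg: float,
    peak_velocity_dps: float,
    onset_s: float = 0.0,
    sample_rate: float = DEFAULT_SAMPLE_RATE_HZ,
) -> np.ndarray:
    """Minimum-jerk gaze displacement sampled at ``sample_rate``.

    Returns the displacement relative to the pre-saccadic position, starting
    at the first sample at or after ``onset_s`` and ending on the final
    amplitude. The profile is x(tau) = A (10 tau^3 - 15 tau^4 + 6 tau^5).
    """
    if amplitude_deg == 0:
        raise ValueError("amplitude must be nonzero")
    if peak_velocity_dps <= 0:
        raise ValueError("peak velocity must be positive")
    T = minimum_jerk_duration_s(amplitude_deg, peak_velocity_dps)
    n = int(np.ceil(T * sample_rate))
    if n < 2:
        raise ValueError(
            f"saccade duration {T * 1e3:.2f} ms spans fewer than 2 samples at {sample_rate} Hz"
        )
    # sub-sample phase of the requested onset relative to the sample grid
    frac = (np.ceil(onset_s * sample_rate) - onset_s * sample_rate) / sample_rate
    tau = np.clip((np.arange(n + 1) / sample_rate + frac) / T, 0.0, 1.0)
    return amplitude_deg * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def synth_pupil_signal(
    profile: GroupProfile,
    schedule: StimulusSchedule,
    sample_rate: float,
    rng: np.random.Generator,
    n_samples: int | None = None,
) -> np.ndarray:
    """One pupil-diameter trace (mm) for one eye.

    baseline + per-trial stimulus-locked constriction dip (raised-cosine
    from stimulus onset, recovering by rest end) + stationary sinusoids at
    the profile's band frequencies with random phases + white noise.
    """
    if n_samples is None:
        n_samples = int(round(schedule.duration_s * sample_rate))
    t = np.arange(n_samples) / sample_rate

    baseline = _draw(rng, profile.pupil_baseline_mm)
    depth = _draw(rng, profile.constriction_amp_mm, lo=0.0)
    if baseline <= 0:
        raise ValueError("pupil baseline must be positive")

    trace = np.full(n_samples, baseline)
    for tr in schedule.trials:
        t0, t1 = tr.stimulus_onset_s, tr.rest_end_s
        i0, i1 = int(np.ceil(t0 * sample_rate)), min(int(np.ceil(t1 * sample_rate)), n_samples)
        if i0 >= i1:
            continue
        phase = (t[i0:i1] - t0) / (t1 - t0)
        trace[i0:i1] -= depth * np.sin(np.pi * phase) ** 2

    for f, amp_ms in sorted(profile.band_osc_amp_mm.items()):
        amp = _draw(rng, amp_ms, lo=0.0)
        phi = rng.uniform(0.0, 2 * np.pi)
        trace += amp * np.sin(2 * np.pi * f * t + phi)

    if profile.noise_sd_mm > 0:
        trace += rng.normal(0.0, profile.noise_sd_mm, n_samples)

    if np.any(trace <= 0):
        raise ValueError("pupil parameters drove diameter <= 0")
    return trace


def simulate_pupil_recording(
    profile: GroupProfile,
    schedule: StimulusSchedule,
    sample_rate: float,
    rng: np.random.Generator,
) -> GazeRecording:
    """A pupil-only recording (flat gaze) with subject-level draws.

    Cheap path for spectral-pipeline studies (e.g. null calibration) that
    do not need the gaze channel.
    """
    subject, _ = _subject_profile(profile, rng)
    n = int(round(schedule.duration_s * sample_rate))
    return GazeRecording(
        subject_id="",
        group=Group.PD,
        task=schedule.task,
        sample_rate_hz=sample_rate,
        t=np.arange(n) / sample_rate,
        gaze_x_deg=np.zeros(n),
        gaze_y_deg=np.zeros(n),
        pupil_left_mm=synth_pupil_signal(subject, schedule, sample_rate, rng, n),
        pupil_right_mm=synth_pupil_signal(subject, schedule, sample_rate, rng, n),
        valid_left=np.ones(n, bool),
        valid_right=np.ones(n, bool),
    )


@dataclass
class SubjectData:
    subject_id: str
    group: Group
    recordings: dict[TaskType, GazeRecording]
    schedules: dict[TaskType, StimulusSchedule]
    truth: dict


@dataclass
class CohortData:
    config: CohortConfig
    subjects: list[SubjectData]
    truth: pd.DataFrame

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_recordings(self) -> int:
        return sum(len(s.recordings) for s in self.subjects)


def _place_saccades(
    n: int,
    moves: list[tuple[float, float, float]],
    sample_rate: float,
) -> np.ndarray:
    """Fill a gaze trace from (onset_s, target_pos, peak_velocity) moves.

    Moves must be time-ordered; overlapping moves are shifted to start after
    the previous one ends.
    """
    gaze = np.zeros(n)
    cur = 0.0
    cursor = 0
    for onset_s, target, vp in moves:
        if target == cur:
            continue
        i0 = max(int(np.ceil(onset_s * sample_rate)), cursor)
        if i0 >= n:
            break
        # small refixations: cap velocity so the movement spans >= 2 samples
        vp_eff = min(vp, _MINJERK_FACTOR * abs(target - cur) * sample_rate / 2.001)
        # keep the true (sub-sample) onset phase unless the previous movement
        # pushed the start later
        phase_onset = onset_s if i0 == int(np.ceil(onset_s * sample_rate)) else i0 / sample_rate
        wave = cur + synth_saccade_waveform(target - cur, vp_eff, onset_s=phase_onset, sample_rate=sample_rate)
        m = min(len(wave), n - i0)
        gaze[cursor:i0] = cur
        gaze[i0 : i0 + m] = wave[:m]
        cursor = i0 + m
        cur = target
    gaze[cursor:] = cur
    return gaze


def _simulate_task(
    task: TaskType,
    profile: GroupProfile,
    config: CohortConfig,
    schedule: StimulusSchedule,
    rng: np.random.Generator,
) -> tuple[GazeRecording, dict]:
    fs = config.sample_rate_hz
    n = int(round(schedule.duration_s * fs))
    ecc = config.eccentricity_deg

    moves: list[tuple[float, float, float]] = []
    drawn_latencies: list[float] = []
    drawn_gains: list[float] = []
    drawn_vps: list[float] = []
    n_pro_correct = 0
    n_anti_error = 0
    n_anti_corrected = 0

    for tr in schedule.trials:
        # draw in ms then convert; clip to plausible, non-anticipatory range
        latency = float(np.clip(rng.normal(*profile.latency_ms) / 1e3, *_LATENCY_CLIP_S))
        gain = _draw(rng, profile.gain, *_GAIN_CLIP)
        vp = _draw(rng, profile.peak_velocity_dps, lo=_MIN_PEAK_VELOCITY_DPS)
        stim = tr.target_deg
        goal = stim if task is TaskType.PRO else -stim

        responded = True
        if task is TaskType.PRO:
            if rng.random() < profile.pro_correct_prob:
                first_target_pos = goal
                n_pro_correct += 1
            else:
                responded = False  # modelled failure mode: no response
        else:
            if rng.random() < profile.anti_error_prob:
                n_anti_error += 1
                first_target_pos = stim * gain  # reflexive error toward the stimulus
            else:
                first_target_pos = goal * gain

        last_end = tr.stimulus_onset_s
        pos = 0.0
        if responded:
            drawn_latencies.append(latency)
            drawn_gains.append(gain)
            drawn_vps.append(vp)
            onset = tr.stimulus_onset_s + latency
            if task is TaskType.ANTI and first_target_pos * goal < 0:
                # direction error, optionally followed by a corrective saccade
                moves.append((onset, first_target_pos, vp))
                last_end = onset + minimum_jerk_duration_s(first_target_pos, vp)
                pos = first_target_pos
                if rng.random() < profile.anti_correction_prob:
                    n_anti_corrected += 1
                    delay = max(rng.normal(*profile.correction_delay_ms) / 1e3, 0.06)
                    c_onset = last_end + delay
                    c_target = goal * _draw(rng, (0.95, 0.05), 0.82, 1.1)
                    moves.append((c_onset, c_target, vp))
                    last_end = c_onset + minimum_jerk_duration_s(c_target - pos, vp)
                    pos = c_target
            else:
                landing = goal * gain
                moves.append((onset, landing, vp))
                last_end = onset + minimum_jerk_duration_s(landing, vp)
                pos = landing
                if abs(landing - goal) > 2.0:
                    # hypometric/hypermetric primary saccade: refixation step
                    isi = max(rng.normal(*_CORRECTIVE_ISI_S), 0.06)
                    c_target = goal * _draw(rng, (0.97, 0.04), 0.85, 1.1)
                    moves.append((last_end + isi, c_target, vp))
                    last_end = last_end + isi + minimum_jerk_duration_s(c_target - pos, vp)
                    pos = c_target
        # re-centre before the next trial's fixation phase
        if pos != 0.0:
            rc_onset = max(tr.rest_end_s - _RECENTER_BEFORE_REST_END_S, last_end + 0.05)
            moves.append((rc_onset, 0.0, max(vp, 300.0)))

    gaze_x = _place_saccades(n, moves, fs)
    pupil_left = synth_pupil_signal(profile, schedule, fs, rng, n_samples=n)
    pupil_right = synth_pupil_signal(profile, schedule, fs, rng, n_samples=n)

    valid = np.ones(n, dtype=bool)
    duration = schedule.duration_s
    n_blinks = rng.poisson(profile.blink_rate_hz * duration)
    for _ in range(n_blinks):
        b0 = rng.uniform(0.0, duration)
        b1 = b0 + rng.uniform(*_BLINK_DUR_RANGE_S)
        i0, i1 = int(b0 * fs), min(int(b1 * fs), n)
        valid[i0:i1] = False
    pupil_left = np.where(valid, pupil_left, 0.0)
    pupil_right = np.where(valid, pupil_right, 0.0)

    rec = GazeRecording(
        subject_id="",
        group=Group.PD,
        task=task,
        sample_rate_hz=fs,
        t=np.arange(n) / fs,
        gaze_x_deg=gaze_x,
        gaze_y_deg=np.zeros(n),
        pupil_left_mm=pupil_left,
        pupil_right_mm=pupil_right,
        valid_left=valid.copy(),
        valid_right=valid.copy(),
    )
    truth = {
        "latency_mean_s": float(np.mean(drawn_latencies)) if drawn_latencies else np.nan,
        "gain_mean": float(np.mean(drawn_gains)) if drawn_gains else np.nan,
        "peak_velocity_mean_dps": float(np.mean(drawn_vps)) if drawn_vps else np.nan,
        "pro_correct_frac": n_pro_correct / len(schedule) if task is TaskType.PRO else np.nan,
        "anti_error_frac": n_anti_error / len(schedule) if task is TaskType.ANTI else np.nan,
        "anti_corrected_frac": (n_anti_corrected / n_anti_error) if (task is TaskType.ANTI and n_anti_error) else np.nan,
        "n_blinks": int(n_blinks),
    }
    return rec, truth


def _subject_profile(profile: GroupProfile, rng: np.random.Generator) -> tuple[GroupProfile, dict]:
    """Draw subject-level parameters and return the within-subject profile.

    The returned profile has subject-specific means with within-subject SDs
    (a fixed fraction of the group's between-subject SD), so group-level
    spread across simulated subjects matches the profile's scale.
    """
    lat = _draw(rng, profile.latency_ms, 120.0, 550.0)
    vp = _draw(rng, profile.peak_velocity_dps, lo=150.0)
    gain = _draw(rng, profile.gain, 0.55, 1.25)
    delay = _draw(rng, profile.correction_delay_ms, 60.0, 800.0)
    baseline = _draw(rng, profile.pupil_baseline_mm, 3.0, 6.0)
    constriction = _draw(rng, profile.constriction_amp_mm, 0.2, 0.8)
    def _jitter_prob(p: float, sd: float, hi: float = 0.98) -> float:
        # degenerate endpoints (forced behaviour) stay deterministic
        if p <= 0.0 or p >= 1.0:
            return p
        return float(np.clip(rng.normal(p, sd), 0.02, hi))

    p_pro = _jitter_prob(profile.pro_correct_prob, _SUBJECT_PROB_SD["pro_correct"], hi=1.0)
    p_err = _jitter_prob(profile.anti_error_prob, _SUBJECT_PROB_SD["anti_error"])
    p_corr = _jitter_prob(profile.anti_correction_prob, _SUBJECT_PROB_SD["anti_correction"])
    band = {
        f: (_draw(rng, ms, lo=0.0), _BAND_AMP_TRACE_SD_FRAC * ms[1])
        for f, ms in profile.band_osc_amp_mm.items()
    }
    subject = GroupProfile(
        latency_ms=(lat, _WITHIN_SD_FRAC * profile.latency_ms[1]),
        peak_velocity_dps=(vp, _WITHIN_SD_FRAC * profile.peak_velocity_dps[1]),
        gain=(gain, _WITHIN_SD_FRAC * profile.gain[1]),
        pro_correct_prob=p_pro,
        anti_error_prob=p_err,
        anti_correction_prob=p_corr,
        correction_delay_ms=(delay, _WITHIN_SD_FRAC * profile.correction_delay_ms[1]),
        pupil_baseline_mm=(baseline, _BASELINE_TRACE_SD_MM),
        constriction_amp_mm=(constriction, _CONSTRICTION_TRACE_SD_MM),
        band_osc_amp_mm=band,
        noise_sd_mm=profile.noise_sd_mm,
        blink_rate_hz=profile.blink_rate_hz,
    )
    truth = {
        "subj_latency_ms": lat,
        "subj_peak_velocity_dps": vp,
        "subj_gain": gain,
        "subj_pro_correct_prob": p_pro,
        "subj_anti_error_prob": p_err,
        "subj_anti_correction_prob": p_corr,
        **{f"subj_band_amp_{f:g}hz": band[f][0] for f in band},
    }
    return subject, truth


def simulate_subject(
    group: Group,
    config: CohortConfig,
    subject_seed: int | np.random.SeedSequence,
    subject_id: str = "S00",
) -> SubjectData:
    """Simulate both task recordings for one subject."""
    group_profile = config.profile(group)
    ss = subject_seed if isinstance(subject_seed, np.random.SeedSequence) else np.random.SeedSequence(subject_seed)
    sched_ss, task_ss = ss.spawn(2)
    sched_seeds = sched_ss.generate_state(2)
    rng = np.random.default_rng(task_ss)
    profile, subject_truth = _subject_profile(group_profile, rng)

    recordings: dict[TaskType, GazeRecording] = {}
    schedules: dict[TaskType, StimulusSchedule] = {}
    truth: dict = {"subject_id": subject_id, "group": group.value, **subject_truth}
    for i, task in enumerate(TaskType):
        schedule = build_schedule(task, config.eccentricity_deg, seed=int(sched_seeds[i]))
        rec, task_truth = _simulate_task(task, profile, config, schedule, rng)
        rec.subject_id = subject_id
        rec.group = group
        recordings[task] = rec
        schedules[task] = schedule
        prefix = "pro" if task is TaskType.PRO else "anti"
        truth.update({f"{prefix}_{k}": v for k, v in task_truth.items()})
    return SubjectData(subject_id=subject_id, group=group, recordings=recordings, schedules=schedules, truth=truth)


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Simulate the full two-group cohort; deterministic given ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    n_total = config.n_pd + config.n_control
    child_seeds = root.spawn(n_total)
    subjects: list[SubjectData] = []
    rows = []
    for i in range(n_total):
        group = Group.PD if i < config.n_pd else Group.CONTROL
        idx = i if group is Group.PD else i - config.n_pd
        sid = f"{'PD' if group is Group.PD else 'HC'}{idx + 1:02d}"
        subj = simulate_subject(group, config, child_seeds[i], subject_id=sid)
        subjects.append(subj)
        rows.append(subj.truth)
    return CohortData(config=config, subjects=subjects, truth=pd.DataFrame(rows))
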