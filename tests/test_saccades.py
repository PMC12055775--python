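import numpy as np
import pytest

from oculopd.protocol import Group, Side, TaskType, GazeRecording, build_schedule
from oculopd.saccades import (
    SaccadeEvent,
    TrialScore,
    detect_saccades,
    gaze_velocity,
    score_trial,
    summarize_subject,
)
from oculopd.synthdata import synth_saccade_waveform


def trace_recording(gaze_x, fs=120.0):
    n = len(gaze_x)
    return GazeRecording(
        "S", Group.PD, TaskType.PRO, fs, np.arange(n) / fs,
        np.asarray(gaze_x, float), np.zeros(n), np.full(n, 3.5), np.full(n, 3.5),
        np.ones(n, bool), np.ones(n, bool),
    )


def embed_saccade(n, onset_idx, amplitude, vp, fs=120.0, start_pos=0.0):
    gaze = np.full(n, float(start_pos))
    wave = start_pos + synth_saccade_waveform(amplitude, vp, onset_s=onset_idx / fs, sample_rate=fs)
    m = min(len(wave), n - onset_idx)
    gaze[onset_idx : onset_idx + m] = wave[:m]
    gaze[onset_idx + m :] = start_pos + amplitude
    return gaze


def brute_force_detect(gaze_x, fs, onset=30.0, offset=20.0, min_dur_ms=10.0, min_amp=1.0):
    """Independent sample-by-sample hysteresis scan (onsets, offsets)."""
    v = gaze_velocity(np.asarray(gaze_x, float), fs)
    speed = np.abs(v)
    t = np.arange(len(speed)) / fs
    found = []
    i = 0
    n = len(speed)
    while i < n:
        if speed[i] >= onset:
            j = i
            while j + 1 < n and speed[j + 1] >= offset:
                j += 1
            stop = min(j + 1, n - 1)
            amp = gaze_x[stop] - gaze_x[i]
            if (t[stop] - t[i]) * 1e3 >= min_dur_ms and abs(amp) >= min_amp:
                found.append((i, stop))
            i = j + 2
        else:
            i += 1
    return found


class TestDetectSaccades:
    def test_constant_gaze_empty(self):
        assert detect_saccades(trace_recording(np.zeros(1000))) == []

    def test_single_minjerk_saccade(self):
        gaze = embed_saccade(600, 240, 10.0, 400.0)
        events = detect_saccades(trace_recording(gaze))
        assert len(events) == 1
        ev = events[0]
        assert ev.amplitude_deg == pytest.approx(10.0, abs=0.2)
        assert ev.peak_velocity_dps == pytest.approx(400.0, rel=0.05)
        assert ev.direction is Side.RIGHT

    def test_one_sample_spike_rejected(self):
        gaze = np.zeros(600)
        gaze[300] = 0.5
        assert detect_saccades(trace_recording(gaze)) == []

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            detect_saccades(trace_recording(np.zeros(100), fs=50.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_scan_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        n = 6000
        gaze = np.zeros(n)
        pos = 0.0
        idx = 120
        while idx < n - 200:
            amp = rng.uniform(3.5, 12.0) * rng.choice([-1, 1])
            if abs(pos + amp) > 15:
                amp = -np.sign(pos) * abs(amp)
            # keep the implied duration >= 2.5 samples at 120 Hz
            vp = rng.uniform(250.0, min(550.0, 85.0 * abs(amp)))
            wave = pos + synth_saccade_waveform(amp, vp, onset_s=idx / 120.0, sample_rate=120.0)
            m = min(len(wave), n - idx)
            gaze[idx : idx + m] = wave[:m]
            pos += amp
            gaze[idx + m :] = pos
            idx += m + rng.integers(60, 150)
        events = detect_saccades(trace_recording(gaze))
        oracle = brute_force_detect(gaze, 120.0)
        assert len(events) == len(oracle)
        for ev, (i, stop) in zip(events, oracle):
            assert abs(ev.onset_s - i / 120.0) <= 1.0 / 120.0 + 1e-9


class TestScoreTrial:
    def test_pro_correct_construction(self):
        tr = [t for t in build_schedule(TaskType.PRO, 10.0, seed=0).trials if t.side is Side.RIGHT][0]
        fs = 120.0
        n = int((tr.rest_end_s + 1) * fs)
        onset_idx = int((tr.stimulus_onset_s + 0.27) * fs)
        gaze = embed_saccade(n, onset_idx, 9.8, 420.0, fs)
        events = detect_saccades(trace_recording(gaze))
        sc = score_trial(tr, events, TaskType.PRO, gaze, np.arange(n) / fs, fs)
        assert sc.correct
        assert sc.first_saccade_latency_ms == pytest.approx(270.0, abs=12.0)
        assert sc.time_to_complete_ms is not None
        assert sc.time_to_complete_ms >= sc.first_saccade_latency_ms

    def test_anti_error_corrected(self):
        tr = [t for t in build_schedule(TaskType.ANTI, 10.0, seed=0).trials if t.side is Side.RIGHT][0]
        fs = 120.0
        n = int((tr.rest_end_s + 1) * fs)
        t = np.arange(n) / fs
        err_onset = int((tr.stimulus_onset_s + 0.25) * fs)
        gaze = embed_saccade(n, err_onset, 9.0, 420.0, fs)
        # corrective saccade to the mirror location 230 ms after error offset
        events_tmp = detect_saccades(trace_recording(gaze))
        err_off = events_tmp[0].offset_s
        corr_onset = int((err_off + 0.23) * fs)
        wave = 9.0 + synth_saccade_waveform(-19.0, 450.0, onset_s=corr_onset / fs, sample_rate=fs)
        m = min(len(wave), n - corr_onset)
        gaze[corr_onset : corr_onset + m] = wave[:m]
        gaze[corr_onset + m :] = -10.0
        events = detect_saccades(trace_recording(gaze))
        sc = score_trial(tr, events, TaskType.ANTI, gaze, t, fs)
        assert sc.direction_error
        assert sc.corrected
        assert sc.correction_time_ms == pytest.approx(230.0, abs=15.0)

    def test_anti_error_uncorrected(self):
        tr = [t for t in build_schedule(TaskType.ANTI, 10.0, seed=0).trials if t.side is Side.RIGHT][0]
        fs = 120.0
        n = int((tr.rest_end_s + 1) * fs)
        onset_idx = int((tr.stimulus_onset_s + 0.25) * fs)
        gaze = embed_saccade(n, onset_idx, 9.0, 420.0, fs)
        events = detect_saccades(trace_recording(gaze))
        sc = score_trial(tr, events, TaskType.ANTI, gaze, np.arange(n) / fs, fs)
        assert sc.direction_error
        assert sc.corrected is False
        assert sc.correction_time_ms is None

    def test_no_response_counted_incorrect(self):
        tr = build_schedule(TaskType.PRO, 10.0, seed=0).trials[0]
        n = int((tr.rest_end_s + 1) * 120)
        gaze = np.zeros(n)
        sc = score_trial(tr, [], TaskType.PRO, gaze, np.arange(n) / 120.0, 120.0)
        assert sc.valid and not sc.responded and not sc.correct

    def test_anticipatory_invalid(self):
        tr = [t for t in build_schedule(TaskType.PRO, 10.0, seed=0).trials if t.side is Side.RIGHT][0]
        fs = 120.0
        n = int((tr.rest_end_s + 1) * fs)
        onset_idx = int((tr.stimulus_onset_s + 0.03) * fs)
        gaze = embed_saccade(n, onset_idx, 9.8, 420.0, fs)
        events = detect_saccades(trace_recording(gaze))
        sc = score_trial(tr, events, TaskType.PRO, gaze, np.arange(n) / fs, fs)
        assert not sc.valid


def _score(correct=0, total=40, task=TaskType.PRO):
    out = []
    for i in range(total):
        s = TrialScore(trial_index=i, task=task, responded=True)
        s.correct = i < correct
        s.first_saccade_latency_ms = 250.0
        s.mean_velocity_dps = 200.0
        s.peak_velocity_dps = 400.0
        if s.correct:
            s.time_to_complete_ms = 400.0
        out.append(s)
    return out


class TestSummarize:
    def test_accuracy_arithmetic(self):
        summ = summarize_subject("S", _score(34), _score(10, task=TaskType.ANTI))
        assert summ.pro_accuracy_pct == pytest.approx(85.0)

    def test_correction_rate_arithmetic(self):
        anti = _score(0, 40, TaskType.ANTI)
        for s in anti[:10]:
            s.direction_error = True
            s.corrected = False
        for s in anti[:3]:
            s.corrected = True
            s.correction_time_ms = 200.0
        summ = summarize_subject("S", _score(30), anti)
        assert summ.anti_error_correction_rate_pct == pytest.approx(30.0)

    def test_no_errors_rate_is_none(self):
        summ = summarize_subject("S", _score(30), _score(5, task=TaskType.ANTI))
        assert summ.anti_error_correction_rate_pct is None

    def test_zero_valid_trials_error(self):
        bad = [TrialScore(trial_index=i, task=TaskType.PRO, valid=False) for i in range(5)]
        with pytest.raises(ValueError):
            summarize_subject("S", bad, _score(5, task=TaskType.ANTI))

    def test_invariants_on_simulated_subject(self, pd_subject_scored):
        pro = pd_subject_scored[TaskType.PRO][2]
        anti = pd_subject_scored[TaskType.ANTI][2]
        summ = summarize_subject("PD01", pro, anti)
        assert 0 <= summ.pro_accuracy_pct <= 100
        assert 0 <= summ.anti_accuracy_pct <= 100
        assert summ.pro_time_to_complete_min_ms <= summ.pro_time_to_complete_avg_ms
        assert summ.pro_velocity_max_dps >= summ.pro_velocity_avg_dps
        assert summ.anti_velocity_max_dps >= summ.anti_velocity_avg_dps

    def test_generator_accuracy_within_binomial_ci(self, pd_subject_scored, pd_subject):
        pro = [s for s in pd_subject_scored[TaskType.PRO][2] if s.valid]
        p = pd_subject.truth["subj_pro_correct_prob"]
        k = sum(s.correct for s in pro)
        n = len(pro)
        half = 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(k / n - p) <= half + 0.02

    def test_pupil_noise_does_not_change_scores(self, pd_subject):
        from oculopd.preprocess import detect_artifacts, repair_or_exclude
        from oculopd.saccades import score_schedule

        rec = pd_subject.recordings[TaskType.PRO]
        sched = pd_subject.schedules[TaskType.PRO]
        noisy = GazeRecording(
            rec.subject_id, rec.group, rec.task, rec.sample_rate_hz, rec.t,
            rec.gaze_x_deg, rec.gaze_y_deg,
            np.clip(rec.pupil_left_mm + np.random.default_rng(1).normal(0, 0.05, rec.n_samples), 0, None),
            rec.pupil_right_mm, rec.valid_left, rec.valid_right,
        )
        base = score_schedule(repair_or_exclude(rec, detect_artifacts(rec), sched), sched)
        pert = score_schedule(repair_or_exclude(noisy, detect_artifacts(noisy), sched), sched)
        assert [s.correct for s in base] == [s.correct for s in pert]


class TestSaccadeEvent:
    def test_invariant_enforcement(self):
        with pytest.raises(ValueError):
            SaccadeEvent(1.0, 0.9, 5.0, 400.0, 200.0, Side.RIGHT)
        with pytest.raises(ValueError):
            SaccadeEvent(1.0, 1.1, -5.0, 400.0, 200.0, Side.RIGHT)
        with pytest.raises(ValueError):
            SaccadeEvent(1.0, 1.1, 5.0, 100.0, 200.0, Side.RIGHT)
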