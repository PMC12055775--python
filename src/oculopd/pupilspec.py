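"""Amplitude spectra of pupil-diameter traces on a fixed 0.1 Hz grid.

Each trace segment is linearly detrended and transformed with a plain DFT;
the single-sided amplitude is ``2/N |X_k|`` where ``N`` is the segment
sample count, evaluated on a 0.1 Hz grid from 0 to a 19 Hz cutoff
(191 bins). Ten-second windows at any integer sample rate resolve the grid
natively; shorter segments are zero-padded to the grid length (this padding
dialect is fixed, not configurable). Windows are rectangular by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import detrend as _detrend

from oculopd.preprocess import CleanRecording
from oculopd.protocol import Eye, StimulusSchedule, TaskType

__all__ = [
    "Band",
    "PupilSpectrum",
    "FrequencyFeature",
    "compute_spectrum",
    "assign_band",
    "subject_features",
    "GRID_DF_HZ",
    "CUTOFF_HZ",
    "N_BINS",
    "WINDOW_S",
    "grid_freqs",
]

GRID_DF_HZ = 0.1
CUTOFF_HZ = 19.0
#: 0.0, 0.1, ..., 19.0 Hz inclusive.
N_BINS = 191
WINDOW_S = 10.0
MIN_SEGMENT_S = 2.0

Band = Literal["low", "medium", "high"]

# Integer band labels (low 0-6, medium 7-12, high 13-19 Hz) leave the open
# intervals (6, 7) and (12, 13) unassigned; bins there are attached to the
# nearer band so every 0.1 Hz bin has exactly one label.
_LOW_EDGE_HZ = 6.95
_MED_EDGE_HZ = 12.95


def grid_freqs() -> np.ndarray:
    return np.round(np.arange(N_BINS) * GRID_DF_HZ, 10)


@dataclass
class PupilSpectrum:
    subject_id: str
    task: TaskType
    eye: Eye
    freqs: np.ndarray
    amplitudes: np.ndarray
    n_windows: int = 1

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.amplitudes):
            raise ValueError("freqs and amplitudes must align")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class FrequencyFeature:
    task: TaskType
    eye: Eye
    frequency_hz: float
    amplitude: float
    band: Band


def assign_band(frequency_hz: float) -> Band:
    """Band label for a grid frequency: low/medium/high."""
    if frequency_hz < 0:
        raise ValueError("frequency must be >= 0")
    if frequency_hz > CUTOFF_HZ:
        raise ValueError(f"frequency {frequency_hz} Hz beyond the {CUTOFF_HZ} Hz cutoff")
    if frequency_hz < _LOW_EDGE_HZ:
        return "low"
    if frequency_hz < _MED_EDGE_HZ:
        return "medium"
    return "high"


def compute_spectrum(
    segment: np.ndarray,
    sample_rate: float,
    detrend: bool = True,
    taper: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided amplitude spectrum of one segment on the 0.1 Hz grid.

    Returns ``(freqs, amplitudes)`` with 191 bins from 0 to 19 Hz. The
    segment must be at least 2 s long and the sample rate at least twice
    the cutoff.
    """
    segment = np.asarray(segment, float)
    n = len(segment)
    if n < MIN_SEGMENT_S * sample_rate:
        raise ValueError(f"segment shorter than {MIN_SEGMENT_S} s")
    if sample_rate < 2 * CUTOFF_HZ:
        raise ValueError("sample rate below twice the spectral cutoff")
    if detrend:
        segment = _detrend(segment, type="linear")
    if taper is not None:
        if len(taper) != n:
            raise ValueError("taper length must match segment length")
        segment = segment * taper
    n_grid = int(round(sample_rate / GRID_DF_HZ))  # 10 s worth of samples
    n_fft = max(n, n_grid)
    if n_fft % n_grid:
        n_fft = int(np.ceil(n_fft / n_grid)) * n_grid  # keep bins on the 0.1 Hz grid
    spec = np.abs(np.fft.rfft(segment, n=n_fft)) * 2.0 / n
    # FFT resolution is sample_rate / n_fft; 0.1 Hz lies every n_fft/n_grid bins
    stride = n_fft // n_grid
    amps = spec[: stride * N_BINS : stride][:N_BINS]
    return grid_freqs(), amps


def _window_starts(n: int, win: int) -> list[int]:
    return [i * win for i in range(n // win)]


def subject_features(
    clean: CleanRecording,
    schedule: StimulusSchedule,
    taper: np.ndarray | None = None,
) -> list[FrequencyFeature]:
    """Per-eye averaged spectral features over consecutive 10 s windows.

    Samples belonging to excluded trials are dropped, the remainder is
    concatenated, and spectra over consecutive complete 10 s windows are
    averaged bin-wise per eye.
    """
    fs = clean.sample_rate_hz
    n = len(clean.t)
    keep = np.ones(n, bool)
    for tr in schedule.trials:
        if clean.is_excluded(tr.index):
            i0 = int(tr.fixation_onset_s * fs)
            i1 = min(int(np.ceil(tr.rest_end_s * fs)), n)
            keep[i0:i1] = False

    win = int(round(WINDOW_S * fs))
    features: list[FrequencyFeature] = []
    freqs = grid_freqs()
    for eye in Eye:
        trace = clean.pupil(eye)[keep]
        starts = _window_starts(len(trace), win)
        if not starts:
            raise ValueError("fewer than one complete spectral window after exclusions")
        acc = np.zeros(N_BINS)
        for s in starts:
            _, amps = compute_spectrum(trace[s : s + win], fs, taper=taper)
            acc += amps
        acc /= len(starts)
        for f, a in zip(freqs, acc):
            features.append(
                FrequencyFeature(
                    task=schedule.task,
                    eye=eye,
                    frequency_hz=float(f),
                    amplitude=float(a),
                    band=assign_band(float(f)),
                )
            )
    return features


def spectrum_from_features(features: list[FrequencyFeature], subject_id: str, task: TaskType, eye: Eye) -> PupilSpectrum:
    sel = [f for f in features if f.task == task and f.eye == eye]
    sel.sort(key=lambda f: f.frequency_hz)
    return PupilSpectrum(
        subject_id=subject_id,
        task=task,
        eye=eye,
        freqs=np.array([f.frequency_hz for f in sel]),
        amplitudes=np.array([f.amplitude for f in sel]),
    )
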