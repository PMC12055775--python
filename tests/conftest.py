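"""Shared fixtures; expensive simulations are session-scoped and reused."""

from __future__ import annotations

import numpy as np
import pytest

from oculopd.preprocess import detect_artifacts, repair_or_exclude
from oculopd.protocol import Group, TaskType
from oculopd.saccades import score_schedule
from oculopd.synthdata import (
    CohortConfig,
    GroupProfile,
    simulate_cohort,
    simulate_subject,
)


def quiet_profile(**overrides) -> GroupProfile:
    """A deterministic, artifact-free profile for construction-style tests."""
    params = dict(
        latency_ms=(270.0, 0.0),
        peak_velocity_dps=(420.0, 0.0),
        gain=(0.95, 0.0),
        pro_correct_prob=1.0,
        anti_error_prob=0.0,
        anti_correction_prob=0.0,
        correction_delay_ms=(250.0, 0.0),
        pupil_baseline_mm=(3.5, 0.0),
        constriction_amp_mm=(0.5, 0.0),
        band_osc_amp_mm={},
        noise_sd_mm=0.0,
        blink_rate_hz=0.0,
    )
    params.update(overrides)
    return GroupProfile(**params)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_pd=4, n_control=3, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def pd_subject():
    cfg = CohortConfig(n_pd=1, n_control=1, seed=3)
    return simulate_subject(Group.PD, cfg, 42, "PD01")


@pytest.fixture(scope="session")
def pd_subject_scored(pd_subject):
    """Cleaned recordings and trial scores for both tasks of one PD subject."""
    out = {}
    for task in TaskType:
        rec = pd_subject.recordings[task]
        schedule = pd_subject.schedules[task]
        clean = repair_or_exclude(rec, detect_artifacts(rec), schedule)
        out[task] = (clean, schedule, score_schedule(clean, schedule))
    return out


@pytest.fixture(scope="session")
def recovery_cohort():
    """A larger single-profile cohort for parameter-recovery tests.

    100 PD subjects (plus the minimum one control); scored lazily by the
    tests that need it.
    """
    cfg = CohortConfig(n_pd=100, n_control=1, seed=17)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
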