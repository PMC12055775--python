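"""Two-group comparison with a normality gate, and band-wise counting.

Each feature is tested with a pooled-variance two-sample t-test when the
Shapiro-Wilk test accepts normality (p >= 0.05) in *both* groups, and with
the two-sided Mann-Whitney U-test otherwise. Significance is uncorrected
p < alpha (default 0.05) per feature; no multiple-testing correction is
applied across the 191 frequency bins, by design — treat the band counts as
descriptive, not confirmatory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from oculopd.protocol import Eye, TaskType
from oculopd.pupilspec import Band, assign_band

__all__ = [
    "ALPHA",
    "TestUsed",
    "GroupComparisonResult",
    "BandSignificanceCounts",
    "choose_test",
    "t_from_summary",
    "compare_feature",
    "count_significant",
    "aggregate_band_counts",
    "proportion_percent",
    "saccade_comparison_table",
    "frequency_bin_results",
    "amplitude_table",
]

ALPHA = 0.05
BANDS: tuple[Band, ...] = ("low", "medium", "high")

TestUsed = Literal["pooled_t", "mann_whitney", "chi_squared"]


@dataclass(frozen=True)
class GroupComparisonResult:
    feature_id: object
    test_used: TestUsed
    statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def _degenerate(x: np.ndarray) -> bool:
    return len(x) < 3 or np.ptp(x) == 0.0


def choose_test(sample_a: Sequence[float], sample_b: Sequence[float], alpha: float = ALPHA) -> TestUsed:
    """Pick pooled t vs Mann-Whitney via a per-group Shapiro-Wilk gate.

    Degenerate (constant) samples fall through to the nonparametric branch.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs n >= 3")
    if _degenerate(a) or _degenerate(b):
        return "mann_whitney"
    if sps.shapiro(a).pvalue >= alpha and sps.shapiro(b).pvalue >= alpha:
        return "pooled_t"
    return "mann_whitney"


def t_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    """Pooled-variance two-sample t from summary statistics (df = n_a+n_b-2)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("SDs must be >= 0")
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    diff = mean_a - mean_b
    if pooled_var == 0.0:
        return 0.0 if diff == 0.0 else float(np.sign(diff) * np.inf)
    se = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    return float(diff / se)


def compare_feature(
    values_pd: Sequence[float],
    values_control: Sequence[float],
    alpha: float = ALPHA,
    feature_id: object = None,
) -> GroupComparisonResult:
    """Run the gated two-group test on one feature."""
    a = np.asarray(values_pd, float)
    b = np.asarray(values_control, float)
    test = choose_test(a, b, alpha)
    if test == "pooled_t":
        res = sps.ttest_ind(a, b, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if np.ptp(np.concatenate([a, b])) == 0.0:
            stat, p = 0.0, 1.0  # identical constants: no evidence of a shift
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparisonResult(
        feature_id=feature_id,
        test_used=test,
        statistic=stat,
        p_value=p,
        mean_a=float(np.mean(a)),
        sd_a=float(np.std(a, ddof=1)),
        n_a=len(a),
        mean_b=float(np.mean(b)),
        sd_b=float(np.std(b, ddof=1)),
        n_b=len(b),
        alpha=alpha,
    )


def aggregate_band_counts(
    left: Mapping[Band, int], right: Mapping[Band, int]
) -> dict[Band, int]:
    """Both-eye totals: per-band sum of the left- and right-eye counts."""
    return {band: int(left.get(band, 0)) + int(right.get(band, 0)) for band in BANDS}


@dataclass
class BandSignificanceCounts:
    """Significant-bin tallies per band for one task, per eye and combined."""

    task: TaskType
    per_eye: dict[Eye, dict[Band, int]]

    @property
    def totals(self) -> dict[Band, int]:
        return aggregate_band_counts(self.per_eye[Eye.LEFT], self.per_eye[Eye.RIGHT])


def count_significant(
    results: Iterable[GroupComparisonResult],
) -> dict[TaskType, BandSignificanceCounts]:
    """Tally significant frequency bins per (task, eye, band).

    Each result's ``feature_id`` must be a ``(task, eye, frequency_hz)``
    triple; duplicate triples raise.
    """
    seen: set[tuple] = set()
    counts: dict[TaskType, BandSignificanceCounts] = {}
    for res in results:
        task, eye, freq = res.feature_id
        task, eye = TaskType(task), Eye(eye)
        key = (task, eye, round(float(freq), 6))
        if key in seen:
            raise ValueError(f"duplicate (task, eye, frequency) key: {key}")
        seen.add(key)
        if task not in counts:
            counts[task] = BandSignificanceCounts(
                task=task, per_eye={e: {b: 0 for b in BANDS} for e in Eye}
            )
        if res.significant:
            counts[task].per_eye[eye][assign_band(float(freq))] += 1
    return counts


def proportion_percent(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of ``count`` out of ``total``, rounded."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------


def saccade_comparison_table(summaries: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Group comparison of the 14 oculomotor parameters.

    ``summaries`` needs a ``group`` column ('PD'/'control') plus one column
    per parameter; rows with missing values are dropped per parameter.
    """
    from oculopd.saccades import SubjectSaccadeSummary

    rows = []
    for param in SubjectSaccadeSummary.PARAMETERS:
        if param not in summaries.columns:
            continue
        sub = summaries[["group", param]].dropna()
        a = sub.loc[sub["group"] == "PD", param].to_numpy(float)
        b = sub.loc[sub["group"] == "control", param].to_numpy(float)
        if len(a) < 3 or len(b) < 3:  # e.g. a single-task run
            continue
        res = compare_feature(a, b, alpha=alpha, feature_id=param)
        rows.append(
            {
                "parameter": param,
                "pd_mean": res.mean_a,
                "pd_sd": res.sd_a,
                "pd_n": res.n_a,
                "control_mean": res.mean_b,
                "control_sd": res.sd_b,
                "control_n": res.n_b,
                "test": res.test_used,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)


def frequency_bin_results(features: pd.DataFrame, alpha: float = ALPHA) -> list[GroupComparisonResult]:
    """Per-(task, eye, frequency) group comparison of amplitude features.

    ``features`` is long-form with columns subject_id, group, task, eye,
    frequency_hz, amplitude.
    """
    results = []
    for (task, eye, freq), sub in features.groupby(["task", "eye", "frequency_hz"], sort=True):
        a = sub.loc[sub["group"] == "PD", "amplitude"].to_numpy(float)
        b = sub.loc[sub["group"] == "control", "amplitude"].to_numpy(float)
        results.append(compare_feature(a, b, alpha=alpha, feature_id=(task, eye, float(freq))))
    return results


def amplitude_table(
    features: pd.DataFrame,
    results: Iterable[GroupComparisonResult] | None = None,
    at_freqs: Sequence[float] | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Mean amplitude per (task, eye, frequency) and group, with significance."""
    if results is None:
        results = frequency_bin_results(features, alpha=alpha)
    sig = {tuple(r.feature_id): r for r in results}
    rows = []
    for (task, eye, freq), sub in features.groupby(["task", "eye", "frequency_hz"], sort=True):
        if at_freqs is not None and not any(abs(freq - f) < 1e-9 for f in at_freqs):
            continue
        res = sig.get((task, eye, float(freq)))
        rows.append(
            {
                "task": task,
                "eye": eye,
                "frequency_hz": float(freq),
                "band": assign_band(float(freq)),
                "pd_mean": float(sub.loc[sub["group"] == "PD", "amplitude"].mean()),
                "control_mean": float(sub.loc[sub["group"] == "control", "amplitude"].mean()),
                "p_value": res.p_value if res else np.nan,
                "significant": res.significant if res else False,
            }
        )
    return pd.DataFrame(rows)
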