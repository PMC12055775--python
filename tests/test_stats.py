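import itertools

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from oculopd.protocol import Eye, TaskType
from oculopd.stats import (
    BandSignificanceCounts,
    GroupComparisonResult,
    aggregate_band_counts,
    choose_test,
    compare_feature,
    count_significant,
    proportion_percent,
    t_from_summary,
)


class TestChooseTest:
    def test_gaussian_samples_pooled_t(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.3, 1, 40)
        # oracle: Shapiro-Wilk accepts both
        assert sps.shapiro(a).pvalue >= 0.05 and sps.shapiro(b).pvalue >= 0.05
        assert choose_test(a, b) == "pooled_t"

    def test_skewed_sample_mann_whitney(self, rng):
        a = rng.exponential(1.0, 40)
        b = rng.normal(0, 1, 40)
        assert sps.shapiro(a).pvalue < 0.05  # oracle: SW rejects
        assert choose_test(a, b) == "mann_whitney"

    def test_constant_sample_falls_back(self):
        assert choose_test(np.ones(10), np.random.default_rng(0).normal(0, 1, 10)) == "mann_whitney"

    def test_small_sample_error(self):
        with pytest.raises(ValueError):
            choose_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestTFromSummary:
    def test_published_group_velocity_statistics(self):
        # group summary rows (mean, SD, n) for average saccade velocity
        assert round(t_from_summary(206.5, 107.1, 43, 279.5, 105.6, 25), 2) == -2.72
        assert round(t_from_summary(154.8, 81.3, 43, 184.5, 101.1, 25), 2) == -1.33

    def test_equal_means_zero(self):
        assert t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12) == 0.0

    def test_zero_variance_unequal_means_infinite(self):
        assert t_from_summary(5.0, 0.0, 10, 4.0, 0.0, 12) == np.inf
        assert t_from_summary(4.0, 0.0, 10, 5.0, 0.0, 12) == -np.inf

    @settings(max_examples=50, deadline=None)
    @given(
        ma=st.floats(-100, 100), mb=st.floats(-100, 100),
        sa=st.floats(0.1, 50), sb=st.floats(0.1, 50),
        na=st.integers(2, 200), nb=st.integers(2, 200),
    )
    def test_reference_implementation(self, ma, mb, sa, sb, na, nb):
        ours = t_from_summary(ma, sa, na, mb, sb, nb)
        ref = sps.ttest_ind_from_stats(ma, sa, na, mb, sb, nb, equal_var=True).statistic
        assert ours == pytest.approx(float(ref), abs=1e-10, rel=1e-10)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            t_from_summary(1.0, 1.0, 1, 2.0, 1.0, 10)
        with pytest.raises(ValueError):
            t_from_summary(1.0, -1.0, 10, 2.0, 1.0, 10)


class TestCompareFeature:
    def test_identical_samples_not_significant(self, rng):
        x = rng.normal(0, 1, 30)
        res = compare_feature(x, x.copy())
        assert not res.significant
        if res.test_used == "pooled_t":
            assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_forced_separation_significant(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        assert compare_feature(a, b).significant

    def test_constant_identical_samples(self):
        res = compare_feature(np.ones(10), np.ones(12))
        assert res.test_used == "mann_whitney"
        assert not res.significant

    @pytest.mark.parametrize("seed", range(3))
    def test_mann_whitney_exhaustive_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 6)
        b = rng.normal(1.0, 1, 5)
        # a high gate alpha forces the nonparametric branch on any draw
        res = compare_feature(a, b, alpha=0.9)
        assert res.test_used == "mann_whitney"
        # brute-force: U statistic under every group relabelling
        combined = np.concatenate([a, b])
        n_a = len(a)

        def u_stat(idx_a):
            aa = combined[list(idx_a)]
            bb = np.delete(combined, list(idx_a))
            return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)

        observed = u_stat(range(n_a))
        null = [u_stat(c) for c in itertools.combinations(range(len(combined)), n_a)]
        mu = n_a * (len(combined) - n_a) / 2.0
        p_exact = np.mean([abs(u - mu) >= abs(observed - mu) - 1e-12 for u in null])
        assert res.p_value == pytest.approx(p_exact, abs=1e-9)


def _bin_result(task, eye, freq, significant):
    return GroupComparisonResult(
        feature_id=(task, eye, freq),
        test_used="mann_whitney",
        statistic=1.0,
        p_value=0.01 if significant else 0.5,
        mean_a=0.0, sd_a=1.0, n_a=43, mean_b=0.0, sd_b=1.0, n_b=25,
    )


def results_with_counts(per_eye_counts):
    """Build synthetic bin results matching given per-(task, eye, band) counts."""
    band_freqs = {"low": np.arange(0.0, 6.9, 0.1), "medium": np.arange(7.0, 12.9, 0.1), "high": np.arange(13.0, 19.01, 0.1)}
    results = []
    for (task, eye), counts in per_eye_counts.items():
        for band, k in counts.items():
            freqs = band_freqs[band]
            for i, f in enumerate(freqs):
                results.append(_bin_result(task, eye, round(float(f), 1), i < k))
    return results


class TestCountSignificant:
    def test_published_per_eye_counts_aggregate(self):
        per_eye = {
            (TaskType.PRO, Eye.LEFT): {"low": 11, "medium": 4, "high": 10},
            (TaskType.PRO, Eye.RIGHT): {"low": 12, "medium": 5, "high": 6},
            (TaskType.ANTI, Eye.LEFT): {"low": 4, "medium": 11, "high": 18},
            (TaskType.ANTI, Eye.RIGHT): {"low": 6, "medium": 18, "high": 25},
        }
        counts = count_significant(results_with_counts(per_eye))
        assert counts[TaskType.PRO].totals == {"low": 23, "medium": 9, "high": 16}
        assert counts[TaskType.ANTI].totals == {"low": 10, "medium": 29, "high": 43}

    def test_no_significance_zero_counts(self):
        per_eye = {(TaskType.PRO, e): {"low": 0, "medium": 0, "high": 0} for e in Eye}
        counts = count_significant(results_with_counts(per_eye))
        assert counts[TaskType.PRO].totals == {"low": 0, "medium": 0, "high": 0}

    def test_saturation(self):
        results = [
            _bin_result(TaskType.PRO, eye, round(0.1 * i, 1), True)
            for eye in Eye
            for i in range(191)
        ]
        counts = count_significant(results)
        # band bin counts on the 0.1 Hz grid: low 70, medium 60, high 61
        assert counts[TaskType.PRO].per_eye[Eye.LEFT] == {"low": 70, "medium": 60, "high": 61}
        assert sum(counts[TaskType.PRO].totals.values()) == 2 * 191

    def test_duplicate_key_rejected(self):
        results = [_bin_result(TaskType.PRO, Eye.LEFT, 2.1, True)] * 2
        with pytest.raises(ValueError):
            count_significant(results)

    def test_permutation_invariance(self, rng):
        per_eye = {
            (TaskType.PRO, Eye.LEFT): {"low": 3, "medium": 2, "high": 7},
            (TaskType.PRO, Eye.RIGHT): {"low": 1, "medium": 0, "high": 4},
        }
        results = results_with_counts(per_eye)
        shuffled = list(results)
        rng.shuffle(shuffled)
        assert count_significant(results)[TaskType.PRO].totals == count_significant(shuffled)[TaskType.PRO].totals

    def test_aggregate_band_counts(self):
        assert aggregate_band_counts({"low": 11, "medium": 4, "high": 10}, {"low": 12, "medium": 5, "high": 6}) == {
            "low": 23,
            "medium": 9,
            "high": 16,
        }


class TestProportionPercent:
    def test_subtype_share(self):
        assert proportion_percent(22, 43) == 51.2

    def test_symptom_share(self):
        assert proportion_percent(16, 43) == 37.2

    def test_bad_total(self):
        with pytest.raises(ValueError):
            proportion_percent(1, 0)


class TestSummaryTables:
    def test_saccade_table_complete(self, rng):
        import pandas as pd

        from oculopd.saccades import SubjectSaccadeSummary
        from oculopd.stats import saccade_comparison_table

        rows = []
        for i in range(20):
            row = {"subject_id": f"S{i}", "group": "PD" if i < 12 else "control"}
            for p in SubjectSaccadeSummary.PARAMETERS:
                row[p] = rng.normal(100, 10)
            rows.append(row)
        tab = saccade_comparison_table(pd.DataFrame(rows))
        assert len(tab) == 14
        assert tab["statistic"].notna().all()
        assert ((tab["p_value"] >= 0) & (tab["p_value"] <= 1)).all()
        # significance markers consistent with p-values
        assert (tab["significant"] == (tab["p_value"] < 0.05)).all()

    def test_amplitude_table_means_brute_force(self, rng):
        import pandas as pd

        from oculopd.stats import amplitude_table

        records = []
        for sid in range(12):
            group = "PD" if sid < 7 else "control"
            for eye in ("left", "right"):
                for f in (2.1, 11.8):
                    records.append(
                        {
                            "subject_id": f"S{sid}",
                            "group": group,
                            "task": "pro_saccade",
                            "eye": eye,
                            "frequency_hz": f,
                            "amplitude": rng.uniform(0.05, 0.5),
                        }
                    )
        df = pd.DataFrame(records)
        tab = amplitude_table(df)
        for row in tab.itertuples():
            sel = df[
                (df["task"] == row.task)
                & (df["eye"] == row.eye)
                & (df["frequency_hz"] == row.frequency_hz)
            ]
            want_pd = sel[sel["group"] == "PD"]["amplitude"].mean()
            assert row.pd_mean == pytest.approx(want_pd, abs=1e-12)
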