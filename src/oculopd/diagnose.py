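"""Feature assembly, Random-Forest diagnostic evaluation, and the pipeline.

Six feature-set configurations are evaluated: the 14 basic oculomotor
parameters, the 382 pro-saccade frequency features (191 bins x 2 eyes), the
382 anti-saccade frequency features, each frequency set combined with the
basic set, and all features together. Evaluation is repeated stratified
k-fold cross-validation with significance-based feature selection performed
*inside* each training fold (never on held-out data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, precision_score, recall_score, f1_score
from sklearn.model_selection import RepeatedStratifiedKFold

from oculopd.preprocess import detect_artifacts, repair_or_exclude
from oculopd.protocol import Eye, Group, TaskType, write_events_csv, write_recording_csv
from oculopd.pupilspec import subject_features
from oculopd.saccades import SubjectSaccadeSummary, score_schedule, summarize_subject
from oculopd.stats import (
    ALPHA,
    GroupComparisonResult,
    amplitude_table,
    compare_feature,
    count_significant,
    frequency_bin_results,
    saccade_comparison_table,
)
from oculopd.synthdata import CohortConfig, CohortData, simulate_cohort

__all__ = [
    "FEATURE_SET_TAGS",
    "FeatureMatrix",
    "ClassifierReport",
    "build_feature_matrix",
    "cohort_tables",
    "select_features",
    "evaluate",
    "PipelineConfig",
    "run_pipeline",
]

FEATURE_SET_TAGS = (
    "basic",
    "freq_pro",
    "freq_anti",
    "freq_pro+basic",
    "freq_anti+basic",
    "all",
)

_TASK_SHORT = {TaskType.PRO: "pro", TaskType.ANTI: "anti"}
_FALLBACK_TOP_K = 5


def _freq_col(task: TaskType, eye: Eye, freq: float) -> str:
    return f"freq_{_TASK_SHORT[task]}:{eye.value}:{freq:.1f}"


@dataclass
class FeatureMatrix:
    """Labelled feature table for one feature-set configuration."""

    X: pd.DataFrame  # rows = subjects (index = subject_id)
    y: pd.Series  # 'PD' / 'control'
    tag: str

    def __post_init__(self) -> None:
        if self.tag not in FEATURE_SET_TAGS:
            raise ValueError(f"unknown feature-set tag {self.tag!r}")
        if len(self.X) != len(self.y):
            raise ValueError("X and y must align")
        if self.y.isna().any():
            raise ValueError("missing labels")

    @property
    def n_subjects(self) -> int:
        return len(self.X)


def _columns_for_tag(columns: Sequence[str], tag: str) -> list[str]:
    want: list[str] = []
    parts = tag.split("+")
    for col in columns:
        kind = col.split(":", 1)[0]
        if kind in parts or (tag == "all" and kind in ("basic", "freq_pro", "freq_anti")):
            want.append(col)
    return want


def build_feature_matrix(
    summaries: pd.DataFrame,
    features: pd.DataFrame,
    tag: str = "all",
) -> FeatureMatrix:
    """Assemble the feature table for one configuration.

    ``summaries`` has subject_id, group, and the 14 parameter columns;
    ``features`` is long-form (subject_id, group, task, eye, frequency_hz,
    amplitude).
    """
    wide = summaries.set_index("subject_id")
    basic = wide[list(SubjectSaccadeSummary.PARAMETERS)].rename(
        columns={p: f"basic:{p}" for p in SubjectSaccadeSummary.PARAMETERS}
    )
    blocks = [basic]
    if len(features):
        piv = features.pivot_table(
            index="subject_id", columns=["task", "eye", "frequency_hz"], values="amplitude"
        )
        piv.columns = [
            _freq_col(TaskType(t), Eye(e), float(f)) for t, e, f in piv.columns
        ]
        blocks.append(piv)
    X = pd.concat(blocks, axis=1).loc[wide.index]
    X = X.dropna(axis=1, how="all")  # e.g. anti-task columns in a pro-only run
    cols = _columns_for_tag(X.columns, tag)
    if not cols:
        raise ValueError(f"no columns available for feature set {tag!r}")
    return FeatureMatrix(X=X[cols], y=wide["group"], tag=tag)


def _column_results(X: pd.DataFrame, y: pd.Series, alpha: float) -> list[GroupComparisonResult]:
    results = []
    pd_mask = (y == Group.PD.value).to_numpy()
    for col in X.columns:
        vals = X[col].to_numpy(float)
        results.append(compare_feature(vals[pd_mask], vals[~pd_mask], alpha=alpha, feature_id=col))
    return results


def select_features(
    results: Iterable[GroupComparisonResult],
    matrix: FeatureMatrix,
) -> FeatureMatrix:
    """Keep only columns whose group comparison was significant.

    Falls back to the top-``5`` columns by p-value when nothing is
    significant, so the classifier never sees an empty design matrix.
    """
    if matrix.X.shape[1] == 0:
        raise ValueError("empty feature matrix")
    by_col = {r.feature_id: r for r in results}
    missing = [c for c in matrix.X.columns if c not in by_col]
    if missing:
        raise ValueError(f"comparison results missing for columns: {missing[:3]}...")
    keep = [c for c in matrix.X.columns if by_col[c].significant]
    if not keep:
        ranked = sorted(matrix.X.columns, key=lambda c: by_col[c].p_value)
        keep = ranked[:_FALLBACK_TOP_K]
    return FeatureMatrix(X=matrix.X[keep], y=matrix.y, tag=matrix.tag)


@dataclass
class FoldRecord:
    subject_ids: list[str]
    y_true: list[str]
    y_pred: list[str]
    n_features: int


@dataclass
class ClassifierReport:
    tag: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    scheme: str
    seed: int
    folds: list[FoldRecord] = field(default_factory=list)

    def metrics(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def evaluate(
    matrix: FeatureMatrix,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    n_trees: int = 500,
    select: bool = True,
    alpha: float = ALPHA,
) -> ClassifierReport:
    """Repeated stratified k-fold Random-Forest evaluation.

    Metrics are macro-averaged over the two classes within each held-out
    fold, then averaged across folds; deterministic given ``seed``.
    """
    y = matrix.y
    class_counts = y.value_counts()
    if len(class_counts) < 2:
        raise ValueError("need both classes present")
    if class_counts.min() < 2:
        raise ValueError("need >= 2 subjects per class")
    folds = min(folds, int(class_counts.min()))

    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    rng = np.random.default_rng(seed)
    X = matrix.X
    records: list[FoldRecord] = []
    accs, precs, recs, f1s = [], [], [], []
    for train_idx, test_idx in cv.split(X, y):
        X_tr, X_te = X.iloc[train_idx], X.iloc[test_idx]
        y_tr, y_te = y.iloc[train_idx], y.iloc[test_idx]
        medians = X_tr.median()
        X_tr = X_tr.fillna(medians)
        X_te = X_te.fillna(medians)
        cols = list(X_tr.columns)
        # the normality gate needs n >= 3 per class; skip selection below that
        if select and y_tr.value_counts().min() >= 3:
            fold_matrix = FeatureMatrix(X=X_tr, y=y_tr, tag=matrix.tag)
            selected = select_features(_column_results(X_tr, y_tr, alpha), fold_matrix)
            cols = list(selected.X.columns)
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        clf.fit(X_tr[cols], y_tr)
        pred = clf.predict(X_te[cols])
        accs.append(accuracy_score(y_te, pred))
        precs.append(precision_score(y_te, pred, average="macro", zero_division=0))
        recs.append(recall_score(y_te, pred, average="macro", zero_division=0))
        f1s.append(f1_score(y_te, pred, average="macro", zero_division=0))
        records.append(
            FoldRecord(
                subject_ids=list(X_te.index),
                y_true=list(y_te),
                y_pred=list(pred),
                n_features=len(cols),
            )
        )
    return ClassifierReport(
        tag=matrix.tag,
        accuracy=float(np.mean(accs)),
        precision=float(np.mean(precs)),
        recall=float(np.mean(recs)),
        f1=float(np.mean(f1s)),
        scheme=f"stratified {folds}-fold x {repeats} repeats",
        seed=seed,
        folds=records,
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    tasks: tuple[TaskType, ...] = (TaskType.PRO, TaskType.ANTI)
    alpha: float = ALPHA
    cv_folds: int = 5
    cv_repeats: int = 10
    n_trees: int = 500
    seed: int = 0
    make_figures: bool = True

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["tasks"] = [t.value for t in self.tasks]
        return d


def extract_cohort_features(
    cohort: CohortData, tasks: Sequence[TaskType] = tuple(TaskType)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clean, score, and spectrally featurise every recording.

    Returns (summaries, features): the per-subject 14-parameter table and
    the long-form per-bin amplitude table.
    """
    summary_rows = []
    feature_rows = []
    for subj in cohort.subjects:
        scores = {}
        for task in tasks:
            rec = subj.recordings[task]
            schedule = subj.schedules[task]
            clean = repair_or_exclude(rec, detect_artifacts(rec), schedule)
            scores[task] = score_schedule(clean, schedule)
            for feat in subject_features(clean, schedule):
                feature_rows.append(
                    {
                        "subject_id": subj.subject_id,
                        "group": subj.group.value,
                        "task": feat.task.value,
                        "eye": feat.eye.value,
                        "frequency_hz": feat.frequency_hz,
                        "band": feat.band,
                        "amplitude": feat.amplitude,
                    }
                )
        summary = summarize_subject(
            subj.subject_id,
            scores.get(TaskType.PRO),
            scores.get(TaskType.ANTI),
        )
        summary_rows.append({"subject_id": subj.subject_id, "group": subj.group.value, **summary.as_dict()})
    return pd.DataFrame(summary_rows), pd.DataFrame(feature_rows)


def cohort_tables(summaries: pd.DataFrame, features: pd.DataFrame, alpha: float = ALPHA) -> dict:
    """Comparison tables: parameters, per-bin results, band counts, amplitudes."""
    bin_results = frequency_bin_results(features, alpha=alpha) if len(features) else []
    return {
        "saccade_comparison": saccade_comparison_table(summaries, alpha=alpha),
        "bin_results": bin_results,
        "band_counts": count_significant(bin_results) if bin_results else {},
        "amplitude_table": amplitude_table(features, bin_results) if len(features) else pd.DataFrame(),
    }


def _band_counts_frame(band_counts: dict) -> pd.DataFrame:
    rows = []
    for task, counts in band_counts.items():
        for eye, per_band in counts.per_eye.items():
            rows.append({"task": task.value, "eye": eye.value, **per_band})
        rows.append({"task": task.value, "eye": "both", **counts.totals})
    return pd.DataFrame(rows)


def _figures(cohort: CohortData, features: pd.DataFrame, out: Path) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    # group-mean pupil trajectories (left eye, pro task)
    fig, ax = plt.subplots(figsize=(9, 4))
    for group, color in [(Group.PD, "tab:red"), (Group.CONTROL, "tab:blue")]:
        traces = [
            s.recordings[TaskType.PRO].pupil_left_mm
            for s in cohort.subjects
            if s.group is group and TaskType.PRO in s.recordings
        ]
        if traces:
            n = min(map(len, traces))
            mean = np.mean([tr[:n] for tr in traces], axis=0)
            t = np.arange(n) / cohort.config.sample_rate_hz
            ax.plot(t, mean, color=color, label=group.value, lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pupil diameter (mm)")
    ax.set_title("Group-mean pupil trajectory, pro-saccade task (left eye)")
    ax.legend()
    path = out / "pupil_trajectory.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(str(path))

    if len(features):
        fig, axes = plt.subplots(1, features["task"].nunique(), figsize=(11, 4), squeeze=False)
        for ax, (task, sub) in zip(axes.ravel(), features.groupby("task")):
            for group, color in [("PD", "tab:red"), ("control", "tab:blue")]:
                prof = (
                    sub[sub["group"] == group]
                    .groupby("frequency_hz")["amplitude"]
                    .mean()
                    .sort_index()
                )
                ax.plot(prof.index, prof.values, color=color, label=group, lw=0.9)
            ax.set_title(task)
            ax.set_xlabel("frequency (Hz)")
            ax.set_ylabel("mean amplitude (mm)")
            ax.legend()
        path = out / "average_amplitude.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(str(path))
    return written


def run_pipeline(config: PipelineConfig, out_dir: str | Path, cohort: CohortData | None = None) -> dict:
    """Simulate (or accept) a cohort, analyse it, and write the report bundle.

    Writes subject summaries, frequency features, comparison tables, band
    counts, classifier reports for every evaluable feature set, figures, and
    a JSON run log. Returns the bundle in memory as well.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = simulate_cohort(config.cohort)

    summaries, features = extract_cohort_features(cohort, config.tasks)
    tables = cohort_tables(summaries, features, alpha=config.alpha)

    available_tags = []
    have_pro = TaskType.PRO in config.tasks
    have_anti = TaskType.ANTI in config.tasks
    for tag in FEATURE_SET_TAGS:
        if ("freq_pro" in tag and not have_pro) or ("freq_anti" in tag and not have_anti):
            continue
        if tag == "all" and not (have_pro and have_anti):
            continue
        available_tags.append(tag)

    reports: dict[str, ClassifierReport] = {}
    for tag in available_tags:
        matrix = build_feature_matrix(summaries, features, tag)
        reports[tag] = evaluate(
            matrix,
            folds=config.cv_folds,
            repeats=config.cv_repeats,
            seed=config.seed,
            n_trees=config.n_trees,
        )

    summaries.to_csv(out / "subject_summaries.csv", index=False)
    features.to_csv(out / "frequency_features.csv", index=False)
    tables["saccade_comparison"].to_csv(out / "saccade_comparison.csv", index=False)
    if len(tables["amplitude_table"]):
        tables["amplitude_table"].to_csv(out / "amplitude_comparison.csv", index=False)
    if tables["band_counts"]:
        _band_counts_frame(tables["band_counts"]).to_csv(out / "band_counts.csv", index=False)
    pd.DataFrame(
        [{"feature_set": t, **r.metrics(), "scheme": r.scheme, "seed": r.seed} for t, r in reports.items()]
    ).to_csv(out / "classifier_reports.csv", index=False)

    figures = _figures(cohort, features, out) if config.make_figures else []

    run_log = {
        "config": config.to_jsonable(),
        "n_subjects": len(cohort),
        "n_recordings": cohort.n_recordings,
        "feature_sets": available_tags,
        "figures": figures,
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))

    return {
        "cohort": cohort,
        "summaries": summaries,
        "features": features,
        "tables": tables,
        "reports": reports,
        "run_log": run_log,
    }


def export_cohort(cohort: CohortData, out_dir: str | Path) -> None:
    """Write recordings/events CSVs plus a subject manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in cohort.subjects:
        for task, rec in subj.recordings.items():
            short = _TASK_SHORT[task]
            write_recording_csv(rec, out / f"{subj.subject_id}_{short}_recording.csv")
            write_events_csv(subj.schedules[task], subj.subject_id, out / f"{subj.subject_id}_{short}_events.csv")
        rows.append({"subject_id": subj.subject_id, "group": subj.group.value})
    pd.DataFrame(rows).to_csv(out / "subjects.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
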