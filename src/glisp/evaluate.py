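"""Metrics, per-task cross-validation, and bootstrap confidence intervals.

Reporting follows the framework's protocol: ROC AUC (midrank / Mann-Whitney
formulation), accuracy, F1, precision, recall and NPV where applicable, at
patch, slide and case level, with nonparametric percentile-bootstrap 95%
intervals resampled at case level (B = 2000 by default). Cross-validation is
stratified at case level, independently per task: a task's labeled sub-cohort
is partitioned into k folds and all slides and patches of a case follow the
case, which is what rules out leakage under weak supervision.

Metrics are kept at full precision internally; rounding to 2 decimals
happens only in rendered reports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .labels import GeneLabelTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion-matrix metrics

@dataclass
class ConfusionMatrix3:
    """3x3 counts; axis semantics declared, class order (astro, oligo, gbm)."""

    counts: np.ndarray
    axes: tuple[str, str] = ("ground_truth", "predicted")
    classes: tuple[str, ...] = ("astrocytoma", "oligodendroglioma", "glioblastoma")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("confusion matrix must hold non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def metrics_from_confusion(cm: ConfusionMatrix3 | np.ndarray) -> dict:
    """Accuracy + per-class precision/recall/F1 from a 3x3 confusion matrix.

    A zero row/column margin makes the corresponding precision or recall
    undefined; it is reported as NaN. Accuracy and F1 are invariant under
    transposition of the matrix, so the ambiguity of which axis is
    "predicted" does not affect them.
    """
    if not isinstance(cm, ConfusionMatrix3):
        cm = ConfusionMatrix3(np.asarray(cm))
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    pred_margin = counts.sum(axis=1) if cm.axes[0] == "predicted" else counts.sum(axis=0)
    truth_margin = counts.sum(axis=0) if cm.axes[0] == "predicted" else counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_margin > 0, tp / pred_margin, np.nan)
        recall = np.where(truth_margin > 0, tp / truth_margin, np.nan)
        f1 = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall),
                      np.nan)
    return {
        "accuracy": float(tp.sum() / total),
        "per_class": {
            cls: {"precision": float(precision[i]), "recall": float(recall[i]),
                  "f1": float(f1[i])}
            for i, cls in enumerate(cm.classes)
        },
    }


def confusion_from_calls(truth: list[str], predicted: list[str],
                         classes: tuple[str, ...] = ("astrocytoma", "oligodendroglioma",
                                                     "glioblastoma")) -> ConfusionMatrix3:
    """Tally class calls into a (ground_truth rows, predicted cols) matrix."""
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(truth, predicted):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix3(counts, axes=("ground_truth", "predicted"), classes=classes)


# ---------------------------------------------------------------------------
# binary metrics

def binary_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """ROC AUC (midrank ties), accuracy, F1, precision, recall and NPV.

    AUC is NaN when only one class is present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.size == 0:
        raise ValueError("empty input")
    preds = (scores >= threshold).astype(int)
    tp = int(((preds == 1) & (labels == 1)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    auc = float(roc_auc_score(labels, scores)) if len(np.unique(labels)) == 2 else np.nan
    precision = tp / (tp + fp) if tp + fp else np.nan
    recall = tp / (tp + fn) if tp + fn else np.nan
    f1 = (2 * precision * recall / (precision + recall)
          if (tp + fp) and (tp + fn) and (precision + recall) else np.nan)
    npv = tn / (tn + fn) if tn + fn else np.nan
    return {
        "roc_auc": auc,
        "accuracy": (tp + tn) / len(labels),
        "f1": f1,
        "precision": precision,
        "recall": recall,
        "npv": npv,
    }


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_ci(metric_fn, data: tuple[np.ndarray, ...], n_boot: int = 2000,
                 seed: int = 0, ci: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap interval of ``metric_fn(*resampled data)``.

    ``data`` arrays are resampled jointly with replacement along their first
    axis (case-level resampling when rows are cases). Degenerate resamples
    for which the metric is undefined (e.g. one-class AUC) are skipped and
    logged.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    n = len(data[0])
    rng = np.random.default_rng(seed)
    vals = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            v = metric_fn(*(d[idx] for d in data))
        except ValueError:
            skipped += 1
            continue
        if v is None or (isinstance(v, float) and np.isnan(v)):
            skipped += 1
            continue
        vals.append(v)
    if skipped:
        log.info("bootstrap: skipped %d degenerate resamples", skipped)
    if not vals:
        raise ValueError("all bootstrap resamples were degenerate")
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# split plans

@dataclass
class SplitPlan:
    """Per-task case-level fold assignment."""

    task: str
    assignment: pd.Series  # index case_id -> fold number (0-based)
    k: int
    seed: int

    def fold_cases(self, fold: int) -> list[str]:
        return sorted(self.assignment.index[self.assignment == fold])


def make_splits(labels: GeneLabelTable, task: str, k: int = 5, seed: int = 0) -> SplitPlan:
    """Stratified case-level k-fold partition of a task's labeled cases."""
    status = labels.for_task(task)
    if len(status) < k:
        raise ValueError(f"task {task!r}: {len(status)} labeled cases < {k} folds")
    cases = np.asarray(status.index)
    y = status.to_numpy()
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        warnings.warn(f"task {task!r}: class with {counts.min()} members < {k} folds; "
                      "stratification relaxed", stacklevel=2)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(cases)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(cases, y)
    assignment = pd.Series(index=pd.Index(cases, name="case_id"), dtype=int)
    for fold, (_, test_idx) in enumerate(folds):
        assignment.iloc[test_idx] = fold
    return SplitPlan(task=task, assignment=assignment.astype(int), k=k, seed=seed)


def assert_no_leakage(plan: SplitPlan, manifest: pd.DataFrame) -> None:
    """Raise if any case's patches would appear in two folds."""
    merged = manifest.merge(plan.assignment.rename("fold"), left_on="case_id",
                            right_index=True, how="inner")
    per_case = merged.groupby("case_id")["fold"].nunique()
    if (per_case > 1).any():
        raise AssertionError(f"patch leakage across folds for cases "
                             f"{per_case[per_case > 1].index.tolist()}")


# ---------------------------------------------------------------------------
# cross-validation driver

@dataclass
class EvalReport:
    task: str
    level: str  # patch / slide / case
    fold: int
    metrics: dict
    ci: dict = field(default_factory=dict)


def render_report(reports: list[EvalReport]) -> pd.DataFrame:
    """Table-2-style summary: mean (+/- sd) over folds, 2-dp, per level."""
    rows = []
    df = pd.DataFrame([{"task": r.task, "level": r.level, "fold": r.fold, **r.metrics}
                       for r in reports])
    for (task, level), grp in df.groupby(["task", "level"]):
        row = {"task": task, "level": level}
        for m in ("roc_auc", "accuracy", "f1", "precision", "recall"):
            if m in grp:
                row[m] = f"{grp[m].mean():.2f} (±{grp[m].std(ddof=0):.3f})"
        rows.append(row)
    return pd.DataFrame(rows)


def run_cv(images: np.ndarray, manifest: pd.DataFrame, labels: GeneLabelTable,
           task: str, k: int = 5, seed: int = 0, p_config=None, w_config=None,
           p_model_config=None, w_model_config=None,
           n_case_draws: int = 8) -> tuple[list[EvalReport], pd.DataFrame]:
    """Per-task k-fold cross-validation of the two-stage pipeline.

    For every fold: train the patch model on the training cases, freeze it,
    encode all patches, train the bag meta-model, then report patch-level and
    case-level metrics on the held-out fold. Failed folds are skipped with a
    warning and the summary covers the completed folds.
    """
    from .glisp_p import TrainConfig, train_glisp_p
    from .glisp_w import WTrainConfig, predict_case, train_glisp_w

    plan = make_splits(labels, task, k=k, seed=seed)
    assert_no_leakage(plan, manifest)
    status = labels.for_task(task)
    reports: list[EvalReport] = []
    for fold in range(k):
        test_cases = set(plan.fold_cases(fold))
        train_mask = manifest["case_id"].isin(set(status.index) - test_cases).to_numpy()
        test_mask = manifest["case_id"].isin(test_cases).to_numpy()
        try:
            pcfg = p_config or TrainConfig(seed=seed + fold)
            model_p, _ = train_glisp_p(images[train_mask],
                                       manifest[train_mask].reset_index(drop=True),
                                       labels, task, config=pcfg,
                                       model_config=p_model_config)
            # patch-level evaluation on held-out cases
            probs = model_p.predict_proba(images[test_mask])
            y_patch = status.loc[manifest["case_id"][test_mask]].to_numpy()
            reports.append(EvalReport(task, "patch", fold,
                                      binary_metrics(probs, y_patch)))
            # encode everything once with the frozen patch model
            encodings = model_p.encode(images)
            slide_enc = {s: encodings[(manifest["slide_id"] == s).to_numpy()]
                         for s in manifest["slide_id"].unique()}
            slide_cases = dict(manifest[["slide_id", "case_id"]]
                               .drop_duplicates().itertuples(index=False))
            train_slide_enc = {s: e for s, e in slide_enc.items()
                               if slide_cases[s] in set(status.index) - test_cases}
            wcfg = w_config or WTrainConfig(seed=seed + fold)
            model_w, _ = train_glisp_w(train_slide_enc, slide_cases, labels, task,
                                       config=wcfg, model_config=w_model_config)
            case_probs, case_y = [], []
            for case in sorted(test_cases):
                encs = [slide_enc[s] for s, c in slide_cases.items() if c == case]
                case_probs.append(predict_case(model_w, encs, n_draws=n_case_draws,
                                               seed=seed + fold))
                case_y.append(int(status.loc[case]))
            reports.append(EvalReport(task, "case", fold,
                                      binary_metrics(case_probs, case_y)))
        except ValueError as exc:
            warnings.warn(f"fold {fold} failed: {exc}", stacklevel=2)
            continue
    summary = render_report(reports)
    return reports, summary
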