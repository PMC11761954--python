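"""Metrics protocol: confusion metrics, AUC, bootstrap, split hygiene."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from glisp.evaluate import (
    ConfusionMatrix3,
    assert_no_leakage,
    binary_metrics,
    bootstrap_ci,
    confusion_from_calls,
    make_splits,
    metrics_from_confusion,
)
from glisp.labels import GeneLabelTable
from glisp.reference import EXTERNAL_VALIDATION_CONFUSION


def tally_oracle(counts):
    """From-scratch per-class precision/recall/F1 with explicit loops."""
    counts = np.asarray(counts, dtype=float)
    out = {}
    for c in range(3):
        tp = counts[c, c]
        fp = counts[c].sum() - tp  # row = predicted reading
        fn = counts[:, c].sum() - tp
        prec = tp / (tp + fp) if tp + fp else np.nan
        rec = tp / (tp + fn) if tp + fn else np.nan
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else np.nan
        out[c] = (prec, rec, f1)
    out["acc"] = np.trace(counts) / counts.sum()
    return out


class TestConfusionMetrics:
    def test_external_cohort_matrix_reproduces_reported_metrics(self):
        m = metrics_from_confusion(EXTERNAL_VALIDATION_CONFUSION)
        assert round(m["accuracy"], 2) == 0.66
        f1s = [round(m["per_class"][c]["f1"], 2)
               for c in ("astrocytoma", "oligodendroglioma", "glioblastoma")]
        assert f1s == [0.70, 0.62, 0.64]

    def test_diagonal_matrix_is_perfect(self):
        m = metrics_from_confusion(np.diag([10, 10, 10]))
        assert m["accuracy"] == 1.0
        assert all(v["f1"] == 1.0 for v in m["per_class"].values())

    @pytest.mark.parametrize("trial", range(50))
    def test_agrees_with_tally_oracle_and_transpose(self, trial):
        rng = np.random.default_rng(trial)
        counts = rng.integers(0, 30, (3, 3))
        if counts.sum() == 0:
            counts[0, 0] = 1
        m = metrics_from_confusion(
            ConfusionMatrix3(counts, axes=("predicted", "ground_truth")))
        oracle = tally_oracle(counts)
        assert m["accuracy"] == pytest.approx(oracle["acc"])
        mt = metrics_from_confusion(counts.T)
        assert mt["accuracy"] == pytest.approx(m["accuracy"])
        for i, cls in enumerate(("astrocytoma", "oligodendroglioma", "glioblastoma")):
            got = m["per_class"][cls]
            np.testing.assert_allclose(
                [got["precision"], got["recall"], got["f1"]], oracle[i], equal_nan=True)
            # accuracy and F1 are transpose-invariant; precision/recall swap
            f1_t = mt["per_class"][cls]["f1"]
            np.testing.assert_allclose(f1_t, got["f1"], equal_nan=True)

    def test_zero_margin_reported_as_nan(self):
        # nothing predicted as oligodendroglioma -> its precision is undefined
        counts = np.array([[5, 0, 0], [3, 0, 0], [2, 0, 0]])
        m = metrics_from_confusion(ConfusionMatrix3(counts))
        assert np.isnan(m["per_class"]["oligodendroglioma"]["precision"])
        assert m["per_class"]["oligodendroglioma"]["recall"] == 0.0

    def test_tally_from_calls_roundtrip(self, rng):
        classes = ("astrocytoma", "oligodendroglioma", "glioblastoma")
        truth = rng.choice(classes, 200)
        pred = rng.choice(classes, 200)
        cm = confusion_from_calls(truth, pred)
        assert cm.total == 200
        for i, t in enumerate(classes):
            for j, p in enumerate(classes):
                assert cm.counts[i, j] == int(((truth == t) & (pred == p)).sum())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix3(np.array([[1, -1, 0], [0, 0, 0], [0, 0, 0]]))


class TestBinaryMetrics:
    def test_perfect_separation_gives_auc_one(self):
        m = binary_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m["roc_auc"] == 1.0 and m["accuracy"] == 1.0

    def test_null_scores_near_half_auc(self):
        rng = np.random.default_rng(0)
        m = binary_metrics(rng.random(2000), rng.integers(0, 2, 2000))
        assert 0.45 <= m["roc_auc"] <= 0.55

    def test_npv_definition(self):
        # 78 true negatives, 22 false negatives, no positive predictions needed
        scores = [0.1] * 100
        labels = [0] * 78 + [1] * 22
        assert binary_metrics(scores, labels)["npv"] == pytest.approx(0.78)

    def test_auc_matches_mann_whitney(self, rng):
        for _ in range(10):
            scores = rng.normal(0, 1, 300)
            labels = rng.integers(0, 2, 300)
            if len(np.unique(labels)) < 2:
                continue
            u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
            auc_mw = u / ((labels == 1).sum() * (labels == 0).sum())
            assert binary_metrics(scores, labels)["roc_auc"] == pytest.approx(
                auc_mw, abs=1e-10)

    def test_one_class_auc_is_nan(self):
        assert np.isnan(binary_metrics([0.1, 0.9], [1, 1])["roc_auc"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics([], [])


class TestBootstrap:
    def test_constant_metric_collapses_interval(self):
        lo, hi = bootstrap_ci(lambda x: 1.0, (np.arange(50),), n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_same_seed_same_interval(self):
        data = (np.random.default_rng(1).random(100),)
        f = lambda x: float(np.mean(x))
        assert bootstrap_ci(f, data, 300, seed=5) == bootstrap_ci(f, data, 300, seed=5)

    def test_interval_contains_point_estimate(self, rng):
        x = rng.random(200)
        lo, hi = bootstrap_ci(lambda v: float(np.mean(v)), (x,), 500, seed=2)
        assert lo <= x.mean() <= hi

    def test_accuracy_ci_width_near_wilson(self):
        """71/108 Bernoulli accuracy: percentile-bootstrap width vs Wilson width."""
        from statsmodels.stats.proportion import proportion_confint

        y = np.array([1] * 71 + [0] * 37)
        lo, hi = bootstrap_ci(lambda v: float(np.mean(v)), (y,), 2000, seed=3)
        wlo, whi = proportion_confint(71, 108, method="wilson")
        assert abs((hi - lo) - (whi - wlo)) <= 0.03

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda x: 0.0, (np.arange(5),), n_boot=50)


class TestSplits:
    def _labels(self, n=100, miss_every=None, task="idh", seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            status = int(rng.integers(0, 2))
            if miss_every and i % miss_every == 0:
                status = np.nan
            rows.append({"case_id": f"c{i:03d}", "task": task, "status": status})
        return GeneLabelTable(pd.DataFrame(rows))

    def test_five_folds_partition_hundred_cases(self):
        plan = make_splits(self._labels(100), "idh", k=5, seed=0)
        sizes = plan.assignment.value_counts()
        assert sorted(sizes) == [20] * 5
        assert plan.assignment.index.is_unique

    def test_no_patch_leakage_against_manifest(self, tiny_cohort):
        plan = make_splits(tiny_cohort.labels, "idh", k=2, seed=1)
        assert_no_leakage(plan, tiny_cohort.manifest)

    def test_tasks_split_independently(self):
        tab = pd.concat([self._labels(60, task="idh", seed=1).table,
                         self._labels(80, task="codel_1p19q", seed=2).table])
        labels = GeneLabelTable(tab.reset_index(drop=True))
        p1 = make_splits(labels, "idh", k=5, seed=3)
        p2 = make_splits(labels, "codel_1p19q", k=5, seed=3)
        assert len(p1.assignment) == 60 and len(p2.assignment) == 80
        shared = p1.assignment.index.intersection(p2.assignment.index)
        assert not p1.assignment.loc[shared].equals(p2.assignment.loc[shared])

    def test_missing_labels_excluded(self):
        plan = make_splits(self._labels(100, miss_every=4), "idh", k=5, seed=0)
        assert len(plan.assignment) == 75

    def test_rare_class_relaxes_stratification_with_warning(self):
        tab = self._labels(40).table
        tab.loc[tab.index[:38], "status"] = 0  # leaves <5 positives
        with pytest.warns(UserWarning):
            make_splits(GeneLabelTable(tab), "idh", k=5, seed=0)

    def test_stratification_balances_prevalence(self):
        plan = make_splits(self._labels(200, seed=4), "idh", k=5, seed=4)
        labels = self._labels(200, seed=4).for_task("idh")
        prevs = [labels.loc[plan.fold_cases(f)].mean() for f in range(5)]
        assert max(prevs) - min(prevs) < 0.12
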