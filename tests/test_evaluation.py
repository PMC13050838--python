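import numpy as np
import pytest

from profusenet.evaluation import (
    BootstrapCI,
    ConfusionCounts,
    bootstrap_ci,
    classification_metrics,
    confusion,
    paired_ttest,
    pr_auc,
    project_2d,
    roc_auc,
    silhouette,
)


def realize_vectors(c: ConfusionCounts):
    """Label/prediction vectors realizing given confusion counts."""
    y_true = [1] * (c.tp + c.fn) + [0] * (c.tn + c.fp)
    y_pred = [1] * c.tp + [0] * c.fn + [0] * c.tn + [1] * c.fp
    return np.array(y_true), np.array(y_pred)


def metrics_oracle(y_true, y_pred):
    """Per-sample brute-force accuracy and per-class precision/recall/F1."""
    acc = float((y_true == y_pred).mean())
    out = {"accuracy": acc}
    for cls, name in ((0, "Control"), (1, "CML")):
        pred_pos = (y_pred == cls).sum()
        actual_pos = (y_true == cls).sum()
        tp = ((y_true == cls) & (y_pred == cls)).sum()
        prec = tp / pred_pos if pred_pos else 0.0
        rec = tp / actual_pos if actual_pos else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[name] = (prec, rec, f1)
    return out


def auc_oracle(scores, labels):
    """Concordant-pair fraction with ties counted one half."""
    pos = [s for s, label in zip(scores, labels) if label == 1]
    neg = [s for s, label in zip(scores, labels) if label == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def silhouette_oracle(points, labels):
    """Double-loop silhouette with the singleton s=0 convention."""
    n = len(points)
    svals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            svals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in own])
        b = np.inf
        for cls in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == cls]
            b = min(b, np.mean([np.linalg.norm(points[i] - points[j]) for j in members]))
        svals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(svals)), svals


class TestConfusion:
    def test_all_correct(self):
        c = confusion([1, 1, 1, 0, 0], [1, 1, 1, 0, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 2, 0, 0)

    def test_paper_counts(self):
        # 120 controls / 120 positives; 5 controls and 3 positives misclassified
        y_true = [0] * 120 + [1] * 120
        y_pred = [1] * 5 + [0] * 115 + [0] * 3 + [1] * 117
        c = confusion(y_true, y_pred)
        assert (c.tp, c.tn, c.fp, c.fn) == (117, 115, 5, 3)

    def test_swapped_predictions_symmetry(self, rng):
        y_true = rng.integers(0, 2, size=30)
        y_pred = rng.integers(0, 2, size=30)
        c = confusion(y_true, y_pred)
        swapped = confusion(y_true, 1 - y_pred)
        assert (swapped.tp, swapped.fn) == (c.fn, c.tp)
        assert (swapped.tn, swapped.fp) == (c.fp, c.tn)

    def test_string_labels(self):
        c = confusion(["CML", "Control"], ["CML", "CML"])
        assert (c.tp, c.fp) == (1, 1)

    def test_non_binary_raises(self):
        with pytest.raises(ValueError):
            confusion([0, 1, 2], [0, 1, 1])


class TestClassificationMetrics:
    def test_table6_reproduction(self):
        m = classification_metrics(ConfusionCounts(tp=117, tn=115, fp=5, fn=3))
        assert round(m.accuracy, 3) == 0.967
        ctrl = m.per_class["Control"]
        assert (round(ctrl.precision, 3), round(ctrl.recall, 3),
                round(ctrl.f1, 3)) == (0.975, 0.958, 0.966)
        cml = m.per_class["CML"]
        assert (round(cml.precision, 3), round(cml.recall, 3),
                round(cml.f1, 3)) == (0.959, 0.975, 0.967)
        assert round(m.macro.f1, 3) == 0.967
        assert round(m.weighted.f1, 3) == 0.967
        assert ctrl.support == cml.support == 120

    def test_symmetric_counts(self):
        m = classification_metrics(ConfusionCounts(tp=5, tn=5, fp=5, fn=5))
        assert m.accuracy == 0.5
        for cls in ("Control", "CML"):
            cm = m.per_class[cls]
            assert cm.precision == cm.recall == cm.f1 == 0.5

    def test_random_counts_match_bruteforce(self, rng):
        for _ in range(25):
            counts = ConfusionCounts(*(int(x) for x in rng.integers(0, 12, size=4)))
            if counts.total == 0:
                continue
            y_true, y_pred = realize_vectors(counts)
            oracle = metrics_oracle(y_true, y_pred)
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m = classification_metrics(counts)
            assert m.accuracy == pytest.approx(oracle["accuracy"])
            for cls in ("Control", "CML"):
                cm = m.per_class[cls]
                assert (cm.precision, cm.recall, cm.f1) == pytest.approx(oracle[cls])

    def test_f1_harmonic_mean_identity(self):
        m = classification_metrics(ConfusionCounts(tp=30, tn=20, fp=10, fn=5))
        for cm in m.per_class.values():
            expected = 2 * cm.precision * cm.recall / (cm.precision + cm.recall)
            assert cm.f1 == pytest.approx(expected)

    def test_balanced_accuracy_equals_mean_recall(self):
        m = classification_metrics(ConfusionCounts(tp=45, tn=40, fp=10, fn=5))
        mean_recall = (m.per_class["Control"].recall + m.per_class["CML"].recall) / 2
        assert m.accuracy == pytest.approx(mean_recall)

    def test_zero_denominator_warns(self):
        with pytest.warns(UserWarning):
            m = classification_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert m.per_class["CML"].precision == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_format_table_contains_rows(self):
        m = classification_metrics(ConfusionCounts(tp=117, tn=115, fp=5, fn=3))
        table = m.format_table()
        assert "Control" in table and "CML" in table and "macro avg" in table


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1]) == 0.5

    def test_four_point_example(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert roc_auc(scores, labels) == pytest.approx(auc_oracle(scores, labels))

    def test_random_sets_match_pair_enumeration(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid to force ties
            assert roc_auc(scores, labels) == pytest.approx(
                auc_oracle(scores, labels)
            )

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_pr_auc_perfect(self):
        assert pr_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_pr_auc_matches_sklearn_style_oracle(self, rng):
        # step-integration oracle: sum precision * delta-recall over thresholds
        for _ in range(10):
            n = int(rng.integers(5, 25))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)
            order = np.argsort(-scores, kind="stable")
            ls, ss = labels[order], scores[order]
            n_pos = labels.sum()
            tp = 0
            seen = 0
            expected = 0.0
            prev_recall = 0.0
            i = 0
            while i < n:
                j = i
                while j < n and ss[j] == ss[i]:
                    tp += ls[j]
                    seen += 1
                    j += 1
                recall = tp / n_pos
                precision = tp / seen
                expected += (recall - prev_recall) * precision
                prev_recall = recall
                i = j
            assert pr_auc(scores, labels) == pytest.approx(expected)


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        ci = bootstrap_ci(lambda yt, s: 0.75, [0, 1, 0, 1], [0, 1, 1, 0], B=50, seed=0)
        assert ci.lower == ci.upper == ci.point == 0.75

    def test_same_seed_identical(self):
        y = np.array([0, 1] * 10)
        preds = np.array([0, 1] * 8 + [1, 0, 1, 0])
        acc = lambda yt, yp: float((yt == yp).mean())
        a = bootstrap_ci(acc, y, preds, B=200, seed=3)
        b = bootstrap_ci(acc, y, preds, B=200, seed=3)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_matches_independent_bootstrap_oracle(self):
        rng = np.random.default_rng(99)
        y = rng.integers(0, 2, size=20)
        while y.sum() in (0, 20):
            y = rng.integers(0, 2, size=20)
        preds = rng.integers(0, 2, size=20)
        acc = lambda yt, yp: float((yt == yp).mean())
        ci = bootstrap_ci(acc, y, preds, B=2000, seed=1)

        oracle_rng = np.random.default_rng(123)  # independent resampler
        vals = []
        for _ in range(2000):
            idx = oracle_rng.integers(0, 20, size=20)
            while y[idx].sum() in (0, 20):
                idx = oracle_rng.integers(0, 20, size=20)
            vals.append(acc(y[idx], preds[idx]))
        lo, hi = np.percentile(vals, [2.5, 97.5])
        assert ci.lower == pytest.approx(lo, abs=0.01 + 1e-9)
        assert ci.upper == pytest.approx(hi, abs=0.01 + 1e-9)

    def test_ci_contains_point(self, rng):
        y = rng.integers(0, 2, size=30)
        while y.sum() in (0, 30):
            y = rng.integers(0, 2, size=30)
        preds = rng.integers(0, 2, size=30)
        acc = lambda yt, yp: float((yt == yp).mean())
        ci = bootstrap_ci(acc, y, preds, B=500, seed=0)
        assert ci.lower <= ci.point <= ci.upper

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(5)
        acc = lambda yt, yp: float((yt == yp).mean())
        widths = []
        for n in (30, 300):
            y = rng.integers(0, 2, size=n)
            preds = np.where(rng.random(n) < 0.8, y, 1 - y)
            ci = bootstrap_ci(acc, y, preds, B=400, seed=2)
            widths.append(ci.upper - ci.lower)
        assert widths[1] < widths[0]

    def test_small_B_raises(self):
        with pytest.raises(ValueError):
            bootstrap_ci(lambda a, b: 0.0, [0, 1], [0, 1], B=1)


class TestPairedTTest:
    def test_identical_runs(self):
        r = paired_ttest([0.9, 0.8, 0.85], [0.9, 0.8, 0.85])
        assert r.statistic == 0.0
        assert r.pvalue == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        r = paired_ttest([2, 2, 2, 2], [1, 1, 1, 1])
        assert r.degenerate
        assert r.pvalue == 0.0

    def test_textbook_closed_form(self):
        diffs = np.array([0.2, -0.1, 0.3, 0.1, 0.0])
        r = paired_ttest(diffs, np.zeros(5))
        mean, sd = diffs.mean(), diffs.std(ddof=1)
        expected_t = mean / (sd / np.sqrt(5))
        assert r.statistic == pytest.approx(expected_t)
        from scipy.stats import ttest_rel

        assert r.pvalue == pytest.approx(ttest_rel(diffs, np.zeros(5)).pvalue)

    def test_too_few_runs(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [0.5])


class TestSilhouette:
    def test_two_tight_far_clusters(self):
        points = np.array([[0, 0], [0, 1], [100, 0], [100, 1]], dtype=float)
        labels = np.array([0, 0, 1, 1])
        result = silhouette(points, labels)
        # hand computation: a=1, b=(100+sqrt(100^2+1))/2
        b = (100 + np.hypot(100, 1)) / 2
        assert result.s == pytest.approx((b - 1) / b)
        assert result.s > 0.99

    def test_equal_a_b_gives_zero(self):
        points = np.array([[0.0], [2.0], [1.0], [3.0]])
        labels = np.array([0, 0, 1, 1])
        result = silhouette(points, labels)
        # point 1 (x=2): a = 2, b = mean(|2-1|,|2-3|) = 1 -> negative; check formula
        _, oracle = silhouette_oracle(points, labels)
        np.testing.assert_allclose(result.per_point, oracle)

    def test_random_points_match_bruteforce(self, rng):
        points = rng.normal(size=(10, 3))
        labels = rng.integers(0, 3, size=10)
        while len(set(labels)) < 2:
            labels = rng.integers(0, 3, size=10)
        result = silhouette(points, labels)
        s_mean, per_point = silhouette_oracle(points, labels)
        assert result.s == pytest.approx(s_mean)
        np.testing.assert_allclose(result.per_point, per_point, atol=1e-12)

    def test_separation_limit(self, rng):
        base = rng.normal(size=(6, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])
        shifted = base.copy()
        shifted[labels == 1] += 1e6
        assert silhouette(shifted, labels).s > 0.999

    def test_bounds(self, rng):
        points = rng.normal(size=(12, 2))
        labels = rng.integers(0, 2, size=12)
        while len(set(labels)) < 2:
            labels = rng.integers(0, 2, size=12)
        assert -1.0 <= silhouette(points, labels).s <= 1.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((3, 2)), [1, 1, 1])


class TestProject2D:
    def test_2d_input_is_rotation(self, rng):
        points = rng.normal(size=(20, 2)) @ np.array([[3.0, 0.0], [0.0, 1.0]])
        coords = project_2d(points, "pca")
        # distances are preserved by an orthogonal map of full-rank 2-D data
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(coords), pdist(points), atol=1e-8)

    def test_deterministic(self, rng):
        x = rng.normal(size=(10, 5))
        np.testing.assert_array_equal(project_2d(x, "pca"), project_2d(x, "pca"))

    def test_collinear_points_stay_collinear(self):
        direction = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        points = np.outer([0.0, 1.0, 2.0], direction)
        coords = project_2d(points, "pca")
        # second principal axis carries no variance
        assert np.abs(coords[:, 1]).max() < 1e-9

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            project_2d(np.zeros((2, 4)), "pca")

    def test_unknown_method(self, rng):
        with pytest.raises(KeyError):
            project_2d(rng.normal(size=(5, 3)), "tsne")
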