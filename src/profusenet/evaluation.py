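"""Classification metrics, AUCs, bootstrap CIs, paired tests, silhouette.

The positive class throughout is the disease label ("CML", encoded 1);
"Control" is encoded 0.  Metrics with a zero denominator return 0 with a
warning, matching common tooling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata, t as t_dist

POSITIVE_NAME = "CML"
NEGATIVE_NAME = "Control"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class MetricReport:
    accuracy: float
    per_class: dict[str, ClassMetrics]
    macro: ClassMetrics
    weighted: ClassMetrics

    def to_dict(self) -> dict:
        return asdict(self)

    def format_table(self) -> str:
        """Human-readable classification report (class rows + averages)."""
        lines = [f"{'':18s}{'precision':>10s}{'recall':>10s}{'f1-score':>10s}{'support':>10s}", ""]
        for name in (NEGATIVE_NAME, POSITIVE_NAME):
            m = self.per_class[name]
            lines.append(
                f"{name:18s}{m.precision:>10.3f}{m.recall:>10.3f}"
                f"{m.f1:>10.3f}{m.support:>10d}"
            )
        total = self.macro.support
        lines.append("")
        lines.append(f"{'accuracy':18s}{'':>10s}{'':>10s}{self.accuracy:>10.3f}{total:>10d}")
        for label, m in (("macro avg", self.macro), ("weighted avg", self.weighted)):
            lines.append(
                f"{label:18s}{m.precision:>10.3f}{m.recall:>10.3f}"
                f"{m.f1:>10.3f}{m.support:>10d}"
            )
        return "\n".join(lines)


@dataclass
class BootstrapCI:
    point: float
    lower: float
    upper: float
    B: int
    seed: int
    redraws: int = 0


@dataclass
class TTestResult:
    statistic: float
    pvalue: float
    n: int
    mean_difference: float
    degenerate: bool = False


@dataclass
class SilhouetteResult:
    s: float
    per_point: np.ndarray
    a: np.ndarray
    b: np.ndarray


@dataclass
class EvalReport:
    confusion: ConfusionCounts
    metrics: MetricReport
    roc_auc: float
    pr_auc: float
    cis: dict[str, BootstrapCI] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion": asdict(self.confusion),
            "metrics": self.metrics.to_dict(),
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "cis": {k: asdict(v) for k, v in self.cis.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _as_binary(arr) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype.kind in "USO":
        arr = (arr == POSITIVE_NAME).astype(int)
    arr = arr.astype(int)
    if not set(np.unique(arr)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1 or Control/CML)")
    return arr


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts with CML (1) as the positive class."""
    y_true = _as_binary(y_true)
    y_pred = _as_binary(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; returning 0", stacklevel=3)
        return 0.0
    return num / den


def _prf(tp: int, fp: int, fn: int, support: int, name: str) -> ClassMetrics:
    precision = _safe_div(tp, tp + fp, f"{name} precision")
    recall = _safe_div(tp, tp + fn, f"{name} recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, f"{name} F1")
    return ClassMetrics(precision=precision, recall=recall, f1=f1, support=support)


def classification_metrics(c: ConfusionCounts) -> MetricReport:
    """Accuracy plus per-class / macro / weighted precision, recall and F1."""
    if c.total == 0:
        raise ValueError("cannot compute metrics for zero samples")
    accuracy = (c.tp + c.tn) / c.total
    pos = _prf(c.tp, c.fp, c.fn, c.tp + c.fn, POSITIVE_NAME)
    # the negative class seen as its own positive: tn/fn/fp swap roles
    neg = _prf(c.tn, c.fn, c.fp, c.tn + c.fp, NEGATIVE_NAME)
    per_class = {NEGATIVE_NAME: neg, POSITIVE_NAME: pos}
    macro = ClassMetrics(
        precision=(neg.precision + pos.precision) / 2,
        recall=(neg.recall + pos.recall) / 2,
        f1=(neg.f1 + pos.f1) / 2,
        support=c.total,
    )
    w_neg = neg.support / c.total
    w_pos = pos.support / c.total
    weighted = ClassMetrics(
        precision=w_neg * neg.precision + w_pos * pos.precision,
        recall=w_neg * neg.recall + w_pos * pos.recall,
        f1=w_neg * neg.f1 + w_pos * pos.f1,
        support=c.total,
    )
    return MetricReport(accuracy=accuracy, per_class=per_class,
                        macro=macro, weighted=weighted)


def roc_auc(scores, labels) -> float:
    """ROC-AUC via the Mann-Whitney pair statistic (ties count half).

    Equivalent to trapezoidal integration of the ROC curve over all
    thresholds.
    """
    labels = _as_binary(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC-AUC")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(scores, labels) -> float:
    """Step-wise integration of precision over recall (average precision)."""
    labels = _as_binary(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("both classes must be present for PR-AUC")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels)
    predicted_pos = np.arange(1, len(labels) + 1)
    # only evaluate at distinct-threshold boundaries (last row of each tie group)
    boundary = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    precision = tp[boundary] / predicted_pos[boundary]
    recall = tp[boundary] / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(((recall - recall_prev) * precision).sum())


def bootstrap_ci(
    metric_fn,
    y_true,
    scores_or_preds,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapCI:
    """Percentile bootstrap CI over resamples of the evaluation set.

    Resamples that lack one of the two classes are redrawn (counted in
    ``redraws``) so that class-dependent metrics stay well defined.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    y_true = np.asarray(y_true)
    s = np.asarray(scores_or_preds)
    n = len(y_true)
    rng = np.random.default_rng(seed)
    binary = _as_binary(y_true)
    values = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if 0 < binary[idx].sum() < n:
                break
            redraws += 1
        values[b] = metric_fn(y_true[idx], s[idx])
    alpha = (1.0 - level) / 2.0
    lower, upper = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(
        point=float(metric_fn(y_true, s)),
        lower=float(lower),
        upper=float(upper),
        B=B,
        seed=seed,
        redraws=redraws,
    )


def paired_ttest(metric_runs_a, metric_runs_b) -> TTestResult:
    """Two-tailed paired t-test on per-run metric differences."""
    a = np.asarray(metric_runs_a, dtype=float)
    b = np.asarray(metric_runs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("runs must be equal-length 1-D vectors")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 paired runs")
    diffs = a - b
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, 1.0, n, 0.0)
        # constant nonzero difference: deterministic, flagged degenerate
        return TTestResult(np.inf if mean > 0 else -np.inf, 0.0, n, float(mean),
                           degenerate=True)
    statistic = mean / (sd / np.sqrt(n))
    pvalue = 2.0 * float(t_dist.sf(abs(statistic), n - 1))
    return TTestResult(float(statistic), pvalue, n, float(mean))


def silhouette(points, labels) -> SilhouetteResult:
    """Mean silhouette coefficient with Euclidean distances.

    Per point: s = (b - a) / max(a, b) where a is the mean distance to the
    point's own cluster and b the smallest mean distance to another cluster.
    Singleton-cluster points get s = 0.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    dist = cdist(points, points)
    a = np.zeros(n)
    b = np.full(n, np.inf)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        for cls in classes:
            members = labels == cls
            if cls == labels[i]:
                if n_own > 1:
                    a[i] = dist[i, own].sum() / (n_own - 1)
            else:
                b[i] = min(b[i], dist[i, members].mean())
        if n_own == 1:
            s[i] = 0.0  # singleton convention
        else:
            denom = max(a[i], b[i])
            s[i] = 0.0 if denom == 0 else (b[i] - a[i]) / denom
    return SilhouetteResult(s=float(s.mean()), per_point=s, a=a, b=b)


def project_2d(vectors, method: str = "pca", seed: int = 0) -> np.ndarray:
    """Project row vectors to 2-D for cluster-separation analysis.

    ``pca`` (default) is deterministic with a fixed sign convention;
    ``umap`` is used if the optional dependency is installed.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[0] < 3:
        raise ValueError("need at least 3 vectors to project")
    if method == "pca":
        centered = vectors - vectors.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        components = vt[:2]
        for i in range(components.shape[0]):  # fix sign for determinism
            j = np.argmax(np.abs(components[i]))
            if components[i, j] < 0:
                components[i] *= -1
        return centered @ components.T
    if method == "umap":
        import umap

        reducer = umap.UMAP(n_components=2, random_state=seed, init="pca")
        return np.asarray(reducer.fit_transform(vectors), dtype=float)
    raise KeyError(f"unknown projection method: {method!r}")


def evaluate_predictions(
    y_true,
    scores,
    B: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalReport:
    """Full report from positive-class scores: confusion, metrics, AUCs, CIs."""
    y_true = _as_binary(y_true)
    scores = np.asarray(scores, dtype=float)
    preds = (scores >= threshold).astype(int)
    counts = confusion(y_true, preds)
    report = EvalReport(
        confusion=counts,
        metrics=classification_metrics(counts),
        roc_auc=roc_auc(scores, y_true),
        pr_auc=pr_auc(scores, y_true),
    )
    report.cis["accuracy"] = bootstrap_ci(
        lambda yt, yp: classification_metrics(confusion(yt, yp)).accuracy,
        y_true, preds, B=B, seed=seed,
    )
    report.cis["roc_auc"] = bootstrap_ci(roc_auc_metric, y_true, scores, B=B, seed=seed)
    return report


def roc_auc_metric(y_true, scores) -> float:
    """Argument-order adapter so AUC can be used as a bootstrap metric_fn."""
    return roc_auc(scores, y_true)
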