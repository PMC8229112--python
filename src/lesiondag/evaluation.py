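"""Metrics and statistical comparisons.

Balanced accuracy (BACC) is the macro-average of per-class recalls; for two
classes this reduces to (sensitivity + specificity) / 2.  AUROC is the
Mann-Whitney probability that a random positive outranks a random negative
(ties counted half).  Model comparison follows a two-stage protocol: a paired
t test for two models, and Kruskal-Wallis with Dunn's rank-based post hoc for
three or more, summarized as group ranks (methods with no significant
pairwise difference share a rank) plus, per method, the set of significantly
worse methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score as _sk_auroc

from .ensemble import PairwiseScoreSet, DDAGStructure, ddag_predict_batch

__all__ = [
    "MetricsReport",
    "ComparisonResult",
    "binarize",
    "confusion",
    "sensitivity",
    "specificity",
    "bacc",
    "auroc_one_vs_rest",
    "metrics_report",
    "paired_t",
    "kruskal_dunn",
    "root_sweep",
]


def binarize(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Decision labels from probability rows.

    Binary case: positive (class 0, the first column) iff p_0 >= threshold.
    Multiclass: argmax (the threshold is recorded by callers but plays no
    role beyond the binary case).
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    if probs.shape[1] == 2:
        return np.where(probs[:, 0] >= threshold, 0, 1)
    return probs.argmax(axis=1)


def confusion(y_true: np.ndarray, y_pred: np.ndarray, K: int) -> np.ndarray:
    """K x K confusion counts; rows index the true class, columns the
    predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    for y in (y_true, y_pred):
        if len(y) and (y.min() < 0 or y.max() >= K):
            raise ValueError("label out of range")
    return _sk_confusion(y_true, y_pred, labels=np.arange(K))


def sensitivity(cm: np.ndarray, class_id: int) -> float:
    """One-vs-rest recall TP / (TP + FN) for ``class_id``."""
    cm = np.asarray(cm)
    tp = cm[class_id, class_id]
    support = cm[class_id].sum()
    if support == 0:
        raise ValueError(f"class {class_id} has no true samples")
    return float(tp / support)


def specificity(cm: np.ndarray, class_id: int) -> float:
    """One-vs-rest true-negative rate TN / (TN + FP) for ``class_id``."""
    cm = np.asarray(cm)
    tp = cm[class_id, class_id]
    fp = cm[:, class_id].sum() - tp
    fn = cm[class_id].sum() - tp
    tn = cm.sum() - tp - fp - fn
    if tn + fp == 0:
        raise ValueError(f"class {class_id} has no true negatives or false positives")
    return float(tn / (tn + fp))


def bacc(cm: np.ndarray) -> float:
    """Balanced accuracy: macro-average of per-class sensitivities.

    For K = 2 this equals (sensitivity + specificity) / 2, since the recall
    of the negative class is the positive class's specificity.
    """
    cm = np.asarray(cm)
    return float(np.mean([sensitivity(cm, c) for c in range(cm.shape[0])]))


def auroc_one_vs_rest(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUROC of per-sample confidences against binary truth (1 = positive)."""
    truth = np.asarray(truth, dtype=int)
    if len(np.unique(truth)) < 2:
        raise ValueError("both truth labels must be present")
    return float(_sk_auroc(truth, np.asarray(scores, dtype=float)))


@dataclass
class MetricsReport:
    """Confusion matrix plus per-class sensitivity / specificity / AUROC,
    BACC, and the decision threshold used."""

    confusion: np.ndarray
    sensitivity: dict[int, float]
    specificity: dict[int, float]
    bacc: float
    auroc: dict[int, float]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "sensitivity": {str(k): v for k, v in self.sensitivity.items()},
            "specificity": {str(k): v for k, v in self.specificity.items()},
            "bacc": self.bacc,
            "auroc": {str(k): v for k, v in self.auroc.items()},
            "threshold": self.threshold,
        }


def metrics_report(
    y_true: np.ndarray, probs: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Full evaluation of probability rows against true labels."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    y_true = np.asarray(y_true, dtype=int)
    K = probs.shape[1]
    y_pred = binarize(probs, threshold)
    cm = confusion(y_true, y_pred, K)
    auroc = {}
    for c in range(K):
        onevsrest = (y_true == c).astype(int)
        auroc[c] = (
            auroc_one_vs_rest(probs[:, c], onevsrest)
            if len(np.unique(onevsrest)) == 2
            else float("nan")
        )
    return MetricsReport(
        confusion=cm,
        sensitivity={c: sensitivity(cm, c) for c in range(K)},
        specificity={c: specificity(cm, c) for c in range(K)},
        bacc=bacc(cm),
        auroc=auroc,
        threshold=threshold,
    )


def paired_t(scores_a: np.ndarray, scores_b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t test on per-sample score differences."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-d score vectors with n >= 2")
    if np.var(a - b) == 0:
        raise ValueError("paired differences have zero variance; t test undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class ComparisonResult:
    """Outcome of the multi-group comparison.

    ``group_ranks`` start at 1 (best mean value); groups with no significant
    pairwise difference share a rank.  ``worse_than[name]`` is the set of
    group names significantly worse than ``name``.
    """

    names: list[str]
    statistic: float
    omnibus_p: float
    alpha: float
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    group_ranks: dict[str, int] = field(default_factory=dict)
    worse_than: dict[str, set[str]] = field(default_factory=dict)


def _dunn_pairwise(groups: list[np.ndarray], adjust: str | None) -> np.ndarray:
    """Two-sided Dunn z-test p-values for all group pairs, with tie
    correction; optional Bonferroni adjustment."""
    pooled = np.concatenate(groups)
    n = np.array([len(g) for g in groups])
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    k = len(groups)
    pvals = np.ones((k, k))
    n_comparisons = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / n[i] + 1.0 / n[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            if adjust == "bonferroni":
                p = min(1.0, p * n_comparisons)
            pvals[i, j] = pvals[j, i] = p
    return pvals


def kruskal_dunn(
    groups: list[np.ndarray],
    alpha: float = 0.05,
    names: list[str] | None = None,
    adjust: str | None = None,
) -> ComparisonResult:
    """Kruskal-Wallis omnibus with Dunn's post hoc and group-rank summary.

    If the omnibus p is below ``alpha``, all pairwise Dunn comparisons are
    run; group ranks are assigned by ordering groups by mean value (best
    first) and merging adjacent groups whose pairwise difference is not
    significant.  Without omnibus significance all groups share rank 1.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    if names is None:
        names = [f"group{i}" for i in range(len(groups))]
    if len(names) != len(groups):
        raise ValueError("names must align with groups")

    try:
        with np.errstate(invalid="ignore"):
            h, p_omni = stats.kruskal(*groups)
        if np.isnan(h):  # every pooled value identical
            h, p_omni = 0.0, 1.0
    except ValueError:
        h, p_omni = 0.0, 1.0
    result = ComparisonResult(
        names=list(names), statistic=float(h), omnibus_p=float(p_omni), alpha=alpha
    )
    order = np.argsort([-g.mean() for g in groups])  # best mean first
    if p_omni >= alpha:
        result.group_ranks = {nm: 1 for nm in names}
        result.worse_than = {nm: set() for nm in names}
        return result

    pvals = _dunn_pairwise(groups, adjust)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            result.pairwise_p[(names[i], names[j])] = float(pvals[i, j])

    means = np.array([g.mean() for g in groups])
    ranks: dict[str, int] = {}
    current_rank = 0
    cluster: list[int] = []
    for gi in order:
        significant_vs_cluster = all(pvals[gi, cj] < alpha for cj in cluster)
        if not cluster or significant_vs_cluster:
            current_rank += 1
            cluster = [gi]
        else:
            cluster.append(gi)
        ranks[names[gi]] = current_rank
    result.group_ranks = ranks
    result.worse_than = {
        names[i]: {
            names[j]
            for j in range(len(groups))
            if j != i and pvals[i, j] < alpha and means[i] > means[j]
        }
        for i in range(len(groups))
    }
    return result


def root_sweep(
    score_sets: list[PairwiseScoreSet], y_true: np.ndarray, K: int
) -> dict[tuple[int, int], float]:
    """BACC of the DDAG for every possible root pair.

    The elimination order is the root pair followed by the remaining classes
    in index order, matching :func:`lesiondag.ensemble.select_root`.
    """
    y_true = np.asarray(y_true, dtype=int)
    table: dict[tuple[int, int], float] = {}
    for i in range(K):
        for j in range(i + 1, K):
            rest = [c for c in range(K) if c not in (i, j)]
            structure = DDAGStructure(class_order=tuple([i, j, *rest]))
            y_pred, _ = ddag_predict_batch(score_sets, structure)
            table[(i, j)] = bacc(confusion(y_true, y_pred, K))
    return table
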