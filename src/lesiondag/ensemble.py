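"""Aggregation of classifier outputs into a K-class decision.

Two families are implemented.  The decision directed acyclic graph (DDAG)
runs a sequential elimination over the K(K-1)/2 pairwise confidences: the
first two classes of the maintained order are compared, the loser is removed,
and after exactly K-1 comparisons a single class remains.  A class that wins
every one of its pairwise comparisons (a Condorcet winner) is returned for
every elimination order.  The five classical fusion rules (arithmetic mean,
product, maximum confidence, geometric mean, and max-win voting) instead
merge m multiclass probability matrices row-wise into one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AGGREGATION_METHODS",
    "PairwiseScoreSet",
    "DDAGStructure",
    "EvaluationRecord",
    "ddag_predict",
    "ddag_predict_batch",
    "select_root",
    "aggregate",
    "pairwise_from_multiclass",
]

#: Names of the supported probability fusion rules.
AGGREGATION_METHODS: tuple[str, ...] = ("avg", "prod", "mconf", "gmean", "max_win")

_PROB_FLOOR = 1e-12  # floor before products so the normalizer cannot vanish


@dataclass
class PairwiseScoreSet:
    """For one sample: unordered pair {i, j} -> (p_i, p_j) with p_i + p_j = 1."""

    scores: dict[tuple[int, int], tuple[float, float]]

    def __post_init__(self) -> None:
        normalized = {}
        for pair, (pi, pj) in self.scores.items():
            i, j = pair
            if i >= j:
                raise ValueError(f"pair {pair} must be ordered i < j")
            if abs(pi + pj - 1.0) > 1e-9:
                raise ValueError(f"confidences of pair {pair} must sum to 1")
            normalized[(i, j)] = (float(pi), float(pj))
        self.scores = normalized

    def confidence(self, a: int, b: int) -> float:
        """Confidence that the sample belongs to class ``a`` against ``b``."""
        i, j = min(a, b), max(a, b)
        if (i, j) not in self.scores:
            raise ValueError(f"missing pairwise score for pair {(i, j)}")
        pi, pj = self.scores[(i, j)]
        return pi if a == i else pj


@dataclass(frozen=True)
class DDAGStructure:
    """Elimination order over the K classes; the first two elements form the
    root pair."""

    class_order: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(self.class_order)
        if k < 2 or sorted(self.class_order) != list(range(k)):
            raise ValueError("class_order must be a permutation of 0..K-1 with K >= 2")

    @property
    def root_pair(self) -> tuple[int, int]:
        a, b = self.class_order[:2]
        return (min(a, b), max(a, b))


@dataclass
class EvaluationRecord:
    """Outcome of one DDAG pass: the decision, the evaluation path (pair
    compared, class eliminated) and the node count K-1."""

    predicted_class: int
    path: list[tuple[tuple[int, int], int]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.path)


def ddag_predict(scores: PairwiseScoreSet, structure: DDAGStructure) -> EvaluationRecord:
    """Run the DDAG elimination for one sample.

    The first two classes of the remaining list are compared and the one with
    the smaller pairwise confidence is removed; on an exact tie the class
    with the larger index is eliminated.  Exactly K-1 comparisons are made.
    """
    remaining = list(structure.class_order)
    path: list[tuple[tuple[int, int], int]] = []
    while len(remaining) > 1:
        a, b = remaining[0], remaining[1]
        pa = scores.confidence(a, b)
        pb = scores.confidence(b, a)
        if pa > pb:
            loser = b
        elif pb > pa:
            loser = a
        else:
            loser = max(a, b)
        pair = (min(a, b), max(a, b))
        path.append((pair, loser))
        remaining.remove(loser)
    return EvaluationRecord(predicted_class=remaining[0], path=path)


def ddag_predict_batch(
    score_sets: list[PairwiseScoreSet], structure: DDAGStructure
) -> tuple[np.ndarray, list[EvaluationRecord]]:
    """Elementwise :func:`ddag_predict`; order preserved."""
    records = [ddag_predict(s, structure) for s in score_sets]
    return np.array([r.predicted_class for r in records], dtype=int), records


def select_root(per_task_scores: dict[tuple[int, int], float]) -> DDAGStructure:
    """Place the pair with the best validation score at the DDAG root.

    Ties go to the lexicographically smallest pair; the remaining classes are
    appended in index order.
    """
    if not per_task_scores:
        raise ValueError("per_task_scores must be non-empty")
    best_pair = min(sorted(per_task_scores), key=lambda p: -per_task_scores[p])
    classes = sorted({c for pair in per_task_scores for c in pair})
    rest = [c for c in classes if c not in best_pair]
    return DDAGStructure(class_order=tuple([*best_pair, *rest]))


def aggregate(prob_stack: list[np.ndarray] | np.ndarray, method: str) -> np.ndarray:
    """Fuse m multiclass probability matrices row-wise.

    avg: arithmetic mean across classifiers.  prod: product across
    classifiers, renormalized over classes.  mconf: per-class maximum across
    classifiers, renormalized.  gmean: m-th root of the product,
    renormalized.  max_win: each classifier casts one vote for its argmax
    class (ties split equally) and the votes are averaged.  Every output row
    sums to 1.
    """
    stack = np.asarray(prob_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("prob_stack must be m matrices of identical shape (n, K)")
    m = stack.shape[0]
    if m == 0:
        raise ValueError("need at least one classifier")
    if method == "avg":
        out = stack.mean(axis=0)
    elif method == "prod":
        out = np.maximum(stack, _PROB_FLOOR).prod(axis=0)
    elif method == "mconf":
        out = stack.max(axis=0)
    elif method == "gmean":
        out = np.maximum(stack, _PROB_FLOOR).prod(axis=0) ** (1.0 / m)
    elif method == "max_win":
        row_max = stack.max(axis=2, keepdims=True)
        votes = (stack == row_max).astype(float)
        votes /= votes.sum(axis=2, keepdims=True)  # split tied argmaxes
        out = votes.mean(axis=0)
    else:
        raise ValueError(f"unknown aggregation method: {method!r}")
    return out / out.sum(axis=1, keepdims=True)


def pairwise_from_multiclass(row: np.ndarray) -> PairwiseScoreSet:
    """Derive pairwise confidences from one multiclass probability row via
    p_i / (p_i + p_j) per pair; a zero pair-sum gets the tie value 0.5."""
    row = np.asarray(row, dtype=float).ravel()
    K = len(row)
    scores: dict[tuple[int, int], tuple[float, float]] = {}
    for i in range(K):
        for j in range(i + 1, K):
            s = row[i] + row[j]
            if s == 0.0:
                warnings.warn(f"pair {(i, j)} has zero total probability; tie assigned",
                              stacklevel=2)
                scores[(i, j)] = (0.5, 0.5)
            else:
                scores[(i, j)] = (row[i] / s, row[j] / s)
    return PairwiseScoreSet(scores=scores)
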