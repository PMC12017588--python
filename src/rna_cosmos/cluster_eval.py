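"""Affinity-propagation clustering of similarity matrices and evaluation
against known class labels.

Affinity propagation is a natural fit for exemplar-based structure
clustering: it consumes similarity scores directly, needs no preset
cluster count and no edge threshold. Evaluation offers purity, pairwise
(co-clustering) precision/recall/accuracy, an optimal-mapping accuracy
variant, and the average subclass split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "ClusterResult",
    "EvalReport",
    "affinity_cluster",
    "purity",
    "pairwise_metrics",
    "mapped_accuracy",
    "subclass_split",
    "evaluate",
]


@dataclass(frozen=True)
class ClusterResult:
    """Labels and exemplars from one affinity-propagation run."""

    ids: tuple[str, ...]
    labels: tuple[int, ...]
    exemplars: tuple[str, ...]
    n_clusters: int
    converged: bool = True


@dataclass(frozen=True)
class EvalReport:
    """Clustering quality against true class labels."""

    purity: float
    accuracy: float
    precision: float
    recall: float
    n_clusters: int
    avg_subclass_split: float


def affinity_cluster(
    ids: Sequence[str],
    matrix: np.ndarray,
    *,
    preference: float | str = "median",
    damping: float = 0.9,
    seed: int = 0,
    max_iter: int = 1000,
    convergence_iter: int = 100,
) -> ClusterResult:
    """Cluster a symmetric similarity matrix with affinity propagation.

    ``preference="median"`` uses the median off-diagonal similarity.
    Items are processed in id-sorted order internally (the seeded
    symmetry-breaking jitter is applied in that order), so permuting the
    input rows permutes the output labels identically. On non-convergence
    a warning is issued and every item becomes its own cluster with
    ``converged=False``.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(ids)
    if matrix.shape != (n, n):
        raise ValueError(f"matrix shape {matrix.shape} does not match {n} ids")
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")
    if not (0.5 <= damping < 1.0):
        raise ValueError(f"damping must be in [0.5, 1), got {damping}")

    order = np.argsort(np.asarray(ids, dtype=object))
    sorted_ids = [ids[i] for i in order]
    S = matrix[np.ix_(order, order)]

    if preference == "median":
        if n > 1:
            off = S[~np.eye(n, dtype=bool)]
            pref = float(np.median(off))
        else:
            pref = 0.0
    else:
        pref = float(preference)

    if n == 1:
        return ClusterResult(tuple(ids), (0,), (ids[0],), 1, True)

    ap = AffinityPropagation(
        affinity="precomputed",
        preference=pref,
        damping=damping,
        max_iter=max_iter,
        convergence_iter=convergence_iter,
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ap.fit(S)
    converged = not any(
        issubclass(w.category, ConvergenceWarning) for w in caught
    )

    centers = np.asarray(ap.cluster_centers_indices_)
    if centers is None or len(centers) == 0 or (ap.labels_ == -1).any():
        warnings.warn(
            "affinity propagation did not converge; returning singleton clusters",
            stacklevel=2,
        )
        labels_sorted = list(range(n))
        exemplars_sorted = list(sorted_ids)
        converged = False
    else:
        # relabel clusters 0..K-1 by exemplar position in id-sorted order
        relabel = {old: new for new, old in enumerate(sorted(set(ap.labels_)))}
        labels_sorted = [relabel[l] for l in ap.labels_]
        exemplars_sorted = [
            sorted_ids[centers[old]]
            for old in sorted(set(ap.labels_))
        ]

    # map back to the caller's order
    labels = [0] * n
    for pos_sorted, pos_orig in enumerate(order):
        labels[pos_orig] = labels_sorted[pos_sorted]
    return ClusterResult(
        ids=tuple(ids),
        labels=tuple(labels),
        exemplars=tuple(exemplars_sorted),
        n_clusters=len(set(labels)),
        converged=converged,
    )


def _check_lengths(pred: Sequence, true: Sequence, minimum: int = 1) -> None:
    if len(pred) != len(true):
        raise ValueError(
            f"label vectors differ in length: {len(pred)} vs {len(true)}"
        )
    if len(pred) < minimum:
        raise ValueError(f"need at least {minimum} items")


def purity(pred: Sequence, true: Sequence) -> float:
    """Fraction of items in the majority true class of their cluster."""
    _check_lengths(pred, true, 1)
    clusters: dict = {}
    for p, t in zip(pred, true):
        clusters.setdefault(p, []).append(t)
    total = sum(
        max(members.count(c) for c in set(members))
        for members in clusters.values()
    )
    return total / len(pred)


def _pair_counts(pred: Sequence, true: Sequence) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) over all unordered item pairs via contingency counts."""
    contingency: dict = {}
    pred_sizes: dict = {}
    true_sizes: dict = {}
    for p, t in zip(pred, true):
        contingency[(p, t)] = contingency.get((p, t), 0) + 1
        pred_sizes[p] = pred_sizes.get(p, 0) + 1
        true_sizes[t] = true_sizes.get(t, 0) + 1
    tp = sum(comb(c, 2) for c in contingency.values())
    same_pred = sum(comb(c, 2) for c in pred_sizes.values())
    same_true = sum(comb(c, 2) for c in true_sizes.values())
    total = comb(len(pred), 2)
    fp = same_pred - tp
    fn = same_true - tp
    tn = total - tp - fp - fn
    return tp, fp, fn, tn


def pairwise_metrics(pred: Sequence, true: Sequence) -> tuple[float, float, float]:
    """Co-clustering precision, recall and accuracy over all item pairs.

    A pair is TP when the two items share both predicted cluster and true
    class; accuracy is the Rand index. 0/0 ratios are taken as 1.0.
    """
    _check_lengths(pred, true, 2)
    tp, fp, fn, tn = _pair_counts(pred, true)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    accuracy = (tp + tn) / (tp + fp + fn + tn)
    return precision, recall, accuracy


def mapped_accuracy(pred: Sequence, true: Sequence) -> float:
    """Accuracy under the optimal one-to-one cluster-to-class assignment."""
    _check_lengths(pred, true, 1)
    pred_ids = sorted(set(pred))
    true_ids = sorted(set(true))
    cost = np.zeros((len(pred_ids), len(true_ids)))
    for p, t in zip(pred, true):
        cost[pred_ids.index(p), true_ids.index(t)] -= 1
    rows, cols = linear_sum_assignment(cost)
    return -cost[rows, cols].sum() / len(pred)


def subclass_split(pred: Sequence, true: Sequence) -> float:
    """Mean number of predicted clusters each true class is scattered over."""
    _check_lengths(pred, true, 1)
    spread: dict = {}
    for p, t in zip(pred, true):
        spread.setdefault(t, set()).add(p)
    return sum(len(s) for s in spread.values()) / len(spread)


def evaluate(
    pred: Sequence, true: Sequence, *, metric_style: str = "pairwise"
) -> EvalReport:
    """Full evaluation report; ``metric_style`` is 'pairwise' or 'mapped'."""
    precision, recall, accuracy = pairwise_metrics(pred, true)
    if metric_style == "mapped":
        accuracy = mapped_accuracy(pred, true)
    elif metric_style != "pairwise":
        raise ValueError(f"unknown metric style {metric_style!r}")
    return EvalReport(
        purity=purity(pred, true),
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        n_clusters=len(set(pred)),
        avg_subclass_split=subclass_split(pred, true),
    )
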