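"""Cross-validated benchmarking of pair scores: ROC and precision-recall.

True-positive and true-negative pair sets are partitioned independently
into k folds; for each fold the clue LR tables are re-estimated on the
remaining folds and the held-out pairs are scored.  Pooled held-out scores
across folds feed a single ROC / PR curve, so every pair contributes
exactly once.

Because the negative set is "no reported interaction" rather than verified
non-interaction, it contains undiscovered true interactions; the FPR
computed against it is therefore an upper bound on the true FPR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bayes import DmiBayesClassifier, DmiMatch
from .io import NsEvidenceTable, PairSet

__all__ = [
    "FoldAssignment",
    "CurvePoint",
    "CVResult",
    "kfold_split",
    "curve_points",
    "roc_curve",
    "pr_curve",
    "cross_validate",
]

Pair = tuple[str, str]


@dataclass
class FoldAssignment:
    """Per-pair fold indices for the TP and TN lists (order-aligned)."""

    k: int
    seed: int
    tp_folds: np.ndarray
    tn_folds: np.ndarray


@dataclass(frozen=True)
class CurvePoint:
    threshold: float
    tpr: float
    fpr: float
    precision: float
    recall: float


@dataclass
class CVResult:
    scores: dict[Pair, float]
    labels: dict[Pair, int]
    roc_points: list[CurvePoint]
    auc: float
    pr_points: list[CurvePoint]
    auprc: float
    fold_assignment: FoldAssignment


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = fold
    return folds


def kfold_split(pairs: PairSet, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Seeded random k-fold partition; TP and TN are split independently and
    fold sizes within each set differ by at most one."""
    if k < 2:
        raise ValueError(f"fold count k={k} must be at least 2")
    if pairs.n_tp < k or pairs.n_tn < k:
        raise ValueError(f"each set must have at least k={k} members")
    rng = np.random.default_rng(seed)
    return FoldAssignment(
        k, seed, _fold_indices(pairs.n_tp, k, rng), _fold_indices(pairs.n_tn, k, rng)
    )


def curve_points(
    scores: Sequence[float], labels: Sequence[int]
) -> list[CurvePoint]:
    """TPR/FPR/precision/recall at every distinct score threshold, descending.

    Tied scores collapse to a single threshold step.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.concatenate([distinct, [s.size - 1]])  # last index of each tie group
    tp = np.cumsum(y == 1)[idx]
    fp = np.cumsum(y == 0)[idx]
    return [
        CurvePoint(
            threshold=float(s[i]),
            tpr=float(t) / n_pos,
            fpr=float(f) / n_neg,
            precision=float(t) / (t + f),
            recall=float(t) / n_pos,
        )
        for i, t, f in zip(idx, tp, fp)
    ]


def roc_curve(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[CurvePoint], float]:
    """ROC curve points and trapezoidal AUC (curve anchored at (0,0))."""
    points = curve_points(scores, labels)
    fpr = np.concatenate([[0.0], [p.fpr for p in points]])
    tpr = np.concatenate([[0.0], [p.tpr for p in points]])
    return points, float(np.trapezoid(tpr, fpr))


def pr_curve(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[CurvePoint], float]:
    """Precision-recall curve points and the step-integral area
    (sum of precision x recall increments, no interpolation)."""
    points = curve_points(scores, labels)
    recall = np.array([p.recall for p in points])
    precision = np.array([p.precision for p in points])
    d_recall = np.diff(np.concatenate([[0.0], recall]))
    return points, float((precision * d_recall).sum())


def cross_validate(
    matches: Sequence[DmiMatch],
    pairs: PairSet,
    ns_table: NsEvidenceTable | None = None,
    k: int = 5,
    seed: int = 0,
    alpha: float = 0.0,
    lr_cap: float = 1e6,
    policy: str = "max",
) -> CVResult:
    """k-fold cross-validated pair scoring with pooled curves.

    For each fold the classifier is fitted on the other k-1 folds' pairs and
    the held-out pairs are scored (interface LR aggregated per pair, times
    NS LR when a table is supplied).  Pairs with no interface match and no
    NS evidence keep the neutral score 1, so the curve denominators stay
    fixed across evidence configurations.
    """
    assignment = kfold_split(pairs, k, seed)
    tp = pairs.positives
    tn = pairs.negatives
    by_pair: dict[Pair, list[DmiMatch]] = {}
    for m in matches:
        by_pair.setdefault(m.pair, []).append(m)

    scores: dict[Pair, float] = {}
    labels: dict[Pair, int] = {}
    for fold in range(k):
        train = PairSet(
            [p for p, f in zip(tp, assignment.tp_folds) if f != fold],
            [p for p, f in zip(tn, assignment.tn_folds) if f != fold],
        )
        test_tp = [p for p, f in zip(tp, assignment.tp_folds) if f == fold]
        test_tn = [p for p, f in zip(tn, assignment.tn_folds) if f == fold]
        train_pairs = set(train.positives) | set(train.negatives)
        train_matches = [m for m in matches if m.pair in train_pairs]
        clf = DmiBayesClassifier(alpha=alpha, lr_cap=lr_cap, policy=policy).fit(
            train_matches, train
        )
        test_pairs = test_tp + test_tn
        # a route absent from the training fold cannot be scored; its
        # matches fall back to the neutral no-evidence score
        test_matches = [
            m
            for p in test_pairs
            for m in by_pair.get(p, [])
            if m.method in clf.lr_tables_
        ]
        preds = clf.predict_pairs(test_matches, test_pairs, ns_table=ns_table)
        for pred, label in zip(preds, [1] * len(test_tp) + [0] * len(test_tn)):
            scores[pred.pair] = pred.lr_final
            labels[pred.pair] = label

    ordered = sorted(scores)
    s = [scores[p] for p in ordered]
    y = [labels[p] for p in ordered]
    roc_points, auc = roc_curve(s, y)
    pr_points, auprc = pr_curve(s, y)
    return CVResult(scores, labels, roc_points, auc, pr_points, auprc, assignment)
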