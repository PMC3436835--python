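"""Evaluation harness: precision/recall sweeps, calibration binning,
k-fold cross-validation and SNP-call contingency metrics.

A true positive at a score threshold is a correctly mapped read whose
score is at or above the threshold; a false positive is an incorrectly
mapped read at or above it; a false negative is a correctly mapped read
below it. Precision is TP/(TP+FP), recall TP/(TP+FN).

Two harmonic summaries are provided: ``f_paper`` computes
1/(1/precision + 1/recall) — half the conventional F1 — and
``f1_score`` computes the conventional 2pr/(p+r). Both are kept under
distinct names because published SNP-calling tables sometimes use the
former definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import LabeledExample, LogisticModel, fit_logistic, predict_probabilities, prob_to_mapq
from .pileup import SnpCall
from .simulate import SnpSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float


@dataclass(frozen=True)
class CalibrationBin:
    bin_index: int  # 1-based
    n: int
    mean_p: float
    mean_predicted_q: float
    theoretical_accuracy: float
    empirical_accuracy: float


@dataclass(frozen=True)
class ContingencyResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_paper: float


def f_paper(precision: float, recall: float) -> float:
    """The harmonic summary as printed in SNP-calling tables:
    F = 1/(1/prec + 1/rec). Note this is half the conventional F1;
    at precision = recall = 1 it equals 0.5. Returns 0 when either
    input is 0."""
    if precision <= 0.0 or recall <= 0.0:
        return 0.0
    return 1.0 / (1.0 / precision + 1.0 / recall)


def f1_score(precision: float, recall: float) -> float:
    """Conventional F1 = 2pr/(p+r)."""
    return 2.0 * f_paper(precision, recall)


def contingency_from_counts(tp: int, fp: int, fn: int) -> ContingencyResult:
    """Derive precision, recall and F from raw contingency counts."""
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return ContingencyResult(
        tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f_paper=f_paper(precision, recall)
    )


def precision_recall_sweep(
    scores: Sequence[float],
    labels: Sequence[bool],
    thresholds: Sequence[float],
) -> list[PRPoint]:
    """TP/FP/FN and precision/recall at each threshold (inclusive >=).

    When no mapping reaches a threshold, precision is defined as 1 by
    convention (logged once).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    points = []
    warned = False
    for t in thresholds:
        above = scores >= t
        tp = int(np.sum(above & y))
        fp = int(np.sum(above & ~y))
        fn = int(np.sum(~above & y))
        if tp + fp == 0 and not warned:
            logger.info("no mappings at threshold %s; precision defined as 1", t)
            warned = True
        precision = tp / (tp + fp) if tp + fp else 1.0
        recall = tp / (tp + fn) if tp + fn else 1.0
        points.append(
            PRPoint(threshold=float(t), tp=tp, fp=fp, fn=fn, precision=precision, recall=recall)
        )
    return points


def calibration_curve(
    predictions: Sequence[float],
    labels: Sequence[bool],
    n_bins: int = 10,
    strategy: str = "width",
    cap: float = 60.0,
) -> list[CalibrationBin]:
    """Group mappings by prediction score and compare accuracies per group.

    ``strategy="width"`` uses equal-width bins on p (0.1-wide for 10
    bins); ``"count"`` uses equal-count (quantile) groups. Each bin
    reports the mean predicted p, the mean Phred-scaled prediction
    Q = -10*log10(1-p), the theoretical accuracy 1 - 10**(-mean Q/10)
    and the empirical fraction of accurate mappings. Empty bins are
    reported with n = 0.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("predictions must lie in [0, 1]")

    if strategy == "width":
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    elif strategy == "count":
        edges = np.quantile(p, np.linspace(0.0, 1.0, n_bins + 1)) if p.size else np.linspace(0.0, 1.0, n_bins + 1)
        edges[0], edges[-1] = 0.0, 1.0
    else:
        raise ValueError(f"unknown binning strategy {strategy!r}")
    # right-inclusive top bin so p = 1 is binned
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, n_bins - 1)

    bins = []
    q_each = np.array([prob_to_mapq(float(v), cap) for v in p]) if p.size else np.empty(0)
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        if n == 0:
            bins.append(
                CalibrationBin(
                    bin_index=b + 1,
                    n=0,
                    mean_p=float("nan"),
                    mean_predicted_q=float("nan"),
                    theoretical_accuracy=float("nan"),
                    empirical_accuracy=float("nan"),
                )
            )
            continue
        mean_p = float(p[mask].mean())
        mean_q = float(q_each[mask].mean())
        bins.append(
            CalibrationBin(
                bin_index=b + 1,
                n=n,
                mean_p=mean_p,
                mean_predicted_q=mean_q,
                theoretical_accuracy=1.0 - 10.0 ** (-mean_q / 10.0),
                empirical_accuracy=float(y[mask].mean()),
            )
        )
    return bins


@dataclass(frozen=True)
class FoldResult:
    fold: int
    test_indices: np.ndarray
    contingency: ContingencyResult
    calibration: list[CalibrationBin]
    accuracy: float


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition into k folds with sizes differing by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need at least k examples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [fold.copy() for fold in np.array_split(perm, k)]


def cross_validate(
    examples: Sequence[LabeledExample],
    k: int = 5,
    seed: int = 0,
    l2: float = 1e-6,
    threshold: float = 0.5,
    n_bins: int = 10,
) -> list[FoldResult]:
    """Standard k-fold cross-validation of the recalibration model.

    Each fold's model is fitted on the other k-1 folds and evaluated on
    the held-out fold: a contingency table at the probability
    ``threshold`` (default 0.5, the documented decision threshold) plus
    a calibration curve.
    """
    folds = kfold_indices(len(examples), k, seed)
    X = np.array([example.features.to_array() for example in examples])
    y = np.array([example.label for example in examples], dtype=bool)
    results = []
    for fold_number, test_idx in enumerate(folds, start=1):
        mask = np.zeros(len(examples), dtype=bool)
        mask[test_idx] = True
        train = [examples[i] for i in np.nonzero(~mask)[0]]
        model = fit_logistic(train, l2=l2)
        p = predict_probabilities(model, X[test_idx])
        y_test = y[test_idx]
        above = p >= threshold
        contingency = ContingencyResult(
            tp=int(np.sum(above & y_test)),
            fp=int(np.sum(above & ~y_test)),
            fn=int(np.sum(~above & y_test)),
            precision=float(np.sum(above & y_test) / max(np.sum(above), 1)),
            recall=float(np.sum(above & y_test) / max(np.sum(y_test), 1)),
            f_paper=0.0,
        )
        contingency = contingency_from_counts(contingency.tp, contingency.fp, contingency.fn)
        results.append(
            FoldResult(
                fold=fold_number,
                test_indices=test_idx,
                contingency=contingency,
                calibration=calibration_curve(p, y_test, n_bins=n_bins),
                accuracy=float(np.mean(above == y_test)),
            )
        )
    return results


def snp_eval(calls: Sequence[SnpCall], truth: Sequence[SnpSpec]) -> ContingencyResult:
    """Contingency metrics for SNP calls against the implanted truth.

    A call is a true positive when both its position and alt allele
    match an implanted SNP; truth entries never called are false
    negatives.
    """
    truth_set = {(snp.position, snp.alt_allele) for snp in truth}
    called = {(call.position, call.alt_allele) for call in calls}
    tp = len(called & truth_set)
    fp = len(called - truth_set)
    fn = len(truth_set - called)
    return contingency_from_counts(tp, fp, fn)
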