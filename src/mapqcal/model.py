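"""Logistic recalibration of mapping quality.

Each mapped line in a truth-annotated training set is labelled accurate
(the aligner reported the read's true reference, strand and leftmost
position) or not, and a logistic regression

    ln(p / (1 - p)) = beta_0 + sum_i beta_i * x_i

is fitted on the feature vector x of the mapping. The predicted
probability p that a mapping is correct is used directly as its quality
and converted to the Phred scale, Q = -10 * log10(1 - p), for writing
back into the SAM MAPQ column.

The fit maximizes the L2-penalized binomial log-likelihood by damped
Newton iteration (step-halving guarantees a monotone loss); features are
standardized internally and the scaling is stored with the model. A small
default penalty (1e-6 on standardized features) stabilizes the fit under
quasi-separation while leaving the plain maximum-likelihood solution
essentially unchanged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .features import FEATURE_NAMES, FeatureVector
from .samio import MappingRecord, parse_sam
from .simulate import SimulatedRead

PROB_EPS = 1e-10
DEFAULT_CAP = 60.0
MAPQ_MAX_SAM = 254


@dataclass(frozen=True)
class LabeledExample:
    features: FeatureVector
    label: bool  # True = accurate


@dataclass
class LogisticModel:
    """Fitted coefficients plus the feature scaling they apply to."""

    feature_names: tuple[str, ...]
    beta0: float
    betas: np.ndarray  # per standardized feature
    center: np.ndarray
    spread: np.ndarray
    l2: float
    cap: float = DEFAULT_CAP
    loss_history: list[float] = field(default_factory=list, repr=False)

    def raw_coefficients(self) -> tuple[float, np.ndarray]:
        """Coefficients on the original (unstandardized) feature scale."""
        betas = self.betas / self.spread
        beta0 = self.beta0 - float(np.dot(betas, self.center))
        return beta0, betas

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "tool": f"mapqcal {__version__}",
            "feature_names": list(self.feature_names),
            "beta0": self.beta0,
            "betas": self.betas.tolist(),
            "scaling": {"center": self.center.tolist(), "spread": self.spread.tolist()},
            "l2": self.l2,
            "cap": self.cap,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LogisticModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(
            feature_names=tuple(doc["feature_names"]),
            beta0=float(doc["beta0"]),
            betas=np.asarray(doc["betas"], dtype=float),
            center=np.asarray(doc["scaling"]["center"], dtype=float),
            spread=np.asarray(doc["scaling"]["spread"], dtype=float),
            l2=float(doc["l2"]),
            cap=float(doc["cap"]),
        )


def label_mapping(record: MappingRecord, truth: SimulatedRead, tolerance: int = 0) -> bool:
    """True iff the mapping hits the read's true origin.

    Requires the same reference name and strand, and a leftmost position
    within ``tolerance`` bases of the true 1-based start (default exact).
    """
    if record.read_id != truth.read_id:
        raise ValueError(f"read id mismatch: {record.read_id!r} vs {truth.read_id!r}")
    if not record.mapped:
        raise ValueError("labels are defined for mapped records only")
    return (
        record.ref_name == truth.true_ref_name
        and record.strand == truth.true_strand
        and abs(record.pos - truth.true_start) <= tolerance
    )


def _neg_log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # -loglik = sum log(1 + exp(eta)) - y * eta, computed stably
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def fit_logistic_xy(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
    l2: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-8,
    cap: float = DEFAULT_CAP,
) -> LogisticModel:
    """Fit the penalized logistic regression on a raw design matrix.

    Features are standardized to zero mean / unit spread (constant
    columns keep unit spread); the intercept is not penalized. Newton
    steps are damped by step-halving so the penalized deviance is
    non-increasing; iteration stops when the gradient infinity-norm
    drops below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError(
            "training data must contain both classes (accurate and not accurate)"
        )
    n, p = X.shape
    if feature_names is None:
        feature_names = tuple(f"x{j}" for j in range(p))
    center = X.mean(axis=0)
    spread = X.std(axis=0)
    spread[spread == 0.0] = 1.0
    Z = (X - center) / spread
    Za = np.hstack([np.ones((n, 1)), Z])

    penalty = np.full(p + 1, l2)
    penalty[0] = 0.0

    beta = np.zeros(p + 1)
    eta = Za @ beta
    loss = _neg_log_likelihood(eta, y) + 0.5 * float(penalty @ (beta**2))
    history = [loss]
    for _ in range(max_iter):
        prob = 1.0 / (1.0 + np.exp(-eta))
        grad = Za.T @ (prob - y) + penalty * beta
        if np.max(np.abs(grad)) <= tol:
            break
        w = prob * (1.0 - prob)
        hess = (Za * w[:, None]).T @ Za + np.diag(penalty)
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(p + 1), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # damped update: halve until the penalized deviance does not increase
        scale = 1.0
        for _ in range(50):
            candidate = beta - scale * step
            eta_new = Za @ candidate
            loss_new = _neg_log_likelihood(eta_new, y) + 0.5 * float(
                penalty @ (candidate**2)
            )
            if loss_new <= loss + 1e-12:
                break
            scale *= 0.5
        beta, eta, loss = candidate, eta_new, loss_new
        history.append(loss)
    return LogisticModel(
        feature_names=tuple(feature_names),
        beta0=float(beta[0]),
        betas=beta[1:].copy(),
        center=center,
        spread=spread,
        l2=l2,
        cap=cap,
        loss_history=history,
    )


def fit_logistic(
    examples: Sequence[LabeledExample],
    l2: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-8,
    cap: float = DEFAULT_CAP,
) -> LogisticModel:
    """Fit the recalibration model on labelled feature vectors."""
    if not examples:
        raise ValueError("no training examples")
    X = np.array([example.features.to_array() for example in examples])
    y = np.array([1.0 if example.label else 0.0 for example in examples])
    return fit_logistic_xy(X, y, FEATURE_NAMES, l2=l2, max_iter=max_iter, tol=tol, cap=cap)


def predict_probabilities(model: LogisticModel, X: np.ndarray) -> np.ndarray:
    """Correctness probabilities for rows of a raw feature matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.betas.size:
        raise ValueError(
            f"expected {model.betas.size} features, got {X.shape[1]}"
        )
    Z = (X - model.center) / model.spread
    eta = model.beta0 + Z @ model.betas
    p = 1.0 / (1.0 + np.exp(-eta))
    return np.clip(p, PROB_EPS, 1.0 - PROB_EPS)


def predict_probability(model: LogisticModel, fv: FeatureVector) -> float:
    return float(predict_probabilities(model, fv.to_array())[0])


def prob_to_mapq(p: float, cap: float = DEFAULT_CAP) -> float:
    """Phred-scale a correctness probability: Q = -10 * log10(1 - p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    if p >= 1.0:
        return cap
    return min(cap, -10.0 * math.log10(1.0 - p))


def phred_to_error_prob(q: float) -> float:
    """Error probability implied by a Phred score: P = 10**(-Q/10)."""
    if q < 0:
        raise ValueError("Phred score must be non-negative")
    return 10.0 ** (-q / 10.0)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def recalibrate_sam(
    sam_in: str | Path,
    model: LogisticModel,
    sam_out: str | Path,
    scores_out: str | Path | None = None,
) -> int:
    """Rewrite the MAPQ column of a SAM file using the fitted model.

    Every mapped alignment line gets MAPQ = round(Q) clamped to [0, 254];
    all other fields (and unmapped or header lines) are passed through
    byte-identically. ``scores_out`` optionally receives a TSV of
    read_id, p and the unrounded recalibrated quality. Returns the number
    of recalibrated lines.
    """
    from .features import extract_features, multiplicity_by_read

    records = list(parse_sam(sam_in))
    counts = multiplicity_by_read(records)
    mapped = [record for record in records if record.mapped]
    if mapped:
        X = np.array(
            [extract_features(r, counts[r.read_id]).to_array() for r in mapped]
        )
        probs = predict_probabilities(model, X)
    else:
        probs = np.empty(0)
    quals = {id(r): (float(p), prob_to_mapq(float(p), model.cap)) for r, p in zip(mapped, probs)}

    n_recal = 0
    by_line = {record.line_number: record for record in mapped}
    scores_handle = open(scores_out, "w") if scores_out is not None else None
    try:
        if scores_handle is not None:
            scores_handle.write("read_id\tp\tq_recal\n")
        with open(sam_in) as src, open(sam_out, "w") as dst:
            for line_number, line in enumerate(src, start=1):
                record = by_line.get(line_number)
                if record is None:
                    dst.write(line)
                    continue
                p, q = quals[id(record)]
                fields = line.rstrip("\n").split("\t")
                fields[4] = str(max(0, min(MAPQ_MAX_SAM, _round_half_away(q))))
                dst.write("\t".join(fields) + "\n")
                if scores_handle is not None:
                    scores_handle.write(f"{record.read_id}\t{p:.10g}\t{q:.6g}\n")
                n_recal += 1
    finally:
        if scores_handle is not None:
            scores_handle.close()
    return n_recal
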