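"""Tanimoto / probability applicability domain and high-confidence errors.

A test prediction is considered in-domain when either of two inclusive
thresholds is met: a maximum Tanimoto similarity to the training set of at
least 0.90, or a predicted-class probability of at least 0.8.  The module
also automates the nearest-neighbour rationale for confidently wrong
predictions: every false positive/negative with probability strictly above
0.8 is annotated with its most similar training molecule and that neighbour's
cross-validated prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .descriptors import FingerprintVector
from .models import ClassificationMetrics, ConfusionMatrix, confusion_metrics

__all__ = [
    "ADResult",
    "HighConfidenceError",
    "StratifiedReport",
    "tanimoto",
    "max_train_similarity",
    "in_domain",
    "assess_domain",
    "stratified_metrics",
    "high_confidence_errors",
]

TC_THRESHOLD = 0.90
PROB_THRESHOLD = 0.8


@dataclass(frozen=True)
class ADResult:
    molecule_id: str
    tc_max: float
    nearest_training_id: str
    probability: float
    in_domain: bool


@dataclass(frozen=True)
class HighConfidenceError:
    molecule_id: str
    error_type: str  # "FP" | "FN"
    probability: float
    nearest_training_id: str
    tc_to_nearest: float
    nearest_training_predicted_class: str


@dataclass(frozen=True)
class StratumMetrics:
    confusion: ConfusionMatrix | None
    metrics: ClassificationMetrics | None  # None when the stratum is empty


@dataclass(frozen=True)
class StratifiedReport:
    in_domain: StratumMetrics
    out_of_domain: StratumMetrics
    overall: ConfusionMatrix


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """|A∧B| / |A∨B| over fingerprint bits; two empty vectors give 0."""
    if a.kind != b.kind:
        raise ValueError(f"fingerprint kinds differ: {a.kind} vs {b.kind}")
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0.0",
                      stacklevel=2)
        return 0.0
    return float(np.count_nonzero(a.bits & b.bits)) / union


def _bit_matrix(fps: list[FingerprintVector]) -> np.ndarray:
    return np.stack([fp.bits.astype(bool) for fp in fps])


def max_train_similarity(query: FingerprintVector,
                         training: list[FingerprintVector],
                         training_ids: list[str] | None = None):
    """Exact maximum Tanimoto over the training set; ties -> first by order.

    Returns (tc_max, nearest_training_id_or_index).
    """
    if not training:
        raise ValueError("training set must be non-empty")
    for fp in training:
        if fp.kind != query.kind:
            raise ValueError(f"fingerprint kinds differ: {query.kind} vs {fp.kind}")
    mat = _bit_matrix(training)
    q = query.bits.astype(bool)
    inter = (mat & q).sum(axis=1).astype(float)
    union = (mat | q).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        tcs = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    best = int(np.argmax(tcs))  # argmax returns the first maximum
    ident = training_ids[best] if training_ids is not None else best
    return float(tcs[best]), ident


def in_domain(tc_max: float, probability: float,
              tc_threshold: float = TC_THRESHOLD,
              prob_threshold: float = PROB_THRESHOLD) -> bool:
    """Inclusive disjunction: tc_max >= 0.90 or probability >= 0.8."""
    for name, v in (("tc_max", tc_max), ("probability", probability)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return tc_max >= tc_threshold or probability >= prob_threshold


def assess_domain(query_ids, query_fps, probabilities,
                  training_fps, training_ids,
                  tc_threshold: float = TC_THRESHOLD,
                  prob_threshold: float = PROB_THRESHOLD) -> list[ADResult]:
    """Per-molecule applicability-domain assessment for a query set."""
    if not (len(query_ids) == len(query_fps) == len(probabilities)):
        raise ValueError("query inputs must be aligned")
    out = []
    for qid, fp, prob in zip(query_ids, query_fps, probabilities):
        tc, nn = max_train_similarity(fp, training_fps, training_ids)
        out.append(ADResult(
            molecule_id=qid, tc_max=tc, nearest_training_id=nn,
            probability=float(prob),
            in_domain=in_domain(tc, float(prob), tc_threshold, prob_threshold)))
    return out


def _stratum(y_true, y_pred, mask, positive) -> StratumMetrics:
    if not np.any(mask):
        return StratumMetrics(confusion=None, metrics=None)
    cm = ConfusionMatrix.from_predictions(
        np.asarray(y_true)[mask], np.asarray(y_pred)[mask], positive=positive)
    return StratumMetrics(confusion=cm, metrics=confusion_metrics(cm))


def stratified_metrics(y_pred, y_true, in_domain_mask,
                       positive="active") -> StratifiedReport:
    """Confusion matrices and metrics inside vs outside the domain.

    The two strata's confusion matrices always sum to the overall matrix;
    an empty stratum is flagged with ``None`` metrics rather than an error.
    """
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    mask = np.asarray(in_domain_mask, dtype=bool)
    if not (len(y_pred) == len(y_true) == len(mask)):
        raise ValueError("predictions, labels and mask must be aligned")
    overall = ConfusionMatrix.from_predictions(y_true, y_pred, positive=positive)
    return StratifiedReport(
        in_domain=_stratum(y_true, y_pred, mask, positive),
        out_of_domain=_stratum(y_true, y_pred, ~mask, positive),
        overall=overall)


def high_confidence_errors(molecule_ids, y_pred, probabilities, y_true,
                           query_fps, training_fps, training_ids,
                           training_cv_predictions,
                           prob_threshold: float = PROB_THRESHOLD,
                           positive="active") -> list[HighConfidenceError]:
    """Misclassifications with predicted-class probability strictly above the
    threshold, each annotated with its nearest training molecule and that
    neighbour's cross-validated predicted class."""
    if not 0.0 <= prob_threshold <= 1.0:
        raise ValueError(f"prob_threshold must be in [0, 1], got {prob_threshold}")
    n = len(molecule_ids)
    if not (n == len(y_pred) == len(probabilities) == len(y_true) == len(query_fps)):
        raise ValueError("inputs must be aligned")
    cv_by_id = dict(zip(training_ids, training_cv_predictions))
    out = []
    for i in range(n):
        if y_pred[i] == y_true[i] or probabilities[i] <= prob_threshold:
            continue
        error_type = "FP" if y_pred[i] == positive else "FN"
        tc, nn = max_train_similarity(query_fps[i], training_fps, training_ids)
        out.append(HighConfidenceError(
            molecule_id=molecule_ids[i], error_type=error_type,
            probability=float(probabilities[i]),
            nearest_training_id=nn, tc_to_nearest=tc,
            nearest_training_predicted_class=str(cv_by_id[nn])))
    return out
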