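"""Anomaly scores, threshold calibration and accept/reject decisions.

The primary familiarity score is the *max logit*: the maximum entry of the
temporal-mean logit vector of a video.  Low values indicate unfamiliar
input; a video is rejected as an unknown view when its score falls below
the minimum acceptance threshold delta (boundary convention: S >= delta
accepts).

Alternative post-hoc scores are provided for comparison (max softmax,
L1 feature mean, negated feature entropy, frame-prediction relative
frequency) plus the summed-softmax score of the outlier-exposure variant.
All scores are sign-oriented so that rejection is always "below threshold".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import softmax

__all__ = [
    "SCORE_KINDS",
    "ThresholdCalibration",
    "max_logit_score",
    "max_softmax_score",
    "l1_feature_score",
    "feature_entropy_score",
    "relative_frequency_score",
    "summed_softmax_score",
    "candidate_thresholds",
    "calibrate_threshold",
    "accept_reject",
]

SCORE_KINDS = ("max_logit", "max_softmax", "l1_feature", "feature_entropy",
               "relative_frequency", "summed_softmax")


def max_logit_score(video_logits: np.ndarray, outlier_exposure: bool = False) -> float:
    """Maximum over the known-class entries of the temporal-mean logit
    vector; the outlier slot (when present) is explicitly ignored."""
    vl = np.asarray(video_logits, dtype=np.float64)
    known = vl[:-1] if outlier_exposure else vl
    return float(known.max())


def max_softmax_score(video_logits: np.ndarray) -> float:
    """Highest softmax probability among classes, in (0, 1]."""
    vl = np.asarray(video_logits, dtype=np.float64)
    return float(softmax(vl).max())


def l1_feature_score(embedding: np.ndarray) -> float:
    """Mean of the D entries of the time-averaged penultimate features."""
    return float(np.asarray(embedding, dtype=np.float64).mean())


def feature_entropy_score(embedding: np.ndarray) -> float:
    """Negated Shannon entropy (natural log) of the sum-normalized
    embedding; <= 0, with 0 for a one-hot vector.

    An all-zero embedding is assigned the minimum possible score, -log D.
    Negative entries are rejected (features are post-activation).
    """
    v = np.asarray(embedding, dtype=np.float64)
    if (v < 0).any():
        raise ValueError("feature entropy requires non-negative activations")
    total = v.sum()
    if total == 0:
        warnings.warn("all-zero embedding: returning minimum entropy score")
        return float(-np.log(v.size))
    p = v / total
    nz = p[p > 0]
    return float(np.sum(nz * np.log(nz)))  # = -entropy


def relative_frequency_score(frame_logits: np.ndarray) -> float:
    """Fraction of frames whose argmax prediction equals the modal
    per-frame prediction, in (0, 1]."""
    fl = np.asarray(frame_logits, dtype=np.float64)
    if fl.ndim != 2 or fl.shape[0] < 1:
        raise ValueError("need a non-empty T' x K logit matrix")
    preds = fl.argmax(axis=1)
    counts = np.bincount(preds)
    return float(counts.max() / preds.size)


def summed_softmax_score(video_logits_with_outlier: np.ndarray) -> float:
    """Sum of the known-class softmax probabilities of an outlier-exposed
    logit vector (equivalently 1 - outlier probability), in (0, 1)."""
    vl = np.asarray(video_logits_with_outlier, dtype=np.float64)
    if vl.ndim != 1 or vl.size < 2:
        raise ValueError("expected a C+1 logit vector from an outlier-exposed model")
    p = softmax(vl)
    return float(p[:-1].sum())


def accept_reject(score: float, delta: float) -> bool:
    """Accept iff S >= delta (the boundary accepts)."""
    return bool(score >= delta)


def candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted unique scores, with -inf/+inf
    sentinels; exhausts every distinct accept/reject partition."""
    u = np.unique(np.asarray(scores, dtype=np.float64))
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


@dataclass(frozen=True)
class ThresholdCalibration:
    delta: float
    criterion: str
    achieved: float
    score_min: float
    score_max: float
    n_known: int
    n_unknown: int
    fallback: bool = False


def _criterion_values(cands: np.ndarray, scores: np.ndarray,
                      is_known: np.ndarray, is_correct: np.ndarray,
                      criterion: str) -> np.ndarray:
    # accepted[i, j] = scores[j] >= cands[i]
    accepted = scores[None, :] >= cands[:, None]
    kn = is_known[None, :]
    if criterion == "max_full_set_accuracy":
        good = (accepted & kn & is_correct[None, :]) | (~accepted & ~kn)
        return good.sum(axis=1) / scores.size
    if criterion == "oscr_specificity_mean":
        n_known = int(is_known.sum())
        n_unknown = scores.size - n_known
        if n_known == 0 or n_unknown == 0:
            raise ValueError("criterion needs both known and unknown clips")
        oscr = (accepted & kn & is_correct[None, :]).sum(axis=1) / n_known
        fpr = (accepted & ~kn).sum(axis=1) / n_unknown
        return (oscr + (1.0 - fpr)) / 2.0
    raise ValueError(f"unknown criterion {criterion!r}")


def calibrate_threshold(scores, is_known, is_correct,
                        criterion: str = "max_full_set_accuracy"
                        ) -> ThresholdCalibration:
    """Pick the acceptance threshold delta on a validation set.

    Candidates are midpoints between consecutive sorted unique scores plus
    -inf/+inf sentinels; the candidate maximizing the criterion is
    returned, with ties broken toward the smallest candidate (favoring
    acceptance).  ``is_correct`` marks known clips whose view prediction
    matches the reference (its value on unknown clips is ignored).

    With no unknown clips, ``max_full_set_accuracy`` is degenerate: a
    warning is issued and the -inf sentinel (accept everything) returned.
    """
    scores = np.asarray(scores, dtype=np.float64)
    is_known = np.asarray(is_known, dtype=bool)
    is_correct = np.asarray(is_correct, dtype=bool) & is_known
    if scores.size == 0:
        raise ValueError("no calibration scores")
    n_known = int(is_known.sum())
    n_unknown = scores.size - n_known
    if criterion == "max_full_set_accuracy" and (n_known == 0 or n_unknown == 0):
        warnings.warn(
            "validation set lacks known or unknown clips: full-set-accuracy "
            "calibration is degenerate; falling back to delta = -inf "
            "(accept everything)")
        return ThresholdCalibration(
            delta=float("-inf"), criterion=criterion, achieved=float("nan"),
            score_min=float(scores.min()), score_max=float(scores.max()),
            n_known=n_known, n_unknown=n_unknown, fallback=True)

    cands = candidate_thresholds(scores)
    vals = _criterion_values(cands, scores, is_known, is_correct, criterion)
    best = int(np.argmax(vals))  # first max = smallest candidate
    return ThresholdCalibration(
        delta=float(cands[best]), criterion=criterion,
        achieved=float(vals[best]),
        score_min=float(scores.min()), score_max=float(scores.max()),
        n_known=n_known, n_unknown=n_unknown)
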