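"""Open-set evaluation metrics, curves and report assembly.

Definitions (all sharing the acceptance convention S >= delta):

* closed-set accuracy — prediction accuracy over known-view clips only;
* full-set accuracy A(delta) — correctly classified *and* accepted knowns
  plus correctly rejected unknowns, over all clips;
* TPR / FPR — acceptance rates over knowns / unknowns; balanced accuracy is
  (TPR + 1 - FPR) / 2;
* OSCR(delta) — accepted-and-correct knowns over all knowns; plotted
  against FPR and summarized by its trapezoidal AUC;
* one-vs-one ROC-AUC over known classes (Hand-and-Till style, unweighted
  pair averaging of both directions' AUCs);
* unknown-view ROC-AUC — area under (FPR, TPR) swept over delta, equal to
  the Mann-Whitney statistic of the anomaly score;
* Spearman rank correlation for quality predictions.

The open-set confusion matrix is (C+1) x (C+1) with the last row/column for
unknown reference labels / rejections; the three unknown subcategories are
collapsed in the matrix but kept for per-subcategory ROC reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as _stats
from sklearn.metrics import roc_auc_score as _sk_roc_auc

from .openset import candidate_thresholds
from .synthdata import UNKNOWN_LABELS

__all__ = [
    "EvalRecord",
    "OpenSetReport",
    "closed_set_accuracy",
    "full_set_accuracy",
    "tpr_fpr",
    "oscr_curve",
    "oscr_auc",
    "roc_curve_unknown",
    "unknown_roc_auc",
    "ovo_roc_auc",
    "spearman",
    "open_confusion_matrix",
    "per_subcategory_roc",
    "summarize_runs",
    "build_report",
]


@dataclass(frozen=True)
class EvalRecord:
    """Per-clip evaluation triplet plus optional quality scores."""

    clip_id: str
    true_label: int | str  # known class index or unknown subcategory label
    predicted_class: int
    score: float
    predicted_quality: float | None = None
    true_quality: float | None = None

    @property
    def is_known(self) -> bool:
        return not isinstance(self.true_label, str)


def _arrays(records: Sequence[EvalRecord]):
    known = np.array([r.is_known for r in records], dtype=bool)
    y = np.array([r.true_label if r.is_known else -1 for r in records])
    pred = np.array([r.predicted_class for r in records])
    s = np.array([r.score for r in records], dtype=np.float64)
    if not np.isfinite(s).all():
        raise ValueError("anomaly scores must be finite")
    return known, y, pred, s


def closed_set_accuracy(records: Sequence[EvalRecord]) -> float:
    """Accuracy over known-view clips; unknown-labeled clips are omitted."""
    known, y, pred, _ = _arrays(records)
    if known.sum() == 0:
        raise ValueError("closed-set accuracy undefined without known clips")
    return float((pred[known] == y[known]).mean())


def full_set_accuracy(records: Sequence[EvalRecord], delta: float) -> float:
    """(correct-and-accepted knowns + rejected unknowns) / all clips."""
    known, y, pred, s = _arrays(records)
    if len(records) == 0:
        raise ValueError("no records")
    acc = s >= delta
    good = (known & (pred == y) & acc) | (~known & ~acc)
    return float(good.mean())


def tpr_fpr(records: Sequence[EvalRecord], delta: float
            ) -> tuple[float, float, float]:
    """(TPR, FPR, balanced accuracy) at a threshold."""
    known, _, _, s = _arrays(records)
    n_known = int(known.sum())
    n_unknown = len(records) - n_known
    if n_known == 0 or n_unknown == 0:
        raise ValueError("need both known and unknown clips")
    acc = s >= delta
    tpr = float((acc & known).sum() / n_known)
    fpr = float((acc & ~known).sum() / n_unknown)
    return tpr, fpr, (tpr + 1.0 - fpr) / 2.0


def _sweep(records: Sequence[EvalRecord]):
    known, y, pred, s = _arrays(records)
    n_known = int(known.sum())
    n_unknown = len(records) - n_known
    if n_known == 0 or n_unknown == 0:
        raise ValueError("need both known and unknown clips")
    cands = candidate_thresholds(s)
    acc = s[None, :] >= cands[:, None]
    tpr = (acc & known).sum(axis=1) / n_known
    fpr = (acc & ~known).sum(axis=1) / n_unknown
    oscr = (acc & known & (pred == y)).sum(axis=1) / n_known
    return cands, tpr, fpr, oscr


def oscr_curve(records: Sequence[EvalRecord]) -> np.ndarray:
    """(FPR, OSCR) points swept over the candidate-threshold grid, sorted by
    FPR ascending with endpoints at FPR = 0 and FPR = 1."""
    _, _, fpr, oscr = _sweep(records)
    pts = np.column_stack([fpr, oscr])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return pts[order]


def oscr_auc(curve_or_records) -> float:
    """Trapezoidal area under the OSCR-vs-FPR curve."""
    if (isinstance(curve_or_records, (list, tuple)) and curve_or_records
            and isinstance(curve_or_records[0], EvalRecord)):
        curve = oscr_curve(curve_or_records)
    else:
        curve = np.asarray(curve_or_records, dtype=np.float64)
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


def roc_curve_unknown(records: Sequence[EvalRecord]) -> np.ndarray:
    """(FPR, TPR) points for accept/reject of knowns vs unknowns."""
    _, tpr, fpr, _ = _sweep(records)
    pts = np.column_stack([fpr, tpr])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return pts[order]


def unknown_roc_auc(records: Sequence[EvalRecord]) -> float:
    """Area under the accept/reject ROC curve (trapezoid over the delta
    sweep); equals the Mann-Whitney statistic of the score separating
    knowns from unknowns."""
    curve = roc_curve_unknown(records)
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


def ovo_roc_auc(records: Sequence[EvalRecord],
                class_scores: np.ndarray) -> float:
    """One-vs-one multiclass ROC-AUC over the known classes.

    For each unordered class pair (i, j), the AUC of the class-i score
    separating i-from-j and the symmetric class-j AUC are averaged; pair
    values are then averaged unweighted, keeping the statistic agnostic to
    the class distribution.  Ties contribute 1/2 (Mann-Whitney convention).
    ``class_scores`` holds one score per known class per record (e.g. the
    video logit vector), aligned with ``records``.
    """
    known, y, _, _ = _arrays(records)
    cs = np.asarray(class_scores, dtype=np.float64)
    if cs.shape[0] != len(records):
        raise ValueError("class_scores misaligned with records")
    yk = y[known]
    sk = cs[known]
    present = sorted(set(int(v) for v in yk))
    if len(present) < 2:
        raise ValueError("one-vs-one AUC needs >= 2 known classes present")
    pair_aucs = []
    for i, j in combinations(present, 2):
        sel = (yk == i) | (yk == j)
        if (yk[sel] == i).sum() == 0 or (yk[sel] == j).sum() == 0:
            warnings.warn(f"skipping pair ({i},{j}): a class has no records")
            continue
        auc_i = _sk_roc_auc((yk[sel] == i).astype(int), sk[sel, i])
        auc_j = _sk_roc_auc((yk[sel] == j).astype(int), sk[sel, j])
        pair_aucs.append((auc_i + auc_j) / 2.0)
    return float(np.mean(pair_aucs))


def spearman(xs, ys) -> float:
    """Spearman rank correlation (average ranks on ties), in [-1, 1]."""
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.shape != ys.shape or xs.ndim != 1 or xs.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(_stats.spearmanr(xs, ys).statistic)


def open_confusion_matrix(records: Sequence[EvalRecord], delta: float,
                          n_classes: int) -> np.ndarray:
    """(C+1) x (C+1) counts; last row = unknown reference (subcategories
    collapsed), last column = rejected clips."""
    known, y, pred, s = _arrays(records)
    cm = np.zeros((n_classes + 1, n_classes + 1), dtype=int)
    acc = s >= delta
    rows = np.where(known, y, n_classes)
    cols = np.where(acc, pred, n_classes)
    for r, c in zip(rows, cols):
        cm[int(r), int(c)] += 1
    return cm


def per_subcategory_roc(records: Sequence[EvalRecord]
                        ) -> dict[str, dict]:
    """Unknown-view ROC per unknown subcategory.

    For each subcategory, the records of the *other two* subcategories are
    removed and the accept/reject ROC is computed on knowns vs the
    remaining unknowns.  Absent subcategories are skipped with a warning.
    """
    out: dict[str, dict] = {}
    for sub in UNKNOWN_LABELS:
        subset = [r for r in records
                  if r.is_known or r.true_label == sub]
        if not any(not r.is_known for r in subset):
            warnings.warn(f"no {sub} clips present; skipping its ROC")
            continue
        curve = roc_curve_unknown(subset)
        out[sub] = {"curve": curve,
                    "auc": float(np.trapezoid(curve[:, 1], curve[:, 0]))}
    return out


def summarize_runs(run_metrics: Sequence[dict]) -> dict[str, tuple[float, float]]:
    """Aggregate repeated evaluation runs (e.g. cross-validation folds)
    into mean +/- sd per metric; non-numeric entries are skipped."""
    if not run_metrics:
        raise ValueError("no runs to summarize")
    out = {}
    for key in run_metrics[0]:
        vals = [m[key] for m in run_metrics
                if isinstance(m.get(key), (int, float)) and m[key] is not None]
        if len(vals) == len(run_metrics):
            out[key] = (float(np.mean(vals)), float(np.std(vals)))
    return out


@dataclass
class OpenSetReport:
    """All open-set metrics at a given threshold plus swept curves."""

    delta: float
    closed_set_accuracy: float
    full_set_accuracy: float
    tpr: float
    fpr: float
    balanced_accuracy: float
    oscr_auc: float
    unknown_roc_auc: float
    ovo_roc_auc: float | None
    confusion_matrix: np.ndarray
    oscr_points: np.ndarray
    roc_points: np.ndarray
    per_subcategory: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "delta": self.delta,
            "closed_set_accuracy": self.closed_set_accuracy,
            "full_set_accuracy": self.full_set_accuracy,
            "tpr": self.tpr,
            "fpr": self.fpr,
            "balanced_accuracy": self.balanced_accuracy,
            "oscr_auc": self.oscr_auc,
            "unknown_roc_auc": self.unknown_roc_auc,
            "ovo_roc_auc": self.ovo_roc_auc,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "per_subcategory_auc": {k: v["auc"]
                                    for k, v in self.per_subcategory.items()},
        }
        return d


def build_report(records: Sequence[EvalRecord], delta: float,
                 n_classes: int,
                 class_scores: np.ndarray | None = None) -> OpenSetReport:
    """Assemble the full open-set report at a given threshold."""
    tpr, fpr, bal = tpr_fpr(records, delta)
    return OpenSetReport(
        delta=float(delta),
        closed_set_accuracy=closed_set_accuracy(records),
        full_set_accuracy=full_set_accuracy(records, delta),
        tpr=tpr, fpr=fpr, balanced_accuracy=bal,
        oscr_auc=oscr_auc(oscr_curve(records)),
        unknown_roc_auc=unknown_roc_auc(records),
        ovo_roc_auc=(ovo_roc_auc(records, class_scores)
                     if class_scores is not None else None),
        confusion_matrix=open_confusion_matrix(records, delta, n_classes),
        oscr_points=oscr_curve(records),
        roc_points=roc_curve_unknown(records),
        per_subcategory=per_subcategory_roc(records),
    )
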