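"""Independent brute-force oracles used to verify the package's metrics.

Everything here is written as plain loops over set definitions or pairwise
comparisons, deliberately sharing no code with the implementation under
test.
"""

from __future__ import annotations

import numpy as np


def oracle_closed_accuracy(labels, preds) -> float:
    num = den = 0
    for y, p in zip(labels, preds):
        if isinstance(y, str):
            continue
        den += 1
        num += int(p == y)
    return num / den


def oracle_full_set_accuracy(labels, preds, scores, delta) -> float:
    good = 0
    for y, p, s in zip(labels, preds, scores):
        if not isinstance(y, str):
            if p == y and s >= delta:
                good += 1
        else:
            if s < delta:
                good += 1
    return good / len(labels)


def oracle_tpr_fpr(labels, scores, delta):
    tp = kn = fp = un = 0
    for y, s in zip(labels, scores):
        if isinstance(y, str):
            un += 1
            fp += int(s >= delta)
        else:
            kn += 1
            tp += int(s >= delta)
    tpr, fpr = tp / kn, fp / un
    return tpr, fpr, (tpr + 1 - fpr) / 2


def oracle_oscr(labels, preds, scores, delta) -> float:
    num = kn = 0
    for y, p, s in zip(labels, preds, scores):
        if isinstance(y, str):
            continue
        kn += 1
        num += int(p == y and s >= delta)
    return num / kn


def oracle_unknown_auc(labels, scores) -> float:
    """Mann-Whitney pair counting: knowns are positives."""
    pos = [s for y, s in zip(labels, scores) if not isinstance(y, str)]
    neg = [s for y, s in zip(labels, scores) if isinstance(y, str)]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def oracle_pair_auc(pos_scores, neg_scores) -> float:
    total = 0.0
    for a in pos_scores:
        for b in neg_scores:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos_scores) * len(neg_scores))


def oracle_ovo_auc(labels, class_scores) -> float:
    """Unweighted pair-averaged one-vs-one AUC over known classes."""
    labels = list(labels)
    known_idx = [i for i, y in enumerate(labels) if not isinstance(y, str)]
    classes = sorted({labels[i] for i in known_idx})
    pair_vals = []
    for ci in range(len(classes)):
        for cj in range(ci + 1, len(classes)):
            i, j = classes[ci], classes[cj]
            idx = [k for k in known_idx if labels[k] in (i, j)]
            ai = oracle_pair_auc(
                [class_scores[k][i] for k in idx if labels[k] == i],
                [class_scores[k][i] for k in idx if labels[k] == j])
            aj = oracle_pair_auc(
                [class_scores[k][j] for k in idx if labels[k] == j],
                [class_scores[k][j] for k in idx if labels[k] == i])
            pair_vals.append((ai + aj) / 2)
    return float(np.mean(pair_vals))


def oracle_best_threshold(scores, is_known, is_correct, criterion):
    """Exhaustive search over the midpoint+sentinel grid; returns
    (best delta, best value) with ties toward the smallest candidate."""
    u = sorted(set(scores))
    cands = [-np.inf] + [(a + b) / 2 for a, b in zip(u[:-1], u[1:])] + [np.inf]
    n = len(scores)
    n_known = sum(is_known)
    n_unknown = n - n_known
    best_d, best_v = None, -np.inf
    for d in cands:
        if criterion == "max_full_set_accuracy":
            good = 0
            for s, k, c in zip(scores, is_known, is_correct):
                if k and c and s >= d:
                    good += 1
                elif not k and s < d:
                    good += 1
            v = good / n
        else:  # oscr_specificity_mean
            oscr = sum(1 for s, k, c in zip(scores, is_known, is_correct)
                       if k and c and s >= d) / n_known
            fpr = sum(1 for s, k in zip(scores, is_known)
                      if not k and s >= d) / n_unknown
            v = (oscr + (1 - fpr)) / 2
        if v > best_v:
            best_d, best_v = d, v
    return best_d, best_v


def lasso_coordinate_descent(X, y, alpha, n_iter=2000, tol=1e-12):
    """Coordinate-descent Lasso for (1/2N)||y - Xw - b||^2 + alpha ||w||_1."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    N, D = X.shape
    w = np.zeros(D)
    b = y.mean()
    col_sq = (X ** 2).sum(axis=0) / N
    for _ in range(n_iter):
        w_old = w.copy()
        b = float(np.mean(y - X @ w))
        for j in range(D):
            if col_sq[j] == 0:
                continue
            r_j = y - b - X @ w + X[:, j] * w[j]
            z = float(X[:, j] @ r_j) / N
            w[j] = np.sign(z) * max(abs(z) - alpha, 0.0) / col_sq[j]
        if np.max(np.abs(w - w_old)) < tol:
            break
    b = float(np.mean(y - X @ w))
    return w, b


def random_open_set_instance(rng, n_max=50, c_max=5):
    """Random labels/predictions/scores for metric-equivalence checks.

    Guarantees at least one known and one unknown record and >= 2 known
    classes; scores are drawn from a coarse grid so ties occur.
    """
    C = int(rng.integers(2, c_max + 1))
    n = int(rng.integers(C + 2, n_max + 1))
    labels = []
    for i in range(n):
        if i < C:
            labels.append(i)  # ensure every class appears
        elif i == C:
            labels.append("novel_category")
        elif rng.random() < 0.3:
            labels.append(str(rng.choice(["novel_category", "poor_quality",
                                          "multiple_views"])))
        else:
            labels.append(int(rng.integers(C)))
    rng.shuffle(labels)
    preds = [int(rng.integers(C)) for _ in range(n)]
    scores = rng.integers(-10, 11, size=n).astype(float) / 2.0
    class_scores = rng.integers(-6, 7, size=(n, C)).astype(float) / 2.0
    return labels, preds, scores, class_scores, C
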