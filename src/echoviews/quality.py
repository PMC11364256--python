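"""View-quality prediction: sparse linear regression on CNN embeddings.

A video's time-averaged penultimate feature vector (from the frozen view
classifier) is mapped to a normalized quality score in [0, 1] by Lasso
regression, i.e. minimizing

    (1 / 2N) * sum_k || w . l_k + b - y_k ||^2  +  alpha * ||w||_1

over the training embeddings l_k and quality labels y_k.  The penalty
alpha is chosen by K-fold cross-validation (default fivefold) over an
automatically scaled logarithmic grid; predictions are clamped to [0, 1].
Features are used unstandardized so the fitted objective is exactly the
one above; an optional standardization flag exists but defaults off.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

__all__ = [
    "QualityModel",
    "QUALITY_BINS",
    "default_alpha_grid",
    "fit_quality_lasso",
    "predict_quality",
    "bin_quality",
    "save_quality_model",
    "load_quality_model",
]

QUALITY_BINS = ("poor", "fair", "good", "excellent")


@dataclass
class QualityModel:
    w: np.ndarray
    b: float
    alpha: float
    cv_folds: int
    seed: int
    standardize: bool = False
    feat_mean: np.ndarray | None = None
    feat_scale: np.ndarray | None = None
    cv_mse_path: list[float] = field(default_factory=list)
    alpha_grid: list[float] = field(default_factory=list)
    nonzero_path: list[int] = field(default_factory=list)

    @property
    def nonzero_count(self) -> int:
        return int(np.count_nonzero(self.w))

    @property
    def n_features(self) -> int:
        return int(self.w.size)


def default_alpha_grid(features: np.ndarray, labels: np.ndarray,
                       n_alphas: int = 50, decades: float = 4.0) -> np.ndarray:
    """Log-spaced grid from the smallest alpha that zeroes all weights
    (alpha_max = max |X_c^T y_c| / N on centered data) down ``decades``
    decades, descending."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    alpha_max = float(np.abs(Xc.T @ yc).max() / X.shape[0])
    if alpha_max <= 0:
        alpha_max = 1e-3
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max) - decades,
                       n_alphas)


def _fit_one(X, y, alpha):
    m = Lasso(alpha=alpha, fit_intercept=True, max_iter=50000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter
        m.fit(X, y)
    return m.coef_.copy(), float(m.intercept_)


def fit_quality_lasso(features: np.ndarray, labels: np.ndarray,
                      folds: int = 5, alpha_grid=None, seed: int = 0,
                      standardize: bool = False) -> QualityModel:
    """Cross-validated Lasso fit of quality labels on embeddings.

    For each alpha on the grid, the mean out-of-fold squared error over a
    seeded K-fold partition is computed; the alpha minimizing it is
    selected and the model refit on all data.  Constant labels short-
    circuit to the trivial model w = 0, b = mean(labels), with a warning.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be N x D aligned with labels")
    N = X.shape[0]
    if N < folds or folds < 2:
        raise ValueError(f"need N >= folds >= 2, got N={N}, folds={folds}")
    if y.min() < 0 or y.max() > 1:
        raise ValueError("quality labels must lie in [0, 1]")

    feat_mean = feat_scale = None
    if standardize:
        feat_mean = X.mean(axis=0)
        feat_scale = X.std(axis=0)
        feat_scale[feat_scale == 0] = 1.0
        X = (X - feat_mean) / feat_scale

    if np.ptp(y) == 0:
        warnings.warn("constant quality labels: returning w = 0 model")
        return QualityModel(w=np.zeros(X.shape[1]), b=float(y[0]),
                            alpha=float("nan"), cv_folds=folds, seed=seed,
                            standardize=standardize, feat_mean=feat_mean,
                            feat_scale=feat_scale)

    grid = (np.asarray(alpha_grid, dtype=np.float64) if alpha_grid is not None
            else default_alpha_grid(X, y))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    cv_mse = []
    for alpha in grid:
        errs = []
        for tr, te in splits:
            w, b = _fit_one(X[tr], y[tr], alpha)
            errs.append(float(np.mean((X[te] @ w + b - y[te]) ** 2)))
        cv_mse.append(float(np.mean(errs)))
    best = int(np.argmin(cv_mse))
    alpha = float(grid[best])

    nonzero_path = []
    for a in grid:
        wa, _ = _fit_one(X, y, a)
        nonzero_path.append(int(np.count_nonzero(wa)))
    w, b = _fit_one(X, y, alpha)
    return QualityModel(w=w, b=b, alpha=alpha, cv_folds=folds, seed=seed,
                        standardize=standardize, feat_mean=feat_mean,
                        feat_scale=feat_scale, cv_mse_path=cv_mse,
                        alpha_grid=[float(a) for a in grid],
                        nonzero_path=nonzero_path)


def lasso_objective(X, y, w, b, alpha) -> float:
    """The penalized loss the fit minimizes; exposed for verification."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    resid = X @ w + b - y
    return float((resid @ resid) / (2 * X.shape[0]) + alpha * np.abs(w).sum())


def predict_quality(model: QualityModel, embedding: np.ndarray) -> float | np.ndarray:
    """clamp(w . l + b, 0, 1) for one embedding or a stack of them."""
    l = np.asarray(embedding, dtype=np.float64)
    single = l.ndim == 1
    L = l[None, :] if single else l
    if L.shape[1] != model.n_features:
        raise ValueError(f"embedding dim {L.shape[1]} != model dim {model.n_features}")
    if model.standardize:
        L = (L - model.feat_mean) / model.feat_scale
    out = np.clip(L @ model.w + model.b, 0.0, 1.0)
    return float(out[0]) if single else out


def bin_quality(score: float) -> str:
    """Quality bins: poor [0, 0.25], fair (0.25, 0.5], good (0.5, 0.75],
    excellent (0.75, 1] — boundaries belong to the lower bin."""
    if not (0.0 <= score <= 1.0):
        raise ValueError("quality score must lie in [0, 1]")
    if score <= 0.25:
        return "poor"
    if score <= 0.5:
        return "fair"
    if score <= 0.75:
        return "good"
    return "excellent"


def save_quality_model(model: QualityModel, path: str | Path) -> None:
    d = {
        "w": model.w.tolist(), "b": model.b, "alpha": model.alpha,
        "cv_folds": model.cv_folds, "seed": model.seed,
        "standardize": model.standardize,
        "feat_mean": None if model.feat_mean is None else model.feat_mean.tolist(),
        "feat_scale": None if model.feat_scale is None else model.feat_scale.tolist(),
        "alpha_grid": model.alpha_grid, "cv_mse_path": model.cv_mse_path,
        "nonzero_path": model.nonzero_path,
    }
    Path(path).write_text(json.dumps(d))


def load_quality_model(path: str | Path) -> QualityModel:
    d = json.loads(Path(path).read_text())
    return QualityModel(
        w=np.asarray(d["w"], dtype=np.float64), b=float(d["b"]),
        alpha=float(d["alpha"]), cv_folds=int(d["cv_folds"]),
        seed=int(d["seed"]), standardize=bool(d["standardize"]),
        feat_mean=None if d["feat_mean"] is None else np.asarray(d["feat_mean"]),
        feat_scale=None if d["feat_scale"] is None else np.asarray(d["feat_scale"]),
        cv_mse_path=d.get("cv_mse_path", []),
        alpha_grid=d.get("alpha_grid", []),
        nonzero_path=d.get("nonzero_path", []),
    )
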