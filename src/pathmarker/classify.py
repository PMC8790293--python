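"""Maximum-margin linear classification of tumor vs normal samples.

The diagnostic model is the linear support vector machine: a separating
hyperplane w.x + b = 0 chosen to maximize the margin 2/||w|| between the
two support hyperplanes, i.e. the solution of

    min_{w,b}  (1/2)||w||^2 + C * sum_i xi_i
    s.t.       y_i (w.x_i + b) >= 1 - xi_i,   xi_i >= 0,

with y_i in {-1, +1} (tumor = +1).  The hard-margin program of the model
equations is the large-C limit and is recovered exactly on separable data.
The dual is solved by a deterministic SMO (sequential minimal optimization)
with maximal-violating-pair working-set selection, run to KKT tolerance
1e-6; there is no randomized state anywhere in the solver.

Evaluation follows the usual diagnostic conventions: stratified 50/50
train/test splits, stratified k-fold cross-validation with pooled
out-of-fold predictions, confusion matrix with tumor as the positive
class, sensitivity TP/(TP+FN), specificity TN/(TN+FP), and AUC computed
from the Mann-Whitney rank statistic with half credit for ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "SplitPlan",
    "SVMModel",
    "EvalReport",
    "ConvergenceError",
    "stratified_split",
    "standardize_fit",
    "train_svm",
    "decision_values",
    "predict",
    "stratified_folds",
    "cross_validate",
    "evaluate",
]

POSITIVE, NEGATIVE = 1, -1


class ConvergenceError(RuntimeError):
    """SMO failed to reach the KKT tolerance within the iteration cap."""


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """A stratified train/test partition of sample indices."""

    train: tuple[int, ...]
    test: tuple[int, ...]
    seed: int


def stratified_split(
    labels: Sequence[int] | np.ndarray, fraction: float = 0.5, seed: int = 0
) -> SplitPlan:
    """Random stratified split preserving class proportions.

    Each class contributes round(fraction * n_class) samples to the
    training side (round-half-up, deterministic), the rest to the test
    side; assignment within a class is a seeded permutation.  Both classes
    must have at least 2 samples.
    """
    y = np.asarray(labels)
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    for cls in sorted(np.unique(y).tolist()):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        n_train = int(np.floor(fraction * idx.size + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx)
        train.extend(perm[:n_train].tolist())
        test.extend(perm[n_train:].tolist())
    return SplitPlan(train=tuple(sorted(train)), test=tuple(sorted(test)), seed=seed)


def stratified_folds(
    labels: Sequence[int] | np.ndarray, k: int, seed: int = 0
) -> list[np.ndarray]:
    """Deterministic stratified k-fold partition (list of test-index arrays)."""
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in sorted(np.unique(y).tolist()):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for pos, sample in enumerate(idx):
            folds[pos % k].append(int(sample))
    return [np.array(sorted(f), dtype=int) for f in folds]


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and standard deviation (zero sd mapped to 1)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

@dataclass
class SVMModel:
    """A fitted linear max-margin model in standardized feature space."""

    w: np.ndarray
    b: float
    C: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    support_indices: np.ndarray = field(default_factory=lambda: np.array([], int))
    n_iter: int = 0

    @property
    def margin(self) -> float:
        """Geometric margin between the support hyperplanes, 2/||w||."""
        return 2.0 / float(np.linalg.norm(self.w))

    def to_dict(self, feature_names: Sequence[str] | None = None) -> dict:
        d = {
            "w": self.w.tolist(),
            "b": self.b,
            "C": self.C,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
        }
        if feature_names is not None:
            d["feature_names"] = list(feature_names)
        return d


def _smo(
    K: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int]:
    """Maximal-violating-pair SMO on the dual of the soft-margin SVM.

    Minimizes (1/2) a'Qa - e'a over 0 <= a <= C with y'a = 0, where
    Q_ij = y_i y_j K_ij.  Returns (alpha, b, iterations).
    """
    n = y.size
    alpha = np.zeros(n)
    grad = -np.ones(n)  # grad = Q alpha - e
    eps = 1e-12
    Qy = K * y  # row i of Q is y_i * Qy[i]; computed lazily per column below

    for it in range(max_iter):
        yg = -y * grad
        up = ((y == 1) & (alpha < C - eps)) | ((y == -1) & (alpha > eps))
        low = ((y == 1) & (alpha > eps)) | ((y == -1) & (alpha < C - eps))
        if not up.any() or not low.any():
            break
        yg_up = np.where(up, yg, -np.inf)
        yg_low = np.where(low, yg, np.inf)
        i = int(np.argmax(yg_up))
        j = int(np.argmin(yg_low))
        m_up, m_low = yg[i], yg[j]
        if m_up - m_low < tol:
            b = 0.5 * (m_up + m_low)
            return alpha, float(b), it
        quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
        quad = max(quad, 1e-12)
        d = (m_up - m_low) / quad
        # move along the feasible direction: alpha_i += y_i d, alpha_j -= y_j d
        if y[i] == 1:
            d = min(d, C - alpha[i])
        else:
            d = min(d, alpha[i])
        if y[j] == 1:
            d = min(d, alpha[j])
        else:
            d = min(d, C - alpha[j])
        delta_i = y[i] * d
        delta_j = -y[j] * d
        alpha[i] += delta_i
        alpha[j] += delta_j
        # grad update: grad += Q[:, i] dalpha_i + Q[:, j] dalpha_j
        grad += y * (Qy[:, i] * delta_i + Qy[:, j] * delta_j)
    else:
        raise ConvergenceError(
            f"SMO did not converge in {max_iter} iterations "
            f"(n={n}, C={C}); final KKT gap unknown"
        )
    # degenerate exit: one side of the box empty
    yg = -y * grad
    return alpha, float(np.median(yg)), it


def train_svm(
    X: np.ndarray,
    y: Sequence[int] | np.ndarray,
    C: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 2_000_000,
    standardize: bool = True,
) -> SVMModel:
    """Fit the soft-margin linear SVM on (samples x features) data.

    Features are standardized with the training data's own mean and sd
    (the stored parameters are applied again at prediction time, so no
    statistics leak from evaluation data).  On linearly separable data
    with large C the fit satisfies the hard-margin constraints
    y_i (w.x_i + b) >= 1 - 1e-6.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n_samples, n_features) matching y")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if not np.array_equal(classes, [-1.0, 1.0]):
        raise ValueError("labels must be -1/+1 with both classes present")
    if C <= 0:
        raise ValueError("C must be positive")

    if standardize:
        mean, sd = standardize_fit(X)
    else:
        mean = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    Xs = (X - mean) / sd

    K = Xs @ Xs.T
    alpha, b, n_iter = _smo(K, y, C, tol, max_iter)
    w = Xs.T @ (alpha * y)
    support = np.flatnonzero(alpha > 1e-8)
    return SVMModel(
        w=w, b=b, C=C, feature_mean=mean, feature_sd=sd,
        support_indices=support, n_iter=n_iter,
    )


def decision_values(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Signed distances w.x_std + b (raw decision scores)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.w.size:
        raise ValueError(
            f"feature count {X.shape[-1]} does not match model ({model.w.size})"
        )
    Xs = (X - model.feature_mean) / model.feature_sd
    return Xs @ model.w + model.b


def predict(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Class labels from the sign of the decision score; score 0 -> +1."""
    scores = decision_values(model, X)
    return np.where(scores >= 0, POSITIVE, NEGATIVE)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Confusion matrix, sensitivity/specificity, ROC points and AUC."""

    tp: int
    fn: int
    fp: int
    tn: int
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_thresholds: np.ndarray

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def to_dict(self) -> dict:
        return {
            "confusion": {"TP": self.tp, "FN": self.fn,
                          "FP": self.fp, "TN": self.tn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def evaluate(
    y_true: Sequence[int] | np.ndarray, scores: Sequence[float] | np.ndarray
) -> EvalReport:
    """Score-based evaluation with tumor (+1) as the positive class.

    The confusion matrix thresholds scores at 0 (score exactly 0 counts as
    positive).  AUC is the Mann-Whitney statistic: the fraction of
    positive-negative pairs ranked correctly, ties counted half.  The ROC
    curve sweeps all unique score thresholds from +inf down.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    if y.size != s.size:
        raise ValueError("labels and scores differ in length")
    pos = y == POSITIVE
    neg = y == NEGATIVE
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")

    pred_pos = s >= 0
    tp = int(np.sum(pred_pos & pos))
    fn = int(np.sum(~pred_pos & pos))
    fp = int(np.sum(pred_pos & neg))
    tn = int(np.sum(~pred_pos & neg))

    ranks = rankdata(s)  # average ranks give half credit for ties
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    sorted_scores = s[order]
    sorted_pos = pos[order].astype(int)
    sorted_neg = neg[order].astype(int)
    # thresholds at each unique score (predict positive when score >= t)
    distinct = np.r_[True, np.diff(sorted_scores) != 0]
    cut = np.flatnonzero(distinct)
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(sorted_neg)
    idx = np.r_[cut[1:] - 1, sorted_scores.size - 1]
    roc_tpr = np.r_[0.0, tps[idx] / n_pos]
    roc_fpr = np.r_[0.0, fps[idx] / n_neg]
    roc_thresholds = np.r_[np.inf, sorted_scores[cut]]

    return EvalReport(
        tp=tp, fn=fn, fp=fp, tn=tn, auc=float(auc),
        roc_fpr=roc_fpr, roc_tpr=roc_tpr, roc_thresholds=roc_thresholds,
    )


def cross_validate(
    X: np.ndarray,
    y: Sequence[int] | np.ndarray,
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> EvalReport:
    """Stratified k-fold CV with pooled out-of-fold predictions.

    One model is trained per fold on the complement (standardized with
    that training fold's statistics only) and scored on the held-out fold;
    the pooled scores across all folds form a single confusion matrix and
    ROC.  If a class has fewer than k samples, k is reduced to the
    smaller class size with a warning.
    """
    import warnings

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    min_class = min(int(np.sum(y == c)) for c in np.unique(y))
    if min_class < k:
        warnings.warn(
            f"reducing k from {k} to {min_class} (smallest class size)",
            stacklevel=2,
        )
        k = min_class
    folds = stratified_folds(y, k, seed=seed)
    pooled_scores = np.empty(y.size)
    for test_idx in folds:
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        model = train_svm(X[train_mask], y[train_mask], C=C)
        pooled_scores[test_idx] = decision_values(model, X[test_idx])
    return evaluate(y, pooled_scores)
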