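"""Classifiers, stratified cross-validation, metric panels and ROC/AUC.

Four linear-algebra-level classifiers (k-NN, LDA, L2 logistic regression,
linear SVM) with a stratified k-fold evaluator.  CRC is the positive class
throughout; the per-class metric panel is produced by role reversal (CO
metrics treat CO as positive), as diagnostic studies usually tabulate.
Fold confusion counts are *pooled* into one whole-cohort matrix rather than
averaging per-fold metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .containers import CLASS_LABELS, SweatvocError

__all__ = [
    "stratified_kfold",
    "fit_predict_knn",
    "fit_predict_lda",
    "fit_predict_logreg",
    "fit_predict_linsvm",
    "confusion_and_metrics",
    "roc_auc",
    "cross_validate",
    "ConfusionMatrix",
    "MetricsPanel",
    "CVResult",
    "CLASSIFIERS",
]


def _labels01(labels) -> np.ndarray:
    lab = np.asarray(labels)
    bad = sorted(set(lab) - set(CLASS_LABELS))
    if bad:
        raise SweatvocError(f"unseen labels {bad}")
    return (lab == "CRC").astype(int)


def _to01(labels) -> tuple[np.ndarray, np.ndarray]:
    lab = np.asarray(labels)
    return lab, _labels01(lab)


# ------------------------------------------------------------------ folds

def stratified_kfold(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1 per sample) preserving class proportions.

    Within each class the fold counts differ by at most one; the extra
    samples of each class go to the folds with the smallest running totals,
    so total fold sizes are as even as the class counts permit.  Shuffling
    is seeded and deterministic.
    """
    lab = np.asarray(labels)
    if k < 2:
        raise SweatvocError("k must be >= 2 (k=1 leaves no held-out data)")
    rng = np.random.default_rng(seed)
    assign = np.empty(lab.size, dtype=int)
    totals = np.zeros(k, dtype=int)
    for cls in sorted(set(lab)):
        idx = np.flatnonzero(lab == cls)
        if idx.size < k:
            raise SweatvocError(f"class {cls!r} has {idx.size} samples, fewer than k={k}")
        idx = rng.permutation(idx)
        base, extra = divmod(idx.size, k)
        counts = np.full(k, base, dtype=int)
        order = np.lexsort((np.arange(k), totals))  # smallest totals first
        counts[order[:extra]] += 1
        start = 0
        for f in range(k):
            assign[idx[start : start + counts[f]]] = f
            start += counts[f]
        totals += counts
    return assign


# ------------------------------------------------------------- classifiers

def fit_predict_knn(train_X, train_labels, test_X, k: int = 5):
    """k-nearest-neighbour vote with Euclidean distances.

    Vote ties are broken by the smaller mean distance to the tied class's
    neighbours, then in favour of the negative (CO) class.  Scores are the
    CRC vote fraction among the k neighbours.
    """
    train_X = np.asarray(train_X, float)
    test_X = np.asarray(test_X, float)
    lab, y = _to01(train_labels)
    if k > train_X.shape[0]:
        raise SweatvocError(f"k={k} exceeds training size {train_X.shape[0]}")
    if k % 2 == 0:
        warnings.warn("even k: vote ties possible; tie rule applies", stacklevel=2)
    d = cdist(test_X, train_X)
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    preds, scores = [], []
    for i in range(test_X.shape[0]):
        votes = y[nn[i]]
        crc = int(votes.sum())
        co = k - crc
        scores.append(crc / k)
        if crc > co:
            preds.append("CRC")
        elif co > crc:
            preds.append("CO")
        else:
            d_crc = d[i, nn[i][votes == 1]].mean()
            d_co = d[i, nn[i][votes == 0]].mean()
            if d_crc < d_co:
                preds.append("CRC")
            elif d_co < d_crc:
                preds.append("CO")
            else:
                preds.append("CO")  # final tie: negative class
    return np.asarray(preds, object), np.asarray(scores)


def fit_predict_lda(train_X, train_labels, test_X, shrinkage_eps: float = 1e-6):
    """Gaussian equal-covariance (Fisher) discriminant.

    Pooled within-class covariance with a ridge ``eps * mean(diag) * I``;
    scores are posterior log-odds for CRC including the class priors.
    """
    X = np.asarray(train_X, float)
    lab, y = _to01(train_labels)
    if y.all() or not y.any():
        raise SweatvocError("both classes must be present in training data")
    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n = X.shape[0]
    scatter = (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
    sw = scatter / max(n - 2, 1)
    ridge = shrinkage_eps * max(np.trace(sw) / sw.shape[0], 1.0)
    sw = sw + ridge * np.eye(sw.shape[0])
    try:
        w = np.linalg.solve(sw, mu1 - mu0)
    except np.linalg.LinAlgError as err:
        raise SweatvocError(
            "singular within-class covariance; reduce dimensions (e.g. PCA) first"
        ) from err
    prior = np.log(y.mean() / (1 - y.mean()))
    b = -0.5 * (mu0 + mu1) @ w + prior
    scores = np.asarray(test_X, float) @ w + b
    preds = np.where(scores > 0, "CRC", "CO").astype(object)
    return preds, scores


def fit_predict_logreg(
    train_X, train_labels, test_X, l2: float = 1.0, tol: float = 1e-6, max_iter: int = 200
):
    """L2-penalized logistic regression by Newton (IRLS) iterations.

    Minimizes mean log-loss + ``l2/2 * ||w||²`` (intercept unpenalized) to a
    gradient norm below ``tol``; scores are the test log-odds.
    """
    X = np.asarray(train_X, float)
    lab, y = _to01(train_labels)
    n, p = X.shape
    Z = np.hstack([X, np.ones((n, 1))])
    beta = np.zeros(p + 1)
    pen = np.full(p + 1, l2)
    pen[-1] = 0.0
    for _ in range(max_iter):
        eta = Z @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = Z.T @ (mu - y) / n + pen * beta
        if np.linalg.norm(grad) < tol:
            break
        wdiag = np.maximum(mu * (1 - mu), 1e-10)
        H = (Z * wdiag[:, None]).T @ Z / n + np.diag(pen)
        step = np.linalg.solve(H, grad)
        # backtracking on the penalized loss for safety
        loss0 = _logloss(Z, y, beta, pen)
        alpha = 1.0
        while alpha > 1e-8:
            cand = beta - alpha * step
            if _logloss(Z, y, cand, pen) <= loss0:
                break
            alpha /= 2
        beta = beta - alpha * step
    else:
        raise SweatvocError(
            f"logistic regression did not converge (grad norm {np.linalg.norm(grad):.3g})"
        )
    scores = np.hstack([np.asarray(test_X, float), np.ones((len(test_X), 1))]) @ beta
    preds = np.where(scores > 0, "CRC", "CO").astype(object)
    return preds, scores


def _logloss(Z, y, beta, pen) -> float:
    eta = Z @ beta
    return float(np.mean(np.logaddexp(0.0, eta) - y * eta) + 0.5 * np.sum(pen * beta**2))


def fit_predict_linsvm(
    train_X, train_labels, test_X, C: float = 1.0, tol: float = 1e-4, max_iter: int = 2000
):
    """Linear soft-margin SVM via dual coordinate descent (hinge loss).

    The bias is handled as an augmented, regularized feature.  Iterates
    sequential coordinate updates until the maximum projected-gradient
    violation falls below ``tol``; scores are signed decision values.
    """
    X = np.asarray(train_X, float)
    lab, y01 = _to01(train_labels)
    ys = 2.0 * y01 - 1.0
    Z = np.hstack([X, np.ones((X.shape[0], 1))])
    n = Z.shape[0]
    qii = (Z**2).sum(axis=1)
    alpha = np.zeros(n)
    w = np.zeros(Z.shape[1])
    for _ in range(max_iter):
        max_viol = 0.0
        for i in range(n):
            g = ys[i] * (Z[i] @ w) - 1.0
            if alpha[i] <= 0:
                viol = max(0.0, -g)
            elif alpha[i] >= C:
                viol = max(0.0, g)
            else:
                viol = abs(g)
            max_viol = max(max_viol, viol)
            if viol > 0 and qii[i] > 0:
                a_new = np.clip(alpha[i] - g / qii[i], 0.0, C)
                if a_new != alpha[i]:
                    w += (a_new - alpha[i]) * ys[i] * Z[i]
                    alpha[i] = a_new
        if max_viol < tol:
            break
    else:
        raise SweatvocError(f"SVM did not converge (max violation {max_viol:.3g})")
    scores = np.hstack([np.asarray(test_X, float), np.ones((len(test_X), 1))]) @ w
    preds = np.where(scores > 0, "CRC", "CO").astype(object)
    return preds, scores


CLASSIFIERS = {
    "knn": fit_predict_knn,
    "lda": fit_predict_lda,
    "lr": fit_predict_logreg,
    "svm": fit_predict_linsvm,
}


# ---------------------------------------------------------------- metrics

@dataclass
class ConfusionMatrix:
    """Binary confusion counts with CO = negative, CRC = positive."""

    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @classmethod
    def from_predictions(cls, truth, predictions) -> "ConfusionMatrix":
        t = _labels01(truth)
        p = _labels01(predictions)
        if t.size != p.size:
            raise SweatvocError("truth and predictions must align")
        return cls(
            tn=int(((t == 0) & (p == 0)).sum()),
            fp=int(((t == 0) & (p == 1)).sum()),
            fn=int(((t == 1) & (p == 0)).sum()),
            tp=int(((t == 1) & (p == 1)).sum()),
        )


def _panel_from_counts(tn, fp, fn, tp) -> dict[str, float]:
    """Metric panel (fractions in %) treating the 'p' side as positive."""

    def frac(a, b):
        return 100.0 * a / b if b else float("nan")

    sens = frac(tp, tp + fn)
    spec = frac(tn, tn + fp)
    prec = frac(tp, tp + fp)
    f1 = (
        2 * prec * sens / (prec + sens)
        if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
        else float("nan")
    )
    return {
        "accuracy": frac(tp + tn, tp + tn + fp + fn),
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
    }


@dataclass
class MetricsPanel:
    """Five-metric panel per class, percentages at full precision.

    The CRC column treats CRC as positive; the CO column swaps the roles.
    ``accuracy`` is the single overall accuracy in both columns.
    """

    per_class: dict[str, dict[str, float]]

    @property
    def accuracy(self) -> float:
        return self.per_class["CRC"]["accuracy"]

    def to_frame(self, decimals: int | None = 1) -> pd.DataFrame:
        df = pd.DataFrame(self.per_class)[list(CLASS_LABELS)]
        df.index.name = "metric"
        return df.round(decimals) if decimals is not None else df


def confusion_and_metrics(truth, predictions) -> tuple[ConfusionMatrix, MetricsPanel]:
    """Pooled confusion matrix plus the per-class five-metric panel."""
    cm = ConfusionMatrix.from_predictions(truth, predictions)
    return cm, metrics_panel(cm)


def metrics_panel(cm: ConfusionMatrix) -> MetricsPanel:
    crc = _panel_from_counts(cm.tn, cm.fp, cm.fn, cm.tp)
    co = _panel_from_counts(tn=cm.tp, fp=cm.fn, fn=cm.fp, tp=cm.tn)  # role reversal
    return MetricsPanel({"CO": co, "CRC": crc})


# ------------------------------------------------------------------- ROC

def roc_auc(truth, scores) -> tuple[pd.DataFrame, float]:
    """ROC curve by threshold sweep and trapezoidal AUC.

    Equal scores share a threshold, which makes the trapezoid AUC equal to
    the pair-counting (Mann–Whitney) statistic with half-credit for ties.
    """
    t = _labels01(truth)
    s = np.asarray(scores, dtype=float)
    npos, nneg = int(t.sum()), int((1 - t).sum())
    if npos == 0 or nneg == 0:
        raise SweatvocError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_ord, t_ord = s[order], t[order]
    tps = np.cumsum(t_ord)
    fps = np.cumsum(1 - t_ord)
    # collapse tied scores to one operating point (the last index of each tie)
    distinct = np.r_[np.flatnonzero(np.diff(s_ord)), s_ord.size - 1]
    tpr = np.r_[0.0, tps[distinct] / npos]
    fpr = np.r_[0.0, fps[distinct] / nneg]
    thresh = np.r_[np.inf, s_ord[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"threshold": thresh, "fpr": fpr, "tpr": tpr})
    return points, auc


# -------------------------------------------------------------------- CV

@dataclass
class CVResult:
    """Stratified cross-validation outcome with pooled counts."""

    fold_assignments: np.ndarray
    predictions: np.ndarray           # one prediction per sample, pooled
    scores: np.ndarray
    confusion: ConfusionMatrix
    metrics: MetricsPanel
    roc_points: pd.DataFrame
    auc: float
    seed: int
    classifier: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return self.metrics.accuracy


def cross_validate(
    X,
    labels,
    classifier: str = "knn",
    k_folds: int = 5,
    seed: int = 0,
    classifier_params: dict | None = None,
    fold_transform=None,
) -> CVResult:
    """Stratified k-fold CV with pooled confusion counts.

    ``fold_transform(train_X, train_labels, test_X) -> (train_X', test_X')``
    lets callers refit preprocessing inside each training fold (the
    leakage-free evaluation mode); when omitted, ``X`` is used as-is.
    Every sample is predicted exactly once.
    """
    if classifier not in CLASSIFIERS:
        raise SweatvocError(f"unknown classifier {classifier!r}; choose from {list(CLASSIFIERS)}")
    X = np.asarray(X, dtype=float)
    lab = np.asarray(labels, dtype=object)
    folds = stratified_kfold(lab, k=k_folds, seed=seed)
    preds = np.empty(lab.size, dtype=object)
    scores = np.empty(lab.size, dtype=float)
    params = classifier_params or {}
    for f in range(k_folds):
        test = folds == f
        train = ~test
        Xtr, Xte = X[train], X[test]
        if fold_transform is not None:
            Xtr, Xte = fold_transform(Xtr, lab[train], Xte)
        p, s = CLASSIFIERS[classifier](Xtr, lab[train], Xte, **params)
        preds[test] = p
        scores[test] = s
    cm, panel = confusion_and_metrics(lab, preds)
    points, auc = roc_auc(lab, scores)
    return CVResult(folds, preds, scores, cm, panel, points, auc, seed, classifier)
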