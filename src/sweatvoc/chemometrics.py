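"""Latent-variable chemometrics: PCA, PLS-DA with VIP scores, OSC, PERMANOVA.

These are the multivariate work-horses of both arms, implemented from
scratch on top of dense linear algebra:

* **PCA** — SVD of the column-centered matrix; explained-variance ratios are
  squared singular values over total centered variance.
* **PLS-DA** — NIPALS PLS1 against a centered 0/1 class dummy: per
  component, the weight vector is the (normalized) covariance direction
  ``X'y``, scores are ``t = Xw``, and both blocks are deflated.  Variable
  importance in projection (VIP) summarises each feature's contribution
  across components, weighted by the Y-variance each component explains;
  over p features the VIP mean square is identically 1.
* **OSC** — orthogonal signal correction in the iterative NIPALS style: a
  candidate score (started from the first PC) is repeatedly orthogonalized
  against the class variable and regressed back onto X until stable, and the
  resulting rank-one component — structured variation mathematically
  unrelated to class — is removed.  Stored weights transform held-out data
  without touching its labels.  This is the drift filter of the E-nose arm.
* **PERMANOVA** — pseudo-F on the Euclidean distance matrix (between-group
  over within-group mean squared distances) with a seeded label-permutation
  null.

All component signs follow one convention (the largest-magnitude loading or
weight entry is positive) so scores and plots are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import FeatureMatrix, SweatvocError

__all__ = [
    "PCAModel",
    "fit_pca",
    "PLSModel",
    "fit_plsda",
    "vip_scores",
    "OSCModel",
    "osc_correct",
    "StatResult",
    "permanova",
]


def _as_X(m) -> np.ndarray:
    X = m.X if isinstance(m, FeatureMatrix) else np.asarray(m, dtype=float)
    if np.isnan(X).any():
        raise SweatvocError("complete matrix required; impute first")
    return X


def _sign_fix(vec: np.ndarray) -> float:
    """Sign making the largest-|entry| element positive."""
    return 1.0 if vec[np.argmax(np.abs(vec))] >= 0 else -1.0


def _y01(labels) -> np.ndarray:
    lab = np.asarray(labels)
    y = (lab == "CRC").astype(float)
    if y.all() or not y.any():
        raise SweatvocError("both classes must be present")
    return y


# --------------------------------------------------------------------- PCA

@dataclass
class PCAModel:
    center: np.ndarray
    loadings: np.ndarray            # features × components, orthonormal columns
    scores: np.ndarray              # samples × components
    explained_variance_ratio: np.ndarray

    def transform(self, m) -> np.ndarray:
        return (_as_X(m) - self.center) @ self.loadings


def fit_pca(m, n_components: int = 3) -> PCAModel:
    """Principal component analysis of a column-centered matrix via SVD."""
    X = _as_X(m)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise SweatvocError(f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}")
    center = X.mean(axis=0)
    Xc = X - center
    total = float((Xc**2).sum())
    if total <= 0:
        raise SweatvocError("constant matrix has no principal components")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    load = Vt[:n_components].T.copy()
    scores = U[:, :n_components] * s[:n_components]
    for a in range(n_components):
        sgn = _sign_fix(load[:, a])
        load[:, a] *= sgn
        scores[:, a] *= sgn
    evr = (s[:n_components] ** 2) / total
    return PCAModel(center, load, scores, evr)


# ------------------------------------------------------------------ PLS-DA

@dataclass
class PLSModel:
    """NIPALS PLS1 decomposition against a centered class dummy.

    ``weights`` W, ``x_loadings`` P (features × LVs), ``y_loadings`` q,
    ``scores`` T (samples × LVs); ``ss_y`` is the Y sum of squares captured
    per component, ``explained_y_ratio`` its fraction of the initial Y
    variance, and ``explained_x_ratio`` the X-variance fraction per LV (the
    percentages usually printed on score-plot axes).
    """

    center: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    ss_y: np.ndarray
    explained_y_ratio: np.ndarray
    explained_x_ratio: np.ndarray
    class_coding: dict = field(default_factory=lambda: {"CO": 0.0, "CRC": 1.0})

    @property
    def n_lv(self) -> int:
        return self.weights.shape[1]

    @property
    def rotation(self) -> np.ndarray:
        """R = W (PᵀW)⁻¹, mapping centered X to scores in one step."""
        return self.weights @ np.linalg.inv(self.x_loadings.T @ self.weights)

    def transform(self, m) -> np.ndarray:
        return (_as_X(m) - self.center) @ self.rotation

    def predict_value(self, m) -> np.ndarray:
        """Continuous class prediction (centered dummy scale + y mean)."""
        t = self.transform(m)
        return self.y_mean + t @ self.y_loadings


def fit_plsda(m, labels=None, n_lv: int = 3, tol: float = 1e-12) -> PLSModel:
    """Fit a PLS1 discriminant model by NIPALS deflation.

    Per component: ``w ∝ Xᵀy`` (unit norm), ``t = Xw``, ``p = Xᵀt/tᵀt``,
    ``q = yᵀt/tᵀt``, then both X and y are deflated.  Components beyond the
    rank of the class covariance are truncated with a warning.
    """
    X = _as_X(m)
    if labels is None:
        if not isinstance(m, FeatureMatrix):
            raise SweatvocError("labels required when m is a bare array")
        labels = m.labels.to_numpy()
    y = _y01(labels)
    center = X.mean(axis=0)
    Xd = X - center
    y_mean = float(y.mean())
    yd = y - y_mean
    ss_y_total = float(yd @ yd)
    ss_x_total = float((Xd**2).sum())

    W, P, T, q, ssy = [], [], [], [], []
    ssx = []
    for a in range(n_lv):
        w = Xd.T @ yd
        nw = float(np.linalg.norm(w))
        scale = max(float(np.linalg.norm(Xd)) * float(np.linalg.norm(yd)), 1e-30)
        if nw < tol * scale or nw == 0.0:
            if a == 0 and float(np.linalg.norm(Xd)) > 0:
                # no class covariance at all: fall back to the dominant PC
                # direction so the fit is defined (its y-loading will be ~0)
                _, _, Vt = np.linalg.svd(Xd, full_matrices=False)
                w = Vt[0]
                nw = 1.0
            else:
                warnings.warn(
                    "PLS components truncated: no class covariance left", stacklevel=2
                )
                break
        w = w / nw
        sgn = _sign_fix(w)
        w = w * sgn
        t = Xd @ w
        tt = float(t @ t)
        if tt < tol:
            warnings.warn("PLS components truncated: degenerate score", stacklevel=2)
            break
        p = Xd.T @ t / tt
        qa = float(yd @ t / tt)
        Xd = Xd - np.outer(t, p)
        yd = yd - qa * t
        W.append(w)
        P.append(p)
        T.append(t)
        q.append(qa)
        ssy.append(qa * qa * tt)
        ssx.append(tt * float(p @ p))
    if not W:
        raise SweatvocError("PLS-DA could not extract any component")
    W = np.column_stack(W)
    P = np.column_stack(P)
    T = np.column_stack(T)
    q = np.asarray(q)
    ssy = np.asarray(ssy)
    ssx = np.asarray(ssx)
    return PLSModel(
        center=center,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        ss_y=ssy,
        explained_y_ratio=ssy / ss_y_total,
        explained_x_ratio=ssx / ss_x_total,
    )


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable importance in projection.

    ``vip_j = sqrt( p * Σ_a SS_a (w_ja / ‖w_a‖)² / Σ_a SS_a )`` where
    ``SS_a`` is the Y variance captured by component a.  The identity
    ``Σ_j vip_j² = p`` holds to rounding error.
    """
    ss = model.ss_y
    total = float(ss.sum())
    if total <= 0:
        raise SweatvocError("model explains no Y variance; VIP undefined")
    W = model.weights
    p = W.shape[0]
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wn**2 @ ss) / total)


# --------------------------------------------------------------------- OSC

@dataclass
class OSCModel:
    """Stored orthogonal-signal-correction components.

    ``weights[a]`` maps centered data to the a-th removed score;
    ``loadings[a]`` is the rank-one direction removed.  Each stored
    ``scores[a]`` from the training fit satisfies |corr(score, y)| ≈ 0.
    """

    center: np.ndarray
    weights: list[np.ndarray]
    loadings: list[np.ndarray]
    scores: list[np.ndarray]
    n_iter: list[int]
    tol: float
    max_iter: int
    variant: str = "nipals-osc"

    def transform(self, m) -> np.ndarray:
        """Remove the learned components from (possibly held-out) data.

        Uses only stored weights/loadings — never the new data's labels.
        """
        Xc = _as_X(m) - self.center
        for w, p in zip(self.weights, self.loadings):
            t = Xc @ w
            Xc = Xc - np.outer(t, p)
        return Xc + self.center


def osc_correct(
    m,
    labels=None,
    n_osc: int = 1,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[FeatureMatrix | np.ndarray, OSCModel]:
    """Remove class-orthogonal structured variation from a matrix.

    Per component: start from the first principal-component score,
    orthogonalize it against the centered class dummy, regress X onto it for
    a unit weight vector (inner PLS step), recompute the score, and iterate
    to convergence; the converged, exactly orthogonalized score and its
    loading are then deflated from X.  With ``n_osc=0`` the input is
    returned unchanged.
    """
    X = _as_X(m)
    if labels is None:
        if not isinstance(m, FeatureMatrix):
            raise SweatvocError("labels required when m is a bare array")
        labels = m.labels.to_numpy()
    y = _y01(labels)
    center = X.mean(axis=0)
    Xc = X - center
    yc = y - y.mean()
    yy = float(yc @ yc)

    weights, loadings, scores, iters = [], [], [], []
    for _ in range(n_osc):
        # start from the dominant PC of the current residual
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        if s.size == 0 or s[0] <= 0:
            break
        t = U[:, 0] * s[0]
        delta = np.inf
        w = None
        for it in range(1, max_iter + 1):
            t_orth = t - yc * (yc @ t) / yy
            w_new = Xc.T @ t_orth
            nw = float(np.linalg.norm(w_new))
            if nw < 1e-12:
                w = None
                break  # nothing orthogonal to y left to remove
            w_new = w_new / nw
            w_new = w_new * _sign_fix(w_new)
            t_new = Xc @ w_new
            denom = max(float(np.linalg.norm(t_new)), 1e-30)
            delta = float(np.linalg.norm(t_new - t)) / denom
            t, w = t_new, w_new
            if delta < tol:
                break
        else:
            raise SweatvocError(
                f"OSC failed to converge in {max_iter} iterations (last delta {delta:.3g})"
            )
        if w is None:
            break
        t_final = t - yc * (yc @ t) / yy  # exact class-orthogonality
        tt = float(t_final @ t_final)
        if tt < 1e-30:
            break
        p = Xc.T @ t_final / tt
        Xc = Xc - np.outer(t_final, p)
        weights.append(w)
        loadings.append(p)
        scores.append(t_final)
        iters.append(it)

    model = OSCModel(center, weights, loadings, scores, iters, tol, max_iter)
    corrected = Xc + center if weights else X  # bit-exact identity when nothing removed
    if isinstance(m, FeatureMatrix):
        return m.with_values(corrected), model
    return corrected, model


# --------------------------------------------------------------- PERMANOVA

@dataclass
class StatResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    name: str = "PERMANOVA pseudo-F"


def _pseudo_f(d2: np.ndarray, groups: np.ndarray) -> float:
    """Anderson's pseudo-F from a squared Euclidean distance matrix."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    uniq = np.unique(groups)
    for g in uniq:
        idx = np.flatnonzero(groups == g)
        if idx.size < 1:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    g = uniq.size
    ss_between = ss_total - ss_within
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova(m, labels=None, n_perm: int = 999, seed: int = 0) -> StatResult:
    """Permutational multivariate ANOVA on Euclidean distances.

    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`` with seeded label
    permutations; every group needs at least two members.
    """
    X = _as_X(m)
    if labels is None:
        if not isinstance(m, FeatureMatrix):
            raise SweatvocError("labels required when m is a bare array")
        labels = m.labels.to_numpy()
    groups = np.asarray(labels)
    uniq, counts = np.unique(groups, return_counts=True)
    if uniq.size < 2:
        raise SweatvocError("need at least two groups")
    if counts.min() < 2:
        raise SweatvocError("every group needs >= 2 samples")
    d2 = squareform(pdist(X, metric="euclidean")) ** 2
    f_obs = _pseudo_f(d2, groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, rng.permutation(groups)) >= f_obs:
            hits += 1
    return StatResult(f_obs, (1 + hits) / (1 + n_perm), n_perm, seed)
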