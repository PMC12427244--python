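"""Univariate feature screening: Wilcoxon rank-sum with a variance fallback.

Each feature is tested for a location difference between the CO and CRC
groups with the two-sided Wilcoxon rank-sum test (midranks for ties; exact
enumeration for tiny tie-free samples, otherwise a tie-corrected normal
approximation with continuity correction).  Features at p < alpha are
retained; when *no* feature clears the threshold the selector falls back to
the k features of highest variance, on the grounds that variability may
still carry discriminatory signal.  No multiple-testing correction is
applied by default (a Benjamini–Hochberg option exists), mirroring standard
raw-p screening in small-cohort volatilomics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import FeatureMatrix, SweatvocError

__all__ = ["wilcoxon_rank_sum", "select_features", "SelectionResult"]

_EXACT_MAX_N = 12


def _normal_sf(z: float) -> float:
    return 0.5 * (1.0 - erf(z / sqrt(2.0)))


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where ``W`` is the rank-sum of ``x`` in the pooled
    midrank ranking.  ``mode="exact"`` enumerates the permutation
    distribution (only valid without ties); ``"normal"`` uses the
    tie-corrected normal approximation with continuity correction;
    ``"auto"`` picks exact when the pooled size is <= 12 and tie-free.
    If every pooled value is identical the test is degenerate and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise SweatvocError("both groups need at least one value")
    if mode not in ("exact", "normal", "auto"):
        raise SweatvocError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = rankdata(pooled, method="average")
    W = float(ranks[:n1].sum())
    if np.all(pooled == pooled[0]):
        return W, 1.0  # degenerate: no information

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if mode == "exact" and has_ties:
        raise SweatvocError("exact mode requires tie-free data")
    if mode == "auto":
        mode = "exact" if (n <= _EXACT_MAX_N and not has_ties) else "normal"

    mu = n1 * (n + 1) / 2.0
    if mode == "exact":
        # enumerate every assignment of n1 ranks out of 1..n
        dist = [sum(c) for c in combinations(range(1, n + 1), n1)]
        extreme = sum(1 for w in dist if abs(w - mu) >= abs(W - mu) - 1e-9)
        return W, extreme / comb(n, n1)

    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return W, 1.0
    z = (abs(W - mu) - 0.5) / sqrt(var)  # continuity-corrected
    z = max(z, 0.0)
    return W, min(1.0, 2.0 * _normal_sf(z))


@dataclass
class SelectionResult:
    """Outcome of univariate screening over a feature matrix.

    ``table`` has one row per feature: statistic W, two-sided p, per-group
    means, direction (group with higher mean), variance used for the
    fallback ranking, and the selected flag.
    """

    table: pd.DataFrame
    alpha: float
    fallback_used: bool
    k_fallback: int

    @property
    def selected_features(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()

    def apply(self, m: FeatureMatrix) -> FeatureMatrix:
        """Reduce a matrix to the selected features (column order preserved)."""
        keep = [f for f in m.feature_names if f in set(self.selected_features)]
        return m.select_features(keep)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "feature"
        out.to_csv(path, float_format="%.10g")


def select_features(
    m: FeatureMatrix,
    alpha: float = 0.05,
    k_fallback: int = 13,
    variance_from: FeatureMatrix | None = None,
    bh_correct: bool = False,
) -> SelectionResult:
    """Screen features by Wilcoxon p-value with a highest-variance fallback.

    ``variance_from`` supplies the matrix on which fallback variances are
    computed — pass the pre-scaling matrix when ``m`` has been autoscaled,
    since autoscaling flattens all variances to one.  ``bh_correct`` applies
    Benjamini–Hochberg to the p-values before thresholding (off by default).
    """
    if np.isnan(m.X).any():
        raise SweatvocError("selection requires a complete matrix; impute first")
    is_crc = m.labels.to_numpy() == "CRC"
    if is_crc.all() or (~is_crc).all():
        raise SweatvocError("both classes must be present")
    X = m.X
    var_src = m if variance_from is None else variance_from
    if var_src.feature_names != m.feature_names:
        raise SweatvocError("variance_from must share the feature set")

    rows = []
    for j, name in enumerate(m.feature_names):
        w, p = wilcoxon_rank_sum(X[~is_crc, j], X[is_crc, j])
        m_co = X[~is_crc, j].mean()
        m_crc = X[is_crc, j].mean()
        rows.append((name, w, p, m_co, m_crc, "CRC" if m_crc > m_co else "CO"))
    table = pd.DataFrame(
        rows, columns=["feature", "W", "p_value", "mean_CO", "mean_CRC", "direction"]
    ).set_index("feature")
    table["variance"] = var_src.X.var(axis=0, ddof=1)

    pvals = table["p_value"].to_numpy()
    if bh_correct:
        order = np.argsort(pvals)
        q = np.empty_like(pvals)
        prev = 1.0
        for rank_i, idx in enumerate(order[::-1]):
            i = len(pvals) - rank_i
            prev = min(prev, pvals[idx] * len(pvals) / i)
            q[idx] = prev
        pvals = q
        table["q_value"] = q

    selected = pvals < alpha
    fallback_used = not selected.any()
    if fallback_used:
        k = k_fallback
        if k > m.n_features:
            warnings.warn(
                f"k_fallback={k} exceeds feature count {m.n_features}; capping",
                stacklevel=2,
            )
            k = m.n_features
        top = np.argsort(-table["variance"].to_numpy(), kind="stable")[:k]
        selected = np.zeros(m.n_features, dtype=bool)
        selected[top] = True
    table["selected"] = selected
    return SelectionResult(table, alpha, fallback_used, k_fallback)
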