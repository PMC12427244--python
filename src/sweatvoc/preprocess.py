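"""Missing-value imputation and the normalization suite.

Imputation replaces each missing peak area by a moving average over a short
centered window of neighbouring samples (rows) within the same feature
column — window size three by default, matching time-ordered acquisition —
falling back to the column mean when the whole window is unobserved.

Normalization offers seven per-feature transforms: min–max scaling, z-score
standardization, quantile normalization, Pareto scaling, autoscaling, and
log / square-root transforms.  All parameters are learned on a training
matrix and re-applied unchanged to held-out data, so cross-validation folds
never leak test statistics.  Autoscaling and z-score are the same transform
under the population (ddof=0) standard-deviation convention used throughout;
both names are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import FeatureMatrix, SweatvocError

__all__ = ["impute_moving_average", "Normalizer", "NORMALIZATION_METHODS"]

NORMALIZATION_METHODS = ("minmax", "zscore", "autoscale", "pareto", "quantile", "log", "sqrt")

_EPS = 1e-12  # sd floor for constant features


def impute_moving_average(
    m: FeatureMatrix,
    window: int = 3,
    fallback_means: Mapping[str, float] | None = None,
) -> FeatureMatrix:
    """Fill missing entries with a centered windowed mean down each column.

    For a missing cell at row ``i``, the imputed value is the mean of the
    *observed* values among rows ``i-h .. i+h`` (``h = window // 2``) of the
    same column, in stored row order.  If the whole window is missing the
    column mean of observed values is used (or ``fallback_means`` when the
    column has no observed value at all, e.g. a held-out fold).  Observed
    values are never altered; imputing a complete matrix is the identity.
    """
    if window < 3 or window % 2 == 0:
        raise SweatvocError("window must be odd and >= 3")
    h = window // 2
    X = m.X.copy()
    orig = m.X  # imputed cells always read original observations
    for j, name in enumerate(m.feature_names):
        col = orig[:, j]
        obs = ~np.isnan(col)
        if not obs.any():
            if fallback_means is not None and name in fallback_means:
                X[:, j] = fallback_means[name]
                continue
            raise SweatvocError(
                f"feature {name!r} is fully missing; drop it upstream or pass fallback_means"
            )
        col_mean = col[obs].mean()
        for i in np.flatnonzero(~obs):
            lo, hi = max(0, i - h), min(len(col), i + h + 1)
            win = col[lo:hi]
            win = win[~np.isnan(win)]
            X[i, j] = win.mean() if win.size else col_mean
    return m.with_values(X)


@dataclass
class Normalizer:
    """Per-feature normalization with train-learned parameters.

    >>> norm = Normalizer("autoscale").fit(train)
    >>> train_z, test_z = norm.transform(train), norm.transform(test)
    """

    method: str = "autoscale"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in NORMALIZATION_METHODS:
            raise SweatvocError(
                f"unknown method {self.method!r}; choose from {NORMALIZATION_METHODS}"
            )

    # ------------------------------------------------------------------
    def fit(self, train: FeatureMatrix) -> "Normalizer":
        X = train.X
        if np.isnan(X).any():
            raise SweatvocError("normalization requires a complete matrix; impute first")
        p = self.params
        p["features"] = train.feature_names
        if self.method == "minmax":
            p["min"] = X.min(axis=0)
            p["range"] = np.maximum(X.max(axis=0) - X.min(axis=0), _EPS)
        elif self.method in ("zscore", "autoscale"):
            p["mean"] = X.mean(axis=0)
            p["sd"] = np.maximum(X.std(axis=0, ddof=0), _EPS)
        elif self.method == "pareto":
            p["mean"] = X.mean(axis=0)
            p["sqrt_sd"] = np.sqrt(np.maximum(X.std(axis=0, ddof=0), _EPS))
        elif self.method == "quantile":
            # reference distribution: per-rank means of the sorted columns
            p["reference"] = np.sort(X, axis=0).mean(axis=1)
        elif self.method == "log":
            p["offset"] = 1.0 if X.min() <= 0 else 0.0
            if X.min() + p["offset"] <= 0:
                raise SweatvocError("log transform needs values > -offset")
        elif self.method == "sqrt":
            if X.min() < 0:
                raise SweatvocError("sqrt transform needs non-negative values")
        return self

    def transform(self, m: FeatureMatrix) -> FeatureMatrix:
        if not self.params:
            raise SweatvocError("fit the normalizer before transforming")
        if m.feature_names != self.params["features"]:
            raise SweatvocError("feature set differs from the training matrix")
        X = m.X
        if np.isnan(X).any():
            raise SweatvocError("normalization requires a complete matrix; impute first")
        p = self.params
        if self.method == "minmax":
            out = (X - p["min"]) / p["range"]
        elif self.method in ("zscore", "autoscale"):
            out = (X - p["mean"]) / p["sd"]
        elif self.method == "pareto":
            out = (X - p["mean"]) / p["sqrt_sd"]
        elif self.method == "quantile":
            ref = p["reference"]
            ref_q = (np.arange(ref.size) + 0.5) / ref.size
            out = np.empty_like(X)
            for j in range(X.shape[1]):
                r = rankdata(X[:, j], method="average")  # midranks for ties
                out[:, j] = np.interp((r - 0.5) / X.shape[0], ref_q, ref)
        elif self.method == "log":
            if X.min() + p["offset"] <= 0:
                raise SweatvocError("log transform needs values > -offset")
            out = np.log(X + p["offset"])
        else:  # sqrt
            if X.min() < 0:
                raise SweatvocError("sqrt transform needs non-negative values")
            out = np.sqrt(X)
        return m.with_values(out)

    def fit_transform(self, m: FeatureMatrix) -> FeatureMatrix:
        return self.fit(m).transform(m)

    # -- sidecar serialization so folds and reports are auditable -------
    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "params": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.params.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        params = {
            k: (np.asarray(v, dtype=float) if isinstance(v, list) and k != "features" else v)
            for k, v in d["params"].items()
        }
        return cls(d["method"], params)
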