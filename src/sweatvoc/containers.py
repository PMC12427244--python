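"""Core in-memory containers shared by both analysis arms.

The common currency of the package is the :class:`FeatureMatrix`: a samples ×
features table of non-negative abundances (GC-MS peak areas, or E-nose Max–Min
response amplitudes) together with a binary class label per sample (``CO`` for
controls, ``CRC`` for cases).  Missing entries are represented as NaN and are
distinct from zero: an absent chromatographic peak is *unobserved*, not a
measured zero area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The two recognised class labels. CO (control) is the negative class,
#: CRC the positive class, everywhere in the package.
CLASS_LABELS = ("CO", "CRC")

#: Channel names of the 14-sensor MEMS metal-oxide array, in board order
#: (sensors 1-8 sit on the digital PCB, 9-14 on the analog PCB).
SENSOR_LABELS = (
    "BMU1", "BMU5", "CCU2", "CCU6", "SGOH", "SGH2", "SGO7", "SGH7",
    "VRED", "VOXU", "VNH3", "VNO2", "VOUT", "VN12",
)

#: Acquisition phases of one E-nose measurement, in temporal order.
PHASES = ("stabilize", "baseline", "sample", "purge")


class SweatvocError(ValueError):
    """Base class for domain errors raised by this package."""


def _check_labels(labels: Iterable[str]) -> None:
    bad = sorted({l for l in labels} - set(CLASS_LABELS))
    if bad:
        raise SweatvocError(f"unknown class labels {bad}; expected {CLASS_LABELS}")


@dataclass
class FeatureMatrix:
    """Samples × features abundance table with class labels.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one float column per feature.
        NaN marks a missing (unobserved) entry.
    labels
        Series aligned with ``values.index``, entries in ``{"CO", "CRC"}``.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.labels = pd.Series(self.labels, index=self.values.index, dtype=object)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise SweatvocError(f"duplicate sample ids: {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise SweatvocError(f"duplicate feature names: {dup}")
        _check_labels(self.labels)

    # -- basic accessors -------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        """Values as a float ndarray (samples × features)."""
        return self.values.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Labels as a 0/1 vector (CO → 0, CRC → 1)."""
        return (self.labels.to_numpy() == "CRC").astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.labels.copy())

    def with_values(self, X: np.ndarray) -> "FeatureMatrix":
        """Same samples/features/labels, new value array."""
        X = np.asarray(X, dtype=float)
        if X.shape != self.values.shape:
            raise SweatvocError(f"shape mismatch {X.shape} vs {self.values.shape}")
        return FeatureMatrix(
            pd.DataFrame(X, index=self.values.index, columns=self.values.columns),
            self.labels.copy(),
        )

    def select_features(self, names: Sequence[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise SweatvocError(f"unknown features {missing}")
        return FeatureMatrix(self.values.loc[:, list(names)].copy(), self.labels.copy())

    def select_samples(self, ids: Sequence) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[list(ids)].copy(), self.labels.loc[list(ids)].copy())

    def iloc_samples(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(self.values.iloc[idx].copy(), self.labels.iloc[idx].copy())

    # -- IO ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write as CSV: sample_id, label, then one column per feature."""
        out = self.values.copy()
        out.insert(0, "label", self.labels)
        out.index.name = "sample_id"
        out.to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        labels = df.pop("label")
        return cls(df, labels)

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        labels: Sequence[str],
        feature_names: Sequence[str],
        sample_ids: Sequence[str] | None = None,
    ) -> "FeatureMatrix":
        X = np.asarray(X, dtype=float)
        if sample_ids is None:
            sample_ids = [f"S{i + 1:03d}" for i in range(X.shape[0])]
        values = pd.DataFrame(X, index=list(sample_ids), columns=list(feature_names))
        return cls(values, pd.Series(list(labels), index=values.index))


@dataclass
class PeakTable:
    """One sample's GC-MS peak list before consolidation.

    ``peaks`` is a list of ``(retention_time_minutes, integrated_area)``
    pairs; ``is_area`` optionally carries the internal-standard (limonene)
    peak area used for run-to-run calibration.
    """

    sample_id: str
    peaks: list[tuple[float, float]] = field(default_factory=list)
    is_area: float | None = None

    def __post_init__(self) -> None:
        for rt, area in self.peaks:
            if rt <= 0:
                raise SweatvocError(f"{self.sample_id}: retention time {rt} must be > 0")
            if area < 0:
                raise SweatvocError(f"{self.sample_id}: peak area {area} must be >= 0")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            if self.is_area is not None:
                fh.write(f"# is_area={self.is_area:.10g}\n")
            fh.write("rt_min,area\n")
            for rt, area in self.peaks:
                fh.write(f"{rt:.10g},{area:.10g}\n")

    @classmethod
    def from_csv(cls, path: str | Path, sample_id: str | None = None) -> "PeakTable":
        path = Path(path)
        is_area = None
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# is_area="):
                is_area = float(first.split("=", 1)[1])
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        peaks = list(zip(df["rt_min"].astype(float), df["area"].astype(float)))
        return cls(sample_id or path.stem, peaks, is_area)


@dataclass
class SensorRecording:
    """One E-nose measurement: a timestamped 14-channel transient.

    ``phase`` tags every timestamp with one of :data:`PHASES`; phases are
    contiguous and appear in acquisition order.  ``meta`` carries
    generator-side ground truth (e.g. the drawn drift slope) and is never
    serialized.
    """

    sample_id: str
    label: str
    time_s: np.ndarray
    channels: pd.DataFrame  # one column per sensor, same length as time_s
    phase: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.time_s.ndim != 1:
            raise SweatvocError("time_s must be 1-D")
        if np.any(np.diff(self.time_s) <= 0):
            raise SweatvocError(f"{self.sample_id}: timestamps must be strictly increasing")
        if len(self.channels) != len(self.time_s):
            raise SweatvocError(f"{self.sample_id}: channel length != time length")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=object)
            if len(self.phase) != len(self.time_s):
                raise SweatvocError(f"{self.sample_id}: phase length != time length")
        _check_labels([self.label])

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels.columns)

    def to_csv(self, path: str | Path) -> None:
        out = pd.DataFrame({"time_s": self.time_s})
        out["phase"] = self.phase if self.phase is not None else ""
        for name in self.channels.columns:
            out[name] = self.channels[name].to_numpy()
        with open(path, "w") as fh:
            fh.write(f"# sample_id={self.sample_id}\n# label={self.label}\n")
            out.to_csv(fh, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SensorRecording":
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("# "):
                key, val = line[2:].strip().split("=", 1)
                meta[key] = val
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh)
        phase = df["phase"].to_numpy(dtype=object) if df["phase"].notna().all() else None
        channels = df.drop(columns=["time_s", "phase"])
        return cls(
            sample_id=meta.get("sample_id", Path(path).stem),
            label=meta.get("label", "CO"),
            time_s=df["time_s"].to_numpy(),
            channels=channels,
            phase=phase,
        )
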