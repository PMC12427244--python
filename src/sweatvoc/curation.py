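"""GC-MS peak-table curation: rounding, merging and consolidation.

Per-sample exports from the chromatography software arrive as (retention
time, integrated area) lists.  Curation turns them into one samples ×
retention-time feature matrix: retention times are rounded to a fixed number
of decimals (one by default) so that redundant peaks of the same compound
collapse onto a single feature, rounded duplicates within a sample are
merged, and the per-sample tables are consolidated on the union of rounded
retention times.  A sample that shows no peak at some retention time gets a
*missing* entry there — not a zero — and is handled later by imputation.

Rounding is half-away-from-zero (fixed-decimal report convention) rather
than banker's rounding, so results are reproducible across platforms.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, PeakTable, SweatvocError

__all__ = [
    "round_half_away",
    "round_and_merge",
    "consolidate",
    "split",
    "drop_empty_features",
    "normalize_to_internal_standard",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero to ``decimals`` places."""
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def _rt_name(rt: float) -> str:
    """Feature name for a rounded retention time; parses back bit-exactly."""
    return format(rt, ".10g")


def round_and_merge(
    table: PeakTable, decimals: int = 1, merge_rule: str = "sum"
) -> PeakTable:
    """Round retention times and merge peaks that collapse onto one RT.

    ``merge_rule="sum"`` (default) conserves total abundance when redundant
    peaks are grouped; ``"max"`` keeps the largest of the merged areas.
    Output retention times are strictly increasing and unique.
    """
    if decimals < 0:
        raise SweatvocError("decimals must be >= 0")
    if merge_rule not in ("sum", "max"):
        raise SweatvocError(f"unknown merge_rule {merge_rule!r}")
    merged: dict[float, float] = {}
    for rt, area in table.peaks:
        key = round_half_away(rt, decimals)
        if key in merged:
            merged[key] = merged[key] + area if merge_rule == "sum" else max(merged[key], area)
        else:
            merged[key] = area
    peaks = sorted(merged.items())
    return PeakTable(table.sample_id, peaks, table.is_area)


def consolidate(
    tables: Sequence[PeakTable], labels: Sequence[str]
) -> FeatureMatrix:
    """Stack rounded peak tables into one matrix on the union of RTs.

    Feature order is the ascending retention-time order; a sample without a
    peak at some RT gets NaN there.  Duplicate sample ids are rejected.
    """
    if len(tables) != len(labels):
        raise SweatvocError("tables and labels must align")
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise SweatvocError(f"duplicate sample ids: {dup}")
    all_rts = sorted({rt for t in tables for rt, _ in t.peaks})
    names = [_rt_name(rt) for rt in all_rts]
    X = np.full((len(tables), len(all_rts)), np.nan)
    col = {rt: j for j, rt in enumerate(all_rts)}
    for i, t in enumerate(tables):
        seen = set()
        for rt, area in t.peaks:
            if rt in seen:
                raise SweatvocError(
                    f"{t.sample_id}: duplicate RT {rt}; run round_and_merge first"
                )
            seen.add(rt)
            X[i, col[rt]] = area
    return FeatureMatrix.from_arrays(X, list(labels), names, ids)


def split(m: FeatureMatrix) -> list[PeakTable]:
    """Inverse of :func:`consolidate`: one peak table per sample row."""
    tables = []
    for sid in m.sample_ids:
        row = m.values.loc[sid]
        peaks = [(float(rt), float(a)) for rt, a in row.items() if not pd.isna(a)]
        tables.append(PeakTable(sid, peaks))
    return tables


def drop_empty_features(m: FeatureMatrix, min_present: int = 1) -> FeatureMatrix:
    """Remove retention times without relevant signal.

    A column is kept when at least ``min_present`` entries are observed and
    non-zero.  Raises if nothing survives.
    """
    if min_present < 1:
        raise SweatvocError("min_present must be >= 1")
    present = ((~m.values.isna()) & (m.values != 0)).sum(axis=0)
    keep = [c for c in m.feature_names if present[c] >= min_present]
    if not keep:
        raise SweatvocError("all features would be removed")
    return m.select_features(keep)


def normalize_to_internal_standard(
    m: FeatureMatrix, is_areas: Mapping[str, float]
) -> FeatureMatrix:
    """Divide each sample's areas by its internal-standard (limonene) area.

    Off by default in the pipeline: the spiked standard guarantees run
    comparability, but quantitative division is an explicit opt-in.
    """
    scale = np.empty(m.n_samples)
    for i, sid in enumerate(m.sample_ids):
        a = is_areas.get(sid)
        if a is None or not np.isfinite(a) or a <= 0:
            raise SweatvocError(f"sample {sid}: internal-standard area missing or non-positive")
        scale[i] = a
    return m.with_values(m.X / scale[:, None])
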