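"""E-nose transient processing: phase segmentation and Max–Min features.

One measurement cycles through sensor stabilization, a 1-minute ambient-air
baseline, and 2 minutes of headspace exposure (plus a purge that overlaps
the next stabilization).  The per-sensor feature is the response amplitude —
the difference between the maximum and minimum recorded signal over the
feature window — which captures the full baseline-to-plateau excursion of
each channel.  The default window spans baseline + sample so the excursion
from the resting level is included; a sample-only window is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureMatrix, SensorRecording, SweatvocError

__all__ = ["PhaseDurations", "segment_phases", "extract_max_min", "build_enose_matrix"]


@dataclass
class PhaseDurations:
    """Acquisition phase lengths in seconds."""

    stabilize_s: float = 0.0
    baseline_s: float = 60.0
    sample_s: float = 120.0


def segment_phases(
    r: SensorRecording, durations: PhaseDurations | None = None
) -> SensorRecording:
    """Tag each timestamp with its acquisition phase by elapsed time.

    Boundaries are assigned by time (robust to jittered or irregular
    sampling), not by sample index.  Trailing purge samples are truncated.
    Raises when the recording does not cover baseline + sample.
    """
    d = durations or PhaseDurations()
    t = r.time_s
    t0 = t[0]
    elapsed = t - t0
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    needed = d.stabilize_s + d.baseline_s + d.sample_s
    if elapsed[-1] < needed - 1.5 * dt:
        raise SweatvocError(
            f"{r.sample_id}: recording covers {elapsed[-1]:.1f}s, "
            f"needs {needed:.0f}s (stabilize+baseline+sample)"
        )
    phase = np.empty(t.size, dtype=object)
    phase[elapsed < d.stabilize_s] = "stabilize"
    phase[(elapsed >= d.stabilize_s) & (elapsed < d.stabilize_s + d.baseline_s)] = "baseline"
    sample_end = d.stabilize_s + d.baseline_s + d.sample_s
    phase[(elapsed >= d.stabilize_s + d.baseline_s) & (elapsed < sample_end)] = "sample"
    phase[elapsed >= sample_end] = "purge"
    keep = phase != "purge"
    return SensorRecording(
        sample_id=r.sample_id,
        label=r.label,
        time_s=t[keep],
        channels=r.channels.iloc[np.flatnonzero(keep)].reset_index(drop=True),
        phase=phase[keep],
        meta=dict(r.meta),
    )


def extract_max_min(r: SensorRecording, window: str = "baseline+sample") -> pd.Series:
    """Per-channel response amplitude: max − min over the feature window.

    ``window`` is ``"baseline+sample"`` (default; full dynamic range from
    resting level to plateau) or ``"sample"`` (exposure phase only).
    Stabilization and purge samples never enter the feature.
    """
    if r.phase is None:
        raise SweatvocError(f"{r.sample_id}: segment the recording first")
    if window == "baseline+sample":
        mask = (r.phase == "baseline") | (r.phase == "sample")
    elif window == "sample":
        mask = r.phase == "sample"
    else:
        raise SweatvocError(f"unknown window {window!r}")
    if not mask.any():
        raise SweatvocError(f"{r.sample_id}: empty feature window")
    sub = r.channels.iloc[np.flatnonzero(mask)]
    return sub.max(axis=0) - sub.min(axis=0)


def build_enose_matrix(
    recordings: list[SensorRecording], window: str = "baseline+sample"
) -> FeatureMatrix:
    """Assemble per-recording Max–Min vectors into a samples × sensors matrix."""
    if not recordings:
        raise SweatvocError("no recordings given")
    channels = recordings[0].channel_names
    rows, labels, ids = [], [], []
    for r in recordings:
        if r.channel_names != channels:
            raise SweatvocError(
                f"{r.sample_id}: channel set differs from {recordings[0].sample_id}"
            )
        rows.append(extract_max_min(r, window).to_numpy())
        labels.append(r.label)
        ids.append(r.sample_id)
    return FeatureMatrix.from_arrays(np.vstack(rows), labels, channels, ids)
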