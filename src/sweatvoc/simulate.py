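"""Synthetic GC-MS feature matrices and E-nose transients.

Both analysis arms of the package run on real exported data, but the study
cohort they were designed around is not publicly deposited, so this module
generates data with the same statistical structure:

* **GC-MS arm** — a 65-sample × 187-retention-time matrix of positive,
  right-skewed peak areas.  Thirteen retention-time features are informative:
  their group geometric means default to the reported mean peak areas of the
  13 discriminant sweat volatiles (e.g. 1,3-dimethylbenzene at RT 10.7 min,
  mean area 1.87e6 in controls vs 8.39e5 in cases).  All remaining features
  are drawn identically in both groups.  Peak areas are lognormal
  (multiplicative noise): areas are positive and right-skewed, and a
  coefficient of variation on the natural scale maps to a sigma on the log
  scale.  Missingness is completely at random (rate 0.05 by default).

* **E-nose arm** — one 3-minute, 14-channel recording per participant
  (1 min ambient-air baseline + 2 min headspace exposure, 1 Hz): a
  per-sensor baseline level, a class-dependent response plateau during the
  sample phase, a per-sample linear drift slope shared by both classes, two
  board-level common-mode sensitivity factors (metal-oxide sensors on the
  same PCB share temperature/humidity response), and additive noise.  The
  drift and common-mode factors are the nuisance structure that orthogonal
  signal correction is meant to strip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CLASS_LABELS, SENSOR_LABELS, FeatureMatrix, SensorRecording, SweatvocError

__all__ = [
    "GCMS_MARKER_MEANS",
    "GcmsSimConfig",
    "EnoseSimConfig",
    "simulate_gcms",
    "simulate_enose",
    "default_rt_grid",
]

#: Reported group mean peak areas for the 13 discriminant retention-time
#: features (minutes → (mean area CO, mean area CRC)); used as the default
#: geometric means of the informative features.
GCMS_MARKER_MEANS: dict[str, tuple[float, float]] = {
    "10.7": (1.87e6, 8.39e5),   # benzene, 1,3-dimethyl
    "20.7": (1.83e6, 3.80e5),   # tetradecanoic acid
    "17.8": (9.22e5, 7.48e5),   # 3,7-dimethylnonane
    "10.8": (5.58e6, 8.57e6),   # styrene
    "18.3": (4.55e5, 2.17e5),   # undecane, 4,6-dimethyl
    "6.7": (2.90e8, 1.70e8),    # octane, 2,4,6-trimethyl
    "24.4": (1.07e6, 1.71e6),   # n-heneicosane
    "16.7": (2.51e6, 2.04e6),   # octane, 5-ethyl-2-methyl
    "17.9": (3.65e5, 2.30e5),   # pentadecane
    "24.0": (2.65e5, 1.40e5),   # tridecane, 2-methyl
    "24.6": (1.34e5, 2.04e5),   # tetradecane
    "24.7": (4.22e5, 9.52e4),   # n-pentacosane
    "8.4": (5.27e5, 2.40e6),    # octane, 4-methyl
}


def default_rt_grid(n_features: int = 187, start: float = 6.2, step: float = 0.1) -> list[str]:
    """Retention-time feature names: a 0.1-min grid inside the 29-min run.

    The default grid (6.2–24.8 min) contains all 13 marker retention times.
    """
    return [f"{start + step * i:.1f}" for i in range(n_features)]


def _default_informative(feature_names: list[str]) -> list[tuple[int, float, float]]:
    out = []
    for rt, (m_co, m_crc) in GCMS_MARKER_MEANS.items():
        if rt not in feature_names:
            raise SweatvocError(f"marker RT {rt} not on the feature grid")
        out.append((feature_names.index(rt), m_co, m_crc))
    return out


@dataclass
class GcmsSimConfig:
    """Configuration for :func:`simulate_gcms`.

    ``informative`` lists ``(feature_index, mean_co, mean_crc)`` triples: the
    group *geometric* means of that feature's lognormal peak-area
    distribution, in arbitrary area units.  ``noise_cv`` is the coefficient
    of variation of the multiplicative noise on the natural scale
    (sigma_log = sqrt(ln(1 + cv^2))).
    """

    n_co: int = 34
    n_crc: int = 31
    n_features: int = 187
    informative: list[tuple[int, float, float]] | None = None  # None → 13 default markers
    noise_cv: float = 1.75
    missing_rate: float = 0.05
    seed: int = 0
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_co < 1 or self.n_crc < 1:
            raise SweatvocError("need at least one sample per group")
        if not 0 <= self.missing_rate < 1:
            raise SweatvocError("missing_rate must be in [0, 1)")
        if self.noise_cv < 0:
            raise SweatvocError("noise_cv must be >= 0")
        if self.feature_names is None:
            self.feature_names = default_rt_grid(self.n_features)
        if len(self.feature_names) != self.n_features:
            raise SweatvocError("feature_names length must equal n_features")
        if self.informative is None:
            if set(GCMS_MARKER_MEANS) <= set(self.feature_names):
                self.informative = _default_informative(self.feature_names)
            else:
                self.informative = []
        if len(self.informative) > self.n_features:
            raise SweatvocError("more informative features than features")
        for j, m_co, m_crc in self.informative:
            if not 0 <= j < self.n_features:
                raise SweatvocError(f"informative feature index {j} out of range")
            if m_co <= 0 or m_crc <= 0:
                raise SweatvocError("informative means must be > 0")


def simulate_gcms(config: GcmsSimConfig) -> FeatureMatrix:
    """Draw a peak-area feature matrix with the configured group structure.

    Uninformative features share one geometric mean in both groups (drawn
    once per feature from a broad plausible-area range); informative feature
    ``j`` has group geometric means ``(mean_co, mean_crc)``.  Entries are
    strictly positive before missingness is applied.  Identical configs
    (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_co + config.n_crc
    p = config.n_features
    sigma = math.sqrt(math.log1p(config.noise_cv**2))

    # geometric means: one shared value per feature, overridden per group
    # for the informative ones
    log_gm = rng.uniform(math.log(1e5), math.log(1e7), size=p)
    log_mu = np.tile(log_gm, (n, 1))
    is_crc = np.array([False] * config.n_co + [True] * config.n_crc)
    for j, m_co, m_crc in config.informative:
        log_mu[~is_crc, j] = math.log(m_co)
        log_mu[is_crc, j] = math.log(m_crc)

    X = np.exp(log_mu + sigma * rng.standard_normal((n, p)))
    if config.missing_rate > 0:
        X[rng.random((n, p)) < config.missing_rate] = np.nan

    labels = ["CO"] * config.n_co + ["CRC"] * config.n_crc
    ids = [f"CO{i + 1:03d}" for i in range(config.n_co)] + [
        f"CRC{i + 1:03d}" for i in range(config.n_crc)
    ]
    return FeatureMatrix.from_arrays(X, labels, config.feature_names, ids)


# --- E-nose ---------------------------------------------------------------

def _default_amplitudes(n_sensors: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean Max–Min response per sensor and class (signal units).

    Controls sit around 1–1.5; case responses differ per sensor in
    alternating directions (x1.3 / x0.75) so the class contrast is roughly
    orthogonal to the all-sensor drift direction.
    """
    co = 1.0 + 0.04 * np.arange(n_sensors)
    ratio = np.where(np.arange(n_sensors) % 2 == 0, 1.5, 0.65)
    return co, co * ratio


def _default_common_mode(n_sensors: int, sd: float) -> np.ndarray:
    """Log-scale loadings of the two board-level sensitivity contrasts.

    Factor 1 is the digital-vs-analog PCB contrast (sensors 1-8 vs 9-14);
    factor 2 contrasts the first and second half of each board.  Both
    patterns are zero-sum, so neither duplicates the all-sensor drift
    direction, and both are roughly orthogonal to the alternating
    per-sensor class contrast.
    """
    loadings = np.zeros((2, n_sensors))
    half = min(8, n_sensors)  # digital PCB carries sensors 1-8
    n2 = n_sensors - half
    loadings[0, :half] = sd
    if n2 > 0:
        loadings[0, half:] = -sd * half / n2
    q = half // 2
    loadings[1, :q] = sd
    loadings[1, q:half] = -sd
    if n2 > 0:
        q2 = (n2 + 1) // 2
        loadings[1, half : half + q2] = sd
        loadings[1, half + q2 :] = -sd * q2 / max(n2 - q2, 1)
    return loadings


@dataclass
class EnoseSimConfig:
    """Configuration for :func:`simulate_enose`.

    ``class_amplitudes`` maps each class to the per-sensor mean response
    plateau (Max–Min amplitude, signal units).  ``drift_slope_sd`` is the
    standard deviation of the per-sample drift slope (signal units per
    second) shared by all channels through fixed per-sensor gains;
    ``common_mode_sd`` is the log-scale magnitude of the two board-level
    sensitivity factors; ``amplitude_cv`` the per-sensor multiplicative
    response variability; ``noise_sd`` additive measurement noise.
    """

    n_co: int = 35
    n_crc: int = 33
    n_sensors: int = 14
    sample_rate: float = 1.0  # Hz
    baseline_s: float = 60.0
    sample_s: float = 120.0
    stabilize_s: float = 0.0
    class_amplitudes: dict[str, np.ndarray] | None = None
    amplitude_cv: float = 0.15
    common_mode_sd: float = 0.35
    drift_slope_sd: float = 0.01
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sensors < 1:
            raise SweatvocError("need at least one sensor")
        if self.baseline_s <= 0 or self.sample_s <= 0:
            raise SweatvocError("phase durations must be > 0")
        if self.sample_rate <= 0:
            raise SweatvocError("sample_rate must be > 0")
        if self.class_amplitudes is None:
            co, crc = _default_amplitudes(self.n_sensors)
            self.class_amplitudes = {"CO": co, "CRC": crc}
        for cls in CLASS_LABELS:
            amp = np.asarray(self.class_amplitudes[cls], dtype=float)
            if amp.shape != (self.n_sensors,):
                raise SweatvocError(f"class_amplitudes[{cls}] must have shape ({self.n_sensors},)")
            if np.any(amp < 0):
                raise SweatvocError("amplitudes must be >= 0")
            self.class_amplitudes[cls] = amp

    @property
    def sensor_names(self) -> list[str]:
        if self.n_sensors == len(SENSOR_LABELS):
            return list(SENSOR_LABELS)
        return [f"S{j + 1:02d}" for j in range(self.n_sensors)]


def simulate_enose(config: EnoseSimConfig) -> list[SensorRecording]:
    """Draw one recording per sample.

    Each channel is: baseline level + class response plateau during the
    sample phase + shared linear drift (one slope per sample, fixed
    per-sensor gains, identical mechanism in both classes) + board-level
    common-mode amplitude modulation + white noise.  Ground-truth draws
    (drift slope, factor scores, plateau amplitudes) are stored in each
    recording's ``meta`` for diagnostics and tests.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_sensors
    names = config.sensor_names
    total_s = config.stabilize_s + config.baseline_s + config.sample_s
    dt = 1.0 / config.sample_rate
    t = np.arange(0.0, total_s, dt)
    sample_start = config.stabilize_s + config.baseline_s
    in_sample = t >= sample_start
    phase = np.where(
        t < config.stabilize_s, "stabilize", np.where(in_sample, "sample", "baseline")
    ).astype(object)

    base_level = 0.5 + 0.02 * np.arange(k)           # per-sensor baseline offset
    drift_gain = np.linspace(0.8, 1.2, k)            # per-sensor drift sensitivity
    cm_loadings = _default_common_mode(k, config.common_mode_sd)

    labels = ["CO"] * config.n_co + ["CRC"] * config.n_crc
    ids = [f"CO{i + 1:03d}" for i in range(config.n_co)] + [
        f"CRC{i + 1:03d}" for i in range(config.n_crc)
    ]

    recordings: list[SensorRecording] = []
    for sid, lab in zip(ids, labels):
        slope = rng.normal(0.0, config.drift_slope_sd)
        cm_scores = rng.standard_normal(2)
        eps = rng.standard_normal(k)
        amp = config.class_amplitudes[lab] * np.exp(
            config.amplitude_cv * eps + cm_scores @ cm_loadings
        )
        sig = (
            base_level[None, :]
            + amp[None, :] * in_sample[:, None]
            + slope * np.outer(t, drift_gain)
        )
        if config.noise_sd > 0:
            sig = sig + rng.normal(0.0, config.noise_sd, size=sig.shape)
        recordings.append(
            SensorRecording(
                sample_id=sid,
                label=lab,
                time_s=t.copy(),
                channels=pd.DataFrame(sig, columns=names),
                phase=phase.copy(),
                meta={"drift_slope": slope, "common_mode": cm_scores, "amplitude": amp},
            )
        )
    return recordings
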