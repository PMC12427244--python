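"""Multi-seed property studies used for validation and reporting.

The study cohort behind the reference numbers is not deposited, so the
package's evidence that the method behaves as described is property-based:
each helper here runs the full pipeline across seeds on the synthetic
generators and summarises one qualitative contrast (drift-correction
benefit, supervised-vs-unsupervised projection benefit, null calibration,
test size).  They are ordinary library functions — the acceptance script and
the test suite call them with small seed counts.
"""

from __future__ import annotations

import numpy as np

from .pipeline import PipelineConfig, run_enose_arm, run_gcms_arm
from .selection import wilcoxon_rank_sum
from .simulate import EnoseSimConfig, GcmsSimConfig

__all__ = [
    "osc_ablation_study",
    "projection_contrast_study",
    "null_pipeline_study",
    "wilcoxon_type1_error",
]


def _seeds(n_seeds: int, seed: int) -> list[int]:
    # spread derived seeds deterministically, keep below 2**31
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n_seeds)]


def osc_ablation_study(
    n_seeds: int = 20,
    seed: int = 0,
    mode: str = "honest",
    classifier: str = "lda",
) -> dict:
    """Accuracy with OSC(1)+PCA(3) vs without OSC on drift-dominated data.

    Runs the E-nose arm on the generator defaults (drift and board-level
    common-mode variance dominate the class contrast) once per seed and
    reports the per-seed accuracies and the median gain in accuracy points.
    """
    with_osc, without_osc = [], []
    for s in _seeds(n_seeds, seed):
        cfg = PipelineConfig(arm="enose", classifier=classifier, mode=mode, seed=s)
        res = run_enose_arm(cfg, sim=EnoseSimConfig(seed=s))
        with_osc.append(res.cv.accuracy)
        without_osc.append(res.cv_no_osc.accuracy)
    with_osc = np.asarray(with_osc)
    without_osc = np.asarray(without_osc)
    return {
        "with_osc": with_osc,
        "without_osc": without_osc,
        "median_with": float(np.median(with_osc)),
        "median_without": float(np.median(without_osc)),
        "median_gain": float(np.median(with_osc - without_osc)),
    }


def projection_contrast_study(
    n_seeds: int = 20,
    seed: int = 0,
    mode: str = "as_paper",
    classifier: str = "knn",
) -> dict:
    """PLS-DA(3)+k-NN(5) vs PCA(3)+k-NN(5) on marker-effect-size simulations.

    Uses the GC-MS generator defaults (65 samples, 187 features, 13
    informative markers at the reported group means) and reports per-seed
    accuracies for both projections plus the median difference in points.
    """
    plsda, pca = [], []
    for s in _seeds(n_seeds, seed):
        sim = GcmsSimConfig(seed=s)
        for proj, bucket in (("plsda", plsda), ("pca", pca)):
            cfg = PipelineConfig(
                arm="gcms", projection=proj, classifier=classifier, mode=mode, seed=s
            )
            bucket.append(run_gcms_arm(cfg, sim=sim).cv.accuracy)
    plsda = np.asarray(plsda)
    pca = np.asarray(pca)
    return {
        "plsda": plsda,
        "pca": pca,
        "median_plsda": float(np.median(plsda)),
        "median_pca": float(np.median(pca)),
        "median_gain": float(np.median(plsda - pca)),
    }


def null_pipeline_study(
    n_seeds: int = 20,
    seed: int = 0,
    arm: str = "gcms",
) -> dict:
    """Cross-validated accuracy of the full honest pipeline on no-signal data.

    GC-MS: no informative features; E-nose: identical class amplitudes.
    Reports per-seed accuracies, their median, and the binomial 95% band
    around the chance rate (majority-class proportion) for one cohort.
    """
    accs = []
    n_total = None
    chance = None
    for s in _seeds(n_seeds, seed):
        if arm == "gcms":
            sim = GcmsSimConfig(informative=[], seed=s)
            cfg = PipelineConfig(arm="gcms", mode="honest", seed=s)
            res = run_gcms_arm(cfg, sim=sim)
            n_total = sim.n_co + sim.n_crc
            chance = max(sim.n_co, sim.n_crc) / n_total
        else:
            esim = EnoseSimConfig(seed=s)
            esim.class_amplitudes["CRC"] = esim.class_amplitudes["CO"].copy()
            cfg = PipelineConfig(arm="enose", classifier="lda", mode="honest", seed=s)
            res = run_enose_arm(cfg, sim=esim)
            n_total = esim.n_co + esim.n_crc
            chance = max(esim.n_co, esim.n_crc) / n_total
        accs.append(res.cv.accuracy)
    accs = np.asarray(accs)
    half_width = 196.0 * np.sqrt(chance * (1 - chance) / n_total)  # 1.96 in % units
    return {
        "accuracies": accs,
        "median": float(np.median(accs)),
        "chance_pct": 100.0 * chance,
        "lower_pct": 100.0 * chance - half_width,
        "upper_pct": 100.0 * chance + half_width,
    }


def wilcoxon_type1_error(
    n_reps: int = 2000,
    n_per_group: int = 30,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo rejection rate of the rank-sum test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = rng.standard_normal(n_per_group)
        y = rng.standard_normal(n_per_group)
        _, p = wilcoxon_rank_sum(x, y)
        if p < alpha:
            rejections += 1
    return rejections / n_reps
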