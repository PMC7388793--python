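"""Study-level validation routines: parameter-recovery simulations that
exercise the whole pipeline against known ground truth.

These are the package's end-to-end checks: single-source localization
accuracy of the depth-weighted inverse, the directional two-group theta-band
study (elevated theta coupling must raise strength/clustering/efficiency and
lower path length, with the effect confined to theta), ANCOVA type-I-error
calibration, and bootstrap confidence-interval coverage. The same routines
back the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import inverse, pipeline, stats, synthdata as sd
from .preprocess import EpochSet

#: Problem sizes of the scaled-down two-group study (see docs/methods.md).
STUDY_N_PER_GROUP = 20
STUDY_DURATION_S = 60.0
STUDY_FS = 250.0
STUDY_N_SOURCES = 148
STUDY_N_NODES = 148
STUDY_COUPLING = (0.30, 0.15)  # theta coupling: patient-like vs control-like


def localization_accuracy(n_trials: int = 50, seed: int = 0,
                          fm: sd.ForwardModel | None = None,
                          snr: float = 1e6) -> float:
    """Fraction of noiseless single-seed-source simulations whose estimated
    node (argmax time-averaged amplitude) is the true node."""
    if fm is None:
        fm = sd.make_forward_model(seed=seed)
    op = inverse.build_inverse_operator(fm, np.ones(fm.n_sensors), snr=snr)
    node_kernel = op.kernel[fm.node_seeds]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_trials):
        node = int(rng.integers(fm.n_nodes))
        src = fm.node_seeds[node]
        m = np.outer(fm.gain[:, src], rng.standard_normal(250))
        j = node_kernel @ m
        hits += int(np.argmax(np.abs(j).mean(axis=1))) == node
    return hits / n_trials


def make_study_cohort(seed: int,
                      n_per_group: int = STUDY_N_PER_GROUP,
                      duration_s: float = STUDY_DURATION_S,
                      fs: float = STUDY_FS,
                      coupling: tuple[float, float] = STUDY_COUPLING
                      ) -> sd.Cohort:
    """Two groups differing only in theta coupling (scaled-down study)."""
    hi, lo = coupling
    patient = sd.GroupSpec(n_per_group, sd.CouplingSpec(
        label="patient", coupling={"theta": hi}, eog_gain=0.3))
    control = sd.GroupSpec(n_per_group, sd.CouplingSpec(
        label="control", coupling={"theta": lo}, eog_gain=0.3))
    spec = sd.CohortSpec(groups=(patient, control), duration_s=duration_s,
                         fs=fs, n_sources=STUDY_N_SOURCES,
                         n_nodes=STUDY_N_NODES, seed=seed)
    return sd.simulate_cohort(spec)


@dataclass
class DirectionalOutcome:
    """One replicate of the two-group theta study."""

    theta_all_significant: bool
    theta_directions_correct: bool
    other_band_flags: int
    theta_rows: "object"  # the four theta rows of the global table
    report: pipeline.StudyReport

    @property
    def success(self) -> bool:
        return (self.theta_all_significant and self.theta_directions_correct
                and self.other_band_flags == 0)


def directional_theta_study(seed: int, n_boot: int = 1000,
                            **cohort_kw) -> DirectionalOutcome:
    """Run one scaled-down two-group study and judge the recovery pattern.

    Success means: all four theta-band global measures pass the 0.05/24
    family threshold, with higher strength/CC/efficiency and lower PL in the
    high-coupling group, and no measure in any other band flagged.
    """
    cohort = make_study_cohort(seed, **cohort_kw)
    config = pipeline.PipelineConfig(seed=seed, n_boot=n_boot)
    report = pipeline.run_study(config, cohort)
    gt = report.global_table.set_index(["band", "measure"])

    theta = gt.loc["theta"]
    all_sig = bool(theta["significant"].all())
    direction_up = {"strength", "cc", "efficiency"}
    ok_dir = all(
        (row["mean_patient"] > row["mean_control"]) == (m in direction_up)
        for m, row in theta.iterrows())
    other = gt.drop(index="theta", level="band")
    return DirectionalOutcome(
        theta_all_significant=all_sig,
        theta_directions_correct=ok_dir,
        other_band_flags=int(other["significant"].sum()),
        theta_rows=theta,
        report=report,
    )


def ancova_type_i_error(n_sims: int = 1000, n_per_group: int = 10,
                        alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical rejection rate of the group ANCOVA on pure-null cohorts."""
    rng = np.random.default_rng(seed)
    group = np.repeat(["a", "b", "c"], n_per_group)
    rejections = 0
    for _ in range(n_sims):
        values = rng.standard_normal(3 * n_per_group)
        covariate = rng.standard_normal(3 * n_per_group)
        comp = stats.ancova_group_compare(values, group, covariate)
        rejections += comp.p < alpha
    return rejections / n_sims


def bootstrap_ci_coverage(rho: float = 0.5, n: int = 34, n_reps: int = 500,
                          n_boot: int = 5000, seed: int = 0) -> float:
    """Fraction of percentile bootstrap CIs covering the true correlation."""
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    covered = 0
    for i in range(n_reps):
        xy = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        res = stats.partial_pearson_bootstrap(
            xy[:, 0], xy[:, 1], None, n_boot=n_boot,
            seed=int(rng.integers(2**31)))
        covered += res.ci95[0] <= rho <= res.ci95[1]
    return covered / n_reps


def noise_variance_recovery(seed: int = 0, n_epochs: int = 30,
                            n_sensors: int = 8, fs: float = 1000.0) -> float:
    """Max relative error of pooled per-sensor variance on unit white noise."""
    rng = np.random.default_rng(seed)
    e = rng.standard_normal((n_epochs, n_sensors, int(2 * fs)))
    labels = tuple(f"ch{i}" for i in range(n_sensors))
    es = EpochSet(epochs=e, fs=fs, labels=labels, eog_channels=(),
                  epoch_len_s=2.0)
    v = inverse.estimate_noise_covariance_diag(es)
    return float(np.abs(v - 1.0).max())
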