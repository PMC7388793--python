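"""Orchestration: screened epochs -> source imaging -> band-limited PLV ->
graph indices -> group statistics, from a single configuration.

``run_subject`` executes the per-subject chain and fails loudly with the
offending stage's name; ``run_study`` adds the cohort-level group comparison
(global 24-test family and nodal 148-test family, Bonferroni-controlled),
post-hoc contrasts for flagged measures, and covariate-adjusted bootstrap
correlations between flagged measures and the metadata score.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import connectivity, inverse, netmetrics, preprocess, spectral, stats
from .exceptions import PipelineStageError
from .synthdata import Cohort, ForwardModel

GLOBAL_MEASURES = ("strength", "cc", "pl", "efficiency")


@dataclass
class PipelineConfig:
    """All tunable analysis parameters in one place."""

    epoch_len_s: float = 2.0
    n_epochs: int = 30
    amp_threshold_uv: float = 75.0
    highpass_hz: float = 1.0
    band_names: tuple[str, ...] = tuple(b.name for b in spectral.CANONICAL_BANDS)
    gamma: float = 1.0
    snr: float = 3.0
    trim_frac: float = 0.1
    alpha: float = 0.05
    global_family: int = stats.GLOBAL_FAMILY_SIZE
    nodal_family: int = stats.NODAL_FAMILY_SIZE
    nodal_band: str = "theta"
    covariate_column: str = "covariate"
    score_column: str = "score"
    correlation_covariates: tuple[str, ...] = ("med_dose", "illness_duration")
    n_boot: int = stats.DEFAULT_N_BOOT
    seed: int = 0

    def __post_init__(self):
        self.band_names = tuple(self.band_names)
        self.correlation_covariates = tuple(self.correlation_covariates)
        for name in self.band_names + (self.nodal_band,):
            spectral.get_band(name)
        if self.n_epochs < 1 or self.epoch_len_s <= 0:
            raise ValueError("n_epochs and epoch_len_s must be positive")

    @property
    def bands(self) -> tuple[spectral.BandDefinition, ...]:
        return tuple(spectral.get_band(n) for n in self.band_names)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("band_names", "correlation_covariates"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class StudyReport:
    """Cohort-level outputs of :func:`run_study`."""

    global_table: pd.DataFrame
    nodal_table: pd.DataFrame
    correlations: pd.DataFrame
    indices: pd.DataFrame
    nodal_cc: dict[str, dict[str, np.ndarray]]  # subject -> band -> 148-vector
    config: PipelineConfig
    config_hash: str = field(default="")

    def __post_init__(self):
        if not self.config_hash:
            self.config_hash = self.config.config_hash()


def _stage(name: str, subject, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(name, subject, exc) from exc


def run_subject(config: PipelineConfig, raw: preprocess.RawRecording,
                fm: ForwardModel, subject=None
                ) -> dict[str, netmetrics.NetworkIndices]:
    """Run the per-subject chain; returns per-band network indices.

    Stages: average reference -> high-pass -> EOG regression -> epoching ->
    amplitude rejection -> drowsiness rejection -> epoch selection -> noise
    covariance -> inverse kernel -> node time series -> per-band PLV ->
    graph indices. Any contract violation raises a
    :class:`~synchnet.exceptions.PipelineStageError` naming the stage.
    """
    r = raw
    if r.reference != "average":
        r = _stage("rereference", subject, preprocess.rereference_average, r)
    r = _stage("highpass", subject, preprocess.highpass, r, config.highpass_hz)
    if r.eog_channels:
        r = _stage("eog_regression", subject, preprocess.regress_eog, r)
    es = _stage("epoching", subject, preprocess.epoch, r, config.epoch_len_s)
    es = _stage("amplitude_rejection", subject, preprocess.reject_amplitude,
                es, config.amp_threshold_uv)
    es = _stage("drowsiness_rejection", subject, preprocess.reject_drowsy, es)
    es = _stage("epoch_selection", subject, preprocess.select_epochs, es,
                config.n_epochs, subject)
    variances = _stage("noise_covariance", subject,
                       inverse.estimate_noise_covariance_diag, es)
    op = _stage("inverse_operator", subject, inverse.build_inverse_operator,
                fm, variances, config.gamma, config.snr)
    node_epochs = _stage("apply_inverse", subject, inverse.apply_inverse,
                         op, es, fm)
    out: dict[str, netmetrics.NetworkIndices] = {}
    for band in config.bands:
        cm = _stage(f"connectivity[{band.name}]", subject,
                    connectivity.plv_matrix, node_epochs, es.fs, band,
                    config.trim_frac)
        out[band.name] = _stage(f"netmetrics[{band.name}]", subject,
                                netmetrics.network_indices, cm.W, band.name,
                                subject)
    return out


def run_study(config: PipelineConfig, cohort: Cohort) -> StudyReport:
    """Full cohort analysis: per-subject indices, global and nodal group
    comparisons with Bonferroni families, and correlations for flagged
    measures."""
    if len({s.group for s in cohort.subjects}) < 2:
        raise ValueError("study requires at least two groups")
    fm = cohort.forward_model
    meta = cohort.metadata.set_index("subject")

    rows = []
    nodal: dict[str, dict[str, np.ndarray]] = {}
    for rec in cohort.subjects:
        per_band = run_subject(config, rec.recording, fm, subject=rec.subject)
        nodal[rec.subject] = {b: ix.nodal_cc for b, ix in per_band.items()}
        for band_name, ix in per_band.items():
            rows.append({"subject": rec.subject, "group": rec.group,
                         "band": band_name, "strength": ix.strength,
                         "cc": ix.cc, "pl": ix.pl,
                         "efficiency": ix.efficiency})
    indices = pd.DataFrame(rows)

    covariate = meta[config.covariate_column]
    thr_global = stats.bonferroni_threshold(config.alpha, config.global_family)
    global_rows = []
    flagged: list[tuple[str, str]] = []
    for band_name in config.band_names:
        sub = indices[indices["band"] == band_name].set_index("subject")
        cov = covariate.loc[sub.index]
        for measure in GLOBAL_MEASURES:
            comp = stats.ancova_group_compare(
                sub[measure], sub["group"], cov,
                measure=f"{band_name}:{measure}", adjusted_alpha=thr_global)
            significant = comp.p < thr_global
            row = {"band": band_name, "measure": measure, "F": comp.F,
                   "p": comp.p, "partial_eta2": comp.partial_eta2,
                   "adjusted_alpha": thr_global, "significant": significant}
            for g, m in comp.group_means.items():
                row[f"mean_{g}"] = m
                row[f"sd_{g}"] = comp.group_sds[g]
            if significant:
                flagged.append((band_name, measure))
                ph = stats.posthoc_pairwise(sub[measure], sub["group"], cov)
                row["posthoc"] = "; ".join(
                    f"{a}{'>' if pr.direction > 0 else '<'}{b} "
                    f"(p={pr.p_bonferroni:.4g})"
                    for (a, b), pr in ((p.pair, p) for p in ph))
            global_rows.append(row)
    global_table = pd.DataFrame(global_rows)

    thr_nodal = stats.bonferroni_threshold(config.alpha, config.nodal_family)
    sub = indices[indices["band"] == config.nodal_band].set_index("subject")
    order = sub.index
    groups = sub["group"]
    cov = covariate.loc[order]
    ncc = np.stack([nodal[s][config.nodal_band] for s in order])
    nodal_rows = []
    for node in range(ncc.shape[1]):
        comp = stats.ancova_group_compare(
            ncc[:, node], groups, cov,
            measure=f"{config.nodal_band}:node{node:03d}",
            adjusted_alpha=thr_nodal)
        nodal_rows.append({"node": node, "F": comp.F, "p": comp.p,
                           "partial_eta2": comp.partial_eta2,
                           "adjusted_alpha": thr_nodal,
                           "significant": comp.p < thr_nodal})
    nodal_table = pd.DataFrame(nodal_rows)

    corr_rows = []
    cov_cols = [c for c in config.correlation_covariates if c in meta.columns]
    for band_name, measure in flagged:
        sub = indices[indices["band"] == band_name].set_index("subject")
        for g in sorted(sub["group"].unique()):
            g_idx = sub.index[sub["group"] == g]
            x = sub.loc[g_idx, measure].to_numpy()
            y = meta.loc[g_idx, config.score_column].to_numpy()
            covs = meta.loc[g_idx, cov_cols].to_numpy() if cov_cols else None
            try:
                res = stats.partial_pearson_bootstrap(
                    x, y, covs, n_boot=config.n_boot,
                    seed=config.seed, covariate_names=tuple(cov_cols))
            except ValueError:
                continue
            corr_rows.append({"band": band_name, "measure": measure,
                              "group": g, "r": res.r, "p": res.p,
                              "ci_lo": res.ci95[0], "ci_hi": res.ci95[1],
                              "n_boot": res.n_boot})
    correlations = pd.DataFrame(corr_rows)

    return StudyReport(global_table=global_table, nodal_table=nodal_table,
                       correlations=correlations, indices=indices,
                       nodal_cc=nodal, config=config)


def write_report(report: StudyReport, outdir) -> None:
    """Write the study tables as TSV plus a JSON metadata sidecar."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.global_table.to_csv(out / "global_indices.tsv", sep="\t", index=False)
    report.nodal_table.to_csv(out / "nodal_cc.tsv", sep="\t", index=False)
    report.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
    report.indices.to_csv(out / "subject_indices.tsv", sep="\t", index=False)
    with open(out / "study_meta.json", "w") as fh:
        json.dump({"config": report.config.to_dict(),
                   "config_hash": report.config_hash}, fh, indent=2,
                  default=list)
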