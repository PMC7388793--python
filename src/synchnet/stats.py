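"""Group statistics for network indices: covariate-adjusted group comparison
(ANCOVA) with partial eta squared, Bonferroni-controlled families, post-hoc
pairwise contrasts, and covariate-adjusted bootstrap Pearson correlations.

The group comparison fits the linear model ``value ~ group + covariate`` and
tests the group term:

    F = ((SS_reduced - SS_full) / df_group) / (SS_full / df_resid)
    partial eta^2 = SS_group / (SS_group + SS_resid)

Two Bonferroni families control multiplicity: the *global* family of 24 tests
(four network measures x six bands, adjusted alpha 0.05/24 = 0.002083) and
the *nodal* family of 148 tests (0.05/148 = 0.000338). Post-hoc pairwise
contrasts are covariate-adjusted differences from the full-model
coefficients, Bonferroni-multiplied by the number of pairs. All tests are
two-tailed.

Partial Pearson correlation residualizes both variables on the covariates
(e.g. medication dose and illness duration) and correlates the residuals; the
confidence interval is a seeded percentile bootstrap over subjects (simple
random resampling with replacement, 5,000 resamples, 95 % by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

DEFAULT_ALPHA = 0.05
GLOBAL_FAMILY_SIZE = 24   # 4 global measures x 6 bands
NODAL_FAMILY_SIZE = 148   # one nodal CC per node
DEFAULT_N_BOOT = 5000
DEFAULT_CI = 95.0


@dataclass
class PairwiseResult:
    """One covariate-adjusted pairwise contrast."""

    pair: tuple[str, str]
    p_bonferroni: float
    direction: int       # sign of adjusted mean (first - second)
    difference: float    # adjusted mean difference (first - second)


@dataclass
class GroupComparison:
    """Omnibus group effect for one measure."""

    measure: str
    F: float
    p: float
    partial_eta2: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    adjusted_alpha: float | None = None
    posthoc: list[PairwiseResult] = field(default_factory=list)


@dataclass
class CorrelationResult:
    """Partial Pearson correlation with a bootstrap percentile interval."""

    r: float
    p: float
    ci95: tuple[float, float]
    n_boot: int
    covariates: tuple[str, ...]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test threshold ``alpha / m``."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return alpha / m


def _frame(values, group, covariate) -> pd.DataFrame:
    df = pd.DataFrame({"value": np.asarray(values, float),
                       "group": np.asarray(group, object)})
    if covariate is not None:
        df["covariate"] = np.asarray(covariate, float)
        if not np.all(np.isfinite(df["covariate"])):
            raise ValueError("covariate must be finite")
    if not np.all(np.isfinite(df["value"])):
        raise ValueError("values must be finite")
    counts = df["group"].value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("need at least two subjects per group")
    return df


def _fit_full(df: pd.DataFrame):
    formula = "value ~ C(group)"
    if "covariate" in df:
        formula += " + covariate"
    fit = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("singular design: covariate collinear with group")
    return fit


def ancova_group_compare(values, group, covariate=None,
                         measure: str = "measure",
                         adjusted_alpha: float | None = None) -> GroupComparison:
    """Covariate-adjusted group comparison of one scalar measure.

    Fits ``value ~ group (+ covariate)`` and tests the group term with a
    partial (type II) F test; the effect size is partial eta squared.
    """
    df = _frame(values, group, covariate)
    fit = _fit_full(df)
    table = anova_lm(fit, typ=2)
    ss_group = float(table.loc["C(group)", "sum_sq"])
    ss_resid = float(table.loc["Residual", "sum_sq"])
    f_stat = float(table.loc["C(group)", "F"])
    p = float(table.loc["C(group)", "PR(>F)"])
    eta2 = ss_group / (ss_group + ss_resid)
    means = df.groupby("group")["value"].mean().to_dict()
    sds = df.groupby("group")["value"].std(ddof=1).to_dict()
    return GroupComparison(measure=measure, F=f_stat, p=p, partial_eta2=eta2,
                           group_means=means, group_sds=sds,
                           adjusted_alpha=adjusted_alpha)


def posthoc_pairwise(values, group, covariate=None) -> list[PairwiseResult]:
    """Covariate-adjusted pairwise contrasts with Bonferroni correction.

    Contrasts come from the full-model group coefficients (adjusted means);
    each two-tailed p is multiplied by the number of pairs and capped at 1.
    """
    df = _frame(values, group, covariate)
    fit = _fit_full(df)
    levels = sorted(df["group"].unique())
    pairs = list(combinations(levels, 2))
    names = fit.params.index
    results = []
    for a, b in pairs:
        contrast = np.zeros(len(names))
        for i, name in enumerate(names):
            if name == f"C(group)[T.{a}]":
                contrast[i] = 1.0
            elif name == f"C(group)[T.{b}]":
                contrast[i] = -1.0
        tt = fit.t_test(contrast)
        diff = float(np.ravel(tt.effect)[0])  # adjusted mean a - adjusted mean b
        p_adj = min(float(np.ravel(tt.pvalue)[0]) * len(pairs), 1.0)
        results.append(PairwiseResult(pair=(a, b), p_bonferroni=p_adj,
                                      direction=int(np.sign(diff)),
                                      difference=diff))
    return results


def _residualize_batched(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residuals of ``v`` on design ``z`` for stacked resamples.

    ``v`` is (B, n); ``z`` is (B, n, k). Solves the normal equations per
    resample (k is tiny), falling back to pseudo-inverse on singular draws.
    """
    g = np.swapaxes(z, 1, 2) @ z                 # (B, k, k)
    rhs = np.einsum("bnk,bn->bk", z, v)
    try:
        beta = np.linalg.solve(g, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.einsum("bkn,bn->bk", np.linalg.pinv(z), v)
    return v - np.einsum("bnk,bk->bn", z, beta)


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = np.sum(a * b, axis=1)
    den = np.sqrt(np.sum(a * a, axis=1) * np.sum(b * b, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def partial_pearson_bootstrap(x, y, covariates=None,
                              n_boot: int = DEFAULT_N_BOOT,
                              ci: float = DEFAULT_CI,
                              seed: int = 0,
                              covariate_names: tuple[str, ...] = ()
                              ) -> CorrelationResult:
    """Partial Pearson correlation with a percentile-bootstrap interval.

    ``x`` and ``y`` are residualized on the covariates (with intercept) and
    their residuals correlated; the p-value uses the t transform with
    ``df = n - 2 - n_covariates``. The CI is the percentile interval of r
    over ``n_boot`` resamples of subjects with replacement (residualization
    repeated within each resample), seeded for determinism.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if y.shape != (n,):
        raise ValueError("x and y must have equal length")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariates must have one row per subject")
    k = cov.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} subjects with {k} covariates")
    z = np.column_stack([np.ones(n), cov])

    rx = _residualize_batched(x[None, :], z[None, :, :])[0]
    ry = _residualize_batched(y[None, :], z[None, :, :])[0]
    scale = max(x.std(), y.std(), 1e-300)
    if rx.std() <= 1e-12 * scale or ry.std() <= 1e-12 * scale:
        raise ValueError("zero residual variance; correlation undefined")
    r = float(_pearson_rows(rx[None, :], ry[None, :])[0])
    dof = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), dof))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    zb = z[idx]
    rxb = _residualize_batched(x[idx], zb)
    ryb = _residualize_batched(y[idx], zb)
    rb = _pearson_rows(rxb, ryb)
    rb = rb[np.isfinite(rb)]
    lo, hi = np.percentile(rb, [(100 - ci) / 2.0, 100 - (100 - ci) / 2.0])
    return CorrelationResult(r=r, p=p, ci95=(float(lo), float(hi)),
                             n_boot=n_boot, covariates=tuple(covariate_names))
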