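"""Polygenic scoring and cohort statistics.

Scores are plain dosage-by-effect-size dot products; all downstream tests
operate on scores standardized against a designated control group. The
statistics mirror common cohort practice: unpooled (Welch-style) Z-tests
for group means, the mid-parent transmission-deviation test for trios,
Pearson correlations, residualized prediction with delta-R2, Bonferroni
flags, and closed-form power for the two standard designs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm


@dataclass(frozen=True)
class PGSRecord:
    sample_id: str
    trait: str
    raw_score: float
    std_score: float | None = None


@dataclass(frozen=True)
class TrioDeviation:
    trio_id: str
    child_score: float
    midparent_score: float
    deviation: float


@dataclass(frozen=True)
class PredictionResult:
    r: float
    p_value: float
    baseline_r2: float | None = None  # adjusted R2, covariate-only model
    delta_r2: float | None = None  # unadjusted R2 gain from adding the PGS
    pct_change: float | None = None  # 100 * delta_r2 / baseline_r2
    baseline_r2_unadj: float | None = None
    full_r2_adj: float | None = None


@dataclass(frozen=True)
class PowerSpec:
    design: str  # "two_sample_mean" | "r2_one_predictor"
    effect: float  # standardized mean difference, or R2
    alpha: float = 0.001
    n1: int | None = None
    n2: int | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.design not in ("two_sample_mean", "r2_one_predictor"):
            raise ValueError(f"unknown design {self.design!r}")


def score(
    dosages: pd.DataFrame,
    weights: Mapping[str, float],
    trait: str = "trait",
    missing: str = "impute",
) -> list[PGSRecord]:
    """raw_score = sum over variants of dosage x effect size.

    ``dosages`` is samples x variants with values in [0, 2] or NaN.
    Missing dosages are imputed as 2 x effect-allele frequency estimated
    from the column (``missing="impute"``, default) or dropped per sample
    (``missing="skip"``). Weight variants absent from the matrix are
    skipped with a warning; zero usable variants is an error.
    """
    usable = [v for v in weights if v in dosages.columns]
    skipped = sorted(set(weights) - set(usable))
    if skipped:
        warnings.warn(f"{len(skipped)} weight variants absent from dosage matrix: "
                      f"{skipped[:5]}{'...' if len(skipped) > 5 else ''}")
    if not usable:
        raise ValueError("zero usable variants: no weight variant found in matrix")
    mat = dosages[usable].astype(float)
    if missing == "impute":
        af = mat.mean(axis=0, skipna=True) / 2.0
        mat = mat.fillna(2.0 * af)
    elif missing == "skip":
        mat = mat.fillna(0.0)
    else:
        raise ValueError(f"missing policy must be 'impute' or 'skip', got {missing!r}")
    w = np.asarray([weights[v] for v in usable], dtype=float)
    raw = mat.to_numpy() @ w
    return [
        PGSRecord(sample_id=str(sid), trait=trait, raw_score=float(r))
        for sid, r in zip(dosages.index, raw)
    ]


def standardize(
    scores: Sequence[PGSRecord], control_ids: set[str] | frozenset[str]
) -> list[PGSRecord]:
    """Standardize raw scores against the control group (mean 0, SD 1 with
    the n-1 denominator among controls)."""
    controls = [s.raw_score for s in scores if s.sample_id in control_ids]
    if len(controls) < 2:
        raise ValueError("need >= 2 control samples to standardize")
    mu = float(np.mean(controls))
    sd = float(np.std(controls, ddof=1))
    if sd == 0:
        raise ValueError("control scores have zero standard deviation")
    return [
        PGSRecord(
            sample_id=s.sample_id,
            trait=s.trait,
            raw_score=s.raw_score,
            std_score=(s.raw_score - mu) / sd,
        )
        for s in scores
    ]


def group_difference(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Unpooled two-sample Z-test of mean difference; returns (z, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("degenerate groups: zero variance with differing means")
    z = (a.mean() - b.mean()) / np.sqrt(va / len(a) + vb / len(b))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def ptdt(
    trios: Sequence[tuple[float, float, float]],
    trio_ids: Sequence[str] | None = None,
) -> tuple[list[TrioDeviation], float, float]:
    """Polygenic transmission-deviation test.

    ``trios`` holds (child, mother, father) standardized scores. Each
    deviation is (child - midparent) scaled by the SD of midparent scores
    across trios; the statistic is a one-sample two-sided t-test of zero
    mean deviation. Returns (deviations, t, p).
    """
    if len(trios) < 2:
        raise ValueError("need >= 2 trios")
    child = np.asarray([t[0] for t in trios], dtype=float)
    mid = np.asarray([(t[1] + t[2]) / 2.0 for t in trios], dtype=float)
    mid_sd = mid.std(ddof=1)
    if mid_sd == 0:
        raise ValueError("all midparent scores identical: deviation scale undefined")
    dev = (child - mid) / mid_sd
    ids = trio_ids if trio_ids is not None else [f"trio{i}" for i in range(len(trios))]
    deviations = [
        TrioDeviation(
            trio_id=str(i), child_score=float(c), midparent_score=float(m),
            deviation=float(d),
        )
        for i, c, m, d in zip(ids, child, mid, dev)
    ]
    if dev.std(ddof=1) == 0:
        # degenerate but well-defined: all deviations equal
        t = 0.0 if dev.mean() == 0 else math.copysign(math.inf, dev.mean())
        p = 1.0 if dev.mean() == 0 else 0.0
    else:
        t, p = stats.ttest_1samp(dev, 0.0)
    return deviations, float(t), float(p)


def spouse_correlation(
    pairs: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Pearson correlation of mother/father scores; returns (r, p)."""
    if len(pairs) < 3:
        raise ValueError("need >= 3 spouse pairs")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise ValueError("degenerate input: zero variance on one side")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def residualize(
    phenotype: Sequence[float],
    covariates: pd.DataFrame,
    always_keep: Sequence[str] = ("age", "sex"),
    alpha: float = 0.05,
) -> tuple[np.ndarray, list[str]]:
    """Backwards stepwise residualization.

    Starting from the full covariate model, repeatedly drop the eliminable
    covariate with the largest p-value above ``alpha`` (covariates in
    ``always_keep`` are never dropped) and refit. Residuals from the final
    fit are standardized to mean 0, SD 1. Returns (residuals, retained).
    """
    y = np.asarray(phenotype, dtype=float)
    if y.std(ddof=1) == 0:
        raise ValueError("phenotype has zero variance")
    if len(y) != len(covariates):
        raise ValueError("phenotype/covariate length mismatch")
    if len(y) <= covariates.shape[1] + 2:
        raise ValueError("too few observations for the covariate count")
    cols = list(covariates.columns)
    X = covariates.astype(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X.to_numpy()]))
    if rank < X.shape[1] + 1:
        raise ValueError(f"rank-deficient design among covariates {cols}")
    while True:
        fit = sm.OLS(y, sm.add_constant(X[cols])).fit()
        droppable = [c for c in cols if c not in always_keep]
        if not droppable:
            break
        pvals = fit.pvalues.drop(labels=["const"], errors="ignore")
        worst = max(droppable, key=lambda c: pvals[c])
        if pvals[worst] <= alpha:
            break
        cols.remove(worst)
    fit = sm.OLS(y, sm.add_constant(X[cols])).fit()
    resid = np.asarray(fit.resid, dtype=float)
    resid = (resid - resid.mean()) / resid.std(ddof=1)
    return resid, cols


def predict(
    residuals: Sequence[float],
    pgs: Sequence[float],
    phenotype: Sequence[float] | None = None,
    covariates: pd.DataFrame | None = None,
) -> PredictionResult:
    """Correlate standardized residuals with PGS; optionally quantify the
    R2 gained by adding the PGS to the covariate-only model on the
    unresidualized scale.

    ``baseline_r2`` is the adjusted R2 of the covariate-only model;
    ``delta_r2`` is the unadjusted R2 increase from adding the PGS
    (adjusted variants are reported alongside).
    """
    res = np.asarray(residuals, dtype=float)
    g = np.asarray(pgs, dtype=float)
    if len(res) != len(g):
        raise ValueError("residual/PGS length mismatch")
    if len(res) < 10:
        raise ValueError("need n >= 10")
    pr = stats.pearsonr(res, g)
    r, p = float(pr.statistic), float(pr.pvalue)
    if phenotype is None or covariates is None:
        return PredictionResult(r=r, p_value=p)
    y = np.asarray(phenotype, dtype=float)
    Xc = sm.add_constant(covariates.astype(float))
    base = sm.OLS(y, Xc).fit()
    Xf = Xc.copy()
    Xf["pgs"] = g
    full = sm.OLS(y, Xf).fit()
    delta = float(full.rsquared - base.rsquared)
    baseline_adj = float(base.rsquared_adj)
    pct = 100.0 * delta / baseline_adj if baseline_adj != 0 else float("nan")
    return PredictionResult(
        r=r,
        p_value=p,
        baseline_r2=baseline_adj,
        delta_r2=delta,
        pct_change=pct,
        baseline_r2_unadj=float(base.rsquared),
        full_r2_adj=float(full.rsquared_adj),
    )


def bonferroni(
    p_values: Sequence[float], m: int = 50, family_alpha: float = 0.05
) -> tuple[list[bool], float]:
    """Flag p <= family_alpha / m (inclusive); returns (flags, threshold)."""
    ps = list(p_values)
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    threshold = family_alpha / m
    return [p <= threshold for p in ps], threshold


def power(spec: PowerSpec) -> float:
    """Analytic power for the two supported designs.

    two_sample_mean: two-sided normal test; noncentrality
    effect / sqrt(1/n1 + 1/n2). r2_one_predictor: noncentral-F with
    df1 = 1, df2 = n - 2, noncentrality n * R2 / (1 - R2).
    """
    if spec.design == "two_sample_mean":
        if spec.n1 is None or spec.n2 is None:
            raise ValueError("two_sample_mean needs n1 and n2")
        ncp = spec.effect / np.sqrt(1.0 / spec.n1 + 1.0 / spec.n2)
        crit = stats.norm.isf(spec.alpha / 2.0)
        return float(stats.norm.sf(crit - ncp) + stats.norm.cdf(-crit - ncp))
    if spec.n is None:
        raise ValueError("r2_one_predictor needs n")
    if spec.effect >= 1.0:
        raise ValueError("R2 must be < 1")
    df2 = spec.n - 2
    ncp = spec.n * spec.effect / (1.0 - spec.effect)
    crit = stats.f.isf(spec.alpha, 1, df2)
    if ncp == 0:  # scipy's ncf is numerically unreliable at zero noncentrality
        return float(stats.f.sf(crit, 1, df2))
    return float(min(max(stats.ncf.sf(crit, 1, df2, ncp), 0.0), 1.0))
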