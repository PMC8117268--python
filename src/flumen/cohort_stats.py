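"""Subject-level outcome and cohort statistics.

Growth-rate computation with the 3 mm/year stable/enlarging rule, normality-
routed group comparisons, Pearson correlation matrices, multivariable OLS
with heteroskedasticity-robust standard errors, and Bland-Altman agreement
summaries for the reproducibility analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import FlumenError

__all__ = [
    "GROWTH_THRESHOLD",
    "GroupComparison",
    "RegressionResult",
    "BlandAltmanResult",
    "growth_rate_and_group",
    "compare_groups",
    "compare_categorical",
    "correlation_matrix",
    "robust_regression",
    "bland_altman",
]

GROWTH_THRESHOLD = 3.0  # mm/year; >= is "enlarging"
ALPHA = 0.05


def growth_rate_and_group(
    baseline: float, followup: float, interval: float
) -> tuple[float, str]:
    """Aortic growth rate (mm/year) and stable/enlarging classification.

    ``rate = (followup - baseline) / interval``; the boundary rate of exactly
    3 mm/year classifies as enlarging.
    """
    if interval <= 0:
        raise FlumenError("scan interval must be positive (years)")
    rate = (followup - baseline) / interval
    group = "enlarging" if rate >= GROWTH_THRESHOLD else "stable"
    return rate, group


@dataclass
class GroupComparison:
    variable: str
    test: str  # "t" | "mann-whitney" | "degenerate"
    statistic: float
    p_value: float
    descriptives: dict
    normal: bool


def _descriptives(x: np.ndarray, normal: bool) -> dict:
    if normal:
        return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    alpha: float = ALPHA,
) -> GroupComparison:
    """Two-group comparison with Shapiro-Wilk normality routing.

    Both groups normal at ``alpha`` -> unpaired t-test; otherwise
    Mann-Whitney U.  Descriptives are mean +/- SD when normal, median (IQR)
    otherwise.
    """
    groups = [g for g in table[group_col].unique()]
    if len(groups) != 2:
        raise FlumenError(f"expected exactly 2 groups, found {groups}")
    samples = []
    for g in sorted(groups):
        x = table.loc[table[group_col] == g, variable].dropna().to_numpy(dtype=float)
        if x.size == 0:
            raise FlumenError(f"group {g!r} is empty for {variable!r}")
        samples.append((g, x))

    constant = all(np.ptp(x) == 0 for _, x in samples)
    if constant and samples[0][1][0] == samples[1][1][0]:
        desc = {g: _descriptives(x, True) for g, x in samples}
        return GroupComparison(variable, "degenerate", 0.0, 1.0, desc, normal=True)

    def is_normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0 or x.size < 3:
            return False
        return stats.shapiro(x).pvalue >= alpha

    normal = all(is_normal(x) for _, x in samples)
    a, b = samples[0][1], samples[1][1]
    if normal:
        res = stats.ttest_ind(a, b)
        test = "t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney"
    desc = {g: _descriptives(x, normal) for g, x in samples}
    return GroupComparison(
        variable=variable,
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        descriptives=desc,
        normal=normal,
    )


def compare_categorical(
    table: pd.DataFrame, variable: str, group_col: str = "group"
) -> GroupComparison:
    """Chi-square test of a categorical variable, Fisher's exact when any
    expected cell count is below 5 (2x2 only for Fisher)."""
    ct = pd.crosstab(table[group_col], table[variable])
    observed = ct.to_numpy()
    chi2, p, _, expected = stats.chi2_contingency(observed, correction=False)
    if (expected < 5).any() and observed.shape == (2, 2):
        res = stats.fisher_exact(observed)
        return GroupComparison(
            variable, "fisher", float(res.statistic), float(res.pvalue), {}, normal=False
        )
    return GroupComparison(variable, "chi-square", float(chi2), float(p), {}, normal=False)


def correlation_matrix(
    table: pd.DataFrame, variables: list[str], min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p with pairwise-complete handling.

    Cells with fewer than ``min_pairs`` complete pairs are flagged NaN.
    """
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            if j <= i:
                continue
            sub = table[[a, b]].dropna()
            if len(sub) < min_pairs:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


@dataclass
class RegressionResult:
    model: str
    coefficients: pd.DataFrame  # index: term; columns: beta, se, ci_low, ci_high, p
    adjusted_r2: float
    n: int
    cov_type: str


def robust_regression(
    table: pd.DataFrame,
    outcome: str = "growth_rate",
    predictors: tuple[str, ...] = ("flef", "baseline_diameter"),
    cov_type: str = "HC1",
) -> RegressionResult:
    """OLS of the outcome on the predictors with robust (HC) standard errors.

    Point estimates are ordinary least squares; standard errors, 95% CIs and
    p-values use the requested heteroskedasticity-consistent covariance
    (HC0-HC3, default HC1).
    """
    sub = table[[outcome, *predictors]].dropna()
    n = len(sub)
    if n <= len(predictors) + 1:
        raise FlumenError(f"n = {n} too small for {len(predictors)} predictors")
    X = sm.add_constant(sub[list(predictors)].to_numpy(dtype=float))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, 1:].T)
        pairs = [
            (predictors[i], predictors[j])
            for i in range(len(predictors))
            for j in range(i + 1, len(predictors))
            if abs(corr[i, j]) > 0.999
        ]
        raise FlumenError(f"design matrix is rank deficient; collinear: {pairs}")
    y = sub[outcome].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit(cov_type=cov_type)
    ci = fit.conf_int(alpha=0.05)
    coef = pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.bse,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": fit.pvalues,
        },
        index=["intercept", *predictors],
    )
    return RegressionResult(
        model=f"{outcome} ~ {' + '.join(predictors)}",
        coefficients=coef,
        adjusted_r2=float(fit.rsquared_adj),
        n=n,
        cov_type=cov_type,
    )


@dataclass
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    pearson_r: float
    n: int
    plot_data: pd.DataFrame = field(repr=False, default=None)


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltmanResult:
    """Agreement between two raters/measurements: bias, SD, LOA, Pearson r.

    Limits of agreement are bias +/- 1.96 * SD of the differences; plot data
    (pair means vs differences) is returned for CSV export.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise FlumenError("measurement vectors must have equal length")
    if a.size < 3:
        raise FlumenError("need at least 3 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r = 1.0 if np.allclose(a - a.mean(), b - b.mean()) else np.nan
    else:
        r = float(stats.pearsonr(a, b).statistic)
    plot = pd.DataFrame({"mean": (a + b) / 2.0, "difference": d})
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        pearson_r=r,
        n=a.size,
        plot_data=plot,
    )
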