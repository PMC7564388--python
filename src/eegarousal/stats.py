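"""Group-comparison statistics for the arousal/depression analysis.

Covers the tests used in the cohort comparison: one- and two-way ANOVA
with partial eta-squared, Levene's homogeneity test, uncorrected Pearson
chi-square on 2x2 tables, Mann-Whitney U with a tie-corrected normal Z,
and binary screening metrics (sensitivity, specificity, the binary AUC
(sens+spec)/2, Youden index) plus a trapezoidal ROC over a graded score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_sq_partial: float


@dataclass(frozen=True)
class ScreeningMetrics:
    sensitivity: float
    specificity: float
    auc_binary: float
    youden: float
    tp: int
    fp: int
    tn: int
    fn: int


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way ANOVA with partial eta-squared.

    ``groups`` may have any number of levels; each level needs at least
    two observations.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    cells = [values[groups == lev] for lev in levels]
    for lev, cell in zip(levels, cells):
        if len(cell) < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 observations")

    grand = values.mean()
    ss_between = sum(len(c) * (c.mean() - grand) ** 2 for c in cells)
    ss_within = sum(((c - c.mean()) ** 2).sum() for c in cells)
    df_b = len(levels) - 1
    df_w = len(values) - len(levels)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        F = 0.0 if ss_between == 0.0 else np.inf
    else:
        F = ms_b / ms_w
    p = float(scipy.stats.f.sf(F, df_b, df_w))
    denom = ss_between + ss_within
    eta = float(ss_between / denom) if denom > 0 else 0.0
    return AnovaResult(float(F), df_b, df_w, p, eta)


def two_way_anova(values, group, gender) -> dict[str, AnovaResult]:
    """Two-factor ANOVA with interaction, Type-III sums of squares.

    Uses sum-to-zero contrasts (the model-comparison convention for
    unbalanced designs).  Returns one :class:`AnovaResult` per effect:
    ``group``, ``gender`` and ``interaction``.  Every factor cell must
    contain at least two observations.
    """
    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "g": np.asarray(group), "s": np.asarray(gender)}
    )
    counts = df.groupby(["g", "s"], observed=True).size()
    n_levels = df["g"].nunique() * df["s"].nunique()
    if len(counts) < n_levels or (counts < 2).any():
        raise ValueError("every group x gender cell needs >= 2 observations")

    model = smf.ols("y ~ C(g, Sum) * C(s, Sum)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    ss_resid = float(table.loc["Residual", "sum_sq"])
    df_resid = int(table.loc["Residual", "df"])
    out: dict[str, AnovaResult] = {}
    for key, row_name in (
        ("group", "C(g, Sum)"),
        ("gender", "C(s, Sum)"),
        ("interaction", "C(g, Sum):C(s, Sum)"),
    ):
        ss = float(table.loc[row_name, "sum_sq"])
        dfe = int(table.loc[row_name, "df"])
        out[key] = AnovaResult(
            F=float(table.loc[row_name, "F"]),
            df_between=dfe,
            df_within=df_resid,
            p=float(table.loc[row_name, "PR(>F)"]),
            eta_sq_partial=ss / (ss + ss_resid),
        )
    return out


def levene_test(values, groups) -> tuple[float, float]:
    """Levene's test on absolute deviations from the group means."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    cells = [values[groups == lev] for lev in np.unique(groups)]
    if len(cells) < 2 or any(len(c) < 2 for c in cells):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    stat, p = scipy.stats.levene(*cells, center="mean")
    return float(stat), float(p)


def chi_square_2x2(counts) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square on a 2x2 contingency table.

    No Yates continuity correction is applied.  Returns
    ``(statistic, df, p)``.
    """
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    res = scipy.stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U with tie-corrected normal Z and two-tailed p.

    Returns ``(U, Z, p)`` where U counts, over all pairs, the times an
    ``x`` observation exceeds a ``y`` observation (ties count 1/2).  Z is
    the tie-corrected normal approximation without continuity
    correction, signed so that stochastically smaller ``x`` gives Z < 0.
    The p-value is exact (full enumeration) for small tie-free samples
    and asymptotic otherwise, matching the scipy ``method="auto"``
    policy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    U = float(res.statistic)

    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1.0)) if n > 1 else 0.0
    sigma_sq = n1 * n2 / 12.0 * (n + 1.0 - tie_term)
    Z = 0.0 if sigma_sq == 0 else (U - mu) / np.sqrt(sigma_sq)
    return U, float(Z), float(res.pvalue)


def screening_metrics(test_positive, condition) -> ScreeningMetrics:
    """Binary screening-test metrics from per-subject indicators."""
    test_positive = np.asarray(test_positive, dtype=bool)
    condition = np.asarray(condition, dtype=bool)
    if test_positive.shape != condition.shape:
        raise ValueError("inputs must have equal length")
    if condition.all() or not condition.any():
        raise ValueError("need at least one case and one non-case")
    tp = int(np.sum(test_positive & condition))
    fp = int(np.sum(test_positive & ~condition))
    tn = int(np.sum(~test_positive & ~condition))
    fn = int(np.sum(~test_positive & condition))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return ScreeningMetrics(
        sensitivity=sens,
        specificity=spec,
        auc_binary=(sens + spec) / 2.0,
        youden=sens + spec - 1.0,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def screening_metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> ScreeningMetrics:
    """Screening metrics from a confusion table given as counts."""
    test_positive = [True] * (tp + fp) + [False] * (fn + tn)
    condition = [True] * tp + [False] * fp + [True] * fn + [False] * tn
    return screening_metrics(test_positive, condition)


def ids_severity_band(ids_sum: int) -> str:
    """Depression-severity band of an IDS-SR sum-score.

    Bands: ``none`` (<14), ``mild`` (14-25), ``moderate`` (26-38),
    ``severe`` (>=39).
    """
    if ids_sum < 0 or ids_sum > 84:
        raise ValueError(f"IDS-SR sum out of range 0-84: {ids_sum}")
    if ids_sum < 14:
        return "none"
    if ids_sum < 26:
        return "mild"
    if ids_sum < 39:
        return "moderate"
    return "severe"


def roc_auc(scores, condition) -> float:
    """Trapezoidal AUC of a graded score against a binary condition.

    Equivalent to the rank-sum (concordance) formulation; provided as a
    supplement to the binary-cutoff AUC, which is the reported quantity.
    """
    scores = np.asarray(scores, dtype=float)
    condition = np.asarray(condition, dtype=bool)
    pos = scores[condition]
    neg = scores[~condition]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one case and one non-case")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))
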