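"""Shared statistical primitives.

Thin, explicitly-contracted wrappers around scipy/statsmodels plus a
few procedures (Haldane-corrected odds ratio, two-stage random-intercept
ANOVA) written here.  Every result carries statistic, degrees of
freedom, two-sided p, and a method label so pipeline tables are
self-describing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float] | None
    pvalue: float
    adjusted_pvalue: float | None = None
    method: str = ""


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson on average ranks).

    Returns NaN when either vector is constant (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def welch_t(a, b) -> TestResult:
    """Two-sided Welch t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      method="welch_t")


def one_sample_t(x, mu0: float = 0.0) -> TestResult:
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:  # zero variance: degenerate t
        mean = x.mean()
        df = float(x.size - 1)
        if mean == mu0:
            return TestResult(0.0, df, 1.0, method="one_sample_t")
        return TestResult(math.copysign(math.inf, mean - mu0), df, 0.0,
                          method="one_sample_t")
    res = sps.ttest_1samp(x, popmean=mu0)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      method="one_sample_t")


def one_way_anova(groups) -> TestResult:
    """One-way fixed-effects ANOVA across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    k = len(groups)
    n = sum(g.size for g in groups)
    res = sps.f_oneway(*groups)
    return TestResult(float(res.statistic), (k - 1, n - k), float(res.pvalue),
                      method="one_way_anova")


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for a 2x2 table.

    The two-sided p sums all tables with the observed margins whose
    conditional probability does not exceed the observed table's.  The
    odds ratio is the cross-product ratio, with the Haldane-Anscombe
    0.5 correction applied to every cell when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a nonnegative 2x2")
    a, b, c, d = t.ravel()
    if 0 in (a, b, c, d):
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    p = float(sps.fisher_exact(t.astype(int), alternative="two-sided")[1])
    return float(orr), min(p, 1.0)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p * m, capped at 1; order preserved."""
    p = np.asarray(p_values, dtype=float)
    m_eff = p.size if m is None else int(m)
    return np.minimum(p * m_eff, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def random_intercept_anova(values, treatment, grouping_factor) -> TestResult:
    """Mean treatment effect across groups, treating group as random.

    Two-stage estimator for balanced small designs: aggregate to one
    treatment-effect mean per group (difference of treatment minus
    control means within the group), then test the across-group mean of
    those effects against zero with a one-sample t (df = n_groups - 1).
    Equivalent to a random-intercept linear model under balance.

    ``treatment`` is a boolean/0-1 vector; ``grouping_factor`` labels
    the random groups (e.g. cell lines).
    """
    v = np.asarray(values, dtype=float)
    trt = np.asarray(treatment).astype(bool)
    grp = np.asarray(grouping_factor)
    labels = np.unique(grp)
    if labels.size < 2:
        raise ValueError("need at least 2 groups for a random-intercept test")
    effects = []
    for g in labels:
        sel = grp == g
        eff = v[sel & trt].mean() - v[sel & ~trt].mean() if (~trt[sel]).any() \
            else v[sel & trt].mean()
        effects.append(eff)
    effects = np.asarray(effects)
    df = float(labels.size - 1)
    if np.ptp(effects) == 0:  # zero standard error: degenerate t
        mean = effects.mean()
        if mean == 0:
            return TestResult(0.0, df, 1.0, method="random_intercept_anova")
        return TestResult(math.copysign(math.inf, mean), df, 0.0,
                          method="random_intercept_anova")
    res = sps.ttest_1samp(effects, popmean=0.0)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      method="random_intercept_anova")
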