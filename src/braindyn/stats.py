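"""Group comparison and correlation layer.

Continuous metrics are screened for normality (Kolmogorov-Smirnov against
a normal with estimated mean/SD), compared between groups with a
pooled-variance two-sample t test (df = n1 + n2 - 2, matching the reported
df convention), categorical variables with a Pearson chi-square, and
per-family multiple comparisons corrected by Benjamini-Hochberg FDR.
Symptom correlations are Pearson within the case group.  The power of the
two-tailed two-sample t test is computed from the noncentral t
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "normality_test",
    "two_sample_t",
    "chi_square_2x2",
    "fdr_adjust",
    "symptom_correlation",
    "ttest_power",
]


@dataclass
class GroupComparison:
    """One metric's two-group comparison (pooled-variance t test)."""

    metric: str
    level: str
    t: float
    df: int
    p: float
    p_fdr: float | None
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


@dataclass
class CorrelationResult:
    region: str
    r: float
    p: float
    n: int


def normality_test(sample) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's mean and SD.

    Parameters are estimated from the data (Lilliefors-style caveat: the
    asymptotic p-value is anti-conservative), which is the common screening
    usage.  Returns (statistic, p).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("sample has zero variance")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)


def two_sample_t(a, b, metric: str = "", level: str = "") -> GroupComparison:
    """Independent-samples pooled-variance (Student) t test, two-tailed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(t):
        raise ValueError("zero pooled variance")
    return GroupComparison(
        metric=metric, level=level, t=float(t), df=a.size + b.size - 2,
        p=float(p), p_fdr=None,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        n_a=int(a.size), n_b=int(b.size))


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table, df = 1.

    No continuity correction by default; set ``yates=True`` for the
    corrected variant.  Returns (statistic, p).
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any() or table.sum() == 0:
        raise ValueError("need a nonnegative 2x2 table with positive total")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("a zero marginal makes the test undefined")
    stat, p, _, _ = sps.chi2_contingency(table, correction=yates)
    return float(stat), float(p)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def symptom_correlation(metric, scores, region: str = "") -> CorrelationResult:
    """Pearson correlation between a per-subject metric and symptom scores."""
    x = np.asarray(metric, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has undefined correlation")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(region=region, r=float(r), p=float(p), n=int(x.size))


def ttest_power(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Power of the two-tailed two-sample t test at effect size d.

    Uses the noncentral t distribution with noncentrality
    ``d * sqrt(n1 n2 / (n1 + n2))`` and ``df = n1 + n2 - 2``.
    """
    if d < 0:
        raise ValueError("effect size must be nonnegative")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 per group")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(1 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
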