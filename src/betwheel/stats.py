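"""Statistical primitives used by the analyses, with exact contracts.

Thin, validated wrappers over scipy for the classical tests, plus a
repeated-measures one-way ANOVA implemented directly from its
sums-of-squares decomposition so the effect size convention is explicit:
eta-squared is reported as SS_effect / (SS_effect + SS_error) (the
within-subjects convention), with the total-SS variant also attached.
All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "fisher_z",
    "fisher_z_inv",
    "one_sample_t",
    "paired_t",
    "pearson_r",
    "ks_two_sample",
    "rm_anova_oneway",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    df: Optional[object] = None  # scalar or (df1, df2)
    effect_size: Optional[float] = None
    ci: Optional[Tuple[float, float]] = None
    extras: dict = field(default_factory=dict)


def fisher_z(r):
    """Variance-stabilizing transform 0.5*ln((1+r)/(1-r)); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return out if out.ndim else float(out)


def fisher_z_inv(z):
    """Inverse of :func:`fisher_z` (tanh)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return out if out.ndim else float(out)


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """Two-sided one-sample t-test with df = n - 1 and a 95% CI of the mean."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least two values")
    if np.std(values, ddof=1) == 0:
        raise ValueError("zero variance")
    res = sps.ttest_1samp(values, mu0)
    lo, hi = res.confidence_interval(0.95)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        df=n - 1,
        ci=(float(lo), float(hi)),
    )


def paired_t(a, b) -> TestResult:
    """Two-sided paired t-test (a - b) via the one-sample test on differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0)


def pearson_r(x, y) -> float:
    """Product-moment correlation; requires equal lengths >= 3 and variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of at least 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(sps.pearsonr(x, y).statistic)


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum ECDF difference; the p-value uses the asymptotic
    Kolmogorov distribution with the standard effective-n correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    res = sps.ks_2samp(a, b, method="asymp")
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue))


def rm_anova_oneway(values) -> TestResult:
    """One-way repeated-measures ANOVA on a complete participants x levels matrix.

    Classical decomposition: SS_total = SS_subjects + SS_effect + SS_error,
    F = MS_effect / MS_error with df (k-1, (k-1)(n-1)).  ``effect_size`` is
    SS_effect / (SS_effect + SS_error); ``extras['eta_squared_total']``
    holds SS_effect / SS_total.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a complete 2-D matrix, >= 2 participants and levels")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix must be complete (no missing cells)")
    n, k = x.shape
    grand = x.mean()
    ss_total = float(np.sum((x - grand) ** 2))
    ss_effect = float(n * np.sum((x.mean(axis=0) - grand) ** 2))
    ss_subject = float(k * np.sum((x.mean(axis=1) - grand) ** 2))
    ss_error = ss_total - ss_effect - ss_subject
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_error = ss_error / df2
    if ms_error == 0:
        f = 0.0 if ss_effect == 0 else np.inf
        p = 1.0 if ss_effect == 0 else 0.0
    else:
        f = (ss_effect / df1) / ms_error
        p = float(sps.f.sf(f, df1, df2))
    denom = ss_effect + ss_error
    eta2 = 0.0 if denom == 0 else ss_effect / denom
    eta2_total = 0.0 if ss_total == 0 else ss_effect / ss_total
    return TestResult(
        statistic=float(f),
        p=p,
        df=(df1, df2),
        effect_size=float(eta2),
        extras={"eta_squared_total": float(eta2_total)},
    )
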