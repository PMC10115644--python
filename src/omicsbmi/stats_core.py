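"""Shared statistical primitives.

Every hypothesis test in the package is two-sided, and every multiple-testing
family is adjusted with the Benjamini-Hochberg step-up procedure. These
primitives are deliberately small and self-contained so that downstream
modules share one set of conventions (p in [0, 1], CI brackets estimate,
NaN-free inputs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "bh_adjust",
    "welch_t_test",
    "pearson_test",
    "out_of_sample_r2",
    "sample_skewness",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test.

    Attributes
    ----------
    statistic : test statistic (t, z, r, ...).
    p_value : two-sided p-value in [0, 1].
    df : degrees of freedom (possibly fractional, e.g. Satterthwaite), or
        ``nan`` for asymptotic tests.
    estimate : the effect estimate the test refers to, where applicable.
    ci_low, ci_high : 95% confidence bounds bracketing ``estimate``.
    """

    statistic: float
    p_value: float
    df: float = float("nan")
    estimate: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up), capped at 1.

    ``adjusted[i] = min_{j: p_(j) >= p_(i)} p_(j) * m / rank(j)`` where the
    minimum runs over the ordered p-values at or above p_(i)'s rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def welch_t_test(sample_a, sample_b) -> TestResult:
    """Two-sided Welch's t-test (unequal variances, Satterthwaite df)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        # Identical constant samples: no evidence against equality.
        return TestResult(0.0, 1.0, float(na + nb - 2), diff, diff, diff)
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    half = sps.t.ppf(0.975, df) * np.sqrt(se2)
    return TestResult(float(t), float(min(p, 1.0)), float(df), float(diff),
                      float(diff - half), float(diff + half))


def pearson_test(x, y) -> TestResult:
    """Two-sided Pearson correlation test with Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has undefined correlation")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / max(1.0 - r**2, np.finfo(float).tiny))
    if abs(r) >= 1.0:
        lo = hi = r
    else:
        z = np.arctanh(r)
        half = sps.norm.ppf(0.975) / np.sqrt(n - 3) if n > 3 else np.inf
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    return TestResult(float(t), float(res.pvalue), float(df), r,
                      float(lo), float(hi))


def out_of_sample_r2(y_true, y_pred, *, center_on: str = "evaluation") -> float:
    """Out-of-sample R-squared, 1 - SSE/SST, on a hold-out evaluation set.

    SST is taken about the mean of the observed values in the evaluation set
    (``center_on='evaluation'``, the default) so a predictor worse than that
    mean yields a negative value. Pass a float via ``center_on`` to use a
    training-set mean instead.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.size != yp.size:
        raise ValueError("lengths differ")
    if yt.size < 2:
        raise ValueError("need n >= 2")
    center = yt.mean() if center_on == "evaluation" else float(center_on)
    sst = np.sum((yt - center) ** 2)
    if sst == 0:
        raise ValueError("zero total sum of squares")
    sse = np.sum((yt - yp) ** 2)
    return float(1.0 - sse / sst)


def sample_skewness(values) -> float:
    """Moment-based (Fisher-Pearson g1) sample skewness."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise ValueError("need n >= 3 non-missing values")
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("constant vector has undefined skewness")
    return float(np.mean(((v - v.mean()) / sd) ** 3))
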