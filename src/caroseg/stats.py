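"""Agreement and paired-comparison statistics.

Normality-gated paired tests (Shapiro-Wilk on the paired differences, then a
paired t-test or a Wilcoxon signed-rank test), the two-way mixed-model
intraclass correlation with absolute agreement ICC(A,1) with its F-based 95%
confidence interval, Pearson correlation, Bland-Altman analysis with the
repeatability coefficient (RPC = 1.96 x SD of the differences) and the
coefficient of variation (CV = SD of the differences over the mean of the
two measurement sets, in percent), and delta/absolute-delta summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats as sps

SHAPIRO_ALPHA = 0.05


class DegenerateSampleError(ValueError):
    """Raised when a test's assumptions are unmeetable (constant data...)."""


@dataclass
class ICCResult:
    icc: float
    ci_lower: float
    ci_upper: float
    n_subjects: int
    n_raters: int

    @property
    def reliability(self) -> str:
        if self.icc >= 0.9:
            return "excellent"
        if self.icc >= 0.75:
            return "good"
        return "moderate/poor"


@dataclass
class BlandAltmanResult:
    bias: float
    rpc: float
    cv: float | None
    loa_lower: float
    loa_upper: float


def normality_gated_paired_test(x, y) -> Tuple[str, float]:
    """Paired two-sided test with a Shapiro-Wilk normality gate.

    The gate is applied to the paired differences (what the paired t-test
    assumes normal): Shapiro-Wilk p >= 0.05 selects the paired t-test,
    otherwise the Wilcoxon signed-rank test. Returns (test name, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1D samples, n >= 3")
    d = y - x
    if np.ptp(d) == 0:
        raise DegenerateSampleError(
            "paired differences are constant; paired tests are undefined")
    sw_p = sps.shapiro(d).pvalue
    if sw_p >= SHAPIRO_ALPHA:
        res = sps.ttest_rel(y, x)
        return "paired_t", float(res.pvalue)
    return "wilcoxon", wilcoxon_signed_rank(x, y)[1]


def wilcoxon_signed_rank(x, y) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Uses the exact sign-permutation null for n <= 25 (zero differences
    dropped), the normal approximation beyond.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = y - x
    d = d[d != 0]
    if len(d) == 0:
        raise DegenerateSampleError("all paired differences are zero")
    res = sps.wilcoxon(d, zero_method="wilcox",
                       method="exact" if len(d) <= 25 else "approx")
    return float(res.statistic), float(res.pvalue)


def icc_absolute_agreement(data: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way mixed, absolute agreement, single measure.

    ``data`` is an (n subjects) x (k raters) matrix with no missing cells.
    Point estimate from the two-way ANOVA mean squares,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

    with the McGraw-Wong F-based two-sided confidence interval.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be subjects x raters")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    grand = data.mean()
    row_m = data.mean(axis=1)
    col_m = data.mean(axis=0)
    ssr = k * np.sum((row_m - grand) ** 2)
    ssc = n * np.sum((col_m - grand) ** 2)
    sse = np.sum((data - row_m[:, None] - col_m[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateSampleError("zero total variance; ICC undefined")
    icc = (msr - mse) / denom

    # F-based CI (McGraw & Wong): Satterthwaite df for the denominator
    if mse == 0 and msc == 0:
        lo, hi = 1.0, 1.0
    else:
        a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isfinite(a):
            num = (a * msc + b * mse) ** 2
            den = ((a * msc) ** 2 / (k - 1)
                   + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            v = num / den if den > 0 else (n - 1) * (k - 1)
            f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (n * (msr - f_l * mse)
                  / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
            hi = (n * (f_u * msr - mse)
                  / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
        else:
            lo, hi = 1.0, 1.0
    lo = min(lo, icc)
    hi = max(hi, icc)
    return ICCResult(icc=float(icc), ci_lower=float(lo), ci_upper=float(min(hi, 1.0)),
                     n_subjects=n, n_raters=k)


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman agreement between two paired measurement sets.

    bias = mean(y - x); RPC = 1.96 x SD(y - x); CV = 100 x SD(y - x) divided
    by the mean of all pairwise averages (undefined -> None when that mean is
    zero); limits of agreement = bias +/- RPC.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need equal-length samples, n >= 2")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    rpc = 1.96 * sd
    pooled_mean = float(((x + y) / 2).mean())
    cv = 100.0 * sd / pooled_mean if pooled_mean != 0 else None
    return BlandAltmanResult(bias=bias, rpc=rpc, cv=cv,
                             loa_lower=bias - rpc, loa_upper=bias + rpc)


def pearson(x, y) -> Tuple[float, float]:
    """Sample Pearson correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need equal-length samples, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSampleError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def delta_summary(auto_vals, manual_vals) -> Tuple[float, float, float, float]:
    """(mean d, SD d, mean |d|, SD |d|) with d = auto - manual."""
    a = np.asarray(auto_vals, dtype=float)
    m = np.asarray(manual_vals, dtype=float)
    if a.shape != m.shape:
        raise ValueError("samples must be paired")
    d = a - m
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    sd_abs = float(np.abs(d).std(ddof=1)) if len(d) > 1 else 0.0
    return float(d.mean()), sd, float(np.abs(d).mean()), sd_abs
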