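"""Agreement and reproducibility statistics.

* ICC(A,1): two-way mixed-effects intraclass correlation for absolute
  agreement of single measurements (McGraw-Wong convention), with the
  F-based confidence interval.
* Short-term precision errors PE(SD) and PE(%CV): root-mean-square of
  the within-subject SD (and %CV) over subjects, the densitometry
  convention of Glueer-style precision analysis.
* Bland-Altman agreement with limits of agreement and a regression test
  for proportional bias.
* Pearson correlation with simple linear regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phantom import RepeatedMeasuresTable

log = logging.getLogger("qma")

__all__ = [
    "ReliabilityResult", "RegressionResult", "BlandAltmanResult",
    "icc_absolute_single", "precision_errors", "bland_altman", "pearson_linreg",
]


@dataclass
class ReliabilityResult:
    icc: float
    ci_lower: float
    ci_upper: float
    pe_sd: float = np.nan
    pe_cv_pct: float = np.nan


@dataclass
class RegressionResult:
    r: float
    r2: float
    slope_m: float
    intercept_b: float
    p_value: float


@dataclass
class BlandAltmanResult:
    bias: float
    loa_lower: float
    loa_upper: float
    proportional_bias_slope: float
    proportional_bias_p: float


def _two_way_anova(values: np.ndarray):
    """Mean squares of the two-way (subjects x repeats) decomposition."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return ms_r, ms_c, ms_e


def icc_absolute_single(table: RepeatedMeasuresTable, alpha: float = 0.05) -> ReliabilityResult:
    """ICC(A,1) with its F-based confidence interval.

    ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)).
    Raises when the table has zero total variance (the coefficient is
    undefined there, not 1).
    """
    x = table.values
    n, k = x.shape
    if np.allclose(x, x.flat[0]):
        raise ValueError("zero total variance: ICC undefined")
    ms_r, ms_c, ms_e = _two_way_anova(x)
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))

    # F-based interval (McGraw-Wong): Satterthwaite df for the
    # denominator mean square
    if ms_e == 0.0:
        return ReliabilityResult(icc=float(icc), ci_lower=float(icc), ci_upper=float(icc))
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    num = (a * ms_c + b * ms_e) ** 2
    den = ((a * ms_c) ** 2 / (k - 1.0)
           + (b * ms_e) ** 2 / ((n - 1.0) * (k - 1.0)))
    v = num / den
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = (n * (ms_r - f_l * ms_e)
             / (f_l * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r))
    upper = (n * (f_u * ms_r - ms_e)
             / (k * ms_c + (k * n - k - n) * ms_e + n * f_u * ms_r))
    log.info("ICC(A,1) = %.4f [%.4f, %.4f] (n=%d, k=%d)", icc, lower, upper, n, k)
    return ReliabilityResult(icc=float(icc), ci_lower=float(lower), ci_upper=float(upper))


def precision_errors(table: RepeatedMeasuresTable):
    """(PE(SD), PE(%CV)): RMS within-subject standard deviation and %CV.

    PE(SD) = sqrt(sum_i SD_i^2 / n) with SD_i the within-subject SD
    (denominator k-1); PE(%CV) uses each subject's own mean and is
    returned NaN (undefined) when any subject mean is <= 0.
    """
    x = table.values
    n = x.shape[0]
    sd = x.std(axis=1, ddof=1)
    pe_sd = float(np.sqrt(np.sum(sd ** 2) / n))
    means = x.mean(axis=1)
    if np.any(means <= 0):
        log.warning("PE(%%CV) undefined: %d subject mean(s) <= 0", int(np.sum(means <= 0)))
        return pe_sd, float("nan")
    pe_cv = float(np.sqrt(np.sum((100.0 * sd / means) ** 2) / n))
    return pe_sd, pe_cv


def bland_altman(x, y, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland-Altman agreement of two paired measurement methods.

    Differences ``x - y`` against means ``(x + y)/2``; limits of
    agreement use the normal quantile (1.96 at alpha = 0.05).  The
    proportional-bias test regresses differences on means and t-tests
    the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    m = (x + y) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    z = float(stats.norm.ppf(1.0 - alpha / 2.0))
    if np.allclose(m, m[0]):
        slope, p = 0.0, float("nan")
    elif np.allclose(d, d[0]):
        slope, p = 0.0, 1.0
    else:
        res = stats.linregress(m, d)
        slope, p = float(res.slope), float(res.pvalue)
    return BlandAltmanResult(bias=bias, loa_lower=bias - z * sd,
                             loa_upper=bias + z * sd,
                             proportional_bias_slope=slope,
                             proportional_bias_p=p)


def pearson_linreg(x, y) -> RegressionResult:
    """Pearson R with simple least-squares regression of y on x.

    p is the two-sided t-transform p-value with n - 2 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance input")
    res = stats.linregress(x, y)
    return RegressionResult(r=float(res.rvalue), r2=float(res.rvalue ** 2),
                            slope_m=float(res.slope),
                            intercept_b=float(res.intercept),
                            p_value=float(res.pvalue))


def reliability_report(table: RepeatedMeasuresTable, alpha: float = 0.05) -> ReliabilityResult:
    """ICC(A,1) + CI + precision errors in one record (report-table row)."""
    res = icc_absolute_single(table, alpha)
    res.pe_sd, res.pe_cv_pct = precision_errors(table)
    return res
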