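"""Validity and reliability statistics for paired angular measurements.

Implements the agreement toolkit used to validate the measurement method:
Bland-Altman limits of agreement with a one-sample t-test for systematic
error, the Dahlberg index for random error, and the single-measurement
absolute-agreement intraclass correlation ICC(A,1) with McGraw-Wong
F-based confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "PairedSample",
    "AgreementStats",
    "ICCResult",
    "bland_altman",
    "dahlberg",
    "icc_single_absolute",
]

#: Conventional normal-quantile multiplier for 95% limits of agreement.
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedSample:
    """Two paired measurement series (degrees) over the same teeth."""

    labels: tuple
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a, float)
        b = np.asarray(self.b, float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValidationError("paired series must be 1-D and equal length")
        if a.size < 2:
            raise ValidationError("paired sample needs n >= 2")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValidationError("paired sample contains non-finite values")
        labels = tuple(self.labels) if self.labels else tuple(range(a.size))
        if len(labels) != a.size:
            raise ValidationError("labels length mismatch")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @classmethod
    def from_diffs(cls, diffs) -> "PairedSample":
        d = np.asarray(diffs, float)
        return cls(tuple(range(d.size)), d, np.zeros_like(d))


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary of the differences d = a - b (degrees).

    ``t_stat``/``p_value`` are NaN when the differences have zero variance
    (the t-test is undefined there); all other fields remain valid.
    """

    n: int
    mean_diff: float
    sd_diff: float
    ci_low: float
    ci_high: float
    loa_low: float
    loa_high: float
    t_stat: float
    p_value: float
    dahlberg: float


@dataclass(frozen=True)
class ICCResult:
    """Single-measurement absolute-agreement intraclass correlation."""

    icc: float
    ci_low: float
    ci_high: float
    model: str  # "two_way_random" | "two_way_mixed"
    definition: str = "absolute_agreement"
    measurement: str = "single"


def dahlberg(diffs) -> float:
    """Dahlberg method-error index sqrt(sum d_i^2 / (2 n)) (degrees)."""
    d = np.asarray(diffs, float)
    if d.size == 0:
        raise ValidationError("Dahlberg index needs at least one difference")
    return float(np.sqrt(np.sum(d * d) / (2.0 * d.size)))


def bland_altman(sample: PairedSample) -> AgreementStats:
    """Bland-Altman agreement analysis of d = a - b.

    Returns the mean difference (bias) with its 95% CI (Student t
    quantile), the sample SD (n-1 denominator), 95% limits of agreement
    (bias +/- 1.96 SD), the one-sample t-test of bias against zero, and
    the Dahlberg random-error index.
    """
    d = sample.a - sample.b
    n = d.size
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_half = LOA_MULTIPLIER * sd
    if sd > 0:
        se = sd / math.sqrt(n)
        tq = float(stats.t.ppf(0.975, n - 1))
        ci_low, ci_high = mean - tq * se, mean + tq * se
        t_stat = mean / se
        p_value = float(2.0 * stats.t.sf(abs(t_stat), n - 1))
    else:
        ci_low = ci_high = mean
        t_stat = p_value = float("nan")
    return AgreementStats(
        n=n,
        mean_diff=mean,
        sd_diff=sd,
        ci_low=ci_low,
        ci_high=ci_high,
        loa_low=mean - loa_half,
        loa_high=mean + loa_half,
        t_stat=float(t_stat),
        p_value=p_value,
        dahlberg=dahlberg(d),
    )


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows = subjects, columns = raters)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = (
        np.sum((x - grand) ** 2)
        - k * np.sum((row_means - grand) ** 2)
        - n * np.sum((col_means - grand) ** 2)
    )
    mse = sse / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_single_absolute(
    data, model: str = "two_way_random", confidence: float = 0.95
) -> ICCResult:
    """ICC(A,1): single measurement, absolute agreement.

    Parameters
    ----------
    data : (n_subjects, k_raters) array-like
        Complete two-way layout, no missing cells.
    model : {"two_way_random", "two_way_mixed"}
        Recorded for reporting; the ICC(A,1) point estimate and its
        McGraw-Wong F-based confidence interval are identical for the two
        models.

    Notes
    -----
    From the two-way ANOVA mean squares (MSR subjects, MSC raters, MSE
    residual)::

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    Constant data (zero variance everywhere) leaves the ICC undefined and
    is reported as NaN.  Perfect agreement (MSE = MSC = 0 with subject
    variance present) returns ICC = 1 with a degenerate CI.
    """
    if model not in ("two_way_random", "two_way_mixed"):
        raise ValidationError(f"unknown ICC model {model!r}")
    x = np.asarray(data, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("ICC needs an (n >= 2) x (k >= 2) matrix")
    if not np.all(np.isfinite(x)):
        raise ValidationError("ICC input has missing or non-finite cells")
    n, k = x.shape
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or np.ptp(x) == 0:
        return ICCResult(float("nan"), float("nan"), float("nan"), model)
    icc = (msr - mse) / denom
    if 1.0 - icc < 1e-12:
        return ICCResult(1.0, 1.0, 1.0, model)

    alpha = 1.0 - confidence
    a = k * icc / (n * (1.0 - icc))
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
    if mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    else:
        v = float(k - 1)
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    ci_low = (
        n * (msr - f_l * mse)
        / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    )
    ci_high = (
        n * (f_u * msr - mse)
        / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    )
    return ICCResult(float(icc), float(ci_low), float(ci_high), model)
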