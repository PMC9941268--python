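"""Method-agreement statistics: Bland–Altman, ICC, Pearson, group tests.

The agreement between modeled and measured threshold speeds is summarized
by the mean difference (bias) with 1.96·SD limits of agreement, by the
single-measure absolute-agreement intraclass correlation from the two-way
ANOVA mean squares (the SPSS "two-way mixed, absolute agreement, single
measures" variant), and by Pearson correlations with the conventional
interpretation bands.  Sex comparisons use independent-samples t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import PairingError, UndefinedStatisticError
from .units import round_half_away

#: Pearson interpretation bands (upper edge inclusive in the lower band)
PEARSON_BANDS = (
    (0.30, "negligible"),
    (0.50, "low"),
    (0.70, "moderate"),
    (0.90, "high"),
    (np.inf, "very high"),
)

#: ICC interpretation bands
ICC_BANDS = (
    (0.50, "poor"),
    (0.75, "moderate"),
    (0.90, "good"),
    (np.inf, "excellent"),
)


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman and ICC summary for one modeled-vs-measured pairing."""

    n: int
    bias: float  # mean(modeled − measured), m/s
    sd_diff: float  # SD of differences (n−1)
    loa_low: float  # bias − 1.96·SD
    loa_high: float  # bias + 1.96·SD
    loa_pct: int  # 1.96·SD as % of the criterion mean, integer-rounded
    icc: float
    icc_ci95: tuple[float, float]
    icc_label: str


def loa_percent(half_width: float, criterion_mean: float) -> int:
    """Limits-of-agreement half-width as an integer percentage of the
    criterion mean (the ±x% convention of agreement summaries)."""
    return int(round_half_away(100.0 * half_width / criterion_mean, 0))


def bland_altman(
    modeled: Sequence[float], measured: Sequence[float]
) -> tuple[float, float, float, float, int]:
    """Bias and limits of agreement of modeled − measured.

    Returns ``(bias, sd_diff, loa_low, loa_high, loa_pct)``; the percent
    limits use the mean of the *measured* (criterion) values as denominator.
    """
    x = np.asarray(modeled, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.shape != y.shape:
        raise PairingError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise PairingError("need at least 3 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    return bias, sd, bias - half, bias + half, loa_percent(half, float(y.mean()))


def icc_absolute_agreement(
    ratings: np.ndarray, ci: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Single-measure absolute-agreement ICC of an n-subjects × k-methods
    matrix, from the two-way ANOVA mean squares:

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    with the F-based confidence interval of McGraw & Wong.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise PairingError("ratings must be an n>=3 by k>=2 matrix")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total <= 0:
        raise UndefinedStatisticError("zero total variance: ICC undefined")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise UndefinedStatisticError("degenerate mean squares: ICC undefined")
    icc = (msr - mse) / denom

    # McGraw–Wong CI for ICC(A,1)
    alpha = 1.0 - ci
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
    else:
        lower = upper = 1.0
    return float(icc), (float(lower), float(upper))


def icc_label(icc: float) -> str:
    for hi, label in ICC_BANDS:
        if icc < hi:
            return label
    return ICC_BANDS[-1][1]


def agreement(
    modeled: Sequence[float], measured: Sequence[float]
) -> AgreementResult:
    """Full modeled-vs-measured agreement summary (Bland–Altman + ICC)."""
    bias, sd, lo, hi, pct = bland_altman(modeled, measured)
    ratings = np.column_stack([modeled, measured])
    icc, ci95 = icc_absolute_agreement(ratings)
    return AgreementResult(
        n=len(np.asarray(modeled)),
        bias=bias,
        sd_diff=sd,
        loa_low=lo,
        loa_high=hi,
        loa_pct=pct,
        icc=icc,
        icc_ci95=ci95,
        icc_label=icc_label(icc),
    )


def pearson_with_label(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, str]:
    """Pearson r with the conventional magnitude label (band edges are
    assigned to the lower band)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise PairingError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise PairingError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    r = float(stats.pearsonr(x, y)[0])
    mag = abs(r)
    label = PEARSON_BANDS[-1][1]
    for hi, name in PEARSON_BANDS:
        if mag <= hi:
            label = name
            break
    return r, label


def compare_groups(
    a: Sequence[float], b: Sequence[float], mode: str = "student"
) -> tuple[float, float, float]:
    """Two-sided independent-samples t-test; returns (t, df, p).

    ``student`` pools variances (the default after variance homogeneity was
    verified); ``welch`` does not.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise PairingError("each group needs at least 2 observations")
    if mode == "student":
        t, p = stats.ttest_ind(a, b, equal_var=True)
        df = a.size + b.size - 2
    elif mode == "welch":
        t, p = stats.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    else:
        raise ValueError(f"unknown t-test mode {mode!r}")
    return float(t), float(df), float(p)
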