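"""Measurement-agreement statistics.

Implements the reliability toolkit used to validate a measurement method
against repeated measurements or a reference method:

* ICC(2,1) -- intraclass correlation, two-way random-effects, single
  measure, absolute agreement -- with a 95% confidence interval by the
  F-based procedure of McGraw & Wong (1996) using Satterthwaite degrees of
  freedom;
* SEM, the standard error of measurement, ``S * sqrt(1 - r_xx)`` with S the
  between-subject SD and r_xx the reliability coefficient;
* Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 SD of the
  paired differences), with skewness/excess-kurtosis descriptives of the
  differences in place of a formal normality test;
* the Portney-Watkins interpretation bands for ICC values.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingsMatrix",
    "ICCResult",
    "SemResult",
    "BlandAltmanResult",
    "icc_2_1",
    "sem",
    "bland_altman",
    "interpret_icc",
    "agreement_report",
    "plot_bland_altman",
]


@dataclasses.dataclass
class RatingsMatrix:
    """n subjects x k occasions/methods, no missing entries."""

    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2-D array")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 occasions")
        if not np.isfinite(self.values).all():
            raise ValueError("ratings must be finite (no missing entries)")
        if self.labels is None:
            self.labels = [f"occasion_{j + 1}" for j in range(k)]
        elif len(self.labels) != k:
            raise ValueError("one label per occasion required")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    category: str
    degenerate: bool = False

    def summary(self) -> str:
        return (
            f"ICC(2,1) = {self.icc:.3f} "
            f"(95% CI {self.ci_low:.3f}-{self.ci_high:.3f}), {self.category}"
        )


@dataclasses.dataclass(frozen=True)
class SemResult:
    sem: float
    sd_used: float
    icc_used: float


@dataclasses.dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    diff_skewness: float
    diff_excess_kurtosis: float


def icc_2_1(m: RatingsMatrix, confidence: float = 0.95) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    The two-way ANOVA mean squares are computed by direct summation and

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).

    The confidence interval uses F quantiles with Satterthwaite approximate
    denominator degrees of freedom.  A matrix with zero total variance is
    degenerate: ICC is reported as 1 with a flag.
    """
    x = m.values
    n, k = m.n, m.k
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    if ss_total == 0.0:
        return ICCResult(1.0, 1.0, 1.0, 0.0, 0.0, 0.0, "excellent", degenerate=True)

    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    if abs(icc - 1.0) < 1e-12:  # identical columns up to float round-off
        icc = 1.0

    alpha = 1.0 - confidence
    # Satterthwaite df for the denominator of the F tests (McGraw & Wong 1996)
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        denom_c = k * msc + (k * n - k - n) * mse
        lower = n * (msr - f_l * mse) / (f_l * denom_c + n * msr)
        upper = n * (f_u * msr - mse) / (denom_c + n * f_u * msr)
    else:  # perfect agreement: no sampling variability in the estimate
        lower = upper = icc
    lower = min(lower, icc)
    upper = max(upper, icc)
    return ICCResult(
        icc=float(icc),
        ci_low=float(lower),
        ci_high=float(min(upper, 1.0)),
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
        category=interpret_icc(icc),
    )


def sem(sd: float, icc: float) -> SemResult:
    """Standard error of measurement: ``SEM = S * sqrt(1 - r_xx)``."""
    if sd < 0:
        raise ValueError("standard deviation must be >= 0")
    if icc > 1:
        raise ValueError("reliability coefficient cannot exceed 1")
    return SemResult(sem=sd * float(np.sqrt(1.0 - icc)), sd_used=sd, icc_used=icc)


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman agreement of two paired measurement vectors.

    Differences are ``x - y``; the limits of agreement are
    ``bias +/- 1.96 * SD`` with the sample (n-1) SD and the literal 1.96
    normal quantile of the classic formulation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    bias = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d > 0:
        skew = float(stats.skew(d, bias=False))
        kurt = float(stats.kurtosis(d, bias=False))
    else:
        skew = kurt = 0.0
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd_d,
        loa_low=bias - 1.96 * sd_d,
        loa_high=bias + 1.96 * sd_d,
        diff_skewness=skew,
        diff_excess_kurtosis=kurt,
    )


def interpret_icc(icc: float) -> str:
    """Portney-Watkins bands: <0.50 poor, 0.50-0.74 moderate, >=0.75 excellent.

    Boundaries belong to the upper band; negative estimates are poor.
    """
    if icc >= 0.75:
        return "excellent"
    if icc >= 0.50:
        return "moderate"
    return "poor"


_PARAMETERS = ["csa_cm2", "fcsa_cm2", "fat_csa_cm2", "fat_fraction"]
_KEY_COLUMNS = ["subject_id", "slice_id", "muscle", "side", "level"]


def agreement_report(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Method-agreement report between two measurement tables.

    Tables follow the measurement schema (one row per subject/slice/muscle/
    side/level).  Rows are matched on the key columns; unmatched rows are
    excluded with a warning.  Per group (``by`` columns, default one pooled
    group) and per composition parameter the report gives mean, SD, ICC(2,1)
    with 95% CI, SEM (from that group's SD and ICC), and the Bland-Altman
    bias and limits of agreement.
    """
    for col in _KEY_COLUMNS:
        if col not in table_a.columns or col not in table_b.columns:
            raise ValueError(f"both tables must carry key column {col!r}")
    merged = table_a.merge(table_b, on=_KEY_COLUMNS, suffixes=("_a", "_b"), how="outer", indicator=True)
    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        ids = sorted(unmatched["subject_id"].astype(str).unique())
        warnings.warn(f"excluding unmatched subjects: {ids}", stacklevel=2)
    merged = merged[merged["_merge"] == "both"].drop(columns="_merge")

    group_iter = (
        merged.groupby(list(by), sort=True) if by else [(("all",), merged)]
    )
    rows = []
    for key, grp in group_iter:
        if not isinstance(key, tuple):
            key = (key,)
        for param in _PARAMETERS:
            a = grp[f"{param}_a"].to_numpy(dtype=float)
            bvals = grp[f"{param}_b"].to_numpy(dtype=float)
            pooled = np.concatenate([a, bvals])
            icc_res = icc_2_1(RatingsMatrix(np.column_stack([a, bvals])))
            sd = float(a.std(ddof=1))  # SD of the first-method measurements
            sem_res = sem(sd, icc_res.icc)
            ba = bland_altman(a, bvals)
            row = dict(zip(by, key)) if by else {"group": "all"}
            row.update(
                parameter=param,
                n=len(a),
                mean=float(pooled.mean()),
                sd=sd,
                icc=icc_res.icc,
                icc_ci_low=icc_res.ci_low,
                icc_ci_high=icc_res.ci_high,
                icc_category=icc_res.category,
                sem=sem_res.sem,
                bias=ba.bias,
                loa_low=ba.loa_low,
                loa_high=ba.loa_high,
                diff_skewness=ba.diff_skewness,
                diff_excess_kurtosis=ba.diff_excess_kurtosis,
            )
            rows.append(row)
    return pd.DataFrame(rows)


def plot_bland_altman(x, y, ax=None, title: str | None = None):
    """Bland-Altman plot: paired means vs differences, solid bias line,
    dashed limits of agreement."""
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = bland_altman(x, y)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2.0, x - y, s=18, alpha=0.8)
    ax.axhline(res.bias, color="k", lw=1.2)
    ax.axhline(res.loa_low, color="k", lw=1.0, ls="--")
    ax.axhline(res.loa_high, color="k", lw=1.0, ls="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (A - B)")
    if title:
        ax.set_title(title)
    return ax
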