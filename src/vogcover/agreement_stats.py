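"""Method-agreement statistics: Bland-Altman, ICC, Pearson, difference table.

These are the validation statistics used to compare a new ocular-
deviation measurement against the alternate prism cover test and to
quantify test-retest and inter-observer reliability:

* Bland-Altman 95% limits of agreement — mean difference ± 1.96 × SD of
  the paired differences; the "half-width" is the 1.96 × SD term.
* Intraclass correlation coefficient — ANOVA-based reliability of a
  subjects × raters/occasions matrix.  The default variant is ICC(2,1),
  two-way random effects, absolute agreement, single measures, with the
  F-distribution confidence interval of McGraw & Wong; ICC(1,1) and
  ICC(3,1) are selectable.
* Pearson product-moment correlation.
* Categorized absolute differences binned as < lo, lo–hi, > hi prism
  diopters, with table-style percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats

from .errors import ComputationError, InputError

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "DifferenceTable",
    "bland_altman",
    "icc",
    "pearson",
    "categorize_differences",
    "agreement_report",
    "bland_altman_plot",
]

ICC_MODELS = ("ICC1", "ICC2", "ICC3")


@dataclass(frozen=True)
class PairedMeasurements:
    """Same quantity measured twice per subject by two methods/raters."""

    subject_ids: tuple
    values_a: np.ndarray
    values_b: np.ndarray
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self):
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)
        if a.shape != b.shape or a.ndim != 1:
            raise InputError("values_a and values_b must be equal-length 1-D")
        if len(self.subject_ids) != a.size:
            raise InputError("subject_ids length must match the values")
        if a.size < 2:
            raise InputError("need at least 2 paired measurements")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise InputError("paired measurements must be complete and finite")

    @property
    def n(self) -> int:
        return int(self.values_a.size)

    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


@dataclass
class AgreementReport:
    """Bundle of agreement statistics for one method pair."""

    mean_diff: float
    sd_diff: float
    loa_halfwidth: float
    loa_lower: float
    loa_upper: float
    n: int
    icc: float | None = None
    icc_ci_low: float | None = None
    icc_ci_high: float | None = None
    pearson_r: float | None = None
    label_a: str = "A"
    label_b: str = "B"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def bland_altman(pairs: PairedMeasurements,
                 loa_multiplier: float = 1.96) -> AgreementReport:
    """Limits of agreement for paired measurements.

    Differences are a - b; the SD uses the n-1 (sample) convention and
    the limits are mean ± 1.96 × SD (no small-sample t correction, per
    the conventional Bland-Altman definition).
    """
    d = pairs.differences()
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    half = loa_multiplier * sd_diff
    return AgreementReport(
        mean_diff=mean_diff, sd_diff=sd_diff, loa_halfwidth=half,
        loa_lower=mean_diff - half, loa_upper=mean_diff + half,
        n=pairs.n, label_a=pairs.label_a, label_b=pairs.label_b)


def _mean_squares(x: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares of a complete subjects × raters matrix."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((x - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc(ratings, model: str = "ICC2", confidence: float = 0.95
        ) -> tuple[float, float, float]:
    """Single-measure intraclass correlation with an F-based CI.

    ``ratings`` is a complete subjects × raters/occasions matrix (no
    imputation is attempted; incomplete data is an error).  Variants:

    * ``ICC1`` — one-way random effects.
    * ``ICC2`` — two-way random effects, absolute agreement (default).
    * ``ICC3`` — two-way mixed effects, consistency.

    Returns ``(icc, ci_low, ci_high)``.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise InputError("ratings must be a 2-D subjects x raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InputError("need at least 2 subjects and 2 raters/occasions")
    if not np.all(np.isfinite(x)):
        raise InputError("ratings matrix must be complete (no missing values)")
    if model not in ICC_MODELS:
        raise InputError(f"model must be one of {ICC_MODELS}")

    msr, msc, mse, n, k = _mean_squares(x)
    alpha = 1.0 - confidence

    with np.errstate(divide="ignore", invalid="ignore"):
        if model == "ICC1":
            msw = (msc * (k - 1) + mse * (k - 1) * (n - 1)) / (n * (k - 1))
            denom = msr + (k - 1) * msw
            value = (msr - msw) / denom if denom > 0 else 1.0
            f = msr / msw if msw > 0 else np.inf
            df1, df2 = n - 1, n * (k - 1)
            fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + (k - 1))
            hi = (fu - 1) / (fu + (k - 1))
        elif model == "ICC3":
            denom = msr + (k - 1) * mse
            value = (msr - mse) / denom if denom > 0 else 1.0
            f = msr / mse if mse > 0 else np.inf
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + (k - 1))
            hi = (fu - 1) / (fu + (k - 1))
        else:  # ICC2, absolute agreement
            denom = msr + (k - 1) * mse + k * (msc - mse) / n
            value = (msr - mse) / denom if denom > 0 else 1.0
            # McGraw & Wong (1996) Satterthwaite-style CI for ICC(A,1)
            if mse <= 0 and msc <= mse:
                lo = hi = 1.0
            else:
                a = k * value / (n * (1 - value)) if value < 1 else np.inf
                b = 1 + k * value * (n - 1) / (n * (1 - value)) if value < 1 else np.inf
                if np.isinf(a) or np.isinf(b):
                    lo = hi = 1.0
                else:
                    v = ((a * msc + b * mse) ** 2 /
                         ((a * msc) ** 2 / (k - 1) +
                          (b * mse) ** 2 / ((n - 1) * (k - 1))))
                    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
                    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
                    lo = (n * (msr - f_l * mse) /
                          (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
                    hi = (n * (f_u * msr - mse) /
                          (k * msc + (k * n - k - n) * mse + n * f_u * msr))

    value = float(np.clip(value, -1.0, 1.0))
    lo = float(np.clip(np.nan_to_num(lo, nan=value), -1.0, 1.0))
    hi = float(np.clip(np.nan_to_num(hi, nan=value), -1.0, 1.0))
    return value, lo, hi


def pearson(values_a, values_b) -> float:
    """Pearson product-moment correlation of two equal-length samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise InputError("need two equal-length 1-D samples with n >= 2")
    if np.ptp(a) < 1e-300 or np.ptp(b) < 1e-300:
        raise ComputationError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DifferenceTable:
    """Absolute differences binned as < lo, lo-hi, > hi."""

    bounds: tuple[float, float]
    counts: tuple[int, int, int]
    percentages: tuple[float, float, float]
    percentages_raw: tuple[float, float, float]
    n: int

    @property
    def cumulative_below_upper_pct(self) -> float:
        """Percentage of subjects with |difference| <= the upper bound."""
        return _round_half_up(100.0 * (self.counts[0] + self.counts[1]) / self.n)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cumulative_below_upper_pct"] = self.cumulative_below_upper_pct
        return d


def categorize_differences(diffs, bounds: tuple[float, float] = (3.0, 5.0)
                           ) -> DifferenceTable:
    """Bin absolute method differences for a clinical summary table.

    The middle bin is closed on both ends ([lo, hi]) so values equal to
    a bound land in "lo-hi".  Percentages are rounded half-up to one
    decimal, with the middle bin set to the remainder so the printed
    column sums to exactly 100.0 — the convention used in clinical
    tables; the unadjusted values are kept in ``percentages_raw``.
    """
    d = np.abs(np.asarray(diffs, dtype=float))
    if d.size == 0:
        raise InputError("diffs must be non-empty")
    if not np.all(np.isfinite(d)):
        raise InputError("diffs must be finite")
    lo, hi = bounds
    if not lo < hi:
        raise InputError("bounds must be increasing")
    c_low = int(np.sum(d < lo))
    c_mid = int(np.sum((d >= lo) & (d <= hi)))
    c_high = int(np.sum(d > hi))
    n = int(d.size)
    raw = tuple(100.0 * c / n for c in (c_low, c_mid, c_high))
    p_low = _round_half_up(raw[0])
    p_high = _round_half_up(raw[2])
    p_mid = float(Decimal("100.0") - Decimal(repr(p_low)) - Decimal(repr(p_high)))
    return DifferenceTable(bounds=(float(lo), float(hi)),
                           counts=(c_low, c_mid, c_high),
                           percentages=(p_low, p_mid, p_high),
                           percentages_raw=raw, n=n)


def agreement_report(pairs: PairedMeasurements,
                     icc_model: str = "ICC2") -> AgreementReport:
    """Full agreement battery for one method pair.

    Combines Bland-Altman limits, the two-column ICC, and Pearson's r in
    one report.
    """
    report = bland_altman(pairs)
    matrix = np.column_stack([pairs.values_a, pairs.values_b])
    value, lo, hi = icc(matrix, model=icc_model)
    report.icc, report.icc_ci_low, report.icc_ci_high = value, lo, hi
    report.pearson_r = pearson(pairs.values_a, pairs.values_b)
    return report


def bland_altman_plot(pairs: PairedMeasurements, ax=None,
                      loa_multiplier: float = 1.96):
    """Standard Bland-Altman scatter with mean-difference and LoA lines."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    report = bland_altman(pairs, loa_multiplier)
    means = (pairs.values_a + pairs.values_b) / 2.0
    diffs = pairs.differences()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=18, color="black")
    ax.axhline(report.mean_diff, color="tab:blue", label="mean difference")
    for y in (report.loa_lower, report.loa_upper):
        ax.axhline(y, color="tab:blue", linestyle=":")
    ax.set_xlabel(f"mean of {pairs.label_a} and {pairs.label_b}")
    ax.set_ylabel(f"{pairs.label_a} - {pairs.label_b}")
    ax.legend(loc="best", fontsize=8)
    return ax
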