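"""Reliability and design statistics.

The measurement-reliability statistic is the intraclass correlation for
absolute agreement, single measure, under a two-way random-effects model —
ICC(2,1) in Shrout-Fleiss notation, ICC(A,1) in McGraw-Wong notation:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with MSR/MSC/MSE the subject, rater and error mean squares of the two-way
ANOVA on an n-subjects x k-raters table. The confidence interval is the
F-based interval of McGraw & Wong.

The pilot sample-size rule is n = ln(1 - confidence) / ln(1 - pi): the
smallest n for which an event of per-subject probability pi is observed at
least once with the stated confidence.

Standard inferential tests (Shapiro-Wilk, paired t, Wilcoxon) are
delegated to scipy.stats; only the table assembly is done here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["RaterTable", "IccResult", "icc_2way_random_single",
           "PilotSampleSize", "pilot_sample_size", "summarize_sides",
           "StatsError"]


class StatsError(ValueError):
    pass


@dataclass
class RaterTable:
    """n subjects x k raters/occasions measurement matrix, no missing cells."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StatsError("rater table must be 2D (subjects x raters)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise StatsError("need >= 2 subjects and >= 2 raters")
        if not np.all(np.isfinite(self.values)):
            raise StatsError("rater table has missing or non-finite cells")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    msr: float
    msc: float
    mse: float


def _mean_squares(y: np.ndarray):
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_2way_random_single(table: RaterTable, confidence: float = 0.95) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure,
    with the McGraw-Wong F-based confidence interval."""
    y = table.values
    n, k = y.shape
    msr, msc, mse = _mean_squares(y)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    scale = np.mean(y ** 2) + 1e-300
    if msr <= 1e-12 * scale:
        raise StatsError("zero between-subject variance; ICC undefined")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = (n * (msr - f_l * mse)) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        ci_high = (n * (f_u * msr - mse)) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr)
    else:  # perfect agreement
        ci_low, ci_high = 1.0, 1.0
    return IccResult(icc=float(icc), ci_low=float(ci_low),
                     ci_high=float(ci_high), msr=msr, msc=msc, mse=mse)


class PilotSampleSize(NamedTuple):
    n: float
    n_rounded: float


def pilot_sample_size(confidence: float, pi: float) -> PilotSampleSize:
    """Pilot sample size: smallest (fractional) n with
    ``1 - (1 - pi)^n >= confidence``, i.e. ``ln(1-confidence)/ln(1-pi)``.

    Returned unrounded and rounded to one decimal.
    """
    if not 0.0 < confidence < 1.0:
        raise StatsError("confidence must be in (0, 1)")
    if not 0.0 < pi < 1.0:
        raise StatsError("pi must be in (0, 1)")
    n = math.log(1.0 - confidence) / math.log(1.0 - pi)
    return PilotSampleSize(n=n, n_rounded=round(n, 1))


def summarize_sides(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-metric, per-period paired comparison of extraction vs
    non-extraction sides.

    ``df`` is tidy with columns ``subject``, ``side`` ("extraction" /
    "control"), ``period``, ``metric``, ``value``. For each metric x period
    the extraction-minus-control differences are summarized
    (mean, SD), tested for normality (Shapiro-Wilk), and compared with a
    paired t-test when normal, a Wilcoxon signed-rank test otherwise.
    """
    required = {"subject", "side", "period", "metric", "value"}
    missing = required - set(df.columns)
    if missing:
        raise StatsError(f"missing columns: {sorted(missing)}")
    rows = []
    for (metric, period), sub in df.groupby(["metric", "period"], sort=True):
        wide = sub.pivot_table(index="subject", columns="side",
                               values="value", aggfunc="first")
        if not {"extraction", "control"} <= set(wide.columns):
            raise StatsError(f"{metric}/{period}: both sides required")
        if wide[["extraction", "control"]].isna().any().any():
            raise StatsError(f"{metric}/{period}: unpaired records")
        diff = (wide["extraction"] - wide["control"]).to_numpy()
        if len(diff) < 2:
            raise StatsError(f"{metric}/{period}: need >= 2 paired subjects")
        if np.allclose(diff, diff[0]):
            sw_stat, sw_p = float("nan"), 1.0
            test, stat, p = "degenerate", 0.0, 1.0
        else:
            sw_stat, sw_p = sps.shapiro(diff)
            if sw_p > alpha:
                stat, p = sps.ttest_rel(wide["extraction"], wide["control"])
                test = "paired-t"
            else:
                stat, p = sps.wilcoxon(wide["extraction"], wide["control"])
                test = "wilcoxon"
        rows.append({
            "metric": metric, "period": period, "n": len(diff),
            "mean_diff": float(np.mean(diff)),
            "sd_diff": float(np.std(diff, ddof=1)),
            "shapiro_w": float(sw_stat), "shapiro_p": float(sw_p),
            "test": test, "statistic": float(stat), "p_value": float(p),
        })
    return pd.DataFrame(rows)
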