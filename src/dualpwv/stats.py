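"""Reproducibility and comparison statistics for paired PWV measurements.

The coefficient of variation used here is the paired-repeatability form
common in observer-agreement studies of arterial stiffness:

    CV% = 100 · SD(a − b) / mean(all 2n values)

i.e. the SD of the differences between paired repeated measurements divided
by the grand mean — not the single-sample SD/mean.  Bland–Altman agreement
reports the bias (mean difference), the SD of differences, and limits of
agreement at bias ± 1.96·SD.  All SDs use the n−1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ParameterError, StatisticsError

__all__ = [
    "ReproPairs",
    "AgreementResult",
    "TTestResult",
    "cv_paired",
    "bland_altman",
    "paired_t",
    "unpaired_t",
    "shapiro_normality",
]


@dataclass(eq=False)
class ReproPairs:
    """Equal-length paired measurements (m/s) from a repeatability design."""

    a: np.ndarray
    b: np.ndarray
    design: str = ""  # e.g. intra-observer / inter-observer / method-vs-method

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ParameterError("a and b must be equal-length 1-D sequences")
        if self.a.size < 2:
            raise ParameterError("need at least 2 pairs")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ParameterError("all paired values must be finite")

    @property
    def n(self) -> int:
        return self.a.size

    @property
    def diffs(self) -> np.ndarray:
        return self.a - self.b


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman summary of a set of measurement pairs."""

    mean_all: float
    mean_diff: float
    sd_diff: float
    cv_percent: float
    loa_low: float
    loa_high: float
    pearson_r: float
    #: per-pair (mean, difference) points for plotting
    pair_means: np.ndarray = field(repr=False, default=None)
    pair_diffs: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def cv_paired(pairs: ReproPairs) -> float:
    """CV% = 100 · SD(a−b) / mean of the concatenated 2n values."""
    mean_all = float(np.mean(np.concatenate([pairs.a, pairs.b])))
    if mean_all == 0:
        raise StatisticsError("CV undefined: mean of all measurements is zero")
    sd_diff = float(np.std(pairs.diffs, ddof=1))
    return 100.0 * sd_diff / mean_all


def bland_altman(pairs: ReproPairs) -> AgreementResult:
    """Bias, SD of differences, 1.96·SD limits of agreement and Pearson r."""
    d = pairs.diffs
    mean_all = float(np.mean(np.concatenate([pairs.a, pairs.b])))
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    if sd_diff > 0 and np.std(pairs.a) > 0 and np.std(pairs.b) > 0:
        r = float(sps.pearsonr(pairs.a, pairs.b).statistic)
    else:
        r = float("nan")
    cv = 100.0 * sd_diff / mean_all if mean_all != 0 else float("nan")
    return AgreementResult(
        mean_all=mean_all,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        cv_percent=cv,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        pearson_r=r,
        pair_means=0.5 * (pairs.a + pairs.b),
        pair_diffs=d,
    )


def paired_t(pairs: ReproPairs) -> TTestResult:
    """Two-sided paired t test; t = mean_diff / (sd_diff/√n), df = n−1."""
    if float(np.std(pairs.diffs, ddof=1)) == 0:
        raise StatisticsError("paired t degenerate: zero SD of differences")
    res = sps.ttest_rel(pairs.a, pairs.b)
    return TTestResult(t=float(res.statistic), df=float(pairs.n - 1), p=float(res.pvalue))


def unpaired_t(x, y, welch: bool = False) -> TTestResult:
    """Two-sided two-sample t test; pooled-variance Student by default,
    Welch with ``welch=True``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("each group needs at least 2 values")
    if np.std(x, ddof=1) == 0 and np.std(y, ddof=1) == 0:
        raise StatisticsError("unpaired t degenerate: zero variance in both groups")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def shapiro_normality(x) -> tuple[float, float]:
    """Shapiro–Wilk normality test; valid for 3 ≤ n ≤ 5000."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ParameterError(f"Shapiro–Wilk needs 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise StatisticsError("Shapiro–Wilk degenerate: constant sample")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)
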