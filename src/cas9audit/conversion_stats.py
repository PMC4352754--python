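"""Population statistics for SNV-driven off-target conversion.

The probability that a personal genome converts at least one off-target of
a guide grows (to first order) linearly with the guide's number of
three-mismatch off-target sites N3.  This module bins per-guide conversion
outcomes by N3, fits a zero-intercept weighted least-squares line to the
binned fractions, and provides the small downstream arithmetic: predicted
conversion rates at a given mean N3, a two-sided Z-test for comparing N3
distributions between site-selection strategies, and the clinical
extrapolation (conversion rate x relative off-target activity).

Slope units: **percent converted per off-target site**, so a per-site
conversion probability of 0.00145 corresponds to a slope of 0.145.

For a regression through the origin the usual centered R-squared is
ill-defined, so the uncentered form ``1 - SS_res / sum(w f^2)`` is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ConversionSummary:
    """Per-guide outcome: off-target count and whether any site converted."""

    target_id: str
    n3: int
    converted: bool

    def __post_init__(self) -> None:
        if self.n3 < 0:
            raise ValueError("n3 must be non-negative")


@dataclass(frozen=True)
class BinSeries:
    """Binned conversion fractions: bin centers x, fractions f, counts n."""

    centers: tuple[float, ...]
    fractions: tuple[float, ...]
    counts: tuple[int, ...]
    bin_width: float

    def __post_init__(self) -> None:
        if not (len(self.centers) == len(self.fractions) == len(self.counts)):
            raise ValueError("centers, fractions and counts must align")
        for f in self.fractions:
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fraction {f} outside [0, 1]")


@dataclass(frozen=True)
class OriginRegression:
    """Zero-intercept weighted fit of conversion fraction vs off-target count."""

    slope_percent: float  # percent converted per off-target site
    r_squared: float
    stderr_percent: float  # binomial-propagated standard error of the slope
    fit_range: tuple[float, float]


@dataclass(frozen=True)
class DistributionStats:
    """Summary statistics of an off-target-count distribution."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 1:
            raise ValueError("n must be at least 1")


def summarize_counts(values: Sequence[float]) -> DistributionStats:
    arr = np.asarray(values, dtype=float)
    return DistributionStats(float(arr.mean()), float(arr.std(ddof=1)), len(arr))


def bin_fractions(
    summaries: Sequence[ConversionSummary],
    bin_width: float = 5,
    value_range: tuple[float, float] = (0, 100),
) -> BinSeries:
    """Bin per-guide outcomes by N3 and compute the converted fraction per bin.

    Bins are ``[lo, lo+w), [lo+w, lo+2w), ...`` over ``value_range`` (the
    last bin is closed on the right); empty bins are omitted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not summaries:
        raise ValueError("no summaries to bin")
    lo, hi = value_range
    edges = np.arange(lo, hi + bin_width, bin_width, dtype=float)
    n3 = np.array([s.n3 for s in summaries], dtype=float)
    conv = np.array([s.converted for s in summaries], dtype=float)
    in_range = (n3 >= lo) & (n3 <= hi)
    idx = np.clip(np.digitize(n3[in_range], edges) - 1, 0, len(edges) - 2)
    centers, fractions, counts = [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        n_b = int(sel.sum())
        if n_b == 0:
            continue
        centers.append(float((edges[b] + edges[b + 1]) / 2))
        fractions.append(float(conv[in_range][sel].mean()))
        counts.append(n_b)
    return BinSeries(tuple(centers), tuple(fractions), tuple(counts), float(bin_width))


def fit_through_origin(
    series: BinSeries, fit_range: tuple[float, float] = (0, 100)
) -> OriginRegression:
    """Weighted least-squares line through the origin on binned fractions.

    With weights ``w = n_b`` (bin target counts) and ``x`` the bin centers,
    ``beta = sum(w x f) / sum(w x^2)``; weighting by counts makes the binned
    fit equal the per-target through-origin fit.  The slope is reported in
    percent per off-target.  The standard error propagates per-bin binomial
    variance ``f(1-f)/n_b``.
    """
    lo, hi = fit_range
    x = np.array(series.centers)
    f = np.array(series.fractions)
    w = np.array(series.counts, dtype=float)
    sel = (x >= lo) & (x <= hi)
    x, f, w = x[sel], f[sel], w[sel]
    if x.size == 0:
        raise ValueError("no bins within the fit range")
    sxx = float(np.sum(w * x * x))
    if sxx == 0:
        raise ValueError("all bin centers are zero; slope undefined")
    beta = float(np.sum(w * x * f)) / sxx
    ss_res = float(np.sum(w * (f - beta * x) ** 2))
    ss_tot = float(np.sum(w * f * f))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    var_f = f * (1.0 - f) / w  # binomial variance of each bin fraction
    var_beta = float(np.sum((w * x) ** 2 * var_f)) / sxx**2
    return OriginRegression(
        slope_percent=100.0 * beta,
        r_squared=r2,
        stderr_percent=100.0 * math.sqrt(var_beta),
        fit_range=(float(lo), float(hi)),
    )


def fit_summaries_through_origin(
    summaries: Sequence[ConversionSummary],
    bin_width: float = 5,
    fit_range: tuple[float, float] = (0, 100),
) -> tuple[BinSeries, OriginRegression]:
    """Convenience: bin then fit."""
    series = bin_fractions(summaries, bin_width=bin_width, value_range=fit_range)
    return series, fit_through_origin(series, fit_range=fit_range)


def predict_rate(regression: OriginRegression, mean_n3: float) -> float:
    """Predicted conversion rate (percent) at a mean off-target count."""
    if mean_n3 < 0:
        raise ValueError("mean_n3 must be non-negative")
    return regression.slope_percent * mean_n3


def two_sided_z_test(stats_a: DistributionStats, stats_b: DistributionStats) -> tuple[float, float]:
    """Two-sided Z-test for a difference in means of two large samples.

    ``z = (mu_a - mu_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b)``; ``p = 2 Phi(-|z|)``
    may underflow to exactly 0 for the genome-scale sample sizes involved.
    Two zero-variance samples with equal means give (0, 1) by convention.
    """
    if stats_a.n < 2 or stats_b.n < 2:
        raise ValueError("both samples need n >= 2")
    se = math.sqrt(stats_a.sd**2 / stats_a.n + stats_b.sd**2 / stats_b.n)
    if se == 0:
        if stats_a.mean == stats_b.mean:
            return 0.0, 1.0
        return math.copysign(math.inf, stats_a.mean - stats_b.mean), 0.0
    z = (stats_a.mean - stats_b.mean) / se
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return z, p


def extrapolate_clinical_rate(conversion_percent: float, relative_activity_fraction: float) -> float:
    """Expected off-target mutation rate relative to the on-target rate.

    Product of the SNV conversion rate (percent) and the relative cutting
    activity of a converted site (fraction of on-target activity), on the
    percent scale — e.g. a 2.0% conversion rate at 33% relative activity
    yields 0.66%.
    """
    if not (0.0 <= conversion_percent <= 100.0):
        raise ValueError("conversion_percent must be within [0, 100]")
    if not (0.0 <= relative_activity_fraction <= 1.0):
        raise ValueError("relative_activity_fraction must be within [0, 1]")
    return conversion_percent * relative_activity_fraction
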