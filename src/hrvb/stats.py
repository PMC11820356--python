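"""Method-agreement and comparison statistics.

Two standard-deviation conventions coexist deliberately: Bland-Altman
limits of agreement use the sample (n-1) SD, while descriptive summary rows
use the population (n) SD.  The Wilcoxon signed-rank test is exact (full
sign-assignment enumeration via a rank-sum distribution) up to n = 25, with
a tie-corrected normal approximation beyond.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "BlandAltmanResult",
    "PairedTestResult",
    "DescriptiveRow",
    "bland_altman",
    "descriptive_row",
    "paired_wilcoxon",
    "hrv_improvement_test",
]

#: limits-of-agreement multiplier (not 2.0)
LOA_Z = 1.96

#: largest n for the exact signed-rank null distribution
EXACT_N_MAX = 25


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float  # sample (n-1) SD of the differences
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float  # W = min of the signed-rank sums
    p_two_sided: float
    n_effective: int  # pairs remaining after zero-difference removal
    alternative: str = "two-sided"

    @property
    def p(self) -> float:
        return self.p_two_sided


@dataclass(frozen=True)
class DescriptiveRow:
    mean: float
    sd: float  # population (n) SD


def bland_altman(x, y) -> BlandAltmanResult:
    """Agreement between two methods: mean difference and 1.96-SD limits."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired inputs must have equal length")
    if x.size < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    d = x - y
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - LOA_Z * sd,
        loa_high=mean + LOA_Z * sd,
        n=x.size,
    )


def descriptive_row(values) -> DescriptiveRow:
    """Mean and population (divide-by-n) SD of a summary column."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value sequence")
    return DescriptiveRow(mean=float(np.mean(values)), sd=float(np.std(values, ddof=0)))


def _signed_rank_cdf_counts(ranks2: np.ndarray) -> np.ndarray:
    """Null counts of the doubled positive-rank sum over all sign choices.

    ``ranks2`` holds the mid-ranks doubled so they are exact integers;
    entry ``s`` of the result counts sign assignments with doubled rank sum
    ``s``.  Polynomial-convolution subset-sum, O(n * total).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    return counts


def paired_wilcoxon(x, y, alternative: str = "two-sided") -> PairedTestResult:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (classical treatment); tied absolute
    differences receive mid-ranks.  For up to 25 effective pairs the p-value
    is exact over all 2^n sign assignments; larger samples use the normal
    approximation with tie correction.  ``alternative`` is ``two-sided``,
    ``greater`` (x > y) or ``less``.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired inputs must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", UserWarning)
        return PairedTestResult(0.0, 1.0, 0, alternative)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)
    if n <= EXACT_N_MAX:
        ranks2 = np.round(2 * ranks).astype(int)
        counts = _signed_rank_cdf_counts(ranks2)
        denom = counts.sum()  # 2^n
        w2 = int(round(2 * w_plus))
        p_le = counts[: w2 + 1].sum() / denom
        p_ge = counts[w2:].sum() / denom
    else:
        mu = n * (n + 1) / 4.0
        tie_counts = np.unique(np.abs(d), return_counts=True)[1]
        correction = (tie_counts**3 - tie_counts).sum() / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - correction)
        p_le = float(norm.cdf((w_plus - mu) / sigma))
        p_ge = float(norm.sf((w_plus - mu) / sigma))
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return PairedTestResult(stat, float(p), n, alternative)


def hrv_improvement_test(pre: dict, post: dict) -> dict[str, PairedTestResult]:
    """One-sided (post > pre) paired Wilcoxon per HRV metric.

    ``pre`` and ``post`` map metric names to equal-length per-session value
    sequences.
    """
    if set(pre) != set(post):
        raise ValueError("pre and post must cover the same metrics")
    return {
        m: paired_wilcoxon(np.asarray(post[m]), np.asarray(pre[m]), "greater")
        for m in pre
    }
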