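"""Small-sample inference for paired hydration measurements.

With five samples per material group, normality is untestable, so the
paired 17 h vs 24 h comparisons use the exact Wilcoxon signed-rank test
(full enumeration of the sign-flip null, no normal approximation) and
the Hodges–Lehmann estimator of the median difference with its
distribution-free order-statistic confidence interval built from Walsh
averages.  Between-group comparisons of published summary statistics use
a two-sample t-test computable from (mean, sd, n) alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "TestResult",
    "HLEstimate",
    "DegenerateDataError",
    "signed_rank_null_pmf",
    "wilcoxon_signed_rank_exact",
    "walsh_averages",
    "hodges_lehmann",
    "two_sample_t_from_summary",
]


class DegenerateDataError(ValueError):
    """Raised when the data admit no test (e.g. all differences zero)."""


@dataclass(frozen=True)
class PairedSample:
    """Paired measurements at the two key hydration timepoints."""

    x_17h: tuple[float, ...]
    x_24h: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.x_17h) != len(self.x_24h):
            raise ValueError("paired samples must have equal length")
        if len(self.x_17h) == 0:
            raise ValueError("paired sample is empty")

    def differences(self) -> np.ndarray:
        """Differences taken as (24 h - 17 h), so growth is positive."""
        return np.asarray(self.x_24h, dtype=float) - np.asarray(
            self.x_17h, dtype=float
        )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two_sided: float
    method: str
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class HLEstimate:
    """Hodges–Lehmann median difference with a distribution-free CI.

    ``achieved_coverage`` is the exact confidence level delivered by the
    order-statistic interval; for very small n the nominal ``1 - alpha``
    may be unattainable, in which case the widest interval is returned
    and ``coverage_met`` is False.
    """

    median_diff: float
    ci_low: float
    ci_high: float
    alpha: float
    achieved_coverage: float
    coverage_met: bool

    def __post_init__(self) -> None:
        if not self.ci_low <= self.median_diff <= self.ci_high:
            raise ValueError("HL point estimate outside its CI")


def signed_rank_null_pmf(ranks: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the signed-rank sum W.

    Under the null every subset of ranks is equally likely to be the
    positive set.  Returns ``(support, pmf)``; built by dynamic
    programming over rank sums so mid-ranks (ties in ``|d|``) are
    handled exactly.  Ranks are doubled internally so half-integer
    mid-ranks stay on an integer lattice.
    """
    r2 = np.asarray(ranks, dtype=float) * 2
    r2i = np.rint(r2).astype(int)
    if not np.allclose(r2, r2i):
        raise ValueError("ranks must be integers or half-integers")
    total = int(r2i.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2i:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    support = np.arange(total + 1) / 2.0
    return support, counts / counts.sum()


def wilcoxon_signed_rank_exact(
    x: Sequence[float], y: Sequence[float] | None = None, max_n: int = 30
) -> TestResult:
    """Exact two-sided Wilcoxon signed-rank test for paired data.

    Parameters
    ----------
    x, y:
        Either the paired samples (differences taken as ``x - y``) or,
        with ``y`` omitted, the differences themselves.

    Zero differences are dropped before ranking (the classic convention)
    and tied magnitudes receive mid-ranks.  The statistic W is the sum
    of ranks of the positive differences; the two-sided p-value is
    ``min(1, 2 * min(P(W <= w), P(W >= w)))`` under full enumeration of
    all sign assignments — no normal approximation at any n.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all differences are zero; no test possible")
    if n > max_n:
        raise ValueError(f"exact enumeration limited to n <= {max_n}, got {n}")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    support, pmf = signed_rank_null_pmf(ranks)
    lower = float(pmf[support <= w + 1e-12].sum())
    upper = float(pmf[support >= w - 1e-12].sum())
    p = min(1.0, 2.0 * min(lower, upper))
    return TestResult(statistic=w, p_two_sided=p, method="wilcoxon-exact")


def walsh_averages(d: Sequence[float]) -> np.ndarray:
    """All n(n+1)/2 pairwise averages (d_i + d_j)/2, i <= j, sorted."""
    arr = np.asarray(d, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot form Walsh averages of an empty sample")
    i, j = np.triu_indices(arr.size)
    return np.sort((arr[i] + arr[j]) / 2.0)


def hodges_lehmann(d: Sequence[float], alpha: float = 0.05) -> HLEstimate:
    """Hodges–Lehmann estimate of the median difference with exact CI.

    The point estimate is the median of the Walsh averages.  The CI is
    the pair of k-th extreme Walsh averages, with k chosen from the
    exact signed-rank null distribution (untied ranks 1..n) as the
    largest k whose two-sided error does not exceed ``alpha``; the
    achieved coverage ``1 - 2 P(W <= k-1)`` is reported.  When even the
    widest interval cannot reach ``1 - alpha`` (possible for n <= 5 at
    95%), that widest interval is returned with ``coverage_met=False``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    arr = np.asarray(d, dtype=float)
    if arr.size == 0:
        raise ValueError("empty difference sample")
    w = walsh_averages(arr)
    est = float(np.median(w))
    n = arr.size
    m = n * (n + 1) // 2
    support, pmf = signed_rank_null_pmf(np.arange(1, n + 1))

    def tail_prob(k: int) -> float:
        return float(pmf[support <= (k - 1) + 1e-9].sum())  # P(W <= k-1)

    # largest k >= 1 with P(W <= k-1) <= alpha/2
    k = 1
    for cand in range(1, m // 2 + 2):
        if tail_prob(cand) <= alpha / 2 + 1e-12:
            k = cand
        else:
            break
    tail = tail_prob(k)
    coverage = 1.0 - 2.0 * tail
    return HLEstimate(
        median_diff=est,
        ci_low=float(w[k - 1]),
        ci_high=float(w[m - k]),
        alpha=alpha,
        achieved_coverage=coverage,
        coverage_met=coverage >= 1.0 - alpha - 1e-12,
    )


def two_sample_t_from_summary(
    m1: float,
    s1: float,
    n1: int,
    m2: float,
    s2: float,
    n2: int,
    variant: Literal["pooled", "welch"] = "pooled",
) -> TestResult:
    """Two-sample t-test from published (mean, sd, n) summaries.

    ``pooled`` assumes equal variances with df = n1 + n2 - 2 (the
    textbook two-sample t-test); ``welch`` uses the Welch–Satterthwaite
    degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if s1 == 0 and s2 == 0:
        raise DegenerateDataError("both groups have zero variance")
    v1, v2 = s1**2, s2**2
    if variant == "pooled":
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variant == "welch":
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t = float((m1 - m2) / se)
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(statistic=t, p_two_sided=p, method=f"t-{variant}", df=float(df))
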