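"""Cohort summary statistics and paired nonparametric comparisons.

Reporting convention: mean ± sample SD (n−1 denominator) with a Student-t
95% confidence interval, mean ± t_{1−α/2, n−1} · sd/√n.  Paired method
comparisons use the two-sided Wilcoxon signed-rank test (exact null for
small samples, normal approximation with tie/continuity corrections
otherwise; zero differences are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["CohortSummary", "summarize", "ci_from_moments", "paired_wilcoxon"]


@dataclass(frozen=True)
class CohortSummary:
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self):
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("CI must contain the mean")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def ci_from_moments(n: int, mean: float, sd: float,
                    level: float = 0.95) -> CohortSummary:
    """Student-t CI reconstructed from (n, mean, sample SD)."""
    if n < 2:
        raise ValueError("need n >= 2")
    tcrit = float(sps.t.ppf(0.5 + level / 2.0, df=n - 1))
    half = tcrit * sd / np.sqrt(n)
    return CohortSummary(n=n, mean=float(mean), sd=float(sd),
                         ci_low=float(mean - half), ci_high=float(mean + half),
                         level=level)


def summarize(values, level: float = 0.95) -> CohortSummary:
    """Mean ± sample SD with a Student-t confidence interval."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    return ci_from_moments(v.size, v.mean(), v.std(ddof=1), level)


def paired_wilcoxon(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-subject values.

    Zero differences are dropped; the exact null distribution is used for
    up to 25 non-zero differences, otherwise the normal approximation with
    continuity correction.  All-zero differences are degenerate and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = np.count_nonzero(d)
    if nz == 0:
        raise ValueError("all paired differences are zero: test undefined")
    method = "exact" if nz <= 25 else "approx"
    res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                       correction=(method == "approx"), method=method)
    return float(res.pvalue)
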