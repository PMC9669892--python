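"""Exact binomial intervals and the comparative statistics used by the DQIs.

Both data-quality indicators are binomial rates k/n:

* concordance — matches divided by possible matches among comparable
  units (episodes or profiles);
* completeness — element agreements divided by the *other* source's
  unit total, computed in both directions.

Exact two-sided 95% Clopper-Pearson intervals accompany every rate,
obtained from beta quantiles (equivalently, quantiles of the F
distribution): for k successes of n,

    low  = BetaInv(alpha/2;     k,     n - k + 1)        (0 if k = 0)
    high = BetaInv(1 - alpha/2; k + 1, n - k)            (1 if k = n)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .model import DQIResult


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval for k successes of n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    low = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def concordance_rate(
    agreements: int, comparable: int, variable: str = "", level: str = "episode",
    alpha: float = 0.05,
) -> DQIResult:
    """Matches in relation to the number of possible matches."""
    if comparable < 1:
        raise ValueError("comparable must be >= 1")
    low, high = clopper_pearson(agreements, comparable, alpha)
    return DQIResult(
        indicator="concordance", variable=variable, k=agreements, n=comparable,
        rate=agreements / comparable, ci_low=low, ci_high=high, level=level,
    )


def completeness_rate(
    agreements: int, source_total: int, variable: str = "", level: str = "episode",
    alpha: float = 0.05,
) -> DQIResult:
    """Element agreements relative to one source's unit total."""
    if source_total < 1:
        raise ValueError("source_total must be >= 1")
    low, high = clopper_pearson(agreements, source_total, alpha)
    return DQIResult(
        indicator="completeness", variable=variable, k=agreements, n=source_total,
        rate=agreements / source_total, ci_low=low, ci_high=high, level=level,
    )


@dataclass(frozen=True, slots=True)
class ContingencyTable2x2:
    """Counts (a, b) / (c, d): rows are groups, columns agree/disagree."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


def chi_square_yates(
    table: ContingencyTable2x2, correction: bool = True
) -> tuple[float, int, float]:
    """Chi-square test on a 2x2 table, Yates-corrected by default.

    statistic = N * (max(0, |ad - bc| - N/2))^2 / (r1 r2 c1 c2)

    The continuity term is capped at |ad - bc| so the statistic is 0 when
    observed equals expected. Returns (statistic, df=1, p).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero marginal")
    cross = abs(a * d - b * c)
    adj = max(0.0, cross - n / 2) if correction else float(cross)
    stat = n * adj**2 / (r1 * r2 * c1 * c2)
    p = float(sps.chi2.sf(stat, 1))
    return stat, 1, p


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test with midrank ties.

    Uses exact enumeration when both samples are small (n <= 20) and
    tie-free, the tie-corrected normal approximation with continuity
    correction otherwise. Returns (U of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if max(x.size, y.size) <= 20 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def threshold_check(dqi: DQIResult, threshold: float = 0.95) -> bool:
    """Registry DQI benchmark: pass iff the rate reaches the threshold.

    The conventional 95% threshold for professionally kept registries is
    not scientifically validated and is therefore configurable.
    """
    return dqi.rate >= threshold


def median_iqr(values) -> tuple[float, float, float, float, float]:
    """(median, q1, q3, min, max) with inclusive linear interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3), float(v.min()), float(v.max())


def format_p(p: float) -> str:
    """Report style: probabilities below 0.001 print as '<.001'."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0") if p < 1 else "1.00"
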