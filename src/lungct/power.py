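"""Power and sample-size computations for t-tests and one-way ANOVA.

Post-hoc power and a-priori sample sizes in the G*Power style, from the
noncentral t and noncentral F distributions:

* two-sided two-sample t-test, effect size Cohen's d: the test statistic
  under the alternative follows a noncentral t with df = n1 + n2 − 2 and
  noncentrality δ = d·√(n1·n2/(n1+n2)); power is the probability that |T′|
  exceeds the central-t critical value.
* one-way fixed-effects ANOVA with k groups, effect size Cohen's f: the F
  statistic follows a noncentral F with (k−1, N−k) df and noncentrality
  λ = f²·N, N the total sample size.

A-priori sample sizes search balanced (equal-allocation) designs upward
from 2 per group, returning the smallest design whose power reaches the
target. Raw powers are kept at full precision; rounding to whole percent
is presentation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "TTestPowerQuery",
    "AnovaPowerQuery",
    "ttest_power",
    "ttest_sample_size",
    "anova_power",
    "anova_sample_size",
]

_MAX_N_PER_GROUP = 100_000


@dataclass(frozen=True)
class TTestPowerQuery:
    cohen_d: float
    n1: int
    n2: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.cohen_d < 0:
            raise ValueError("cohen_d must be non-negative")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class AnovaPowerQuery:
    cohen_f: float
    group_sizes: tuple[int, ...]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.cohen_f < 0:
            raise ValueError("cohen_f must be non-negative")
        sizes = tuple(int(n) for n in self.group_sizes)
        object.__setattr__(self, "group_sizes", sizes)
        if len(sizes) < 2:
            raise ValueError("ANOVA needs at least 2 groups")
        if any(n < 2 for n in sizes):
            raise ValueError("each group needs n >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _nct_cdf_safe(x: float, df: float, ncp: float) -> float:
    """Noncentral-t CDF with a normal fallback for the deep far tail.

    scipy's nct can return NaN far in the tail opposite a large
    noncentrality; there the probability is numerically negligible and a
    normal approximation (T' ≈ N(ncp, 1)) bounds it safely.
    """
    v = stats.nct.cdf(x, df, ncp)
    if math.isfinite(v):
        return float(v)
    return float(stats.norm.cdf(x - ncp))


def ttest_power(q: TTestPowerQuery) -> float:
    """Power of the two-sided two-sample t-test at effect size d.

    With d = 0 the test rejects with probability α exactly.
    """
    df = q.n1 + q.n2 - 2
    ncp = q.cohen_d * math.sqrt(q.n1 * q.n2 / (q.n1 + q.n2))
    tcrit = stats.t.ppf(1.0 - q.alpha / 2.0, df)
    upper = 1.0 - _nct_cdf_safe(tcrit, df, ncp)
    lower = _nct_cdf_safe(-tcrit, df, ncp)
    return min(1.0, upper + lower)


def ttest_sample_size(
    cohen_d: float, target_power: float, alpha: float = 0.05
) -> tuple[int, int, float]:
    """Smallest balanced two-group design reaching the target power.

    Returns (n per group, total N, achieved power). Searches n upward
    from 2 by 1.
    """
    if cohen_d <= 0:
        raise ValueError("target power unreachable with cohen_d = 0")
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    for n in range(2, _MAX_N_PER_GROUP + 1):
        power = ttest_power(TTestPowerQuery(cohen_d, n, n, alpha))
        if power >= target_power:
            return n, 2 * n, power
    raise ValueError("no balanced design reaches the target power within the search range")


def anova_power(q: AnovaPowerQuery) -> float:
    """Power of the one-way fixed-effects ANOVA F-test at effect size f."""
    k = len(q.group_sizes)
    n_total = sum(q.group_sizes)
    df1, df2 = k - 1, n_total - k
    lam = q.cohen_f**2 * n_total
    fcrit = stats.f.ppf(1.0 - q.alpha, df1, df2)
    if lam == 0.0:  # scipy's ncf is undefined at zero noncentrality
        return float(stats.f.sf(fcrit, df1, df2))
    power = stats.ncf.sf(fcrit, df1, df2, lam)
    if not math.isfinite(power):  # far-tail fallback mirroring _nct_cdf_safe
        power = 1.0
    return min(1.0, float(power))


def anova_sample_size(
    cohen_f: float, k: int, target_power: float, alpha: float = 0.05
) -> tuple[int, int, float]:
    """Smallest equal-allocation k-group design reaching the target power.

    Returns (n per group, total N, achieved power).
    """
    if cohen_f <= 0:
        raise ValueError("target power unreachable with cohen_f = 0")
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    for n in range(2, _MAX_N_PER_GROUP + 1):
        power = anova_power(AnovaPowerQuery(cohen_f, (n,) * k, alpha))
        if power >= target_power:
            return n, k * n, power
    raise ValueError("no balanced design reaches the target power within the search range")
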