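"""Empirical-CDF machinery: two-sample Kolmogorov–Smirnov test and one-way ANOVA.

The two-sample K–S statistic is the decision statistic of the whole
package, so it is implemented from first principles here rather than
delegated: D is the supremum over the pooled sample values of the absolute
difference between the two empirical CDFs, with *both* one-sided gaps
evaluated at every jump point so that heavily tied (quantized pixel) data
are handled exactly.  The p-value uses the asymptotic Kolmogorov
distribution

    Q(lambda) = 2 * sum_{k>=1} (-1)^(k-1) * exp(-2 k^2 lambda^2),

evaluated at lambda = sqrt(n1*n2/(n1+n2)) * D, truncated when a term
drops below 1e-12 and clamped to [0, 1].  No small-sample continuity
correction is applied; intended sample sizes are >= 1024 values (whole
images), where the asymptotic form is accurate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import ValidationError


@dataclass(frozen=True)
class KSTestResult:
    d_statistic: float
    n1: int
    n2: int
    p_value: float

    def to_record(self) -> dict:
        return {"d": self.d_statistic, "n1": self.n1, "n2": self.n2, "p": self.p_value}


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


def ecdf_eval(sample: np.ndarray, x: float) -> float:
    """Right-continuous empirical CDF of ``sample`` evaluated at ``x``.

    ``sample`` must be sorted ascending and non-empty.
    """
    sample = np.asarray(sample)
    if sample.size == 0:
        raise ValidationError("sample: must be non-empty")
    return float(np.searchsorted(sample, x, side="right") / sample.size)


def kolmogorov_sf(lam: float, tol: float = 1e-12) -> float:
    """Survival function of the Kolmogorov distribution, Q(lambda)."""
    if lam <= 0:
        return 1.0
    total = 0.0
    sign = 1.0
    for k in range(1, 100001):
        term = np.exp(-2.0 * k * k * lam * lam)
        total += sign * term
        if term < tol:
            break
        sign = -sign
    return float(min(1.0, max(0.0, 2.0 * total)))


def ks_two_sample(a, b) -> KSTestResult:
    """Two-sample Kolmogorov–Smirnov test with exact tie handling.

    D = sup_x |F_a(x) - F_b(x)| taken over the pooled sorted values; at
    each jump both the left and right limits of the ECDF difference are
    inspected, so ties never under-estimate D.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("samples: both must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("samples: non-finite values")
    a_sorted = np.sort(a)
    b_sorted = np.sort(b)
    pooled = np.concatenate([a_sorted, b_sorted])
    pooled.sort()
    # right limits F(x) at every pooled point
    fa_hi = np.searchsorted(a_sorted, pooled, side="right") / a.size
    fb_hi = np.searchsorted(b_sorted, pooled, side="right") / b.size
    # left limits F(x-) cover the gap just below each jump
    fa_lo = np.searchsorted(a_sorted, pooled, side="left") / a.size
    fb_lo = np.searchsorted(b_sorted, pooled, side="left") / b.size
    d = float(max(np.abs(fa_hi - fb_hi).max(), np.abs(fa_lo - fb_lo).max()))
    n1, n2 = a.size, b.size
    lam = np.sqrt(n1 * n2 / (n1 + n2)) * d
    p = 1.0 if d == 0.0 else kolmogorov_sf(lam)
    return KSTestResult(d_statistic=d, n1=n1, n2=n2, p_value=p)


def anova_oneway(groups: list) -> AnovaResult:
    """One-way fixed-effects ANOVA from explicit sums of squares.

    F = (SS_between / df_between) / (SS_within / df_within); the p-value is
    the upper tail of the F(df_between, df_within) distribution.  A fully
    degenerate case (all values identical everywhere) returns F = 0, p = 1;
    perfect separation (zero within-group variance but non-zero
    between-group variance) returns F = +inf, p = 0.
    """
    arrays = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValidationError("groups: need at least 2 groups")
    if any(g.size == 0 for g in arrays):
        raise ValidationError("groups: every group needs at least 1 value")
    n_total = sum(g.size for g in arrays)
    k = len(arrays)
    if n_total - k < 1:
        raise ValidationError("groups: need at least one group with >= 2 values")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(_sps.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p)
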