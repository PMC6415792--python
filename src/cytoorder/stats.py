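"""Statistical comparison of per-cell order values between conditions.

Distributions of a per-cell summary (by convention the radial orientation
function value at 90 degrees, where strain effects peak) are compared with
the non-parametric two-sample Kolmogorov-Smirnov test, and the effect size
is the bias-corrected standardized mean difference (Hedges' g):

    g = b * (<x1> - <x2>) / s_p,      b = 1 - 3 / (4 (n1 + n2) - 9)

with s_p the pooled standard deviation
sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)).  Raw p-values are
reported without multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats


@dataclass(frozen=True)
class EffectSize:
    """Hedges' g with its ingredients."""

    g: float
    b: float
    sp: float
    n1: int
    n2: int
    mean1: float
    mean2: float
    s1: float
    s2: float


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns the D statistic (supremum of the empirical CDF difference) and
    the p-value (exact for small samples, asymptotic otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = spstats.ks_2samp(x, y, method="auto")
    return float(res.statistic), float(res.pvalue)


def hedges_g(x, y) -> EffectSize:
    """Bias-corrected standardized mean difference between two samples.

    Sample standard deviations use the n-1 denominator (the pooled-variance
    weights are n1-1 and n2-1).  Raises if both samples are constant
    (pooled SD of zero leaves g undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per sample")
    s1 = float(np.std(x, ddof=1))
    s2 = float(np.std(y, ddof=1))
    sp = float(np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)))
    if sp == 0:
        raise ValueError("pooled standard deviation is zero")
    b = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    m1, m2 = float(np.mean(x)), float(np.mean(y))
    g = b * (m1 - m2) / sp
    return EffectSize(
        g=g, b=b, sp=sp, n1=n1, n2=n2, mean1=m1, mean2=m2, s1=s1, s2=s2
    )
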