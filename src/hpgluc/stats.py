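"""Group summaries and significance testing.

All results are summarized as mean +/- sample standard deviation; group
differences use the unpaired two-tailed Welch t-test (unequal variances,
Satterthwaite degrees of freedom) at alpha = 0.05. The test statistic, degrees
of freedom and p-value are computed from the defining formulas; the Student-t
CDF is the only numerical primitive used. No multiple-testing correction is
applied — each endpoint is tested at alpha on its own, and reports flag this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist

__all__ = ["GroupComparison", "summarize", "welch_t_test", "significance_stars"]


@dataclass(frozen=True)
class GroupComparison:
    """Welch test result with the group summaries it was built from."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_stat: float
    dof: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def summarize(values) -> tuple:
    """Arithmetic mean and sample SD (n-1 denominator)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty sample")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
    return mean, sd


def welch_t_test(a, b) -> GroupComparison:
    """Unpaired two-tailed t-test with unequal variances.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom; two-sided p from the t CDF.
    Two groups that are both constant with equal means give p = 1 by
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    ma, mb = float(np.mean(a)), float(np.mean(b))
    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    sa, sb = np.sqrt(va), np.sqrt(vb)
    se2 = va / na + vb / nb
    if se2 == 0:
        # degenerate: no variability in either group
        t_stat = 0.0 if ma == mb else np.inf * np.sign(ma - mb)
        dof = float(na + nb - 2)
        p = 1.0 if ma == mb else 0.0
        return GroupComparison(ma, mb, sa, sb, na, nb, float(t_stat), dof, p)
    t_stat = (ma - mb) / np.sqrt(se2)
    dof = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(t_dist.sf(abs(t_stat), dof))
    return GroupComparison(ma, mb, sa, sb, na, nb, float(t_stat), float(dof),
                           min(p, 1.0))


def significance_stars(p: float) -> str:
    """Figure-style tiers: * p<0.05, ** p<0.01, *** p<0.001, else 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
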