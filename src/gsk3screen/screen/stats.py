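"""Unpaired t-tests with the star-band significance scheme.

Stars follow the printed bands with inclusive lower edges:
*  0.01 <= p < 0.05, ** 0.001 <= p < 0.01, *** 0.0001 <= p < 0.001,
**** p < 0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    stars: str


def stars_from_p(p: float) -> str:
    """Map a two-sided p-value onto the star bands."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def unpaired_ttest(
    group_a: list[float], group_b: list[float], equal_var: bool = True
) -> TTestResult:
    """Two-sided unpaired t-test (pooled variance; Welch optional).

    Zero pooled variance with equal means gives t = 0, p = 1 and no
    stars rather than an indeterminate statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("unpaired_ttest needs at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            df = len(a) + len(b) - 2
            return TTestResult(t=0.0, df=float(df), p=1.0, stars="")
        # distinct means, zero spread: infinitely significant
        return TTestResult(t=float("inf"), df=float(len(a) + len(b) - 2),
                           p=0.0, stars="****")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    p = float(res.pvalue)
    return TTestResult(t=float(res.statistic), df=df, p=p, stars=stars_from_p(p))
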