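"""Experiment-level statistics applied to batch quantification output.

Covers the three analyses typically run on per-sample milk summaries:
two-group comparisons (Welch's t-test by default, pooled-variance as a
sensitivity option), five-number boxplot summaries with √n-proportional box
widths, and ordinary least-squares fits with R² and a slope t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "BoxplotSummary",
    "RegressionFit",
    "welch_t_test",
    "boxplot_summary",
    "linear_fit",
]

ALPHA = 0.05


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool  # p <= 0.05


@dataclass
class BoxplotSummary:
    label: str
    n: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    box_width: float  # sqrt(n), normalized so the largest group has width 1


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided, slope t-test with n-2 df


def welch_t_test(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    pooled: bool = False,
) -> GroupComparison:
    """Two-sided two-sample t-test, unequal variances by default.

    With Welch's form the degrees of freedom follow the
    Welch–Satterthwaite approximation.  Two zero-variance samples with
    equal means return t = 0, p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            df = float(a.size + b.size - 2)
            return GroupComparison(labels, (a.size, b.size), (a.mean(), b.mean()),
                                   0.0, df, 1.0, False)
        raise ValueError("zero variance in both samples with unequal means")
    res = sps.ttest_ind(a, b, equal_var=pooled)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    return GroupComparison(
        labels=labels,
        n=(int(a.size), int(b.size)),
        means=(float(a.mean()), float(b.mean())),
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
        significant=p <= ALPHA,
    )


def boxplot_summary(groups: Mapping[str, Sequence[float]]) -> list[BoxplotSummary]:
    """Five-number summaries per group, widths ∝ √n.

    Quartiles use linear interpolation between order statistics; whiskers
    run to the sample minimum and maximum.  Widths are √n normalized to the
    largest group.
    """
    if not groups:
        raise ValueError("no groups supplied")
    sizes = {}
    for label, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {label!r} is empty")
        sizes[label] = v
    max_n = max(v.size for v in sizes.values())
    out = []
    for label, v in sizes.items():
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
        out.append(
            BoxplotSummary(
                label=label,
                n=int(v.size),
                minimum=float(v.min()),
                q1=float(q1),
                median=float(med),
                q3=float(q3),
                maximum=float(v.max()),
                box_width=float(math.sqrt(v.size / max_n)),
            )
        )
    return out


def linear_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares y = slope·x + intercept.

    R² is the squared Pearson correlation; the p-value comes from the
    slope's t statistic with n − 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    res = sps.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )
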