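"""Cohort-level hypothesis tests, implemented from closed forms.

The three tests the planning comparison needs: a one-sided paired t test
(sMRI vs conventional volumes and recurrence coverage), a one-sided
one-sample t test against a fixed population mean (Dice against 1.0),
and one-way ANOVA (target coverage and brainstem dose across plan
variants). Statistics are computed from the textbook sum-of-squares
formulas; tail probabilities come from the regularized incomplete beta
function, the closed form of the Student-t and F distribution tails.
No multiple-testing correction is applied (flagged in the result
metadata); test direction is always an explicit argument, never
inferred from the data's sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import betainc

__all__ = ["TestResult", "paired_t_one_sided", "one_sample_t_vs_unity",
           "one_way_anova"]


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: Union[float, Tuple[float, float]]
    p_value: float
    n: int
    direction: Optional[str] = None
    note: str = "no multiple-testing correction applied"

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def _t_tail(t: float, df: float, direction: str) -> float:
    """P(T >= t) or P(T <= t) for Student t via the incomplete beta.

    For t >= 0: P(T >= t) = I_{df/(df+t^2)}(df/2, 1/2) / 2; the other
    cases follow by symmetry.
    """
    x = df / (df + t * t)
    half = 0.5 * betainc(df / 2.0, 0.5, x)
    upper = half if t >= 0 else 1.0 - half
    if direction == "greater":
        return float(upper)
    if direction == "less":
        return float(1.0 - upper)
    if direction == "two-sided":
        return float(2.0 * min(upper, 1.0 - upper))
    raise ValueError(f"direction must be 'greater', 'less' or 'two-sided', got {direction!r}")


def _f_tail(f: float, d1: float, d2: float) -> float:
    """Upper tail P(F >= f) of the F(d1, d2) distribution."""
    if f <= 0:
        return 1.0
    x = d2 / (d2 + d1 * f)
    return float(betainc(d2 / 2.0, d1 / 2.0, x))


def _t_stat(values: np.ndarray, mu: float, what: str) -> Tuple[float, float, int]:
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError(f"{what}: need n >= 2, got n = {n}")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError(
            f"{what}: zero variance (all values identical: {values[0]!r}); "
            "the t statistic is undefined")
    t = (values.mean() - mu) / (sd / math.sqrt(n))
    return float(t), float(n - 1), n


def paired_t_one_sided(x: Sequence[float], y: Sequence[float],
                       direction: str = "greater") -> TestResult:
    """One-sided paired t test on differences d = x - y.

    ``direction='greater'`` tests mean(x - y) > 0. Degenerate (zero
    variance) differences are an error, not a p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired samples must match in length ({x.size} vs {y.size})")
    t, df, n = _t_stat(x - y, 0.0, "paired t test")
    return TestResult("paired-t", t, df, _t_tail(t, df, direction), n, direction)


def one_sample_t_vs_unity(x: Sequence[float], direction: str = "less",
                          mu: float = 1.0) -> TestResult:
    """One-sided one-sample t test against a fixed population mean
    (default 1.0, the perfect-overlap reference for Dice)."""
    t, df, n = _t_stat(np.asarray(x, dtype=float), mu, "one-sample t test")
    return TestResult("one-sample-t", t, df, _t_tail(t, df, direction), n, direction)


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within with
    (k - 1, N - k) degrees of freedom."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise ValueError(f"ANOVA group {i} has n = {g.size} < 2")
    k = len(arrs)
    N = sum(g.size for g in arrs)
    grand = np.concatenate(arrs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    d1, d2 = float(k - 1), float(N - k)
    if ss_within == 0:
        raise ValueError(
            "ANOVA within-group variance is zero (all groups constant); "
            "F is infinite/undefined")
    f = (ss_between / d1) / (ss_within / d2)
    return TestResult("one-way-anova", float(f), (d1, d2), _f_tail(f, d1, d2), N)
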