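"""Group summaries, 90% confidence intervals and two-sample t-tests.

Works either from raw values or from published summary statistics
(mean, error bar, n), since group comparisons must often be recomputed
from printed numbers alone.  Error bars are explicitly disambiguated
between SEM and 90% CI half-width (both conventions occur in practice):
``ci90_halfwidth = t_{0.95, n-1} * sem``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "t_test_from_summary",
    "t_test_from_values",
    "summary_from_errorbar",
]

Method = Literal["pooled", "welch"]
ErrorbarKind = Literal["sem", "ci90"]


def _ci90_factor(n: int) -> float:
    """t quantile mapping SEM to a 90% CI half-width for sample size n."""
    return float(sps.t.ppf(0.95, n - 1))


@dataclass(frozen=True)
class GroupSummary:
    """Mean, dispersion and sample size of one group of scalar measurements."""

    name: str
    n: int
    mean: float
    sd: float
    sem: float
    ci90_halfwidth: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a group summary requires n >= 2")
        if self.sd < 0 or self.sem < 0:
            raise ValueError("dispersions must be non-negative")

    @classmethod
    def from_mean_sem(cls, name: str, mean: float, sem: float, n: int) -> "GroupSummary":
        sd = sem * math.sqrt(n)
        return cls(name=name, n=int(n), mean=float(mean), sd=sd, sem=float(sem),
                   ci90_halfwidth=_ci90_factor(n) * sem)


@dataclass(frozen=True)
class TestResult:
    """Two-sample t-test outcome."""

    t: float
    df: float
    p: float
    method: Method
    group_a: GroupSummary
    group_b: GroupSummary
    degenerate: bool = False  # both dispersions zero with unequal means


def summarize(values: Iterable[float], name: str = "") -> GroupSummary:
    """Summarise raw values: mean, sd (ddof=1), SEM and 90% CI half-width."""
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("summarize requires at least 2 values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    sem = sd / math.sqrt(n)
    return GroupSummary(name=name, n=n, mean=mean, sd=sd, sem=sem,
                        ci90_halfwidth=_ci90_factor(n) * sem)


def summary_from_errorbar(mean: float, halfwidth: float, n: int,
                          interpretation: ErrorbarKind, name: str = "") -> GroupSummary:
    """Build a GroupSummary from a printed ``mean ± halfwidth`` error bar.

    ``interpretation='sem'`` treats the half-width as the standard error of
    the mean; ``'ci90'`` treats it as a 90% confidence-interval half-width
    and divides by the t quantile t_{0.95, n-1}.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be non-negative")
    if interpretation == "sem":
        sem = float(halfwidth)
    elif interpretation == "ci90":
        sem = float(halfwidth) / _ci90_factor(n)
    else:
        raise ValueError(f"unknown errorbar interpretation {interpretation!r}")
    return GroupSummary.from_mean_sem(name, mean, sem, n)


def t_test_from_summary(a: GroupSummary, b: GroupSummary,
                        method: Method = "pooled") -> TestResult:
    """Two-sided two-sample t-test from group summaries.

    ``pooled`` is the classical Student test with df = n_a + n_b - 2;
    ``welch`` uses the Welch-Satterthwaite degrees of freedom.
    """
    diff = a.mean - b.mean
    va, vb = a.sem ** 2, b.sem ** 2
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return TestResult(t=0.0, df=float(a.n + b.n - 2), p=1.0,
                              method=method, group_a=a, group_b=b)
        # zero dispersion with unequal means: p collapses to a 0 sentinel
        return TestResult(t=math.inf if diff > 0 else -math.inf,
                          df=float(a.n + b.n - 2), p=0.0, method=method,
                          group_a=a, group_b=b, degenerate=True)

    if method == "pooled":
        df = float(a.n + b.n - 2)
        sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / df
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    elif method == "welch":
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    else:
        raise ValueError(f"unknown method {method!r}")

    t = diff / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(t=float(t), df=float(df), p=min(p, 1.0), method=method,
                      group_a=a, group_b=b)


def t_test_from_values(values_a: Sequence[float], values_b: Sequence[float],
                       method: Method = "pooled",
                       names: tuple = ("a", "b")) -> TestResult:
    """Convenience wrapper: summarise raw samples then test."""
    return t_test_from_summary(summarize(values_a, names[0]),
                               summarize(values_b, names[1]), method=method)
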