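"""Count-based inference for attraction, maturation and safety experiments.

The experiments yield proportions: eggs attracted vs not, mature vs immature
within those groups, embryos implanted or born out of those transferred, and
time-courses of attraction during reversibility treatments.  Comparisons use
the Pearson chi-square test on 2x2 tables (no continuity correction by
default), and per-proportion uncertainty uses Wilson score intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CountTable2x2",
    "ProportionSeries",
    "TestResult",
    "ReversibilitySummary",
    "CompositionResult",
    "chi_square_2x2",
    "proportion_ci",
    "reversibility_summary",
    "composition_table",
]


@dataclass(frozen=True)
class CountTable2x2:
    """Two binomial arms: successes and totals for groups a and b."""

    successes_a: int
    n_a: int
    successes_b: int
    n_b: int

    def __post_init__(self) -> None:
        for s, n, arm in (
            (self.successes_a, self.n_a, "a"),
            (self.successes_b, self.n_b, "b"),
        ):
            if s < 0 or n < 0:
                raise ValueError(f"counts must be non-negative (arm {arm})")
            if s > n:
                raise ValueError(f"successes exceed total in arm {arm}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.successes_a, self.n_a - self.successes_a],
                [self.successes_b, self.n_b - self.successes_b],
            ]
        )


@dataclass(frozen=True)
class ProportionSeries:
    """Successes/totals along an ordered axis (minutes, pipetting strokes...)."""

    labels: np.ndarray
    successes: np.ndarray
    totals: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=float)
        s = np.asarray(self.successes, dtype=int)
        n = np.asarray(self.totals, dtype=int)
        if not (len(labels) == len(s) == len(n)):
            raise ValueError("labels, successes, totals must have equal lengths")
        if len(labels) >= 2 and np.any(np.diff(labels) <= 0):
            raise ValueError("labels must be strictly increasing")
        if np.any(s < 0) or np.any(n <= 0) or np.any(s > n):
            raise ValueError("require 0 <= successes <= totals, totals > 0")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "successes", s)
        object.__setattr__(self, "totals", n)

    @property
    def fractions(self) -> np.ndarray:
        return self.successes / self.totals


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def chi_square_2x2(table: CountTable2x2, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-square test of homogeneity on a 2x2 table (df = 1).

    Continuity correction is off by default; raises ``ValueError`` on a
    degenerate table (any zero row or column margin).
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero row or column margin")
    stat, p, df, _ = chi2_contingency(arr, correction=continuity_correction)
    method = "pearson-chi2" + ("-yates" if continuity_correction else "")
    return TestResult(statistic=float(stat), df=int(df), p_value=float(p), method=method)


def proportion_ci(successes: int, n: int, level: float = 0.95):
    """Wilson score interval for a binomial proportion.

    Returns ``(lower, upper)``.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not (0 <= successes <= n):
        raise ValueError("require 0 <= successes <= n")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="wilson")
    return float(lo), float(hi)


@dataclass(frozen=True)
class ReversibilitySummary:
    """Per-point attraction fractions with Wilson CIs and a monotonicity flag.

    ``non_increasing`` is True when each successive fraction either drops (or
    stays) relative to the previous one, allowing slack where the two Wilson
    intervals overlap (sampling noise can locally invert an underlying
    decreasing course)."""

    series: ProportionSeries
    fractions: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    non_increasing: bool
    level: float


def reversibility_summary(series: ProportionSeries, level: float = 0.95) -> ReversibilitySummary:
    """Summarize a detachment time/dose course of attraction fractions."""
    if len(series.labels) < 2:
        raise ValueError("need at least 2 points in the series")
    cis = [proportion_ci(s, n, level) for s, n in zip(series.successes, series.totals)]
    lo = np.array([c[0] for c in cis])
    hi = np.array([c[1] for c in cis])
    frac = series.fractions
    ok = True
    for i in range(1, len(frac)):
        if frac[i] <= frac[i - 1]:
            continue
        # increase: tolerate only if CIs overlap
        if lo[i] > hi[i - 1]:
            ok = False
            break
    return ReversibilitySummary(
        series=series, fractions=frac, ci_lower=lo, ci_upper=hi,
        non_increasing=ok, level=level,
    )


@dataclass(frozen=True)
class CompositionResult:
    """Maturation composition of attracted vs non-attracted eggs."""

    attracted_mature_pct: float
    attracted_immature_pct: float
    nonattracted_mature_pct: float
    nonattracted_immature_pct: float
    test: TestResult


def composition_table(
    attracted_mature: int,
    attracted_immature: int,
    nonattracted_mature: int,
    nonattracted_immature: int,
) -> CompositionResult:
    """Row-wise maturation percentages and the association chi-square test.

    Rows are attraction outcome, columns maturation stage; raises
    ``ValueError`` when a row is empty.
    """
    n_att = attracted_mature + attracted_immature
    n_non = nonattracted_mature + nonattracted_immature
    if n_att == 0 or n_non == 0:
        raise ValueError("empty row in the composition table")
    table = CountTable2x2(attracted_mature, n_att, nonattracted_mature, n_non)
    test = chi_square_2x2(table)
    return CompositionResult(
        attracted_mature_pct=100.0 * attracted_mature / n_att,
        attracted_immature_pct=100.0 * attracted_immature / n_att,
        nonattracted_mature_pct=100.0 * nonattracted_mature / n_non,
        nonattracted_immature_pct=100.0 * nonattracted_immature / n_non,
        test=test,
    )
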