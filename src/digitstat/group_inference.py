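"""Two-group and k-group frequentist comparisons from raw data or summaries.

All inference here is computable from (mean, SD, n) triples alone, so
printed summary tables are first-class inputs.  The raw-vector entry
points are exact wrappers: ``welch_from_raw`` agrees with
``welch_from_summary`` applied to the vectors' own summaries.

Conventions:

* Welch's t with the Welch-Satterthwaite df approximation; two-tailed p.
* Cohen's d with the unweighted average-variance denominator
  ``sqrt((s1^2 + s2^2) / 2)`` (the Becker-calculator form), not the
  n-weighted pooled SD.
* One-way ANOVA reconstructed from group summaries, with Cohen's f
  ``sqrt(SS_between / SS_within)`` as the effect-size scale.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    """A (mean, SD, n) triple — the unit of summary-statistic inference."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group n must be >= 2 for variance-based inference, got {self.n}")
        if not math.isfinite(self.sd) or self.sd < 0:
            raise ValueError(f"group sd must be finite and >= 0, got {self.sd}")
        if not math.isfinite(self.mean):
            raise ValueError(f"group mean must be finite, got {self.mean}")


@dataclasses.dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_two_tailed: float


@dataclasses.dataclass(frozen=True)
class EffectSize:
    """Standardized mean difference; sign follows mean1 - mean2."""

    d: float


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    cohen_f: float


def summarize(x: Sequence[float]) -> GroupSummary:
    """(mean, SD, n) of a raw vector, with the n-1 denominator SD."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-d vector of length >= 2")
    return GroupSummary(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size))


def welch_from_summary(g1: GroupSummary, g2: GroupSummary) -> WelchResult:
    """Welch's unequal-variance t-test from two (mean, SD, n) summaries.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2); df by Welch-Satterthwaite;
    p two-tailed from the t distribution.  Both SDs zero is an error (the
    statistic is undefined).
    """
    v1 = g1.sd**2 / g1.n
    v2 = g2.sd**2 / g2.n
    if v1 + v2 == 0.0:
        raise ValueError("both group SDs are zero; Welch t is undefined")
    se = math.sqrt(v1 + v2)
    t = (g1.mean - g2.mean) / se
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(t=t, df=df, p_two_tailed=min(p, 1.0))


def welch_from_raw(x1: Sequence[float], x2: Sequence[float]) -> WelchResult:
    """Welch's t-test on raw vectors; exactly welch_from_summary of their summaries."""
    return welch_from_summary(summarize(x1), summarize(x2))


def cohens_d(g1: GroupSummary, g2: GroupSummary) -> EffectSize:
    """Cohen's d with the unweighted average-variance denominator.

    d = (m1 - m2) / sqrt((s1^2 + s2^2) / 2).  This form (rather than the
    n-weighted pooled SD) is what the common web effect-size calculators
    report, and is invariant under a common affine rescaling of both
    groups.
    """
    denom = math.sqrt((g1.sd**2 + g2.sd**2) / 2.0)
    if denom == 0.0:
        raise ValueError("both group SDs are zero; Cohen's d is undefined")
    return EffectSize(d=(g1.mean - g2.mean) / denom)


def anova_oneway(groups: Sequence[GroupSummary]) -> AnovaResult:
    """One-way fixed-effects ANOVA reconstructed from group summaries.

    With k = 2 groups the F statistic equals the square of the
    pooled-variance t statistic.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    n_total = ns.sum()
    grand_mean = float((ns * means).sum() / n_total)
    ss_between = float((ns * (means - grand_mean) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_between = len(groups) - 1
    df_within = int(n_total) - len(groups)
    if ss_within == 0.0:
        raise ValueError("zero within-group variance; F is undefined")
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    cohen_f = math.sqrt(ss_between / ss_within)
    return AnovaResult(F=F, df_between=df_between, df_within=df_within, p=p, cohen_f=cohen_f)
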