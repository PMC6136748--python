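"""Duplicate-measurement averaging, digit ratios, and reliability statistics.

Each digit is measured twice; the mean of the two repeats is the working
length.  2D:4D is the ratio of the averaged second-digit length to the
averaged fourth-digit length of one hand, 2D:5D the analogue for the
fifth digit.  Missing duplicate pairs propagate: a ratio is undefined
whenever either contributing digit cell is missing, which is what makes
per-ratio sample sizes vary across a cohort.

Reliability of the duplicated measurements is summarized per (hand,
digit) cell by the test-retest Pearson r between first and second
measurements and by the intraclass correlation coefficient (two-way
random effects, single measure, consistency form — ICC(C,1)).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from digitstat.cohort_data import Digit, Hand, SubjectRecord

#: Minimum complete pairs for a per-cell reliability statistic.
MIN_RELIABILITY_PAIRS = 3


@dataclasses.dataclass(frozen=True)
class HandRatios:
    """Digit ratios of one hand; None marks a ratio with a missing input."""

    hand: Hand
    ratio_2d4d: float | None
    ratio_2d5d: float | None
    mean_finger_length: float | None


@dataclasses.dataclass(frozen=True)
class CellReliability:
    hand: Hand
    digit: Digit
    n_pairs: int
    test_retest_r: float | None
    icc: float | None

    @property
    def defined(self) -> bool:
        return self.test_retest_r is not None


@dataclasses.dataclass(frozen=True)
class ReliabilityResult:
    cells: tuple[CellReliability, ...]

    def cell(self, hand: Hand, digit: Digit) -> CellReliability:
        for c in self.cells:
            if c.hand is hand and c.digit is digit:
                return c
        raise KeyError((hand, digit))


@dataclasses.dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    undefined: bool = False


def compute_ratios(subject: SubjectRecord) -> tuple[HandRatios, HandRatios]:
    """(left, right) digit ratios of a subject from repeat-mean lengths.

    The mean finger length of a hand is the mean of its three averaged
    digit lengths, itself None if any digit cell is missing.
    """
    out = []
    for hand in (Hand.LEFT, Hand.RIGHT):
        lengths: dict[Digit, float | None] = {}
        for digit in (Digit.D2, Digit.D4, Digit.D5):
            m = subject.measurement(hand, digit)
            lengths[digit] = None if m is None else m.mean_length
        d2, d4, d5 = lengths[Digit.D2], lengths[Digit.D4], lengths[Digit.D5]
        ratio_24 = None if d2 is None or d4 is None else d2 / d4
        ratio_25 = None if d2 is None or d5 is None else d2 / d5
        mfl = None
        if d2 is not None and d4 is not None and d5 is not None:
            mfl = (d2 + d4 + d5) / 3.0
        out.append(
            HandRatios(hand=hand, ratio_2d4d=ratio_24, ratio_2d5d=ratio_25, mean_finger_length=mfl)
        )
    return out[0], out[1]


def _cell_pairs(
    cohort: Iterable[SubjectRecord], hand: Hand, digit: Digit
) -> tuple[np.ndarray, np.ndarray]:
    first, second = [], []
    for s in cohort:
        m = s.measurement(hand, digit)
        if m is not None:
            first.append(m.length_first)
            second.append(m.length_second)
    return np.asarray(first), np.asarray(second)


def test_retest(cohort: Sequence[SubjectRecord]) -> ReliabilityResult:
    """Pearson r between first and second measurements, per (hand, digit)."""
    cells = []
    for hand in (Hand.LEFT, Hand.RIGHT):
        for digit in (Digit.D2, Digit.D4, Digit.D5):
            x, y = _cell_pairs(cohort, hand, digit)
            if x.size < MIN_RELIABILITY_PAIRS:
                cells.append(CellReliability(hand, digit, int(x.size), None, None))
                continue
            if np.allclose(x, y):
                r = 1.0
            else:
                r = float(stats.pearsonr(x, y).statistic)
            cells.append(CellReliability(hand, digit, int(x.size), r, None))
    return ReliabilityResult(cells=tuple(cells))


def _icc_c1(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(C,1): two-way random effects, single measure, consistency.

    From the two-way subject x repeat ANOVA with n subjects and k = 2
    repeats: ICC = (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error),
    where MS_error is the residual (interaction) mean square after
    removing the repeat (column) effect.
    """
    data = np.column_stack([x, y]).astype(float)
    n, k = data.shape
    grand = data.mean()
    subject_means = data.mean(axis=1)
    repeat_means = data.mean(axis=0)
    ss_subjects = k * ((subject_means - grand) ** 2).sum()
    ss_repeats = n * ((repeat_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_error = ss_total - ss_subjects - ss_repeats
    ms_subjects = ss_subjects / (n - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))
    denom = ms_subjects + (k - 1) * ms_error
    if denom == 0.0:
        return math.nan
    return float((ms_subjects - ms_error) / denom)


def icc(cohort: Sequence[SubjectRecord]) -> ReliabilityResult:
    """Intraclass correlation ICC(C,1) of the duplicate measurements.

    Equals 1 when repeats are identical across subjects with nonzero
    between-subject variance; approaches 0 when repeats are independent
    noise with no subject effect.
    """
    cells = []
    for hand in (Hand.LEFT, Hand.RIGHT):
        for digit in (Digit.D2, Digit.D4, Digit.D5):
            x, y = _cell_pairs(cohort, hand, digit)
            if x.size < MIN_RELIABILITY_PAIRS:
                cells.append(CellReliability(hand, digit, int(x.size), None, None))
                continue
            cells.append(
                CellReliability(hand, digit, int(x.size), None, _icc_c1(x, y))
            )
    return ReliabilityResult(cells=tuple(cells))


def ks_normality(values: Sequence[float]) -> TestResult:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    The reference normal uses the sample mean and sample SD (ddof=1); the
    p-value is the plain KS p without the Lilliefors small-sample
    correction for estimated parameters, and is therefore conservative
    (approximate).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 5:
        raise ValueError("KS normality check needs at least 5 observations")
    sd = arr.std(ddof=1)
    if sd == 0.0:
        return TestResult(statistic=math.nan, p_value=math.nan, undefined=True)
    res = stats.kstest(arr, "norm", args=(arr.mean(), sd))
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue))


def levene(groups: Sequence[Sequence[float]]) -> TestResult:
    """Levene's test for equality of variances, mean-centred.

    Constant input (all within-group deviations zero) leaves the
    statistic undefined; the result is flagged rather than raised so
    that batch pipelines can continue.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("Levene's test needs at least 2 groups")
    if any(a.size < 5 for a in arrays):
        raise ValueError("Levene's test here requires >= 5 observations per group")
    deviations = [np.abs(a - a.mean()) for a in arrays]
    if all(np.all(d == 0.0) for d in deviations):
        return TestResult(statistic=math.nan, p_value=math.nan, undefined=True)
    res = stats.levene(*arrays, center="mean")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue))
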