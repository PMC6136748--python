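import math

import numpy as np
import pytest
from scipy import stats

from digitstat.cohort_data import (
    Ancestry,
    AthleteStatus,
    Digit,
    DigitMeasurement,
    Hand,
    SubjectRecord,
)
from digitstat.morphometry import compute_ratios, icc, ks_normality, levene
from digitstat.morphometry import test_retest as retest  # avoid pytest collection


def _subject(sid, cells):
    """cells: {(hand, digit): (first, second)}"""
    measurements = {
        (h, d): DigitMeasurement(hand=h, digit=d, length_first=a, length_second=b)
        for (h, d), (a, b) in cells.items()
    }
    return SubjectRecord(
        subject_id=sid,
        ancestry=Ancestry.EUROPEAN,
        status=AthleteStatus.NON_ATHLETE,
        measurements=measurements,
    )


def _full_subject(sid, lengths, jitter=0.0):
    """lengths: (d2, d4, d5) applied to both hands; repeats differ by jitter."""
    d2, d4, d5 = lengths
    cells = {}
    for hand in Hand:
        for digit, ln in ((Digit.D2, d2), (Digit.D4, d4), (Digit.D5, d5)):
            cells[(hand, digit)] = (ln - jitter, ln + jitter)
    return _subject(sid, cells)


class TestRatios:
    def test_ratio_uses_repeat_means(self):
        s = _subject(
            "a",
            {
                (Hand.RIGHT, Digit.D2): (73.9, 74.1),
                (Hand.RIGHT, Digit.D4): (77.7, 77.7),
            },
        )
        _, right = compute_ratios(s)
        assert right.ratio_2d4d == pytest.approx(74.0 / 77.7, rel=1e-12)
        assert right.ratio_2d5d is None  # D5 missing

    def test_identical_means_give_unit_ratio(self):
        s = _subject(
            "a",
            {
                (Hand.LEFT, Digit.D2): (70.0, 70.4),
                (Hand.LEFT, Digit.D4): (70.2, 70.2),
            },
        )
        left, _ = compute_ratios(s)
        assert left.ratio_2d4d == pytest.approx(1.0)

    def test_thrower_scale_lengths_give_expected_ratios(self):
        # D2 ~ 73.9, D4 ~ 77.7, D5 ~ 63.1 mm: 2D:4D ~ 0.951, 2D:5D ~ 1.17
        s = _full_subject("a", (73.9, 77.7, 63.1))
        left, right = compute_ratios(s)
        assert right.ratio_2d4d == pytest.approx(0.951, abs=5e-4)
        assert right.ratio_2d5d == pytest.approx(1.171, abs=5e-4)
        assert left.mean_finger_length == pytest.approx((73.9 + 77.7 + 63.1) / 3)

    def test_ratios_are_scale_invariant(self):
        base = _full_subject("a", (72.0, 75.5, 61.0), jitter=0.3)
        scaled = _full_subject("b", (72.0 * 1.17, 75.5 * 1.17, 61.0 * 1.17), jitter=0.3 * 1.17)
        r1 = compute_ratios(base)[1]
        r2 = compute_ratios(scaled)[1]
        assert r1.ratio_2d4d == pytest.approx(r2.ratio_2d4d, rel=1e-12)
        assert r1.ratio_2d5d == pytest.approx(r2.ratio_2d5d, rel=1e-12)

    def test_missing_cells_propagate_and_count(self, default_cohort):
        """n per ratio equals the count of subjects with both digits complete."""
        import copy

        cohort = copy.deepcopy(list(default_cohort))
        # knock out right D4 for three subjects and right D2 for one more
        for rec in cohort[:3]:
            del rec.measurements[(Hand.RIGHT, Digit.D4)]
        del cohort[3].measurements[(Hand.RIGHT, Digit.D2)]
        ratios = [compute_ratios(r)[1] for r in cohort]
        n_24 = sum(r.ratio_2d4d is not None for r in ratios)
        n_25 = sum(r.ratio_2d5d is not None for r in ratios)
        assert n_24 == len(cohort) - 4
        assert n_25 == len(cohort) - 1


class TestReliability:
    def test_identical_repeats_are_perfectly_reliable(self):
        cohort = [_full_subject(f"s{i}", (70 + i, 73 + i, 60 + i)) for i in range(6)]
        r = retest(cohort).cell(Hand.LEFT, Digit.D2).test_retest_r
        i = icc(cohort).cell(Hand.LEFT, Digit.D2).icc
        assert r == pytest.approx(1.0)
        assert i == pytest.approx(1.0)

    def test_no_subject_effect_gives_icc_near_zero(self):
        # repeats are independent noise around one common mean
        rng = np.random.default_rng(42)
        cohort = []
        for i in range(4000):
            a, b = 70.0 + rng.normal(0, 1, 2)
            cohort.append(
                _subject(f"s{i}", {(Hand.LEFT, Digit.D2): (a, b)})
            )
        val = icc(cohort).cell(Hand.LEFT, Digit.D2).icc
        assert abs(val) < 0.05

    def test_calibrated_noise_gives_high_icc(self):
        # between-subject SD 4.6 mm, repeat noise SD 0.5 mm:
        # sigma_b^2/(sigma_b^2+sigma_e^2) = 21.16/21.41 ~ 0.988
        rng = np.random.default_rng(3)
        cohort = []
        for i in range(3000):
            true = 73.9 + rng.normal(0, 4.6)
            a, b = true + rng.normal(0, 0.5, 2)
            cohort.append(_subject(f"s{i}", {(Hand.LEFT, Digit.D2): (a, b)}))
        val = icc(cohort).cell(Hand.LEFT, Digit.D2).icc
        assert val > 0.97
        assert val == pytest.approx(21.16 / 21.41, abs=0.01)

    def test_reliability_invariant_to_constant_shift(self):
        rng = np.random.default_rng(5)
        base = []
        for i in range(50):
            true = 70 + rng.normal(0, 4)
            a, b = true + rng.normal(0, 0.5, 2)
            base.append((a, b))
        cohort = [_subject(f"s{i}", {(Hand.LEFT, Digit.D4): ab}) for i, ab in enumerate(base)]
        shifted = [
            _subject(f"s{i}", {(Hand.LEFT, Digit.D4): (a + 100, b + 100)})
            for i, (a, b) in enumerate(base)
        ]
        c1 = retest(cohort).cell(Hand.LEFT, Digit.D4)
        c2 = retest(shifted).cell(Hand.LEFT, Digit.D4)
        assert c1.test_retest_r == pytest.approx(c2.test_retest_r, rel=1e-9)
        i1 = icc(cohort).cell(Hand.LEFT, Digit.D4).icc
        i2 = icc(shifted).cell(Hand.LEFT, Digit.D4).icc
        assert i1 == pytest.approx(i2, rel=1e-9)

    def test_too_few_pairs_flagged_undefined(self):
        cohort = [_full_subject("a", (70, 73, 60)), _full_subject("b", (71, 74, 61))]
        cell = retest(cohort).cell(Hand.LEFT, Digit.D2)
        assert not cell.defined and cell.n_pairs == 2

    def test_icc_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(11)
        first = 70 + rng.normal(0, 4, 40)
        second = first + rng.normal(0, 0.8, 40)
        cohort = [
            _subject(f"s{i}", {(Hand.RIGHT, Digit.D5): (a, b)})
            for i, (a, b) in enumerate(zip(first, second))
        ]
        ours = icc(cohort).cell(Hand.RIGHT, Digit.D5).icc
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(40), 2),
                "rater": np.tile(["m1", "m2"], 40),
                "value": np.column_stack([first, second]).ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="value")
        icc3 = float(ref.loc[ref["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert ours == pytest.approx(icc3, abs=1e-10)


class TestNormalityAndVariance:
    def test_ks_statistic_matches_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 2, 10)
        res = ks_normality(x)
        xs = np.sort(x)
        cdf = stats.norm.cdf(xs, x.mean(), x.std(ddof=1))
        n = len(xs)
        d_plus = np.max(np.arange(1, n + 1) / n - cdf)
        d_minus = np.max(cdf - np.arange(0, n) / n)
        assert res.statistic == pytest.approx(max(d_plus, d_minus), abs=1e-12)

    def test_ks_on_large_normal_sample_is_calm(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.97, 0.035, 10_000)
        res = ks_normality(x)
        assert res.statistic < 0.02
        assert res.p_value > 0.01

    def test_levene_zero_for_shifted_identical_groups(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = levene([g, [v + 10 for v in g]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_levene_constant_groups_flagged(self):
        res = levene([[1.0] * 6, [2.0] * 6])
        assert res.undefined and math.isnan(res.statistic)

    def test_levene_matches_scipy_mean_centered(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 2, 25)
        res = levene([a, b])
        ref = stats.levene(a, b, center="mean")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
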