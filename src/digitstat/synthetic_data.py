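"""Synthetic cohort generator for the digit-ratio pipeline.

Emulates a cohort of college-age women in three athlete-status groups
(non-athlete / varsity / club) with:

* six digit lengths per subject (2 hands x digits 2, 4, 5) drawn from a
  multivariate normal whose correlation is the Kronecker product of an
  inter-hand block (default r = 0.6) and a within-hand equicorrelation
  block across digits (default r = 0.85, which places the implied
  2D:4D SD near 0.035);
* duplicate measurements of every digit with independent Gaussian
  instrument noise (default SD 0.5 mm), calibrated so test-retest r and
  ICC exceed 0.97;
* one college sport per athlete drawn from a fixed roster, plus a
  configurable number of non-athletes who played an overhand-throwing
  sport (softball) in high school only;
* an overhand-throwing effect injected on the *lengths* of digits 4 and
  5 (not directly on ratios), sized by a delta-method calibration so the
  expected standardized ratio difference equals a configurable Cohen's d
  (default 0.75).  Injecting on lengths rather than ratios keeps the
  ANCOVA scaling check meaningful: throwers end up with slightly longer
  fourth and fifth digits, as a real allometric confound would produce.

All randomness flows from a single integer seed; the same seed yields an
identical cohort.
"""

from __future__ import annotations

import dataclasses
import math
from types import MappingProxyType
from typing import Mapping

import numpy as np

from digitstat.cohort_data import (
    Ancestry,
    AthleteStatus,
    Digit,
    DigitMeasurement,
    Hand,
    Role,
    SubjectRecord,
    code_sport,
)

#: Default college-sport roster (players per sport among the 181 college
#: athletes; softball 10 + water polo 1 college throwers, joined by 6
#: high-school-only softball players for 17 throwers in total).
DEFAULT_SPORT_COUNTS: Mapping[str, int] = MappingProxyType(
    {
        "basketball": 14,
        "cheerleading": 11,
        "dance": 8,
        "golf": 5,
        "ice hockey": 12,
        "lacrosse": 15,
        "rowing": 11,
        "rugby": 16,
        "soccer": 22,
        "softball": 10,
        "swimming": 8,
        "synchronized skating": 4,
        "tennis": 8,
        "track & field": 24,
        "volleyball": 12,
        "water polo": 1,
    }
)

_DIGITS = (Digit.D2, Digit.D4, Digit.D5)


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the emulated cohort."""

    n_non_athlete: int = 77
    n_varsity: int = 103
    n_club: int = 78
    sport_counts: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SPORT_COUNTS)
    )
    n_high_school_overhand: int = 6
    digit_mean_mm: Mapping[Digit, float] = dataclasses.field(
        default_factory=lambda: {Digit.D2: 73.9, Digit.D4: 75.6, Digit.D5: 61.2}
    )
    digit_sd_mm: Mapping[Digit, float] = dataclasses.field(
        default_factory=lambda: {Digit.D2: 4.6, Digit.D4: 4.7, Digit.D5: 4.3}
    )
    within_hand_digit_corr: float = 0.85
    inter_hand_corr: float = 0.6
    repeat_noise_sd_mm: float = 0.5
    overhand_effect_d: float = 0.75
    prob_non_european: float = 12 / 258
    prob_starter: float = 0.79
    seed: int = 0

    @property
    def n_athletes(self) -> int:
        return self.n_varsity + self.n_club

    @property
    def n_total(self) -> int:
        return self.n_non_athlete + self.n_athletes

    def validate(self) -> None:
        if min(self.n_non_athlete, self.n_varsity, self.n_club) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_total == 0:
            raise ValueError("empty cohort")
        for name in self.sport_counts:
            code_sport(name)  # raises on unknown sports
        if any(c < 0 for c in self.sport_counts.values()):
            raise ValueError("sport counts must be non-negative")
        if sum(self.sport_counts.values()) != self.n_athletes:
            raise ValueError(
                f"sport counts sum to {sum(self.sport_counts.values())} but "
                f"there are {self.n_athletes} college athletes"
            )
        if self.n_high_school_overhand > self.n_non_athlete:
            raise ValueError(
                "more high-school overhand players than non-athletes"
            )
        if any(sd <= 0 for sd in self.digit_sd_mm.values()):
            raise ValueError("digit SDs must be positive")
        if self.repeat_noise_sd_mm < 0:
            raise ValueError("repeat noise SD must be >= 0")
        if not -1.0 < self.within_hand_digit_corr < 1.0:
            raise ValueError("within-hand digit correlation must be in (-1, 1)")
        if not -1.0 < self.inter_hand_corr < 1.0:
            raise ValueError("inter-hand correlation must be in (-1, 1)")
        for p in (self.prob_non_european, self.prob_starter):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def expected_ratio_sd(cfg: SyntheticConfig, denominator: Digit) -> float:
    """Delta-method SD of the 2D:denominator ratio implied by the config."""
    m2 = cfg.digit_mean_mm[Digit.D2]
    md = cfg.digit_mean_mm[denominator]
    cv2 = cfg.digit_sd_mm[Digit.D2] / m2
    cvd = cfg.digit_sd_mm[denominator] / md
    rho = cfg.within_hand_digit_corr
    rel_var = cv2**2 + cvd**2 - 2.0 * rho * cv2 * cvd
    return (m2 / md) * math.sqrt(max(rel_var, 0.0))


def overhand_shift_mm(cfg: SyntheticConfig, denominator: Digit) -> float:
    """Additive length shift on a denominator digit for overhand throwers.

    Chosen so the expected ratio difference (non-throwers minus throwers)
    equals cfg.overhand_effect_d standard deviations of the ratio, via
    the delta-method ratio SD: lengthening the denominator digit lowers
    the thrower ratio by the target gap.
    """
    m2 = cfg.digit_mean_mm[Digit.D2]
    md = cfg.digit_mean_mm[denominator]
    r0 = m2 / md
    gap = cfg.overhand_effect_d * expected_ratio_sd(cfg, denominator)
    if gap >= r0:
        raise ValueError("overhand effect too large for the configured means")
    if gap == 0.0:
        return 0.0
    return m2 / (r0 - gap) - md


def _length_covariance(cfg: SyntheticConfig) -> np.ndarray:
    """6x6 covariance of (left, right) x (D2, D4, D5) true lengths."""
    sds = np.array([cfg.digit_sd_mm[d] for d in _DIGITS])
    k = len(_DIGITS)
    digit_corr = np.full((k, k), cfg.within_hand_digit_corr)
    np.fill_diagonal(digit_corr, 1.0)
    hand_corr = np.array([[1.0, cfg.inter_hand_corr], [cfg.inter_hand_corr, 1.0]])
    corr = np.kron(hand_corr, digit_corr)
    scale = np.tile(sds, 2)
    return corr * np.outer(scale, scale)


def generate_cohort(cfg: SyntheticConfig) -> list[SubjectRecord]:
    """Generate a reproducible synthetic cohort of SubjectRecords."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    statuses = (
        [AthleteStatus.NON_ATHLETE] * cfg.n_non_athlete
        + [AthleteStatus.VARSITY] * cfg.n_varsity
        + [AthleteStatus.CLUB] * cfg.n_club
    )
    # one college sport per athlete, shuffled over the athlete block
    college_sports: list[tuple[str, ...]] = []
    for name, count in sorted(cfg.sport_counts.items()):
        college_sports.extend([(name,)] * count)
    rng.shuffle(college_sports)  # type: ignore[arg-type]
    sports_by_subject: list[tuple[str, ...]] = [()] * cfg.n_non_athlete + college_sports
    # high-school-only softball players among the non-athletes
    hs_idx = rng.choice(cfg.n_non_athlete, size=cfg.n_high_school_overhand, replace=False)
    for i in hs_idx:
        sports_by_subject[int(i)] = ("softball",)

    mean = np.tile([cfg.digit_mean_mm[d] for d in _DIGITS], 2)
    cov = _length_covariance(cfg)
    true_lengths = rng.multivariate_normal(mean, cov, size=cfg.n_total, method="cholesky")

    shift4 = overhand_shift_mm(cfg, Digit.D4)
    shift5 = overhand_shift_mm(cfg, Digit.D5)

    records: list[SubjectRecord] = []
    for i in range(cfg.n_total):
        sports = sports_by_subject[i]
        is_overhand = bool(sports) and any(code_sport(s).overhand for s in sports)
        lengths = true_lengths[i].copy()
        if is_overhand:
            lengths[[1, 4]] += shift4  # D4 on both hands
            lengths[[2, 5]] += shift5  # D5 on both hands
        noise = rng.normal(0.0, cfg.repeat_noise_sd_mm, size=(6, 2))
        measurements = {}
        for j, (hand, digit) in enumerate(
            (h, d) for h in (Hand.LEFT, Hand.RIGHT) for d in _DIGITS
        ):
            measurements[(hand, digit)] = DigitMeasurement(
                hand=hand,
                digit=digit,
                length_first=float(lengths[j] + noise[j, 0]),
                length_second=float(lengths[j] + noise[j, 1]),
            )
        ancestry = (
            Ancestry.NON_EUROPEAN
            if rng.random() < cfg.prob_non_european
            else Ancestry.EUROPEAN
        )
        if sports:
            role = Role.STARTER if rng.random() < cfg.prob_starter else Role.RESERVE
        else:
            role = Role.NOT_APPLICABLE
        records.append(
            SubjectRecord(
                subject_id=f"S{i + 1:04d}",
                ancestry=ancestry,
                status=statuses[i],
                sports=sports,
                role=role,
                measurements=measurements,
            )
        )
    return records
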