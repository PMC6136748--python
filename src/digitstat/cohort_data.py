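"""Subject-level data model, canonical sport coding, and tabular I/O.

Each participant carries up to twelve digit-length measurements (two hands
x three digits x two non-consecutive repeats), an ancestry flag, an
athlete-status level, the list of organized sports she played, and a
starter/reserve role.  Sports are mapped onto five binary attributes
(team, contact, ball, overhand throwing, subjectively judged) by a fixed
canonical table; subjects who played several sports are pooled
attribute-wise (a subject counts in a category if any of her sports has
the attribute).
"""

from __future__ import annotations

import csv
import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Sequence


class Hand(enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Digit(enum.Enum):
    D2 = "d2"
    D4 = "d4"
    D5 = "d5"


class Ancestry(enum.Enum):
    EUROPEAN = "european"
    NON_EUROPEAN = "non_european"


class AthleteStatus(enum.Enum):
    NON_ATHLETE = "non_athlete"
    VARSITY = "varsity"
    CLUB = "club"


class Role(enum.Enum):
    STARTER = "starter"
    RESERVE = "reserve"
    NOT_APPLICABLE = "not_applicable"


#: Soft plausibility window for adult female digit lengths, in mm.
PLAUSIBLE_MM = (30.0, 120.0)


@dataclasses.dataclass(frozen=True)
class DigitMeasurement:
    """One duplicated length measurement of a single digit on one hand."""

    hand: Hand
    digit: Digit
    length_first: float
    length_second: float

    def __post_init__(self) -> None:
        if self.length_first <= 0 or self.length_second <= 0:
            raise ValueError(
                f"digit lengths must be positive, got "
                f"({self.length_first}, {self.length_second}) for "
                f"{self.hand.value} {self.digit.value}"
            )

    @property
    def mean_length(self) -> float:
        return (self.length_first + self.length_second) / 2.0

    @property
    def in_plausible_range(self) -> bool:
        lo, hi = PLAUSIBLE_MM
        return lo <= self.length_first <= hi and lo <= self.length_second <= hi


@dataclasses.dataclass(frozen=True)
class SportAttributes:
    """Binary coding of a sport (or of a multi-sport subject, by OR)."""

    team: bool
    contact: bool
    ball: bool
    overhand: bool
    judged: bool

    def __or__(self, other: "SportAttributes") -> "SportAttributes":
        return SportAttributes(
            team=self.team or other.team,
            contact=self.contact or other.contact,
            ball=self.ball or other.ball,
            overhand=self.overhand or other.overhand,
            judged=self.judged or other.judged,
        )


#: The 16 canonical sports and their attribute coding.  Individual sports
#: are golf, swimming, tennis, track & field; contact sports are
#: basketball, ice hockey, rugby, soccer, water polo; overhand-throwing
#: sports are softball and water polo; subjectively judged sports are
#: cheerleading, dance, and synchronized skating.
_SPORT_TABLE: dict[str, SportAttributes] = {
    "basketball": SportAttributes(True, True, True, False, False),
    "cheerleading": SportAttributes(True, False, False, False, True),
    "dance": SportAttributes(True, False, False, False, True),
    "golf": SportAttributes(False, False, True, False, False),
    "ice hockey": SportAttributes(True, True, True, False, False),
    "lacrosse": SportAttributes(True, False, True, False, False),
    "rowing": SportAttributes(True, False, False, False, False),
    "rugby": SportAttributes(True, True, True, False, False),
    "soccer": SportAttributes(True, True, True, False, False),
    "softball": SportAttributes(True, False, True, True, False),
    "swimming": SportAttributes(False, False, False, False, False),
    "synchronized skating": SportAttributes(True, False, False, False, True),
    "tennis": SportAttributes(False, False, True, False, False),
    "track & field": SportAttributes(False, False, False, False, False),
    "volleyball": SportAttributes(True, False, True, False, False),
    "water polo": SportAttributes(True, True, True, True, False),
}

#: Spelling variants accepted on input; cross-country runners all also
#: competed in track & field and are merged into that category.
_ALIASES: dict[str, str] = {
    "cross country": "track & field",
    "cross-country": "track & field",
    "track and field": "track & field",
    "track & field/cross country": "track & field",
    "swimming & diving": "swimming",
    "swimming and diving": "swimming",
}

CANONICAL_SPORTS: tuple[str, ...] = tuple(sorted(_SPORT_TABLE))


def canonical_sport_name(name: str) -> str:
    """Normalize a sport name (case-insensitive, trimmed; known aliases)."""
    key = " ".join(name.strip().lower().split())
    key = _ALIASES.get(key, key)
    if key not in _SPORT_TABLE:
        raise ValueError(f"unknown sport: {name!r}")
    return key


def code_sport(name: str) -> SportAttributes:
    """Return the canonical attribute coding of a single sport.

    Raises ``ValueError`` naming the offending sport if it is not one of
    the 16 canonical sports (no silent default).
    """
    return _SPORT_TABLE[canonical_sport_name(name)]


@dataclasses.dataclass
class SubjectRecord:
    """One participant of the cohort."""

    subject_id: str
    ancestry: Ancestry
    status: AthleteStatus
    sports: tuple[str, ...] = ()
    role: Role = Role.NOT_APPLICABLE
    measurements: dict[tuple[Hand, Digit], DigitMeasurement] = dataclasses.field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        self.sports = tuple(canonical_sport_name(s) for s in self.sports)
        if self.role is not Role.NOT_APPLICABLE and not self.sports:
            raise ValueError(
                f"subject {self.subject_id}: role {self.role.value} requires "
                "a non-empty sports list"
            )
        for (hand, digit), m in self.measurements.items():
            if (m.hand, m.digit) != (hand, digit):
                raise ValueError(
                    f"subject {self.subject_id}: measurement keyed "
                    f"({hand.value}, {digit.value}) holds data for "
                    f"({m.hand.value}, {m.digit.value})"
                )

    def measurement(self, hand: Hand, digit: Digit) -> DigitMeasurement | None:
        """The (hand, digit) duplicate pair, or None if the cell is missing."""
        return self.measurements.get((hand, digit))


def classify_subject(subject: SubjectRecord) -> SportAttributes:
    """Pool a subject's sports into one attribute tuple by attribute-wise OR.

    A subject counts in a category (team, contact, ball, overhand, judged)
    if any sport she played has that attribute.  Raises on subjects with an
    empty sports list, for whom the attributes are undefined.
    """
    if not subject.sports:
        raise ValueError(
            f"subject {subject.subject_id} played no organized sport; "
            "sport attributes are undefined"
        )
    attrs = code_sport(subject.sports[0])
    for name in subject.sports[1:]:
        attrs = attrs | code_sport(name)
    return attrs


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_MEASUREMENT_COLUMNS: list[tuple[Hand, Digit, int]] = [
    (hand, digit, rep)
    for hand in (Hand.LEFT, Hand.RIGHT)
    for digit in (Digit.D2, Digit.D4, Digit.D5)
    for rep in (1, 2)
]

CSV_COLUMNS: list[str] = ["subject_id", "ancestry", "status", "sports", "role"] + [
    f"{hand.value}_{digit.value}_m{rep}" for hand, digit, rep in _MEASUREMENT_COLUMNS
]


def write_cohort(records: Iterable[SubjectRecord], path: str | Path) -> None:
    """Write subjects to CSV (one row each; missing cells as empty fields)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            row: list[str] = [
                rec.subject_id,
                rec.ancestry.value,
                rec.status.value,
                ";".join(rec.sports),
                rec.role.value,
            ]
            for hand, digit, rep in _MEASUREMENT_COLUMNS:
                m = rec.measurement(hand, digit)
                if m is None:
                    row.append("")
                else:
                    row.append(repr(m.length_first if rep == 1 else m.length_second))
            writer.writerow(row)


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort CSV written in the :data:`CSV_COLUMNS` schema.

    Raises ``ValueError`` with the offending 1-based row number on a
    malformed row, a half-present duplicate pair, or a duplicate
    subject_id.
    """
    path = Path(path)
    records: list[SubjectRecord] = []
    seen_ids: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != CSV_COLUMNS:
            raise ValueError(
                f"{path}: unexpected header; expected columns {CSV_COLUMNS}"
            )
        for row_no, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue
            try:
                records.append(_parse_row(row))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: row {row_no}: {exc}") from exc
            if records[-1].subject_id in seen_ids:
                raise ValueError(
                    f"{path}: row {row_no}: duplicate subject_id "
                    f"{records[-1].subject_id!r}"
                )
            seen_ids.add(records[-1].subject_id)
    return records


def _parse_row(row: Sequence[str]) -> SubjectRecord:
    if len(row) != len(CSV_COLUMNS):
        raise ValueError(f"expected {len(CSV_COLUMNS)} fields, got {len(row)}")
    subject_id, ancestry, status, sports_field, role = (c.strip() for c in row[:5])
    if not subject_id:
        raise ValueError("empty subject_id")
    sports = tuple(s for s in (p.strip() for p in sports_field.split(";")) if s)
    measurements: dict[tuple[Hand, Digit], DigitMeasurement] = {}
    cells = row[5:]
    for i in range(0, len(cells), 2):
        hand, digit, _ = _MEASUREMENT_COLUMNS[i]
        first, second = cells[i].strip(), cells[i + 1].strip()
        if not first and not second:
            continue  # cell marked missing
        if not first or not second:
            raise ValueError(
                f"half-present duplicate pair for {hand.value} {digit.value}: "
                "both repeats must be present or both empty"
            )
        measurements[(hand, digit)] = DigitMeasurement(
            hand=hand,
            digit=digit,
            length_first=float(first),
            length_second=float(second),
        )
    return SubjectRecord(
        subject_id=subject_id,
        ancestry=Ancestry(ancestry),
        status=AthleteStatus(status),
        sports=sports,
        role=Role(role),
        measurements=measurements,
    )
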