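"""Core domain types: documents, spans, time-expression types and the
normalized-value grammar.

The normalized-value scheme is a tagged union over calendar values, day
parts, periods, bounded intervals, ranges, age values and categorical
life-stage references.  Every variant serializes to a canonical string
(:func:`serialize_value`) and the canonical strings parse back losslessly
(:func:`parse_value`), with one deliberate ambiguity: ``P45Y`` is either a
45-year duration or a current-age value and is disambiguated only by the
carrying expression's :class:`TimexType`, never by string inspection.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

__all__ = [
    "TimexType",
    "DayPartKind",
    "PeriodUnit",
    "BoundKind",
    "AgeMode",
    "CategoricalKind",
    "CalendarValue",
    "DayPart",
    "Period",
    "BoundedInterval",
    "Range",
    "AgeValue",
    "CategoricalRef",
    "Unresolved",
    "RawValue",
    "NormalizedValue",
    "ValueParseError",
    "serialize_value",
    "parse_value",
    "Span",
    "Document",
    "TimeExpression",
    "AnnotationSet",
    "UNRESOLVED",
]


class TimexType(str, Enum):
    """The five expression types."""

    DATE = "DATE"
    TIME = "TIME"
    DURATION = "DURATION"
    FREQUENCY = "FREQUENCY"
    AGE_RELATED = "AGE_RELATED"


class DayPartKind(str, Enum):
    TMO = "TMO"  # morning
    TAF = "TAF"  # afternoon
    TEV = "TEV"  # evening
    TNI = "TNI"  # night


class PeriodUnit(str, Enum):
    """Granularity units for periods. MIN renders as ``M`` after the ``T``
    marker; the marker position is what separates it from months."""

    Y = "Y"
    M = "M"
    W = "W"
    D = "D"
    H = "H"
    MIN = "MIN"
    S = "S"

    @property
    def sub_day(self) -> bool:
        return self in (PeriodUnit.H, PeriodUnit.MIN, PeriodUnit.S)

    @property
    def letter(self) -> str:
        return "M" if self is PeriodUnit.MIN else self.value


class BoundKind(str, Enum):
    SIN = "SIN"  # open-ended interval since an anchor
    UNT = "UNT"  # open-ended interval until an anchor


class AgeMode(str, Enum):
    CURRENT = "CURRENT"  # the patient's age now -> P prefix
    PAST = "PAST"  # age at a previous point in time -> A prefix


class CategoricalKind(str, Enum):
    PAST_REF = "PAST_REF"
    PRESENT_REF = "PRESENT_REF"
    CHILD_REF = "CHILD_REF"
    SCHOOL_REF = "SCHOOL_REF"
    TEENS_REF = "TEENS_REF"
    ADULT_REF = "ADULT_REF"
    UNI_REF = "UNI_REF"
    OTHER_REF = "OTHER_REF"


LIFE_STAGE_REFS = frozenset(
    {
        CategoricalKind.CHILD_REF,
        CategoricalKind.SCHOOL_REF,
        CategoricalKind.TEENS_REF,
        CategoricalKind.ADULT_REF,
        CategoricalKind.UNI_REF,
        CategoricalKind.OTHER_REF,
    }
)


@dataclass(frozen=True)
class CalendarValue:
    """A (partially specified) calendar value.

    Granularity is whatever fields are present: ``2007``, ``2009-10``,
    ``2012-10-05``, ``2011-03-14T18:00``.  When ``date_known`` is False the
    date part renders as placeholders (``XXXX-XX-XXT18:00``) and
    year/month/day must be absent.
    """

    year: Optional[int] = None
    month: Optional[int] = None
    day: Optional[int] = None
    hour: Optional[int] = None
    minute: Optional[int] = None
    date_known: bool = True

    def __post_init__(self) -> None:
        if self.date_known:
            if self.year is None:
                raise ValueError("date_known CalendarValue requires a year")
            if self.day is not None and self.month is None:
                raise ValueError("day without month")
        else:
            if self.year is not None or self.month is not None or self.day is not None:
                raise ValueError("placeholder CalendarValue must not carry date fields")
        if (self.hour is None) != (self.minute is None):
            raise ValueError("hour and minute must be set together")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None and not 1 <= self.day <= 31:
            raise ValueError(f"day out of range: {self.day}")
        if self.hour is not None and not 0 <= self.hour <= 23:
            raise ValueError(f"hour out of range: {self.hour}")
        if self.minute is not None and not 0 <= self.minute <= 59:
            raise ValueError(f"minute out of range: {self.minute}")

    @classmethod
    def from_date(cls, d: _dt.date) -> "CalendarValue":
        return cls(year=d.year, month=d.month, day=d.day)

    def to_date(self) -> Optional[_dt.date]:
        """Full date when day-granular, else None."""
        if self.date_known and self.day is not None:
            return _dt.date(self.year, self.month, self.day)
        return None

    def sort_key(self) -> tuple:
        """Chronological key; partial fields compare as their earliest point."""
        return (
            self.year if self.year is not None else 0,
            self.month or 1,
            self.day or 1,
            self.hour or 0,
            self.minute or 0,
        )


@dataclass(frozen=True)
class DayPart:
    part: DayPartKind


@dataclass(frozen=True)
class Period:
    """``P (T)? count unit`` — durations and frequency intervals.

    ``count`` may be the vague placeholder ``"X"``.  ``clock`` controls the
    ``T`` marker; it is mandatory for ``MIN``/``S`` (``PT15M`` vs months
    ``P3M``), forbidden for calendar units, and optional for hours (the
    value scheme prints ``PXH`` without it).
    """

    count: Union[int, str]
    unit: PeriodUnit
    clock: Optional[bool] = None

    def __post_init__(self) -> None:
        if isinstance(self.count, str):
            if self.count != "X":
                raise ValueError("string count must be the placeholder 'X'")
        elif self.count <= 0:
            raise ValueError("period count must be positive")
        if self.clock is None:
            object.__setattr__(
                self, "clock", self.unit in (PeriodUnit.MIN, PeriodUnit.S)
            )
        if self.unit in (PeriodUnit.MIN, PeriodUnit.S) and not self.clock:
            raise ValueError(f"{self.unit} requires the T marker")
        if self.unit in (PeriodUnit.Y, PeriodUnit.M, PeriodUnit.W, PeriodUnit.D) and self.clock:
            raise ValueError(f"T marker invalid for calendar unit {self.unit}")


@dataclass(frozen=True)
class BoundedInterval:
    """Open-ended interval: ``SIN2007``, ``UNT2018``, ``SINTEENS_REF``."""

    bound: BoundKind
    anchor: Union["CalendarValue", "AgeValue", "CategoricalRef"]


@dataclass(frozen=True)
class Range:
    """Explicit start/end range, rendered ``(start, end)``."""

    start: CalendarValue
    end: CalendarValue

    def __post_init__(self) -> None:
        if self.start.date_known and self.end.date_known:
            if self.start.sort_key() > self.end.sort_key():
                raise ValueError("range start after end")


@dataclass(frozen=True)
class AgeValue:
    """Patient age: ``P45Y`` (current) / ``A15Y`` (past).

    ``unit`` is years except for the month-granular extension used by
    phrases like "age 3 months" (rendered ``A3M``).
    """

    mode: AgeMode
    count: int
    unit: PeriodUnit = PeriodUnit.Y

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("age must be non-negative")
        if self.unit not in (PeriodUnit.Y, PeriodUnit.M):
            raise ValueError("age unit must be Y or M")


@dataclass(frozen=True)
class CategoricalRef:
    kind: CategoricalKind


@dataclass(frozen=True)
class Unresolved:
    """Sentinel for surfaces the normalizer could not resolve; never dropped."""


@dataclass(frozen=True)
class RawValue:
    """Verbatim value string from an external annotation scheme (e.g. a
    TIMEX3 ``val`` attribute outside the canonical grammar).  Not part of
    the canonical grammar; excluded from round-trip guarantees."""

    text: str


UNRESOLVED = Unresolved()

NormalizedValue = Union[
    CalendarValue,
    DayPart,
    Period,
    BoundedInterval,
    Range,
    AgeValue,
    CategoricalRef,
    Unresolved,
    RawValue,
]


class ValueParseError(ValueError):
    """Raised by :func:`parse_value` on a malformed canonical string."""


def serialize_value(v: NormalizedValue) -> str:
    """Render a normalized value as its canonical string. Total function."""
    if isinstance(v, CalendarValue):
        if v.date_known:
            s = f"{v.year:04d}"
            if v.month is not None:
                s += f"-{v.month:02d}"
            if v.day is not None:
                s += f"-{v.day:02d}"
        else:
            s = "XXXX-XX-XX"
        if v.hour is not None:
            s += f"T{v.hour:02d}:{v.minute:02d}"
        return s
    if isinstance(v, DayPart):
        return v.part.value
    if isinstance(v, Period):
        t = "T" if v.clock else ""
        return f"P{t}{v.count}{v.unit.letter}"
    if isinstance(v, BoundedInterval):
        return v.bound.value + serialize_value(v.anchor)
    if isinstance(v, Range):
        return f"({serialize_value(v.start)}, {serialize_value(v.end)})"
    if isinstance(v, AgeValue):
        prefix = "P" if v.mode is AgeMode.CURRENT else "A"
        return f"{prefix}{v.count}{v.unit.letter}"
    if isinstance(v, CategoricalRef):
        return v.kind.value
    if isinstance(v, Unresolved):
        return "UNRESOLVED"
    if isinstance(v, RawValue):
        return v.text
    raise TypeError(f"not a NormalizedValue: {v!r}")


_CAL_RE = re.compile(
    r"^(?:(?P<year>\d{4})(?:-(?P<month>\d{2})(?:-(?P<day>\d{2}))?)?"
    r"|(?P<ph>XXXX-XX-XX))"
    r"(?:T(?P<hour>\d{2}):(?P<minute>\d{2}))?$"
)
_PERIOD_RE = re.compile(r"^P(?P<t>T?)(?P<count>\d+|X)(?P<unit>[YMWDHS])$")
_AGE_RE = re.compile(r"^(?P<prefix>[PA])(?P<count>\d+)(?P<unit>[YM])$")
_RANGE_RE = re.compile(r"^\((?P<start>[^,]+), (?P<end>[^)]+)\)$")


def _parse_calendar(s: str) -> CalendarValue:
    m = _CAL_RE.match(s)
    if not m:
        raise ValueParseError(f"not a calendar value: {s!r}")
    if m.group("ph"):
        return CalendarValue(
            date_known=False,
            hour=int(m.group("hour")) if m.group("hour") else None,
            minute=int(m.group("minute")) if m.group("minute") else None,
        )
    return CalendarValue(
        year=int(m.group("year")),
        month=int(m.group("month")) if m.group("month") else None,
        day=int(m.group("day")) if m.group("day") else None,
        hour=int(m.group("hour")) if m.group("hour") else None,
        minute=int(m.group("minute")) if m.group("minute") else None,
    )


def parse_value(s: str, timex_type: Optional[TimexType] = None) -> NormalizedValue:
    """Parse a canonical value string back into its variant.

    ``timex_type`` resolves the documented ``P<n>Y``-style ambiguity: with
    ``AGE_RELATED`` such strings parse as current-age values, otherwise as
    periods.  Raises :class:`ValueParseError` on malformed input, naming
    the offending token.
    """
    s = s.strip()
    if not s:
        raise ValueParseError("empty value string")
    if s == "UNRESOLVED":
        return UNRESOLVED
    if s in CategoricalKind._value2member_map_:
        return CategoricalRef(CategoricalKind(s))
    if s in DayPartKind._value2member_map_:
        return DayPart(DayPartKind(s))
    if s[:3] in ("SIN", "UNT"):
        anchor = parse_value(s[3:], timex_type)
        if not isinstance(anchor, (CalendarValue, AgeValue, CategoricalRef)):
            raise ValueParseError(f"invalid bound anchor: {s[3:]!r}")
        return BoundedInterval(BoundKind(s[:3]), anchor)
    m = _RANGE_RE.match(s)
    if m:
        start = _parse_calendar(m.group("start"))
        end = _parse_calendar(m.group("end"))
        return Range(start, end)
    m = _AGE_RE.match(s)
    if m and (m.group("prefix") == "A" or timex_type is TimexType.AGE_RELATED):
        mode = AgeMode.CURRENT if m.group("prefix") == "P" else AgeMode.PAST
        return AgeValue(mode, int(m.group("count")), PeriodUnit(m.group("unit")))
    m = _PERIOD_RE.match(s)
    if m:
        count: Union[int, str] = m.group("count")
        if count != "X":
            count = int(count)
        letter = m.group("unit")
        clock = bool(m.group("t"))
        if letter == "M":
            unit = PeriodUnit.MIN if clock else PeriodUnit.M
        else:
            unit = PeriodUnit(letter)
        try:
            return Period(count, unit, clock)
        except ValueError as exc:
            raise ValueParseError(f"bad period {s!r}: {exc}") from None
    try:
        return _parse_calendar(s)
    except ValueParseError:
        raise ValueParseError(f"unrecognized value string: {s!r}") from None


@dataclass(frozen=True)
class Span:
    """0-based, half-open character offsets."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Document:
    """A narrative document plus its creation date and optional metadata."""

    doc_id: str
    text: str
    dct: Optional[_dt.date] = None
    structured_dates: dict[str, _dt.date] = field(default_factory=dict)
    meta: dict[str, str] = field(default_factory=dict)


@dataclass
class TimeExpression:
    """An annotated span: surface text, type, and (after normalization) a
    value.  The surface must equal the document substring at the span; when
    a rule matched a leading temporal preposition the preposition is inside
    the span."""

    span: Span
    surface: str
    type: TimexType
    value: Optional[NormalizedValue] = None
    meta: dict[str, str] = field(default_factory=dict)

    def value_string(self) -> Optional[str]:
        return None if self.value is None else serialize_value(self.value)


@dataclass
class AnnotationSet:
    """Expressions for one document, kept sorted by start offset."""

    doc_id: str
    expressions: list[TimeExpression] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.expressions.sort(key=lambda e: (e.span.start, e.span.end))

    def __len__(self) -> int:
        return len(self.expressions)

    def __iter__(self):
        return iter(self.expressions)

    def add(self, expr: TimeExpression) -> None:
        self.expressions.append(expr)
        self.expressions.sort(key=lambda e: (e.span.start, e.span.end))

    def validate_against(self, doc: Document) -> None:
        """Check span bounds and surface copies against the document."""
        if doc.doc_id != self.doc_id:
            raise ValueError(f"doc id mismatch: {doc.doc_id} vs {self.doc_id}")
        for e in self.expressions:
            if e.span.end > len(doc.text):
                raise ValueError(f"span {e.span} outside document {doc.doc_id}")
            actual = doc.text[e.span.start : e.span.end]
            if actual != e.surface:
                raise ValueError(
                    f"surface mismatch at {e.span}: {e.surface!r} vs {actual!r}"
                )
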