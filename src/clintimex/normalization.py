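"""Value assignment for extracted time expressions.

Dates resolve to calendar values (relative ones anchored to the document
creation time), times to clock values or day parts, durations to periods,
bounded intervals (since/until) or ranges, frequencies to period-based set
values, and age-related expressions to age values or categorical
life-stage references.  Anything the rules cannot interpret gets the
UNRESOLVED sentinel — never silently dropped.

Anchoring policy: by default the structured DCT is used; a
first-in-text-date policy and an explicit override are available.  A
running anchor (re-anchoring to previously mentioned dates) exists but is
off by default.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Union

from dateutil.relativedelta import relativedelta

from .model import (
    UNRESOLVED,
    AgeMode,
    AgeValue,
    AnnotationSet,
    BoundedInterval,
    BoundKind,
    CalendarValue,
    CategoricalKind,
    CategoricalRef,
    DayPart,
    DayPartKind,
    Document,
    NormalizedValue,
    Period,
    PeriodUnit,
    Range,
    TimeExpression,
    TimexType,
)

__all__ = [
    "DctPolicy",
    "DateOrder",
    "AnchorContext",
    "AgeLexicon",
    "default_age_lexicon",
    "normalize",
    "normalize_all",
    "resolve_relative",
    "postprocess_age",
    "age_ref_to_range",
    "DEFAULT_AGE_RANGES",
    "make_context",
]


class DctPolicy(str, Enum):
    STRUCTURED = "STRUCTURED"
    FIRST_IN_TEXT_DATE = "FIRST_IN_TEXT_DATE"
    OVERRIDE = "OVERRIDE"


class DateOrder(str, Enum):
    """Component order for purely numeric dates (12/10/2011)."""

    DMY = "DMY"
    MDY = "MDY"


@dataclass
class AnchorContext:
    """Anchor state for normalizing relative expressions."""

    dct: Optional[_dt.date] = None
    dct_policy: DctPolicy = DctPolicy.STRUCTURED
    date_order: DateOrder = DateOrder.DMY
    use_running_anchor: bool = False
    last_resolved_date: Optional[CalendarValue] = None

    @property
    def anchor_date(self) -> Optional[_dt.date]:
        if self.use_running_anchor and self.last_resolved_date is not None:
            d = self.last_resolved_date.to_date()
            if d is not None:
                return d
        return self.dct


@dataclass
class AgeLexicon:
    """Keyword -> categorical life-stage mapping for vague age references."""

    keywords: dict[str, CategoricalKind] = field(default_factory=dict)

    def __post_init__(self) -> None:
        from .model import LIFE_STAGE_REFS

        for kw, ref in self.keywords.items():
            if ref not in LIFE_STAGE_REFS:
                raise ValueError(f"{kw!r} maps to non-life-stage ref {ref}")

    def lookup(self, surface: str) -> Optional[CategoricalKind]:
        low = surface.lower()
        for kw, ref in self.keywords.items():
            if re.search(rf"(?<!\w){re.escape(kw)}(?!\w)", low):
                return ref
        return None


def default_age_lexicon() -> AgeLexicon:
    return AgeLexicon(
        {
            "childhood": CategoricalKind.CHILD_REF,
            "child": CategoricalKind.CHILD_REF,
            "baby": CategoricalKind.CHILD_REF,
            "infancy": CategoricalKind.CHILD_REF,
            "growing up": CategoricalKind.CHILD_REF,
            "little": CategoricalKind.CHILD_REF,
            "adolescence": CategoricalKind.TEENS_REF,
            "teens": CategoricalKind.TEENS_REF,
            "teenager": CategoricalKind.TEENS_REF,
            "school": CategoricalKind.SCHOOL_REF,
            "university": CategoricalKind.UNI_REF,
            "college": CategoricalKind.UNI_REF,
            "twenties": CategoricalKind.ADULT_REF,
            "thirties": CategoricalKind.ADULT_REF,
            "adult": CategoricalKind.ADULT_REF,
            "adulthood": CategoricalKind.ADULT_REF,
        }
    )


# age ranges for life-stage refs; only the teens pair is authoritative,
# the rest are implementation defaults and user-overridable
DEFAULT_AGE_RANGES: dict[CategoricalKind, tuple[int, int]] = {
    CategoricalKind.CHILD_REF: (0, 12),
    CategoricalKind.SCHOOL_REF: (5, 18),
    CategoricalKind.TEENS_REF: (13, 19),
    CategoricalKind.UNI_REF: (18, 22),
    CategoricalKind.ADULT_REF: (20, 65),
}


def age_ref_to_range(
    ref: CategoricalKind,
    ranges: Optional[dict[CategoricalKind, tuple[int, int]]] = None,
) -> Optional[tuple[AgeValue, AgeValue]]:
    """Configured (start, end) past-age pair for a life-stage reference,
    e.g. TEENS_REF -> (A13Y, A19Y); OTHER_REF (and anything unmapped)
    yields None."""
    table = DEFAULT_AGE_RANGES if ranges is None else ranges
    pair = table.get(ref)
    if pair is None:
        return None
    return AgeValue(AgeMode.PAST, pair[0]), AgeValue(AgeMode.PAST, pair[1])


# ---------------------------------------------------------------- lexical maps

_MONTHS = {}
for i, name in enumerate(
    "january february march april may june july august september october "
    "november december".split(),
    start=1,
):
    _MONTHS[name] = i
    _MONTHS[name[:3]] = i
_MONTHS["sept"] = 9

_WORD_NUM = {
    "a": 1, "an": 1, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "twenty": 20, "thirty": 30,
}

_UNIT_MAP = {
    "year": PeriodUnit.Y, "yr": PeriodUnit.Y,
    "month": PeriodUnit.M, "mth": PeriodUnit.M,
    "week": PeriodUnit.W, "wk": PeriodUnit.W,
    "day": PeriodUnit.D,
    "hour": PeriodUnit.H, "hr": PeriodUnit.H,
    "minute": PeriodUnit.MIN, "min": PeriodUnit.MIN,
    "second": PeriodUnit.S, "sec": PeriodUnit.S,
}


def _num(tok: str) -> Optional[int]:
    tok = tok.lower()
    if tok.isdigit():
        return int(tok)
    return _WORD_NUM.get(tok)


def _unit(tok: str) -> Optional[PeriodUnit]:
    return _UNIT_MAP.get(tok.lower().rstrip("s").rstrip("."))


_MONTH_PAT = r"(?:jan(?:uary)?|feb(?:ruary)?|mar(?:ch)?|apr(?:il)?|may|jun(?:e)?|jul(?:y)?|aug(?:ust)?|sep(?:t(?:ember)?)?|oct(?:ober)?|nov(?:ember)?|dec(?:ember)?)"
_WEEKDAY_PAT = r"(?:mon|tues?|wednes|thurs?|fri|satur|sun)day"
_NUM_PAT = r"(?:\d{1,3}|an?|one|two|three|four|five|six|seven|eight|nine|ten|eleven|twelve|twenty|thirty)"
_UNIT_PAT = r"(?:years?|yrs?|months?|mths?|weeks?|wks?|days?|hours?|hrs?|minutes?|mins?|seconds?|secs?)"

_WEEKDAYS = {
    name: i
    for i, name in enumerate(
        "monday tuesday wednesday thursday friday saturday sunday".split()
    )
}

_RE_FULL_DMY = re.compile(
    rf"(?:{_WEEKDAY_PAT},?\s+)?(?:the\s+)?(\d{{1,2}})(?:st|nd|rd|th)?(?:\s+of)?\s+({_MONTH_PAT}),?\s+((?:19|20)\d{{2}})",
    re.I,
)
_RE_FULL_MDY = re.compile(
    rf"(?:{_WEEKDAY_PAT},?\s+)?({_MONTH_PAT})\s+(\d{{1,2}})(?:st|nd|rd|th)?,?\s+((?:19|20)\d{{2}})",
    re.I,
)
_RE_DAY_MONTH = re.compile(
    rf"(\d{{1,2}})(?:st|nd|rd|th)?\s+({_MONTH_PAT})|({_MONTH_PAT})\s+(\d{{1,2}})(?:st|nd|rd|th)?",
    re.I,
)
_RE_MONTH_YEAR = re.compile(rf"({_MONTH_PAT})\s+(?:of\s+)?((?:19|20)\d{{2}})", re.I)
_RE_NUMERIC = re.compile(r"(\d{1,2})[/.](\d{1,2})[/.](\d{4}|\d{2})")
_RE_ISO = re.compile(r"((?:19|20)\d{2})[/.-](\d{1,2})[/.-](\d{1,2})")
_RE_YEAR = re.compile(r"(?<!\d)((?:19|20)\d{2})(?!\d)")
_RE_AGO = re.compile(
    rf"({_NUM_PAT})\s+({_UNIT_PAT})\s+(ago|back|earlier|previously|prior)", re.I
)
_RE_LAST_NEXT = re.compile(
    rf"(last|next|this|the\s+previous|the\s+following|earlier\s+th(?:is|at))\s+(week|month|year|{_MONTH_PAT}|{_WEEKDAY_PAT})",
    re.I,
)
_RE_CLOCK_AMPM = re.compile(
    r"(?:at\s+)?(\d{1,2})(?:[:.](\d{2}))?\s*(am|pm|a\.m\.|p\.m\.)", re.I
)
_RE_CLOCK_24 = re.compile(r"(\d{1,2}):(\d{2})")
_RE_FOR_N_UNIT = re.compile(
    rf"for\s+(?:(?:the\s+)?(?:last|past|next)\s+)?({_NUM_PAT})\s+({_UNIT_PAT})", re.I
)
_RE_FOR_VAGUE = re.compile(
    rf"for\s+(?:(?:many|several|a\s+few|some|a\s+couple\s+of|a\s+number\s+of)\s+)?({_UNIT_PAT})",
    re.I,
)
_RE_OVER_PAST = re.compile(
    rf"(?:over|during|in)\s+the\s+(?:last|past|previous|next|coming)\s+(?:({_NUM_PAT})\s+)?({_UNIT_PAT})",
    re.I,
)
_RE_YEAR_RANGE = re.compile(
    r"((?:19|20)\d{2})\s*(?:[–—-]|to)\s*((?:19|20)\d{2})"
)
_RE_FROM_TO = re.compile(
    r"from\s+(.+?)\s+(?:to|until|till)\s+(.+)$", re.I
)
_RE_N_UNIT = re.compile(rf"({_NUM_PAT})\s+({_UNIT_PAT})", re.I)
_RE_SINCE_UNTIL = re.compile(r"^(since|until|till|up\s+until)\s+(.*)$", re.I)
_RE_TIMES_PER = re.compile(
    rf"(once|twice|thrice|({_NUM_PAT})\s+times)\s+(?:a|per|each|every)\s+(day|night|morning|evening|week|month|year|hour)",
    re.I,
)
_RE_EVERY = re.compile(
    rf"every\s+(?:({_NUM_PAT})\s+)?({_UNIT_PAT}|day|night|morning|evening|week|month|year|hour|{_WEEKDAY_PAT})",
    re.I,
)
_RE_AGE_N = re.compile(
    r"(?:at|from|since|until|till)\s+(?:the\s+age\s+of|age)\s+(\d{1,3})(\s+months?)?", re.I
)
_RE_AGE_OLD = re.compile(
    rf"({_NUM_PAT})(?:\s+|-)(?:years?|yrs?)(?:\s+|-)old", re.I
)
_RE_AGED = re.compile(r"aged\s+(\d{1,3})", re.I)
_RE_WHEN_WAS_N = re.compile(
    r"when\s+(?:he|she|they|i|the\s+patient)\s+(?:was|were)\s+(\d{1,3})", re.I
)

_PRESENT_WORDS = re.compile(
    r"^(?:now|currently|at\s+(?:the\s+)?present|at\s+the\s+moment|at\s+this\s+time|presently|these\s+days)$",
    re.I,
)
_PAST_WORDS = re.compile(
    r"^(?:in\s+the\s+past|previously|historically|in\s+the\s+old\s+days|some\s+time\s+ago|recently|lately|of\s+late)$",
    re.I,
)


# ------------------------------------------------------------- date resolution


def _parse_explicit_date(s: str, order: DateOrder) -> Optional[CalendarValue]:
    """Parse an explicit (non-relative) date surface at its own granularity."""
    m = _RE_FULL_DMY.search(s)
    if m:
        return _mk_date(int(m.group(3)), _MONTHS[m.group(2).lower()], int(m.group(1)))
    m = _RE_FULL_MDY.search(s)
    if m:
        return _mk_date(int(m.group(3)), _MONTHS[m.group(1).lower()], int(m.group(2)))
    m = _RE_ISO.search(s)
    if m:
        return _mk_date(int(m.group(1)), int(m.group(2)), int(m.group(3)))
    m = _RE_NUMERIC.search(s)
    if m:
        a, b, y = int(m.group(1)), int(m.group(2)), int(m.group(3))
        if y < 100:
            y += 2000 if y < 50 else 1900
        day, month = (a, b) if order is DateOrder.DMY else (b, a)
        # fall back to the other order when the chosen one is impossible
        if month > 12 and day <= 12:
            day, month = month, day
        return _mk_date(y, month, day)
    m = _RE_MONTH_YEAR.search(s)
    if m:
        return CalendarValue(year=int(m.group(2)), month=_MONTHS[m.group(1).lower()])
    m = _RE_YEAR.search(s)
    if m:
        return CalendarValue(year=int(m.group(1)))
    return None


def _mk_date(y: int, mo: int, d: int) -> Optional[CalendarValue]:
    try:
        _dt.date(y, mo, d)
    except ValueError:
        return None
    return CalendarValue(year=y, month=mo, day=d)


def resolve_relative(surface: str, ctx: AnchorContext) -> CalendarValue:
    """Calendar arithmetic for relative expressions against the anchor.

    Output granularity equals the coarsest unit mentioned: years -> YYYY,
    months -> YYYY-MM, weeks/days -> full date.  With no anchor available
    the placeholder calendar value is returned.
    """
    s = surface.strip().lower()
    anchor = ctx.anchor_date
    if anchor is None:
        return CalendarValue(date_known=False)

    if s == "today":
        return CalendarValue.from_date(anchor)
    if s == "yesterday":
        return CalendarValue.from_date(anchor - _dt.timedelta(days=1))
    if s == "tomorrow":
        return CalendarValue.from_date(anchor + _dt.timedelta(days=1))

    m = _RE_AGO.search(s)
    if m:
        n = _num(m.group(1))
        unit = _unit(m.group(2))
        if n is None or unit is None:
            return CalendarValue(date_known=False)
        return _shift(anchor, unit, -n)

    m = _RE_LAST_NEXT.search(s)
    if m:
        word = re.sub(r"\s+", " ", m.group(1).lower())
        target = m.group(2).lower()
        back = word in ("last", "the previous")
        sign = -1 if back else (1 if word in ("next", "the following") else 0)
        if target in ("week", "month", "year"):
            unit = _UNIT_MAP[target]
            if unit is PeriodUnit.W:
                monday = anchor - _dt.timedelta(days=anchor.weekday())
                return CalendarValue.from_date(monday + _dt.timedelta(weeks=sign))
            return _shift(anchor, unit, sign)
        if target in _WEEKDAYS:
            wd = _WEEKDAYS[target]
            delta = (anchor.weekday() - wd) % 7 or 7
            if sign >= 0:
                delta = -((wd - anchor.weekday()) % 7 or 7)
            return CalendarValue.from_date(anchor - _dt.timedelta(days=delta))
        mo = _MONTHS.get(target[:3])
        if mo:
            year = anchor.year
            if back and mo >= anchor.month:
                year -= 1
            elif not back and sign > 0 and mo <= anchor.month:
                year += 1
            return CalendarValue(year=year, month=mo)
    return CalendarValue(date_known=False)


def _shift(anchor: _dt.date, unit: PeriodUnit, n: int) -> CalendarValue:
    if unit is PeriodUnit.Y:
        return CalendarValue(year=anchor.year + n)
    if unit is PeriodUnit.M:
        d = anchor + relativedelta(months=n)
        return CalendarValue(year=d.year, month=d.month)
    if unit is PeriodUnit.W:
        return CalendarValue.from_date(anchor + _dt.timedelta(weeks=n))
    if unit is PeriodUnit.D:
        return CalendarValue.from_date(anchor + _dt.timedelta(days=n))
    # sub-day shifts keep day granularity
    return CalendarValue.from_date(anchor)


_RELATIVE_HINT = re.compile(
    rf"^(?:today|yesterday|tomorrow)$|\b(?:ago|back|earlier|prior)\b|^(?:last|next|this|the\s+previous|the\s+following|earlier\s+th(?:is|at))\b",
    re.I,
)


def _normalize_date(s: str, ctx: AnchorContext) -> NormalizedValue:
    if _PRESENT_WORDS.match(s):
        return CategoricalRef(CategoricalKind.PRESENT_REF)
    if _PAST_WORDS.match(s):
        return CategoricalRef(CategoricalKind.PAST_REF)
    if _RELATIVE_HINT.search(s):
        v = resolve_relative(s, ctx)
        if not v.date_known and ctx.anchor_date is not None:
            # anchor was available but the relative pattern is unknown
            return UNRESOLVED
        return v
    v = _parse_explicit_date(s, ctx.date_order)
    return v if v is not None else UNRESOLVED


def _normalize_time(s: str, ctx: AnchorContext) -> NormalizedValue:
    low = s.lower()
    if re.search(r"\bmorning\b", low):
        return DayPart(DayPartKind.TMO)
    if re.search(r"\bafternoon\b", low):
        return DayPart(DayPartKind.TAF)
    if re.search(r"\bevening\b", low):
        return DayPart(DayPartKind.TEV)
    if re.search(r"\bnight|tonight|overnight\b", low):
        return DayPart(DayPartKind.TNI)
    m = _RE_CLOCK_AMPM.search(s)
    if m:
        hour = int(m.group(1)) % 12
        if m.group(3).lower().startswith("p"):
            hour += 12
        minute = int(m.group(2)) if m.group(2) else 0
        return _clock_value(hour, minute, ctx)
    m = _RE_CLOCK_24.search(s)
    if m:
        hour, minute = int(m.group(1)), int(m.group(2))
        if hour > 23 or minute > 59:
            return UNRESOLVED
        return _clock_value(hour, minute, ctx)
    return UNRESOLVED


def _clock_value(hour: int, minute: int, ctx: AnchorContext) -> CalendarValue:
    if ctx.anchor_date is not None:
        d = ctx.anchor_date
        return CalendarValue(year=d.year, month=d.month, day=d.day, hour=hour, minute=minute)
    return CalendarValue(date_known=False, hour=hour, minute=minute)


def _parse_bound_anchor(rest: str, ctx: AnchorContext) -> Optional[CalendarValue]:
    rest = rest.strip()
    if _RELATIVE_HINT.search(rest):
        v = resolve_relative(rest, ctx)
        return v
    v = _parse_explicit_date(rest, ctx.date_order)
    if v is not None:
        return v
    # bare month name: most recent occurrence not after the anchor date
    m = re.fullmatch(_MONTH_PAT, rest, re.I)
    if m and ctx.anchor_date is not None:
        mo = _MONTHS[rest.lower()[:3]]
        year = ctx.anchor_date.year
        if mo > ctx.anchor_date.month:
            year -= 1
        return CalendarValue(year=year, month=mo)
    return None


def _parse_endpoint(part: str, ctx: AnchorContext) -> Optional[CalendarValue]:
    part = part.strip()
    m = _RE_CLOCK_AMPM.fullmatch(part) or _RE_CLOCK_AMPM.search(part)
    if m and re.search(r"am|pm", part, re.I):
        hour = int(m.group(1)) % 12
        if m.group(3).lower().startswith("p"):
            hour += 12
        minute = int(m.group(2)) if m.group(2) else 0
        return CalendarValue(date_known=False, hour=hour, minute=minute)
    return _parse_explicit_date(part, ctx.date_order)


def _normalize_duration(s: str, ctx: AnchorContext) -> NormalizedValue:
    m = _RE_SINCE_UNTIL.match(s.strip())
    if m:
        bound = BoundKind.SIN if m.group(1).lower() == "since" else BoundKind.UNT
        anchor = _parse_bound_anchor(m.group(2), ctx)
        if anchor is None:
            return UNRESOLVED
        return BoundedInterval(bound, anchor)

    m = _RE_YEAR_RANGE.search(s)
    if m:
        y1, y2 = int(m.group(1)), int(m.group(2))
        if y1 > y2:
            return UNRESOLVED
        return Range(CalendarValue(year=y1), CalendarValue(year=y2))

    m = _RE_FROM_TO.match(s.strip())
    if m:
        start = _parse_endpoint(m.group(1), ctx)
        end = _parse_endpoint(m.group(2), ctx)
        if start is None or end is None:
            return UNRESOLVED
        try:
            return Range(start, end)
        except ValueError:
            return UNRESOLVED

    m = _RE_FOR_N_UNIT.search(s)
    if m:
        n, unit = _num(m.group(1)), _unit(m.group(2))
        if n is not None and unit is not None:
            return Period(n, unit)
    m = _RE_OVER_PAST.search(s)
    if m:
        unit = _unit(m.group(2))
        if unit is not None:
            n = _num(m.group(1)) if m.group(1) else 1
            return Period(n if n is not None else 1, unit)
    m = _RE_FOR_VAGUE.search(s)
    if m:
        unit = _unit(m.group(1))
        if unit is not None:
            return Period("X", unit)
    m = _RE_N_UNIT.search(s)
    if m:
        n, unit = _num(m.group(1)), _unit(m.group(2))
        if n is not None and unit is not None:
            return Period(n, unit)
    return UNRESOLVED


_FREQ_ADVERBS = {
    "daily": (1, PeriodUnit.D, 1),
    "nightly": (1, PeriodUnit.D, 1),
    "weekly": (1, PeriodUnit.W, 1),
    "fortnightly": (2, PeriodUnit.W, 1),
    "monthly": (1, PeriodUnit.M, 1),
    "yearly": (1, PeriodUnit.Y, 1),
    "annually": (1, PeriodUnit.Y, 1),
    "hourly": (1, PeriodUnit.H, 1),
}

_FREQ_UNIT_MAP = {
    "day": PeriodUnit.D, "night": PeriodUnit.D, "morning": PeriodUnit.D,
    "evening": PeriodUnit.D, "week": PeriodUnit.W, "month": PeriodUnit.M,
    "year": PeriodUnit.Y, "hour": PeriodUnit.H,
}


def _normalize_frequency(s: str, ctx: AnchorContext) -> tuple[NormalizedValue, Optional[int]]:
    """Returns (period value, per-interval count) — the count rides along in
    expression metadata since the period template has no slot for it."""
    low = s.strip().lower()
    if low in _FREQ_ADVERBS:
        n, unit, times = _FREQ_ADVERBS[low]
        return Period(n, unit), times
    m = _RE_TIMES_PER.search(s)
    if m:
        word = m.group(1).lower()
        times = {"once": 1, "twice": 2, "thrice": 3}.get(word)
        if times is None:
            times = _num(m.group(2)) or 1
        unit = _FREQ_UNIT_MAP[m.group(3).lower()]
        return Period(1, unit), times
    m = _RE_EVERY.search(s)
    if m:
        target = m.group(2).lower()
        n = _num(m.group(1)) if m.group(1) else 1
        if target in _WEEKDAYS:
            return Period(1, PeriodUnit.W), 1
        unit = _FREQ_UNIT_MAP.get(target) or _unit(target)
        if unit is not None:
            return Period(n or 1, unit), 1
    return UNRESOLVED, None


def postprocess_age(tx: TimeExpression, lex: Optional[AgeLexicon] = None) -> TimeExpression:
    """Resolve an AGE_RELATED expression to an age value or a categorical
    life-stage reference.

    Current-age attribute patterns ("45 year old", "aged 45") map to
    current-age values; past patterns ("at age 8", "when he was 15") to
    past-age values; lexicon keyword hits to categorical refs; anything
    else to OTHER_REF.  A leading since/from (until) wraps the value in a
    SIN (UNT) bound.
    """
    if tx.type is not TimexType.AGE_RELATED:
        raise ValueError("postprocess_age expects an AGE_RELATED expression")
    if lex is None:
        lex = default_age_lexicon()
    s = tx.surface.strip()
    low = s.lower()
    value: NormalizedValue

    m = _RE_AGE_N.search(s)
    if m:
        n = int(m.group(1))
        unit = PeriodUnit.M if m.group(2) else PeriodUnit.Y
        age = AgeValue(AgeMode.PAST, n, unit)
        lead = low.split()[0]
        if lead in ("since", "from"):
            value = BoundedInterval(BoundKind.SIN, age)
        elif lead in ("until", "till"):
            value = BoundedInterval(BoundKind.UNT, age)
        else:
            value = age
        return replace(tx, value=value)

    m = _RE_WHEN_WAS_N.search(s)
    if m:
        return replace(tx, value=AgeValue(AgeMode.PAST, int(m.group(1))))

    m = _RE_AGE_OLD.search(s) or _RE_AGED.search(s)
    if m:
        n = _num(m.group(1))
        if n is not None:
            return replace(tx, value=AgeValue(AgeMode.CURRENT, n))

    ref = lex.lookup(low)
    kind = ref if ref is not None else CategoricalKind.OTHER_REF
    cat = CategoricalRef(kind)
    lead = low.split()[0] if low.split() else ""
    if lead in ("since", "from"):
        return replace(tx, value=BoundedInterval(BoundKind.SIN, cat))
    if lead in ("until", "till"):
        return replace(tx, value=BoundedInterval(BoundKind.UNT, cat))
    return replace(tx, value=cat)


def normalize(
    tx: TimeExpression,
    ctx: Optional[AnchorContext] = None,
    lex: Optional[AgeLexicon] = None,
) -> TimeExpression:
    """Assign a normalized value to one extracted expression.

    Deterministic given (expression, context, lexicon); unknown surfaces
    get the UNRESOLVED sentinel.
    """
    if ctx is None:
        ctx = AnchorContext()
    s = tx.surface.strip()
    if tx.type is TimexType.AGE_RELATED:
        return postprocess_age(tx, lex)
    if tx.type is TimexType.DATE:
        return replace(tx, value=_normalize_date(s, ctx))
    if tx.type is TimexType.TIME:
        return replace(tx, value=_normalize_time(s, ctx))
    if tx.type is TimexType.DURATION:
        return replace(tx, value=_normalize_duration(s, ctx))
    if tx.type is TimexType.FREQUENCY:
        value, times = _normalize_frequency(s, ctx)
        out = replace(tx, value=value)
        if times is not None:
            out.meta = {**tx.meta, "freq_count": str(times)}
        return out
    return replace(tx, value=UNRESOLVED)


def make_context(
    doc: Document,
    policy: DctPolicy = DctPolicy.STRUCTURED,
    override: Optional[_dt.date] = None,
    date_order: DateOrder = DateOrder.DMY,
    use_running_anchor: bool = False,
) -> AnchorContext:
    """Build an anchor context for a document under the chosen DCT policy."""
    if policy is DctPolicy.OVERRIDE:
        if override is None:
            raise ValueError("OVERRIDE policy requires an explicit date")
        dct = override
    elif policy is DctPolicy.FIRST_IN_TEXT_DATE:
        dct = _first_in_text_date(doc.text, date_order) or doc.dct
    else:
        dct = doc.dct
    return AnchorContext(
        dct=dct,
        dct_policy=policy,
        date_order=date_order,
        use_running_anchor=use_running_anchor,
    )


def _first_in_text_date(text: str, order: DateOrder) -> Optional[_dt.date]:
    hits: list[tuple[int, CalendarValue]] = []
    for rx in (_RE_FULL_DMY, _RE_FULL_MDY, _RE_ISO, _RE_NUMERIC):
        m = rx.search(text)
        if m:
            v = _parse_explicit_date(m.group(0), order)
            if v is not None and v.to_date() is not None:
                hits.append((m.start(), v))
    if not hits:
        return None
    return min(hits, key=lambda h: h[0])[1].to_date()


def normalize_all(
    doc: Document,
    ann: AnnotationSet,
    ctx: Optional[AnchorContext] = None,
    lex: Optional[AgeLexicon] = None,
) -> AnnotationSet:
    """Normalize every expression of an annotation set in document order,
    updating the running anchor when the context enables it."""
    if ctx is None:
        ctx = make_context(doc)
    out = AnnotationSet(doc_id=ann.doc_id)
    for tx in ann:
        ntx = normalize(tx, ctx, lex)
        if (
            ctx.use_running_anchor
            and isinstance(ntx.value, CalendarValue)
            and ntx.value.to_date() is not None
        ):
            ctx.last_resolved_date = ntx.value
        out.add(ntx)
    return out
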