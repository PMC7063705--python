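"""Deterministic generator of gold-annotated clinical-style notes.

Notes emulate long mental-health narratives: structured header dates,
past-history paragraphs, and embedded time expressions drawn from surface
templates restricted to the phrase families the extraction ruleset claims
to cover.  Gold spans, types and values are recorded exactly as embedded,
so every downstream stage is testable without any external data.

A single integer seed governs all randomness; each document gets a
substream derived from (seed, doc_index).
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

from .model import (
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
    Span,
    TimeExpression,
    TimexType,
    serialize_value,
)

__all__ = ["GenProfile", "generate_note", "generate_corpus", "simulate_second_annotator"]


_DEFAULT_MIX = {
    TimexType.DATE: 0.50,
    TimexType.DURATION: 0.18,
    TimexType.FREQUENCY: 0.12,
    TimexType.TIME: 0.111,
    TimexType.AGE_RELATED: 0.089,
}


@dataclass
class GenProfile:
    """Knobs for the generator; defaults mirror the narrative statistics
    the ruleset targets (long documents, a small Age_related share, about
    a third of date/time expressions relative)."""

    n_docs: int = 10
    seed: int = 0
    mean_tokens: int = 3974
    type_mix: dict[TimexType, float] = field(default_factory=lambda: dict(_DEFAULT_MIX))
    relative_fraction: float = 0.37
    categorical_fraction: float = 0.15
    header_date_prob: float = 0.9
    noise: bool = True  # spelling variants (yrs), lowercase months
    tokens_per_expression: int = 40

    def __post_init__(self) -> None:
        total = sum(self.type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type mixture sums to {total}, not 1")
        for frac in (self.relative_fraction, self.categorical_fraction,
                     self.header_date_prob):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


# Filler vocabulary chosen to never trigger the default ruleset: no digits,
# no month/unit/deictic words.
_FILLER = (
    "patient reports ongoing symptoms mood low he denies sleep appetite "
    "review clinic plan continue medication stable family support noted "
    "presents with and of the team assessment referral history described "
    "episode anxiety worsening engagement insight limited risk none carer "
    "attended discussed follow up community nurse prescribed dose unchanged "
    "concerns raised regarding functioning social isolation withdrawn affect "
    "flat speech normal thought content guarded denied harm ideation plans "
    "housing benefits employment college voices distressing intermittent"
).split()

_MONTH_NAMES = [
    "January", "February", "March", "April", "May", "June", "July",
    "August", "September", "October", "November", "December",
]
_MONTH_ABBR = [m[:3] for m in _MONTH_NAMES]


def _fmt_month(month: int, rng: random.Random, noise: bool) -> str:
    name = rng.choice([_MONTH_NAMES[month - 1], _MONTH_ABBR[month - 1]])
    if noise and rng.random() < 0.4:
        name = name.lower()
    return name


Template = Callable[[random.Random, _dt.date, GenProfile], tuple[str, NormalizedValue]]


def _rand_past_date(rng: random.Random, dct: _dt.date) -> _dt.date:
    back = rng.randrange(30, 365 * 15)
    return dct - _dt.timedelta(days=back)


# -- DATE -----------------------------------------------------------------


def _date_absolute(rng: random.Random, dct: _dt.date, prof: GenProfile):
    d = _rand_past_date(rng, dct)
    kind = rng.randrange(4)
    if kind == 0:  # full written date, optionally with weekday
        surface = f"{d.day} {_fmt_month(d.month, rng, prof.noise)} {d.year}"
        if rng.random() < 0.3:
            surface = f"{d.strftime('%A')} {surface}"
        return surface, CalendarValue.from_date(d)
    if kind == 1:  # month + year
        return (
            f"{_fmt_month(d.month, rng, prof.noise)} {d.year}",
            CalendarValue(year=d.year, month=d.month),
        )
    if kind == 2:  # numeric d/m/y
        return f"{d.day:02d}/{d.month:02d}/{d.year}", CalendarValue.from_date(d)
    return str(d.year), CalendarValue(year=d.year)


def _date_relative(rng: random.Random, dct: _dt.date, prof: GenProfile):
    kind = rng.randrange(6)
    if kind == 0:
        return "today", CalendarValue.from_date(dct)
    if kind == 1:
        return "yesterday", CalendarValue.from_date(dct - _dt.timedelta(days=1))
    if kind == 2:
        n = rng.randrange(1, 12)
        unit = "yrs" if (prof.noise and rng.random() < 0.4) else (
            "year" if n == 1 else "years"
        )
        tail = rng.choice(["ago", "back"])
        return f"{n} {unit} {tail}", CalendarValue(year=dct.year - n)
    if kind == 3:
        n = rng.randrange(1, 11)
        when = dct - _dt.timedelta(weeks=n)
        return f"{n} weeks ago", CalendarValue.from_date(when)
    if kind == 4:
        return "last year", CalendarValue(year=dct.year - 1)
    monday = dct - _dt.timedelta(days=dct.weekday()) - _dt.timedelta(weeks=1)
    return "last week", CalendarValue.from_date(monday)


_DATE_CATEGORICAL = [
    ("now", CategoricalKind.PRESENT_REF),
    ("currently", CategoricalKind.PRESENT_REF),
    ("at this time", CategoricalKind.PRESENT_REF),
    ("in the past", CategoricalKind.PAST_REF),
    ("previously", CategoricalKind.PAST_REF),
    ("recently", CategoricalKind.PAST_REF),
]


def _gen_date(rng: random.Random, dct: _dt.date, prof: GenProfile):
    if rng.random() < prof.categorical_fraction:
        surface, kind = rng.choice(_DATE_CATEGORICAL)
        return surface, CategoricalRef(kind)
    if rng.random() < prof.relative_fraction:
        return _date_relative(rng, dct, prof)
    return _date_absolute(rng, dct, prof)


# -- TIME -----------------------------------------------------------------

_DAYPARTS = [
    ("in the morning", DayPartKind.TMO),
    ("in the afternoon", DayPartKind.TAF),
    ("in the evening", DayPartKind.TEV),
    ("at night", DayPartKind.TNI),
]


def _gen_time(rng: random.Random, dct: _dt.date, prof: GenProfile):
    if rng.random() >= prof.relative_fraction:
        surface, part = rng.choice(_DAYPARTS)
        return surface, DayPart(part)
    hour12 = rng.randrange(1, 13)
    ampm = rng.choice(["am", "pm"])
    hour = hour12 % 12 + (12 if ampm == "pm" else 0)
    style = rng.randrange(3)
    if style == 0:
        surface = f"{hour12} {ampm} sharp"
    elif style == 1:
        surface = f"at {hour12} {ampm}"
    else:
        surface = f"{hour12}{ampm}"
    value = CalendarValue(
        year=dct.year, month=dct.month, day=dct.day, hour=hour, minute=0
    )
    return surface, value


# -- DURATION -------------------------------------------------------------


def _gen_duration(rng: random.Random, dct: _dt.date, prof: GenProfile):
    kind = rng.randrange(6)
    if kind == 0:  # for N unit
        choice = rng.randrange(3)
        if choice == 0:
            n = rng.randrange(1, 20)
            unit_word = "year" if n == 1 else "years"
            return f"for {n} {unit_word}", Period(n, PeriodUnit.Y)
        if choice == 1:
            n = rng.choice([5, 10, 15, 20, 30, 45])
            return f"for {n} min", Period(n, PeriodUnit.MIN)
        n = rng.randrange(1, 12)
        unit_word = "month" if n == 1 else "months"
        return f"for {n} {unit_word}", Period(n, PeriodUnit.M)
    if kind == 1:  # vague
        surface, unit = rng.choice(
            [
                ("for hours", PeriodUnit.H),
                ("for many years", PeriodUnit.Y),
                ("for several weeks", PeriodUnit.W),
                ("for days", PeriodUnit.D),
            ]
        )
        return surface, Period("X", unit)
    if kind == 2:  # since/until year
        year = rng.randrange(max(1990, dct.year - 20), dct.year)
        bound, word = rng.choice([(BoundKind.SIN, "since"), (BoundKind.UNT, "until")])
        return f"{word} {year}", BoundedInterval(bound, CalendarValue(year=year))
    if kind == 3:  # since month-year
        d = _rand_past_date(rng, dct)
        return (
            f"since {_fmt_month(d.month, rng, prof.noise)} {d.year}",
            BoundedInterval(BoundKind.SIN, CalendarValue(year=d.year, month=d.month)),
        )
    if kind == 4:  # until a year ago
        return (
            "until a year ago",
            BoundedInterval(BoundKind.UNT, CalendarValue(year=dct.year - 1)),
        )
    y2 = rng.randrange(max(1992, dct.year - 15), dct.year)
    y1 = y2 - rng.randrange(1, 8)
    dash = rng.choice(["–", "-"])
    return (
        f"{y1}{dash}{y2}",
        Range(CalendarValue(year=y1), CalendarValue(year=y2)),
    )


# -- FREQUENCY ------------------------------------------------------------

_FREQ_TEMPLATES = [
    ("daily", Period(1, PeriodUnit.D), 1),
    ("weekly", Period(1, PeriodUnit.W), 1),
    ("monthly", Period(1, PeriodUnit.M), 1),
    ("twice a week", Period(1, PeriodUnit.W), 2),
    ("once a day", Period(1, PeriodUnit.D), 1),
    ("twice a day", Period(1, PeriodUnit.D), 2),
    ("every 2 weeks", Period(2, PeriodUnit.W), 1),
    ("every day", Period(1, PeriodUnit.D), 1),
]


def _gen_frequency(rng: random.Random, dct: _dt.date, prof: GenProfile):
    surface, value, _times = rng.choice(_FREQ_TEMPLATES)
    return surface, value


# -- AGE_RELATED ----------------------------------------------------------


def _gen_age(rng: random.Random, dct: _dt.date, prof: GenProfile):
    kind = rng.randrange(7)
    if kind == 0:
        n = rng.randrange(18, 70)
        return f"{n} year old", AgeValue(AgeMode.CURRENT, n)
    if kind == 1:
        n = rng.randrange(18, 70)
        return f"aged {n}", AgeValue(AgeMode.CURRENT, n)
    if kind == 2:
        n = rng.randrange(5, 40)
        return f"when he was {n}", AgeValue(AgeMode.PAST, n)
    if kind == 3:
        n = rng.randrange(3, 17)
        return f"at age {n}", AgeValue(AgeMode.PAST, n)
    if kind == 4:
        n = rng.randrange(5, 30)
        return (
            f"since age {n}",
            BoundedInterval(BoundKind.SIN, AgeValue(AgeMode.PAST, n)),
        )
    if kind == 5:
        surface, ref = rng.choice(
            [
                ("when he was a child", CategoricalKind.CHILD_REF),
                ("in his teens", CategoricalKind.TEENS_REF),
                ("during adolescence", CategoricalKind.TEENS_REF),
                ("at university", CategoricalKind.UNI_REF),
            ]
        )
        return surface, CategoricalRef(ref)
    return (
        "since his teens",
        BoundedInterval(BoundKind.SIN, CategoricalRef(CategoricalKind.TEENS_REF)),
    )


_GENERATORS = {
    TimexType.DATE: _gen_date,
    TimexType.TIME: _gen_time,
    TimexType.DURATION: _gen_duration,
    TimexType.FREQUENCY: _gen_frequency,
    TimexType.AGE_RELATED: _gen_age,
}


def _filler(rng: random.Random, n: int) -> str:
    return " ".join(rng.choice(_FILLER) for _ in range(n))


def generate_note(
    profile: GenProfile, doc_index: int
) -> tuple[Document, AnnotationSet]:
    """One synthetic note plus its gold annotations; byte-identical for the
    same (profile, doc_index)."""
    rng = random.Random(f"{profile.seed}:{doc_index}")
    dct = _dt.date(2008 + rng.randrange(12), rng.randrange(1, 13), rng.randrange(1, 29))
    doc_id = f"synth-{profile.seed}-{doc_index:05d}"
    ann = AnnotationSet(doc_id=doc_id)
    parts: list[str] = []
    pos = 0
    structured: dict[str, _dt.date] = {}

    def emit(text: str) -> None:
        nonlocal pos
        parts.append(text)
        pos += len(text)

    def emit_expr(surface: str, ttype: TimexType, value: NormalizedValue) -> None:
        start = pos
        emit(surface)
        ann.add(
            TimeExpression(
                span=Span(start, start + len(surface)),
                surface=surface,
                type=ttype,
                value=value,
            )
        )

    if rng.random() < profile.header_date_prob:
        structured["visit"] = dct
        emit("Date of visit: ")
        surface = f"{dct.day} {_MONTH_NAMES[dct.month - 1]} {dct.year}"
        emit_expr(surface, TimexType.DATE, CalendarValue.from_date(dct))
        emit("\n")
        dob = _dt.date(dct.year - rng.randrange(18, 60), rng.randrange(1, 13), rng.randrange(1, 29))
        structured["birth"] = dob
        emit("Date of birth: ")
        surface = f"{dob.day} {_MONTH_NAMES[dob.month - 1]} {dob.year}"
        emit_expr(surface, TimexType.DATE, CalendarValue.from_date(dob))
        emit("\n\n")

    n_expr = max(1, round(profile.mean_tokens / profile.tokens_per_expression))
    types = list(profile.type_mix)
    weights = [profile.type_mix[t] for t in types]
    sentences_since_break = 0
    for _ in range(n_expr):
        ttype = rng.choices(types, weights=weights)[0]
        surface, value = _GENERATORS[ttype](rng, dct, profile)
        emit(_filler(rng, rng.randrange(3, 9)).capitalize() + " ")
        emit_expr(surface, ttype, value)
        emit(" " + _filler(rng, rng.randrange(2, 7)) + ". ")
        sentences_since_break += 1
        if sentences_since_break >= rng.randrange(3, 7):
            emit("\n\n")
            sentences_since_break = 0

    doc = Document(
        doc_id=doc_id,
        text="".join(parts),
        dct=dct,
        structured_dates=structured,
        meta={"patient_id": f"pat-{profile.seed}-{doc_index // 3:05d}"},
    )
    ann.validate_against(doc)
    return doc, ann


def generate_corpus(profile: GenProfile) -> list[tuple[Document, AnnotationSet]]:
    return [generate_note(profile, i) for i in range(profile.n_docs)]


def simulate_second_annotator(
    gold: AnnotationSet,
    deletion_rate: float = 0.0,
    boundary_jitter: float = 0.0,
    value_error_rate: float = 0.0,
    seed: int = 0,
) -> AnnotationSet:
    """Perturbed copy of a gold set imitating a second annotator: drops
    expressions, shrinks span edges (always keeping overlap), and rewrites
    values.  Deterministic per (gold.doc_id, seed)."""
    for rate in (deletion_rate, boundary_jitter, value_error_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = random.Random(f"{seed}:{gold.doc_id}")
    out = AnnotationSet(doc_id=gold.doc_id)
    for tx in gold:
        if rng.random() < deletion_rate:
            continue
        span, surface = tx.span, tx.surface
        if rng.random() < boundary_jitter and len(surface) > 2:
            if rng.random() < 0.5:
                span = Span(span.start + 1, span.end)
                surface = surface[1:]
            else:
                span = Span(span.start, span.end - 1)
                surface = surface[:-1]
        value = tx.value
        if value is not None and rng.random() < value_error_rate:
            value = _corrupt_value(value)
        out.add(replace(tx, span=span, surface=surface, value=value))
    return out


def _corrupt_value(value: NormalizedValue) -> NormalizedValue:
    """A value guaranteed to serialize differently from the input."""
    wrong = CategoricalRef(CategoricalKind.OTHER_REF)
    if serialize_value(value) == serialize_value(wrong):
        wrong = CategoricalRef(CategoricalKind.PAST_REF)
    return wrong
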