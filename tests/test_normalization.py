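import datetime as dt

import pytest
from dateutil.relativedelta import relativedelta

from clintimex.model import (
    AgeMode,
    AgeValue,
    BoundedInterval,
    BoundKind,
    CalendarValue,
    CategoricalKind,
    CategoricalRef,
    Period,
    PeriodUnit,
    Span,
    TimeExpression,
    TimexType,
    Unresolved,
    serialize_value,
)
from clintimex.normalization import (
    AgeLexicon,
    AnchorContext,
    DctPolicy,
    age_ref_to_range,
    default_age_lexicon,
    make_context,
    normalize,
    postprocess_age,
    resolve_relative,
)


def _tx(surface, ttype):
    return TimeExpression(Span(0, len(surface)), surface, ttype)


def _norm(surface, ttype, ctx=None):
    return normalize(_tx(surface, ttype), ctx).value_string()


# Every surface->value pair printed in the source material must reproduce
# exactly (with DCT 2011-03-14 where a date anchor is needed).
ORACLE_TABLE = [
    ("for 4 years", TimexType.DURATION, "P4Y"),
    ("for 15 min", TimexType.DURATION, "PT15M"),
    ("since 2007", TimexType.DURATION, "SIN2007"),
    ("2009–2012", TimexType.DURATION, "(2009, 2012)"),
    ("for hours", TimexType.DURATION, "PXH"),
    ("a 45 year old", TimexType.AGE_RELATED, "P45Y"),
    ("when he was 15", TimexType.AGE_RELATED, "A15Y"),
    ("when he was a child", TimexType.AGE_RELATED, "CHILD_REF"),
    ("in the past", TimexType.DATE, "PAST_REF"),
    ("now", TimexType.DATE, "PRESENT_REF"),
    ("in the morning", TimexType.TIME, "TMO"),
    ("at night", TimexType.TIME, "TNI"),
    ("6 pm sharp", TimexType.TIME, "2011-03-14T18:00"),
]


class TestOracleTable:
    @pytest.mark.parametrize("surface,ttype,expected", ORACLE_TABLE)
    def test_pair(self, surface, ttype, expected, ctx):
        assert _norm(surface, ttype, ctx) == expected


class TestNormalizeDates:
    def test_explicit_dates(self, ctx):
        assert _norm("5 October 2012", TimexType.DATE, ctx) == "2012-10-05"
        assert _norm("oct 2009", TimexType.DATE, ctx) == "2009-10"
        assert _norm("2007", TimexType.DATE, ctx) == "2007"

    def test_numeric_date_dialects(self, dct):
        dmy = AnchorContext(dct=dct)
        assert _norm("04/10/2012", TimexType.DATE, dmy) == "2012-10-04"
        from clintimex.normalization import DateOrder

        mdy = AnchorContext(dct=dct, date_order=DateOrder.MDY)
        assert _norm("04/10/2012", TimexType.DATE, mdy) == "2012-04-10"

    def test_impossible_component_order_flips(self, ctx):
        # 25 cannot be a month, so DMY reading is forced even in MDY mode
        from clintimex.normalization import DateOrder

        mdy = AnchorContext(dct=ctx.dct, date_order=DateOrder.MDY)
        assert _norm("25/03/2012", TimexType.DATE, mdy) == "2012-03-25"

    def test_unknown_surface_is_unresolved_not_dropped(self, ctx):
        out = normalize(_tx("the following spring", TimexType.DATE), ctx)
        assert isinstance(out.value, Unresolved)
        assert out.value_string() == "UNRESOLVED"

    def test_only_today_resolves_to_dct(self, ctx):
        assert _norm("today", TimexType.DATE, ctx) == "2011-03-14"
        assert _norm("currently", TimexType.DATE, ctx) == "PRESENT_REF"
        assert _norm("at this time", TimexType.DATE, ctx) == "PRESENT_REF"


class TestResolveRelative:
    def test_today(self, ctx):
        assert resolve_relative("today", ctx) == CalendarValue(year=2011, month=3, day=14)

    def test_two_yrs_back(self, ctx):
        # derived: 2011 minus 2 at year granularity
        assert serialize_value(resolve_relative("2 yrs back", ctx)) == "2009"

    def test_until_a_year_ago_bound(self):
        ctx = AnchorContext(dct=dt.date(2019, 6, 1))
        assert _norm("until a year ago", TimexType.DURATION, ctx) == "UNT2018"

    @pytest.mark.parametrize("n,unit", [(1, "years"), (5, "years"), (3, "months"), (2, "weeks"), (10, "days")])
    def test_arithmetic_matches_dateutil_oracle(self, n, unit, dct):
        ctx = AnchorContext(dct=dct)
        got = resolve_relative(f"{n} {unit} ago", ctx)
        if unit == "years":
            assert got == CalendarValue(year=dct.year - n)
        elif unit == "months":
            ref = dct - relativedelta(months=n)
            assert got == CalendarValue(year=ref.year, month=ref.month)
        elif unit == "weeks":
            assert got == CalendarValue.from_date(dct - dt.timedelta(weeks=n))
        else:
            assert got == CalendarValue.from_date(dct - dt.timedelta(days=n))

    def test_granularity_preserved(self, ctx):
        # a year-granular relative never yields a full date
        v = resolve_relative("3 years ago", ctx)
        assert v.month is None and v.day is None
        v = resolve_relative("3 months ago", ctx)
        assert v.month is not None and v.day is None

    def test_no_anchor_gives_placeholder(self):
        ctx = AnchorContext(dct=None)
        v = resolve_relative("2 years ago", ctx)
        assert not v.date_known

    def test_last_week_is_previous_iso_monday(self):
        ctx = AnchorContext(dct=dt.date(2011, 3, 14))  # a Monday
        assert resolve_relative("last week", ctx) == CalendarValue(2011, 3, 7)

    def test_dct_shift_property(self):
        # shifting the DCT shifts every day-granular relative by the same offset
        surfaces = ["today", "yesterday", "3 weeks ago", "10 days ago"]
        base = dt.date(2011, 3, 14)
        for k in (1, 40, 365):
            shifted = base + dt.timedelta(days=k)
            for s in surfaces:
                v0 = resolve_relative(s, AnchorContext(dct=base)).to_date()
                v1 = resolve_relative(s, AnchorContext(dct=shifted)).to_date()
                assert v1 - v0 == dt.timedelta(days=k)


class TestNormalizeTimes:
    def test_clock_without_dct_uses_placeholders(self):
        ctx = AnchorContext(dct=None)
        assert _norm("6 pm sharp", TimexType.TIME, ctx) == "XXXX-XX-XXT18:00"

    def test_am_pm(self, ctx):
        assert _norm("at 9 am", TimexType.TIME, ctx) == "2011-03-14T09:00"
        assert _norm("12 am", TimexType.TIME, ctx) == "2011-03-14T00:00"
        assert _norm("12 pm", TimexType.TIME, ctx) == "2011-03-14T12:00"

    def test_dayparts(self, ctx):
        assert _norm("in the afternoon", TimexType.TIME, ctx) == "TAF"
        assert _norm("in the evening", TimexType.TIME, ctx) == "TEV"


class TestNormalizeDurations:
    def test_from_to_times(self, ctx):
        assert (
            _norm("from 10 pm to 4 am", TimexType.DURATION, ctx)
            == "(XXXX-XX-XXT22:00, XXXX-XX-XXT04:00)"
        )

    def test_from_to_years(self, ctx):
        assert _norm("from 2009 to 2012", TimexType.DURATION, ctx) == "(2009, 2012)"

    def test_vague(self, ctx):
        assert _norm("for many years", TimexType.DURATION, ctx) == "PXY"
        assert _norm("for several weeks", TimexType.DURATION, ctx) == "PXW"

    def test_since_month_year(self, ctx):
        assert _norm("since May 2009", TimexType.DURATION, ctx) == "SIN2009-05"

    def test_bare_duration(self, ctx):
        assert _norm("3 years", TimexType.DURATION, ctx) == "P3Y"

    def test_reversed_range_unresolved(self, ctx):
        out = normalize(_tx("2012–2009", TimexType.DURATION), ctx)
        assert isinstance(out.value, Unresolved)


class TestNormalizeFrequencies:
    def test_twice_a_week(self, ctx):
        out = normalize(_tx("twice a week", TimexType.FREQUENCY), ctx)
        assert out.value == Period(1, PeriodUnit.W)
        assert out.meta["freq_count"] == "2"

    @pytest.mark.parametrize(
        "surface,expected",
        [("daily", "P1D"), ("weekly", "P1W"), ("every 2 weeks", "P2W"),
         ("3 times a day", "P1D"), ("fortnightly", "P2W")],
    )
    def test_values(self, surface, expected, ctx):
        assert _norm(surface, TimexType.FREQUENCY, ctx) == expected


class TestPostprocessAge:
    def test_at_age(self):
        out = postprocess_age(_tx("at age 8", TimexType.AGE_RELATED))
        assert out.value == AgeValue(AgeMode.PAST, 8)

    def test_in_his_teens(self):
        out = postprocess_age(_tx("in his teens", TimexType.AGE_RELATED))
        assert out.value == CategoricalRef(CategoricalKind.TEENS_REF)

    def test_since_age_3_months_extension(self):
        out = postprocess_age(_tx("since age 3 months", TimexType.AGE_RELATED))
        assert out.value == BoundedInterval(
            BoundKind.SIN, AgeValue(AgeMode.PAST, 3, PeriodUnit.M)
        )
        assert out.value_string() == "SINA3M"

    def test_current_vs_past(self):
        cur = postprocess_age(_tx("aged 45", TimexType.AGE_RELATED))
        assert cur.value == AgeValue(AgeMode.CURRENT, 45)
        past = postprocess_age(_tx("when she was 12", TimexType.AGE_RELATED))
        assert past.value == AgeValue(AgeMode.PAST, 12)

    def test_fallback_other_ref(self):
        out = postprocess_age(_tx("when he was younger", TimexType.AGE_RELATED))
        assert out.value == CategoricalRef(CategoricalKind.OTHER_REF)

    def test_wrong_type_rejected(self):
        with pytest.raises(ValueError):
            postprocess_age(_tx("2007", TimexType.DATE))

    def test_custom_lexicon(self):
        lex = AgeLexicon({"nursery": CategoricalKind.CHILD_REF})
        out = postprocess_age(_tx("at nursery", TimexType.AGE_RELATED), lex)
        assert out.value == CategoricalRef(CategoricalKind.CHILD_REF)

    def test_lexicon_rejects_non_life_stage(self):
        with pytest.raises(ValueError):
            AgeLexicon({"today": CategoricalKind.PRESENT_REF})


class TestAgeRefToRange:
    def test_teens_default(self):
        lo, hi = age_ref_to_range(CategoricalKind.TEENS_REF)
        assert (serialize_value(lo), serialize_value(hi)) == ("A13Y", "A19Y")

    def test_other_ref_none(self):
        assert age_ref_to_range(CategoricalKind.OTHER_REF) is None

    def test_child_default_overridable(self):
        lo, hi = age_ref_to_range(CategoricalKind.CHILD_REF)
        assert (lo.count, hi.count) == (0, 12)
        custom = {CategoricalKind.CHILD_REF: (0, 10)}
        lo, hi = age_ref_to_range(CategoricalKind.CHILD_REF, custom)
        assert (lo.count, hi.count) == (0, 10)


class TestContextPolicies:
    def test_structured_default(self, dct):
        from clintimex.model import Document

        doc = Document("d", "text", dct=dct)
        ctx = make_context(doc)
        assert ctx.dct == dct

    def test_first_in_text_date(self):
        from clintimex.model import Document

        doc = Document(
            "d",
            "Clinic letter dated 14 March 2011. Seen today.",
            dct=dt.date(2020, 1, 1),  # wrong structured DCT
        )
        ctx = make_context(doc, DctPolicy.FIRST_IN_TEXT_DATE)
        assert ctx.dct == dt.date(2011, 3, 14)

    def test_override(self):
        from clintimex.model import Document

        doc = Document("d", "text", dct=dt.date(2020, 1, 1))
        ctx = make_context(doc, DctPolicy.OVERRIDE, override=dt.date(2011, 3, 14))
        assert ctx.dct == dt.date(2011, 3, 14)
        with pytest.raises(ValueError):
            make_context(doc, DctPolicy.OVERRIDE)

    def test_running_anchor_off_by_default(self, dct):
        ctx = AnchorContext(dct=dct, last_resolved_date=CalendarValue(2000, 1, 1))
        assert ctx.anchor_date == dct
        ctx.use_running_anchor = True
        assert ctx.anchor_date == dt.date(2000, 1, 1)

    def test_determinism(self, ctx):
        lex = default_age_lexicon()
        for surface, ttype, _ in ORACLE_TABLE:
            a = normalize(_tx(surface, ttype), ctx, lex)
            b = normalize(_tx(surface, ttype), ctx, lex)
            assert a == b
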