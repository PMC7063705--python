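# Default extraction ruleset.
#
# Each rule: name, pattern (regex; {MONTH}/{YEAR}/{NUM}/{UNIT}/... macros are
# expanded at load time; compiled case-insensitive with word-boundary
# anchoring), type (one of DATE/TIME/DURATION/FREQUENCY/AGE_RELATED),
# priority (tie-break among equal-length overlapping matches; higher wins)
# and optional hints consumed by the normalizer.
#
# Conventions: preposition-led expressions (since/until/for ...) keep the
# preposition inside the span and are typed DURATION (or AGE_RELATED for
# life-stage phrases); the preposition is decisive for Date/Duration.
# Non-standard dates like "week 3" / "over the weekend" are deliberately
# not matched by the default set; stub patterns are included commented out
# for extension.

rules:
  # ---- age-related (high priority: they embed digits/durations) ----
  - name: age_year_old
    pattern: '{NUM}(?:\s+|-){UNIT}(?:\s+|-)old'
    type: AGE_RELATED
    priority: 40
    hints: {age_mode: CURRENT}
  - name: age_aged
    pattern: 'aged\s+\d{1,3}'
    type: AGE_RELATED
    priority: 40
    hints: {age_mode: CURRENT}
  - name: age_at_age
    pattern: '(?:at|from)\s+(?:the\s+age\s+of|age)\s+\d{1,3}(?:\s+months?)?'
    type: AGE_RELATED
    priority: 40
    hints: {age_mode: PAST}
  - name: age_since_until_age
    pattern: '(?:since|until|till)\s+(?:the\s+age\s+of|age)\s+\d{1,3}(?:\s+months?)?'
    type: AGE_RELATED
    priority: 41
  - name: age_when_was
    pattern: 'when\s+(?:he|she|they|i|the\s+patient)\s+(?:was|were)\s+(?:\d{1,3}(?:\s+(?:years?|yrs?)(?:\s+old)?)?|a\s+child|a\s+teenager|a\s+baby|young|little|younger|at\s+school|at\s+university)'
    type: AGE_RELATED
    priority: 40
  - name: age_life_stage_possessive
    pattern: '(?:in|since|from|during|throughout)\s+{PRONOUN}\s+(?:(?:early|mid|late)[\s-])?(?:teens|twenties|thirties|childhood|adolescence|youth|infancy)'
    type: AGE_RELATED
    priority: 40
  - name: age_life_stage_bare
    pattern: '(?:in|since|during|throughout)\s+(?:early\s+)?(?:childhood|adolescence|infancy)|as\s+a\s+(?:child|teenager|young\s+(?:man|woman|adult|person))|at\s+(?:primary\s+|secondary\s+)?school|at\s+university|growing\s+up'
    type: AGE_RELATED
    priority: 39

  # ---- durations ----
  - name: dur_since_until_date
    pattern: '(?:since|until|till|up\s+until)\s+(?:(?:{WEEKDAY},?\s+)?{DAYNUM}\s+{MONTH}\s+{YEAR}|{MONTH}\s+{YEAR}|{MONTH}|{YEAR}|last\s+(?:week|month|year)|yesterday)'
    type: DURATION
    priority: 30
  - name: dur_since_until_relative
    pattern: '(?:since|until|till)\s+{NUM}\s+{UNIT}\s+(?:ago|back|earlier)'
    type: DURATION
    priority: 31
  - name: dur_for_n_unit
    pattern: 'for\s+(?:(?:the\s+)?(?:last|past|next)\s+)?{NUM}\s+{UNIT}|for\s+{UNIT}'
    type: DURATION
    priority: 30
  - name: dur_for_vague
    pattern: 'for\s+(?:many|several|a\s+few|some|a\s+couple\s+of|a\s+number\s+of)\s+{UNIT}'
    type: DURATION
    priority: 31
  - name: dur_over_past
    pattern: '(?:over|during|in)\s+the\s+(?:last|past|previous|next|coming)\s+(?:{NUM}\s+)?{UNIT}'
    type: DURATION
    priority: 30
  - name: dur_year_range
    pattern: '{YEAR}\s*(?:[–—-]|to)\s*{YEAR}'
    type: DURATION
    priority: 30
  - name: dur_from_to
    pattern: 'from\s+(?:{YEAR}|{MONTH}\s+{YEAR}|\d{1,2}(?::\d{2})?\s*(?:am|pm))\s+(?:to|until|till)\s+(?:{YEAR}|{MONTH}\s+{YEAR}|\d{1,2}(?::\d{2})?\s*(?:am|pm))'
    type: DURATION
    priority: 31
  - name: dur_bare
    pattern: '{NUM}\s+{UNIT}'
    type: DURATION
    priority: 5

  # ---- frequencies ----
  - name: freq_adverb
    pattern: 'daily|weekly|monthly|yearly|annually|nightly|hourly|fortnightly'
    type: FREQUENCY
    priority: 20
  - name: freq_times_per
    pattern: '(?:once|twice|thrice|{NUM}\s+times)\s+(?:a|per|each|every)\s+{FREQUNIT}'
    type: FREQUENCY
    priority: 35
  - name: freq_every
    pattern: 'every\s+(?:{NUM}\s+)?(?:{UNIT}|{FREQUNIT}|{WEEKDAY})'
    type: FREQUENCY
    priority: 34

  # ---- times ----
  - name: time_clock_ampm
    pattern: '(?:at\s+)?\d{1,2}(?:[:.]\d{2})?\s*(?:am|pm|a\.m\.|p\.m\.)(?:\s+sharp)?'
    type: TIME
    priority: 25
  - name: time_clock_24h
    pattern: '\d{1,2}:\d{2}(?:\s*(?:hrs|hours))?'
    type: TIME
    priority: 24
  - name: time_daypart
    pattern: '(?:in|during)\s+the\s+(?:morning|afternoon|evening|night)|at\s+night(?:time)?|(?:this|that)\s+(?:morning|afternoon|evening)|tonight|last\s+night|overnight'
    type: TIME
    priority: 25

  # ---- dates ----
  - name: date_full_dmy
    pattern: '(?:{WEEKDAY},?\s+)?(?:the\s+)?{DAYNUM}(?:\s+of)?\s+{MONTH},?\s+{YEAR}'
    type: DATE
    priority: 15
  - name: date_full_mdy
    pattern: '(?:{WEEKDAY},?\s+)?{MONTH}\s+{DAYNUM},?\s+{YEAR}'
    type: DATE
    priority: 14
  - name: date_day_month
    pattern: '{DAYNUM}\s+{MONTH}|{MONTH}\s+{DAYNUM}'
    type: DATE
    priority: 8
  - name: date_month_year
    pattern: '{MONTH}\s+(?:of\s+)?{YEAR}'
    type: DATE
    priority: 15
  - name: date_numeric
    pattern: '\d{1,2}[/.]\d{1,2}[/.](?:\d{4}|\d{2})|{YEAR}[/.-]\d{1,2}[/.-]\d{1,2}'
    type: DATE
    priority: 15
  - name: date_year
    pattern: '{YEAR}'
    type: DATE
    priority: 3
  - name: date_relative_ago
    pattern: '{NUM}\s+{UNIT}\s+(?:ago|back|earlier|previously|prior)'
    type: DATE
    priority: 20
  - name: date_deictic_day
    pattern: 'today|yesterday|tomorrow'
    type: DATE
    priority: 20
  - name: date_last_next
    pattern: '(?:last|next|this|the\s+previous|the\s+following)\s+(?:week|month|year|{MONTH}|{WEEKDAY})|earlier\s+(?:this|that)\s+(?:week|month|year)'
    type: DATE
    priority: 18
  - name: date_present_ref
    pattern: 'now|currently|at\s+(?:the\s+)?present|at\s+the\s+moment|at\s+this\s+time|presently|these\s+days'
    type: DATE
    priority: 18
    hints: {categorical: PRESENT_REF}
  - name: date_past_ref
    pattern: 'in\s+the\s+past|previously|historically|in\s+the\s+old\s+days|some\s+time\s+ago'
    type: DATE
    priority: 18
    hints: {categorical: PAST_REF}
  - name: date_recent
    pattern: 'recently|lately|of\s+late'
    type: DATE
    priority: 17
    hints: {categorical: PAST_REF}

  # stubs for non-standard dates the default set deliberately ignores:
  # - name: date_week_number
  #   pattern: 'week\s+\d{1,2}'
  #   type: DATE
  # - name: date_weekend
  #   pattern: '(?:over|at|during)\s+the\s+weekend'
  #   type: DATE
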