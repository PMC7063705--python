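"""Pattern-rule engine detecting time-expression spans and assigning types.

Rules are ordered regex patterns, each carrying the type it assigns, a
priority for tie-breaking, and an optional normalization hint.  Overlap
resolution is longest-match-wins with priority then leftmost-start as
tie-breakers.  A packaged default ruleset (``data/default_rules.yaml``)
covers U.K.-style clinical narrative; date component order defaults to
day-month-year with a switch for month-day-year.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

from .model import AnnotationSet, Document, Span, TimeExpression, TimexType

__all__ = ["Rule", "RuleSet", "load_ruleset", "default_ruleset", "extract",
           "resolve_overlaps", "count_timexes"]

# macros expandable inside rule patterns; kept simple on purpose
_MACROS = {
    "MONTH": (
        r"(?:jan(?:uary)?|feb(?:ruary)?|mar(?:ch)?|apr(?:il)?|may|jun(?:e)?"
        r"|jul(?:y)?|aug(?:ust)?|sep(?:t(?:ember)?)?|oct(?:ober)?"
        r"|nov(?:ember)?|dec(?:ember)?)"
    ),
    "WEEKDAY": r"(?:mon|tues?|wednes|thurs?|fri|satur|sun)day",
    "YEAR": r"(?:19|20)\d{2}",
    "DAYNUM": r"\d{1,2}(?:st|nd|rd|th)?",
    "NUM": (
        r"(?:\d{1,3}|an?|one|two|three|four|five|six|seven|eight|nine|ten"
        r"|eleven|twelve|twenty|thirty)"
    ),
    "UNIT": (
        r"(?:years?|yrs?|months?|mths?|weeks?|wks?|days?|hours?|hrs?"
        r"|minutes?|mins?|seconds?|secs?)"
    ),
    "FREQUNIT": r"(?:day|night|morning|evening|week|month|year|hour)",
    "PRONOUN": r"(?:his|her|their|my)",
}


@dataclass(frozen=True)
class Rule:
    """One surface pattern.  ``hints`` feed the normalizer (e.g.
    ``bound: SIN``); patterns are compiled case-insensitive and anchored to
    word boundaries."""

    name: str
    pattern: str
    type: TimexType
    priority: int = 0
    hints: dict = field(default_factory=dict, hash=False)

    def compile(self) -> re.Pattern:
        pat = self.pattern
        for macro, expansion in _MACROS.items():
            pat = pat.replace("{%s}" % macro, expansion)
        return re.compile(rf"(?<!\w)(?:{pat})(?!\w)", re.IGNORECASE)


class RuleSet:
    """Ordered, deterministic collection of :class:`Rule`."""

    def __init__(self, rules: Iterable[Rule]):
        self.rules = list(rules)
        self._compiled = [(r, r.compile()) for r in self.rules]

    def __len__(self) -> int:
        return len(self.rules)

    def scan(self, text: str) -> list[tuple[Span, TimexType, int, Rule]]:
        """All raw candidate matches, before overlap resolution."""
        out = []
        for rule, rx in self._compiled:
            for m in rx.finditer(text):
                if m.start() == m.end():
                    continue
                out.append((Span(m.start(), m.end()), rule.type, rule.priority, rule))
        return out


def load_ruleset(path: Union[str, Path]) -> RuleSet:
    """Load rules from a YAML file: a list of mappings with keys
    ``name, pattern, type, priority, hints``."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    rules = []
    for entry in raw["rules"]:
        rules.append(
            Rule(
                name=entry["name"],
                pattern=entry["pattern"],
                type=TimexType(entry["type"]),
                priority=int(entry.get("priority", 0)),
                hints=dict(entry.get("hints", {})),
            )
        )
    return RuleSet(rules)


_DEFAULT_CACHE: Optional[RuleSet] = None


def default_ruleset() -> RuleSet:
    """The packaged default ruleset (cached)."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        ref = resources.files("clintimex").joinpath("data/default_rules.yaml")
        with resources.as_file(ref) as p:
            _DEFAULT_CACHE = load_ruleset(p)
    return _DEFAULT_CACHE


def resolve_overlaps(
    candidates: list[tuple[Span, TimexType, int, Rule]]
) -> list[tuple[Span, TimexType, int, Rule]]:
    """Longest match wins; ties broken by higher rule priority, then
    leftmost start.  Output sorted by start, pairwise disjoint."""
    ranked = sorted(
        candidates,
        key=lambda c: (-(c[0].end - c[0].start), -c[2], c[0].start, c[0].end),
    )
    kept: list[tuple[Span, TimexType, int, Rule]] = []
    for cand in ranked:
        if all(not cand[0].overlaps(k[0]) for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c[0].start)
    return kept


def extract(doc: Document, rules: Optional[RuleSet] = None) -> AnnotationSet:
    """Detect time-expression spans in ``doc`` and assign types.

    Values are left unset; run the normalizer for those.  Deterministic:
    identical input always yields identical output.
    """
    if rules is None:
        rules = default_ruleset()
    ann = AnnotationSet(doc_id=doc.doc_id)
    if not doc.text:
        return ann
    for span, ttype, _prio, rule in resolve_overlaps(rules.scan(doc.text)):
        expr = TimeExpression(
            span=span,
            surface=doc.text[span.start : span.end],
            type=ttype,
            meta={"rule": rule.name, **{k: str(v) for k, v in rule.hints.items()}},
        )
        ann.add(expr)
    return ann


def count_timexes(doc: Document, rules: Optional[RuleSet] = None) -> int:
    """Number of extracted time expressions in ``doc``."""
    return len(extract(doc, rules))
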