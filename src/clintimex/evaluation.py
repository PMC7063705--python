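"""Scoring of annotation pairs: lenient span F1, value accuracy on
matching spans, relaxed Time accuracy (acc*), and a per-type breakdown.

A match is any pair of spans from the two sides that overlap by at least
one character; pairing is a maximum-cardinality one-to-one matching over
the overlap relation, computed exactly with augmenting paths (sets are
small) and tie-broken toward leftmost pairings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .model import AnnotationSet, TimeExpression, TimexType

__all__ = [
    "MatchSet",
    "TypeRow",
    "EvalReport",
    "lenient_match",
    "lenient_f1",
    "value_accuracy",
    "relaxed_time_accuracy",
    "per_type_report",
    "evaluate",
]


@dataclass
class MatchSet:
    """One-to-one span pairing between two annotation sets for a document."""

    doc_id: str
    pairs: list[tuple[TimeExpression, TimeExpression]]
    unmatched_a: list[TimeExpression]
    unmatched_b: list[TimeExpression]


@dataclass
class TypeRow:
    type: TimexType
    matches: int
    acc: Optional[float]
    acc_star: Optional[float]
    type_disagreements: int


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    n_matches: int
    n_a: int
    n_b: int
    value_acc: Optional[float]
    value_acc_star: Optional[float]
    per_type: list[TypeRow] = field(default_factory=list)


def lenient_match(a: AnnotationSet, b: AnnotationSet) -> MatchSet:
    """Maximum one-to-one matching of overlapping spans (lenient matching).

    Deterministic: among maximum matchings, pairing is built greedily from
    the leftmost A-span, each augmenting search preferring leftmost B-spans.
    """
    if a.doc_id != b.doc_id:
        raise ValueError(f"doc id mismatch: {a.doc_id!r} vs {b.doc_id!r}")
    ea, eb = list(a), list(b)
    adj = [
        [j for j, y in enumerate(eb) if x.span.overlaps(y.span)]
        for x in ea
    ]
    match_b: list[Optional[int]] = [None] * len(eb)

    def augment(i: int, seen: set[int]) -> bool:
        for j in adj[i]:
            if j in seen:
                continue
            seen.add(j)
            if match_b[j] is None or augment(match_b[j], seen):
                match_b[j] = i
                return True
        return False

    for i in range(len(ea)):
        augment(i, set())

    pairs = sorted(
        ((match_b[j], j) for j in range(len(eb)) if match_b[j] is not None),
    )
    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}
    return MatchSet(
        doc_id=a.doc_id,
        pairs=[(ea[i], eb[j]) for i, j in pairs],
        unmatched_a=[x for i, x in enumerate(ea) if i not in matched_a],
        unmatched_b=[y for j, y in enumerate(eb) if j not in matched_b],
    )


def lenient_f1(a: AnnotationSet, b: AnnotationSet) -> tuple[float, float, float]:
    """(precision, recall, F1) with A as system/annotator-1 and B as
    reference/annotator-2.  Empty vs empty scores 1.0 by convention; an
    empty side alone scores 1.0 on its own ratio."""
    m = lenient_match(a, b)
    n = len(m.pairs)
    precision = n / len(a) if len(a) else 1.0
    recall = n / len(b) if len(b) else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def _value_str(tx: TimeExpression) -> Optional[str]:
    return tx.value_string()


def value_accuracy(m: MatchSet) -> Optional[float]:
    """Share of matched pairs with identical canonical value strings; None
    on an empty match set (undefined, not zero)."""
    if not m.pairs:
        return None
    same = sum(1 for x, y in m.pairs if _value_str(x) == _value_str(y))
    return same / len(m.pairs)


_CLOCK_SUFFIX = re.compile(r"T\d{2}:\d{2}$")


def _relaxed_equal(x: TimeExpression, y: TimeExpression, ref_type: TimexType) -> bool:
    vx, vy = _value_str(x), _value_str(y)
    if vx == vy:
        return True
    if ref_type is not TimexType.TIME or vx is None or vy is None:
        return False
    mx, my = _CLOCK_SUFFIX.search(vx), _CLOCK_SUFFIX.search(vy)
    if mx and my:
        return mx.group(0) == my.group(0)
    return False


def relaxed_time_accuracy(m: MatchSet) -> Optional[float]:
    """Like value accuracy, but Time-typed pairs whose values carry a
    full-date ``Thh:mm`` form are compared on the clock portion only."""
    if not m.pairs:
        return None
    same = sum(1 for x, y in m.pairs if _relaxed_equal(x, y, y.type))
    return same / len(m.pairs)


def per_type_report(m: MatchSet) -> list[TypeRow]:
    """Per-type match counts and accuracies; a pair's type is read from the
    reference (B) side, with disagreeing system types tallied."""
    rows = []
    for t in TimexType:
        pairs = [(x, y) for x, y in m.pairs if y.type is t]
        n = len(pairs)
        acc = acc_star = None
        if n:
            acc = sum(1 for x, y in pairs if _value_str(x) == _value_str(y)) / n
            acc_star = sum(1 for x, y in pairs if _relaxed_equal(x, y, t)) / n
        disagreements = sum(1 for x, y in pairs if x.type is not t)
        rows.append(TypeRow(t, n, acc, acc_star, disagreements))
    return rows


def evaluate(a: AnnotationSet, b: AnnotationSet) -> EvalReport:
    """Full report for one document pair."""
    m = lenient_match(a, b)
    precision, recall, f1 = lenient_f1(a, b)
    return EvalReport(
        precision=precision,
        recall=recall,
        f1=f1,
        n_matches=len(m.pairs),
        n_a=len(a),
        n_b=len(b),
        value_acc=value_accuracy(m),
        value_acc_star=relaxed_time_accuracy(m),
        per_type=per_type_report(m),
    )


def evaluate_corpus(
    pairs: list[tuple[AnnotationSet, AnnotationSet]], macro: bool = False
) -> EvalReport:
    """Pooled (micro) corpus-level report by default; ``macro`` averages
    per-document metrics instead."""
    if macro:
        reports = [evaluate(a, b) for a, b in pairs]
        n = len(reports)
        if n == 0:
            return EvalReport(1.0, 1.0, 1.0, 0, 0, 0, None, None)
        accs = [r.value_acc for r in reports if r.value_acc is not None]
        stars = [r.value_acc_star for r in reports if r.value_acc_star is not None]
        return EvalReport(
            precision=sum(r.precision for r in reports) / n,
            recall=sum(r.recall for r in reports) / n,
            f1=sum(r.f1 for r in reports) / n,
            n_matches=sum(r.n_matches for r in reports),
            n_a=sum(r.n_a for r in reports),
            n_b=sum(r.n_b for r in reports),
            value_acc=sum(accs) / len(accs) if accs else None,
            value_acc_star=sum(stars) / len(stars) if stars else None,
        )

    matches = [lenient_match(a, b) for a, b in pairs]
    n_match = sum(len(m.pairs) for m in matches)
    n_a = sum(len(a) for a, _ in pairs)
    n_b = sum(len(b) for _, b in pairs)
    precision = n_match / n_a if n_a else 1.0
    recall = n_match / n_b if n_b else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    all_pairs = [p for m in matches for p in m.pairs]
    pooled = MatchSet("*", all_pairs, [], [])
    per_type = per_type_report(pooled) if all_pairs else []
    return EvalReport(
        precision=precision,
        recall=recall,
        f1=f1,
        n_matches=n_match,
        n_a=n_a,
        n_b=n_b,
        value_acc=value_accuracy(pooled),
        value_acc_star=relaxed_time_accuracy(pooled),
        per_type=per_type,
    )
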