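"""Four-stage corpus triage: document length, average line length, symptom
keyword presence, and time-expression count.

Thresholds follow the strict reading of the filter description: length and
average line length strictly greater than their thresholds, at least one
keyword, and strictly more than ``min_timex_count_exclusive`` extracted
time expressions.  The final retained set is invariant under stage-order
permutation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from .extraction import RuleSet, count_timexes
from .model import Document

__all__ = [
    "FilterConfig",
    "DocRecord",
    "StageReport",
    "FilterReport",
    "doc_stats",
    "keyword_count",
    "derive_percentile_thresholds",
    "filter_corpus",
    "default_keywords",
    "STAGE_NAMES",
]

STAGE_NAMES = ("length", "avg_line_length", "keyword", "timex_count")


def default_keywords() -> list[str]:
    """Packaged stand-in list of 26 psychosis symptom terms (the clinical
    source list is external and access-controlled; replace via config)."""
    ref = resources.files("clintimex").joinpath("data/psychosis_keywords.txt")
    text = ref.read_text(encoding="utf-8")
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


@dataclass
class FilterConfig:
    min_chars: int = 2000
    min_avg_line_chars: float = 30.0
    keywords: Sequence[str] = field(default_factory=default_keywords)
    min_timex_count_exclusive: int = 5
    percentile_mode: bool = False
    substring_keywords: bool = False  # default whole-word matching
    stage_order: Sequence[str] = STAGE_NAMES

    def __post_init__(self) -> None:
        if self.min_chars < 0 or self.min_avg_line_chars < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_timex_count_exclusive < 0:
            raise ValueError("timex threshold must be non-negative")
        if "keyword" in self.stage_order and not list(self.keywords):
            raise ValueError("keyword stage enabled with empty keyword list")
        unknown = set(self.stage_order) - set(STAGE_NAMES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class DocRecord:
    """Per-document filter measurements."""

    doc_id: str
    patient_id: Optional[str]
    char_length: int
    avg_line_length: float
    keyword_hits: int  # distinct matched terms
    keyword_occurrences: int  # total occurrences over all terms
    timex_count: int
    stage_pass: dict[str, bool] = field(default_factory=dict)

    @property
    def retained(self) -> bool:
        return all(self.stage_pass.values())


@dataclass
class StageReport:
    stage: str
    docs_in: int
    docs_out: int
    patients_out: int


@dataclass
class FilterReport:
    stages: list[StageReport]
    records: list[DocRecord]

    @property
    def retained_ids(self) -> list[str]:
        return [r.doc_id for r in self.records if r.retained]


def doc_stats(doc: Document) -> tuple[int, float]:
    """Total characters and mean characters per newline-split line (an
    empty trailing line is not counted)."""
    n = len(doc.text)
    if n == 0:
        return 0, 0.0
    lines = doc.text.split("\n")
    if lines and lines[-1] == "":
        lines = lines[:-1]
    if not lines:
        return n, 0.0
    return n, sum(len(ln) for ln in lines) / len(lines)


def keyword_count(doc: Document, keywords: Sequence[str], substring: bool = False) -> int:
    """Case-insensitive occurrence count summed over terms (whole-word by
    default)."""
    total = 0
    low = doc.text.lower()
    for kw in keywords:
        kw = kw.lower()
        if substring:
            total += low.count(kw)
        else:
            total += len(re.findall(rf"(?<!\w){re.escape(kw)}(?!\w)", low))
    return total


def _nearest_rank(values: Sequence[float], pct: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    if not values:
        raise ValueError("empty corpus")
    ordered = sorted(values)
    rank = max(1, math.ceil(pct / 100.0 * len(ordered)))
    return ordered[rank - 1]


def derive_percentile_thresholds(corpus: Sequence[Document]) -> tuple[int, float]:
    """(50th percentile of char length, 25th percentile of average line
    length), nearest-rank method."""
    if not corpus:
        raise ValueError("cannot derive thresholds from an empty corpus")
    stats = [doc_stats(d) for d in corpus]
    min_chars = int(_nearest_rank([s[0] for s in stats], 50.0))
    min_avg = float(_nearest_rank([s[1] for s in stats], 25.0))
    return min_chars, min_avg


def _measure(doc: Document, cfg: FilterConfig, rules: Optional[RuleSet]) -> DocRecord:
    length, avg_line = doc_stats(doc)
    low = doc.text.lower()
    hits = 0
    for kw in cfg.keywords:
        k = kw.lower()
        found = (k in low) if cfg.substring_keywords else bool(
            re.search(rf"(?<!\w){re.escape(k)}(?!\w)", low)
        )
        hits += int(found)
    occurrences = keyword_count(doc, cfg.keywords, cfg.substring_keywords)
    return DocRecord(
        doc_id=doc.doc_id,
        patient_id=doc.meta.get("patient_id"),
        char_length=length,
        avg_line_length=avg_line,
        keyword_hits=hits,
        keyword_occurrences=occurrences,
        timex_count=count_timexes(doc, rules),
    )


def filter_corpus(
    corpus: Sequence[Document],
    cfg: Optional[FilterConfig] = None,
    rules: Optional[RuleSet] = None,
) -> tuple[list[Document], FilterReport]:
    """Run the triage and return (retained documents, report).

    Stage predicates: char length > min_chars; average line length >
    min_avg_line_chars; keyword occurrences >= 1; timex count >
    min_timex_count_exclusive.  Stage order only affects the per-stage
    counts in the report, never the final set.
    """
    if cfg is None:
        cfg = FilterConfig()
    min_chars, min_avg = cfg.min_chars, cfg.min_avg_line_chars
    if cfg.percentile_mode:
        min_chars, min_avg = derive_percentile_thresholds(corpus)

    records = [_measure(d, cfg, rules) for d in corpus]
    predicates = {
        "length": lambda r: r.char_length > min_chars,
        "avg_line_length": lambda r: r.avg_line_length > min_avg,
        "keyword": lambda r: r.keyword_occurrences >= 1,
        "timex_count": lambda r: r.timex_count > cfg.min_timex_count_exclusive,
    }
    for rec in records:
        for stage in cfg.stage_order:
            rec.stage_pass[stage] = bool(predicates[stage](rec))

    stages: list[StageReport] = []
    alive = {r.doc_id for r in records}
    by_id = {r.doc_id: r for r in records}
    for stage in cfg.stage_order:
        docs_in = len(alive)
        alive = {i for i in alive if by_id[i].stage_pass[stage]}
        patients = {
            by_id[i].patient_id for i in alive if by_id[i].patient_id is not None
        }
        stages.append(StageReport(stage, docs_in, len(alive), len(patients)))

    retained = [d for d in corpus if d.doc_id in alive]
    return retained, FilterReport(stages=stages, records=records)
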