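"""Readers and writers: plain-text documents with a metadata table,
tab-separated standoff annotations, and a TIMEX3-XML adapter.

Standoff dialect (one annotation per ``T`` line, brat-like, 0-based
half-open offsets)::

    T1<TAB>DATE 10 18<TAB>oct 2009
    A1<TAB>value T1 2009-10
    #1<TAB>meta T1<TAB>{"rule": "date_month_year"}

The adapter never converts external TIMEX3 values into the canonical
scheme; non-canonical value strings are preserved verbatim.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import logging
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional, Union

from .model import (
    AnnotationSet,
    Document,
    RawValue,
    Span,
    TimeExpression,
    TimexType,
    ValueParseError,
    parse_value,
    serialize_value,
)

__all__ = [
    "read_documents",
    "write_documents",
    "write_standoff",
    "read_standoff",
    "read_timex3_xml",
]

logger = logging.getLogger("clintimex")


# ------------------------------------------------------------------ documents


def _read_metadata(path: Path) -> list[dict[str, str]]:
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or "doc_id" not in reader.fieldnames:
            raise ValueError(f"metadata table {path} lacks a doc_id column")
        return list(reader)


def read_documents(doc_dir: Union[str, Path], metadata: Union[str, Path]) -> list[Document]:
    """Load documents named ``<doc_id>.txt`` under ``doc_dir`` using a
    delimited metadata table with columns ``doc_id`` and optionally
    ``patient_id`` and ``dct`` (ISO date).

    Text is read exactly as on disk.  A missing DCT only logs a warning; a
    missing document file or malformed row is an error naming the row.
    """
    doc_dir = Path(doc_dir)
    docs = []
    for i, row in enumerate(_read_metadata(Path(metadata)), start=1):
        doc_id = (row.get("doc_id") or "").strip()
        if not doc_id:
            raise ValueError(f"metadata row {i}: empty doc_id")
        path = doc_dir / f"{doc_id}.txt"
        if not path.exists():
            raise FileNotFoundError(f"metadata row {i}: no document file for {doc_id!r}")
        text = path.read_text(encoding="utf-8")
        dct: Optional[_dt.date] = None
        raw_dct = (row.get("dct") or "").strip()
        if raw_dct:
            try:
                dct = _dt.date.fromisoformat(raw_dct)
            except ValueError as exc:
                raise ValueError(f"metadata row {i} ({doc_id}): bad dct {raw_dct!r}") from exc
        else:
            logger.warning("document %s has no DCT; relative expressions will not anchor", doc_id)
        meta = {
            k: v for k, v in row.items() if k not in ("doc_id", "dct") and v
        }
        docs.append(Document(doc_id=doc_id, text=text, dct=dct, meta=meta))
    return docs


def write_documents(docs: list[Document], doc_dir: Union[str, Path], metadata: Union[str, Path]) -> None:
    """Inverse of :func:`read_documents` (text files + metadata CSV/TSV)."""
    doc_dir = Path(doc_dir)
    doc_dir.mkdir(parents=True, exist_ok=True)
    metadata = Path(metadata)
    delim = "\t" if metadata.suffix.lower() in (".tsv", ".tab") else ","
    extra_keys = sorted({k for d in docs for k in d.meta})
    with open(metadata, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(["doc_id", "dct", *extra_keys])
        for d in docs:
            (doc_dir / f"{d.doc_id}.txt").write_text(d.text, encoding="utf-8")
            writer.writerow(
                [d.doc_id, d.dct.isoformat() if d.dct else "",
                 *[d.meta.get(k, "") for k in extra_keys]]
            )


# ------------------------------------------------------------------- standoff


def write_standoff(ann: AnnotationSet, path: Union[str, Path]) -> None:
    """Write an annotation set in the tab-separated standoff dialect.
    Byte-deterministic given identical input."""
    lines = []
    for i, tx in enumerate(ann, start=1):
        lines.append(f"T{i}\t{tx.type.value} {tx.span.start} {tx.span.end}\t{tx.surface}")
        if tx.value is not None:
            lines.append(f"A{i}\tvalue T{i} {serialize_value(tx.value)}")
        if tx.meta:
            blob = json.dumps(tx.meta, sort_keys=True)
            lines.append(f"#{i}\tmeta T{i}\t{blob}")
    Path(path).write_text("".join(ln + "\n" for ln in lines), encoding="utf-8")


def read_standoff(path: Union[str, Path], doc: Document) -> AnnotationSet:
    """Read standoff annotations back, validating offsets and surfaces
    against ``doc``.  Record order on disk does not matter."""
    spans: dict[str, TimeExpression] = {}
    values: dict[str, str] = {}
    metas: dict[str, dict] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        rid = fields[0]
        if rid.startswith("T"):
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: malformed span line")
            ttype, start, end = fields[1].split(" ")
            span = Span(int(start), int(end))
            if span.end > len(doc.text):
                raise ValueError(f"{path}:{lineno}: record {rid} offset outside document")
            surface = fields[2]
            if doc.text[span.start : span.end] != surface:
                raise ValueError(f"{path}:{lineno}: record {rid} surface mismatch")
            spans[rid] = TimeExpression(span=span, surface=surface, type=TimexType(ttype))
        elif rid.startswith("A"):
            _attr, target, raw = fields[1].split(" ", 2)
            values[target] = raw
        elif rid.startswith("#"):
            _tag, target = fields[1].split(" ", 1)
            metas[target] = json.loads(fields[2])
    ann = AnnotationSet(doc_id=doc.doc_id)
    for rid, tx in spans.items():
        if rid in values:
            tx.value = parse_value(values[rid], tx.type)
        if rid in metas:
            tx.meta = metas[rid]
        ann.add(tx)
    return ann


# ---------------------------------------------------------------- TIMEX3 XML

_TIMEX3_TYPE_MAP = {
    "DATE": TimexType.DATE,
    "TIME": TimexType.TIME,
    "DURATION": TimexType.DURATION,
    "FREQUENCY": TimexType.FREQUENCY,
    "SET": TimexType.FREQUENCY,
}


def read_timex3_xml(path: Union[str, Path]) -> tuple[Document, AnnotationSet]:
    """Read an i2b2-2012-style XML file: a ``TEXT`` element plus ``TIMEX3``
    tags with character offsets, a type and a ``val`` attribute.

    Unknown TIMEX3 types are logged and kept, tagged ``OTHER`` in the
    expression metadata; ``val`` strings outside the canonical grammar are
    preserved verbatim.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    text_el = root.find("TEXT")
    text = text_el.text or "" if text_el is not None else (root.text or "")
    doc = Document(doc_id=path.stem, text=text)
    ann = AnnotationSet(doc_id=doc.doc_id)
    for el in root.iter("TIMEX3"):
        start = int(el.get("start", el.get("START", "0")))
        end = int(el.get("end", el.get("END", "0")))
        surface = el.get("text", el.get("TEXT", ""))
        # tolerate 1-based offset exports
        if text[start:end] != surface and text[start - 1 : end - 1] == surface:
            start, end = start - 1, end - 1
        raw_type = (el.get("type", el.get("TYPE", "")) or "").upper()
        ttype = _TIMEX3_TYPE_MAP.get(raw_type)
        meta = {"timex3_type": raw_type}
        if ttype is None:
            logger.warning("%s: unknown TIMEX3 type %r kept as OTHER", path, raw_type)
            meta["other"] = "true"
            ttype = TimexType.DATE
        raw_val = el.get("val", el.get("VAL"))
        value = None
        if raw_val:
            try:
                value = parse_value(raw_val, ttype)
            except ValueParseError:
                value = RawValue(raw_val)
        if el.get("functionInDocument") == "CREATION_TIME" and raw_val:
            try:
                doc.dct = _dt.date.fromisoformat(raw_val[:10])
            except ValueError:
                pass
        try:
            span = Span(start, end)
        except ValueError:
            logger.warning("%s: TIMEX3 %s has unusable offsets [%s, %s); skipped",
                           path, el.get("id", "?"), start, end)
            continue
        ann.add(
            TimeExpression(
                span=span,
                surface=surface or text[start:end],
                type=ttype,
                value=value,
                meta=meta,
            )
        )
    return doc, ann
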