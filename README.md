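# clintimex

Rule-based time expression extraction, normalization, document triage and
evaluation for long clinical narratives (e.g. mental-health EHR notes),
plus a deterministic synthetic-corpus generator so the whole pipeline is
testable without any restricted data.

## What it does

- **Extraction** (`clintimex.extraction`): a regex rule engine detects time
  expression spans and assigns one of five types — `DATE`, `TIME`,
  `DURATION`, `FREQUENCY`, `AGE_RELATED`. Preposition-led expressions
  ("since 2007", "for 4 years") keep the preposition in the span and are
  typed `DURATION`; overlaps resolve longest-match-first, then by rule
  priority. The default ruleset ships in
  `src/clintimex/data/default_rules.yaml` and is replaceable.
- **Normalization** (`clintimex.normalization`): assigns canonical value
  strings — calendar values (`2009-10`, `2012-10-05`,
  `2011-03-14T18:00`), day parts (`TMO`/`TAF`/`TEV`/`TNI`), periods
  (`P4Y`, `PT15M`, vague `PXH`), bounded intervals (`SIN2007`,
  `UNT2018`), ranges (`(2009, 2012)`), age values (current `P45Y`, past
  `A15Y`) and categorical life-stage references (`CHILD_REF`,
  `TEENS_REF`, ...). Relative expressions anchor to the document creation
  time (DCT); the anchoring policy (structured field, first in-text date,
  or explicit override) and the numeric date order (DMY default / MDY)
  are configurable. Unknown surfaces get an explicit `UNRESOLVED` value,
  never dropped.
- **Filtering** (`clintimex.filtering`): four-stage corpus triage —
  character length > 2000, average line length > 30, at least one symptom
  keyword, more than 5 extracted time expressions. Thresholds are
  configurable (including a percentile mode that derives them from the
  corpus); the final retained set is invariant under stage order. The
  packaged 26-term keyword list is a stand-in for the access-controlled
  clinical list and is replaceable.
- **Evaluation** (`clintimex.evaluation`): lenient span F1 (any character
  overlap counts, exact maximum one-to-one matching), value accuracy on
  matching spans, relaxed Time accuracy (acc\*: Time values compared on the
  `Thh:mm` portion only), and a per-type breakdown.
- **Synthetic corpus** (`clintimex.synth`): seed-deterministic generator of
  gold-annotated clinical-style notes (header dates, past-history
  paragraphs, configurable type mixture with a minority of age-related
  references, relative-expression fraction, spelling noise), plus a
  simulated second annotator for agreement-style testing.
- **I/O** (`clintimex.io_formats`): plain-text documents with a CSV/TSV
  metadata table, a tab-separated brat-like standoff dialect (0-based,
  half-open offsets), and a TIMEX3-XML reader for i2b2-2012-style files
  (external values kept verbatim).

## CLI

```sh
# generate a gold-annotated synthetic corpus
clintimex synth --n-docs 20 --seed 1 --out corpus/

# extract + normalize into standoff files
clintimex tag --docs corpus/docs --metadata corpus/metadata.csv --out tagged/

# four-stage triage with a per-document report
clintimex filter --docs corpus/docs --metadata corpus/metadata.csv \
    --min-chars 2000 --min-avg-line 30 --min-timex 5 --report filter.tsv

# score system output against reference standoff annotations
clintimex evaluate tagged/ corpus/gold --docs corpus/docs \
    --metadata corpus/metadata.csv
```

## Value scheme notes

- `P45Y` is ambiguous between a 45-year duration and a current-age value;
  it is disambiguated by the carrying expression's type (`parse_value`
  takes the type as a hint), never by string inspection.
- `P3M` (3 months) vs `PT3M` (3 minutes) are separated by the `T` marker.
- Life-stage age ranges (e.g. `TEENS_REF` -> `(A13Y, A19Y)`) are exposed by
  `age_ref_to_range`; all boundaries except the teens pair are
  implementation defaults and user-overridable.
- Extension: "since age 3 months" normalizes to `SINA3M` (bounded past-age
  with month granularity); "since his teens" to `SINTEENS_REF` (bounded
  categorical).
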