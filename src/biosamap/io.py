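"""File formats: biosample gold tables, annotation tables, reports, tallies.

The gold-standard table is tab-separated with the six-column schema
``Biosample label, CLO ID, CL ID, UBERON ID, BTO ID, Type of concept``.
Empty cells and ``-`` denote an absent identifier on read; writing always
emits the empty string.  Concept-type tokens are CL / CT / A / empty
(cell line, cell type, anatomical structure, untyped); full words are
accepted on input.  Unknown trailing columns are ignored and logged,
except a ``Description`` column which is captured.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

from .annotators import AnnotationResult, parse_model_output
from .evaluation import (
    ConfusionCell,
    ConfusionTable,
    MetricsRow,
    NAMESPACES,
)
from .inference import ConceptType
from .ontology import TermId, TermIdError, parse_term_id

log = logging.getLogger(__name__)

BIOSAMPLES_HEADER = (
    "Biosample label",
    "CLO ID",
    "CL ID",
    "UBERON ID",
    "BTO ID",
    "Type of concept",
)

_CONCEPT_TOKENS = {
    "CL": ConceptType.CELL_LINE,
    "CT": ConceptType.CELL_TYPE,
    "A": ConceptType.ANATOMICAL_STRUCTURE,
    "": ConceptType.NONE,
    "-": ConceptType.NONE,
    "CELL LINE": ConceptType.CELL_LINE,
    "CELL TYPE": ConceptType.CELL_TYPE,
    "ANATOMICAL STRUCTURE": ConceptType.ANATOMICAL_STRUCTURE,
    "NO CONCEPT": ConceptType.NONE,
    "NONE": ConceptType.NONE,
}

_CONCEPT_ORDER = (
    ConceptType.CELL_LINE,
    ConceptType.CELL_TYPE,
    ConceptType.ANATOMICAL_STRUCTURE,
    ConceptType.NONE,
)


class SchemaError(ValueError):
    """Header or structure of an input file does not match the schema."""


class RowError(ValueError):
    """A data row cannot be parsed; the message carries the line number."""


class IntegrityError(ValueError):
    """Table-level constraint violated (e.g. duplicate labels)."""


@dataclass(frozen=True)
class BiosampleRecord:
    """One biosample label with its gold identifiers and concept type.

    ``source_id`` is provenance used by the synthetic generator (the term
    the entity was derived from); it is never read from or written to
    TSV files.
    """

    label: str
    gold: Mapping[str, Optional[TermId]]
    concept: ConceptType
    description: Optional[str] = None
    source_id: Optional[TermId] = field(default=None, compare=False)


def _open(source: Union[str, TextIO], mode: str = "r"):
    if isinstance(source, str):
        return open(source, mode, newline="", encoding="utf-8"), True
    return source, False


def _parse_cell(token: str, lineno: int) -> Optional[TermId]:
    token = token.strip()
    if token in ("", "-"):
        return None
    try:
        tid = parse_term_id(token)
    except TermIdError as exc:
        raise RowError(f"line {lineno}: {exc}") from exc
    return None if tid.is_placeholder else tid


def read_biosamples_tsv(source: Union[str, TextIO]) -> list[BiosampleRecord]:
    """Read a gold-standard table; rejects bad headers and duplicate labels."""
    fh, close = _open(source)
    try:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty file") from None
        expected = [h.casefold() for h in BIOSAMPLES_HEADER]
        got = [h.strip().casefold() for h in header[: len(expected)]]
        if got != expected:
            raise SchemaError(
                f"bad header {header[:6]!r}; expected {BIOSAMPLES_HEADER!r}"
            )
        extra = [h.strip() for h in header[len(expected) :]]
        desc_col = None
        for i, name in enumerate(extra):
            if name.casefold() == "description":
                desc_col = len(expected) + i
            else:
                log.info("ignoring unknown column %r", name)

        records: list[BiosampleRecord] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(c.strip() for c in row):
                continue
            if len(row) < 6:
                raise RowError(f"line {lineno}: expected 6 columns, got {len(row)}")
            label = row[0].strip()
            if not label:
                raise RowError(f"line {lineno}: empty label")
            if label in seen:
                raise IntegrityError(f"duplicate label {label!r} at line {lineno}")
            seen.add(label)
            gold = {
                ns: _parse_cell(row[i + 1], lineno)
                for i, ns in enumerate(NAMESPACES)
            }
            token = row[5].strip().upper()
            if token not in _CONCEPT_TOKENS:
                raise RowError(f"line {lineno}: unknown concept type {row[5]!r}")
            description = (
                row[desc_col].strip() or None
                if desc_col is not None and len(row) > desc_col
                else None
            )
            records.append(
                BiosampleRecord(
                    label=label,
                    gold=gold,
                    concept=_CONCEPT_TOKENS[token],
                    description=description,
                )
            )
        return records
    finally:
        if close:
            fh.close()


def write_biosamples_tsv(
    records: Iterable[BiosampleRecord], sink: Union[str, TextIO]
) -> None:
    """Write the gold table; absent identifiers render as empty cells."""
    fh, close = _open(sink, "w")
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(BIOSAMPLES_HEADER)
        for rec in records:
            writer.writerow(
                [rec.label]
                + [
                    (rec.gold.get(ns).render() if rec.gold.get(ns) else "")
                    for ns in NAMESPACES
                ]
                + [rec.concept.value if rec.concept is not ConceptType.NONE else ""]
            )
    finally:
        if close:
            fh.close()


ANNOTATIONS_HEADER = ("Biosample label", "Output", "Annotator")


def write_annotations_tsv(
    results: Iterable[AnnotationResult], sink: Union[str, TextIO]
) -> None:
    """Write annotator outputs as raw bracketed lists (or raw failure text)."""
    fh, close = _open(sink, "w")
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATIONS_HEADER)
        for r in results:
            writer.writerow([r.label, r.raw_output.replace("\n", " "), r.annotator_id])
    finally:
        if close:
            fh.close()


def read_annotations_tsv(source: Union[str, TextIO]) -> list[AnnotationResult]:
    """Read annotator outputs, re-parsing format validity from the raw text."""
    fh, close = _open(source)
    try:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.casefold() for h in header[:2]] != [
            h.casefold() for h in ANNOTATIONS_HEADER[:2]
        ]:
            raise SchemaError(f"bad annotations header: {header!r}")
        results = []
        for row in reader:
            if not row:
                continue
            raw = row[1]
            proposed, ok = parse_model_output(raw)
            results.append(
                AnnotationResult(
                    label=row[0],
                    proposed=proposed,
                    format_ok=ok,
                    raw_output=raw,
                    annotator_id=row[2] if len(row) > 2 else "unknown",
                )
            )
        return results
    finally:
        if close:
            fh.close()


def round3(value: Optional[float]) -> str:
    """Half-up rounding to 3 decimals for report display; '' for absent."""
    if value is None:
        return ""
    return str(Decimal(repr(value)).quantize(Decimal("0.001"), ROUND_HALF_UP))


REPORT_HEADER = (
    "Concept",
    "Ontology",
    "I",
    "R",
    "C",
    "E",
    "IC",
    "FN",
    "TN",
    "Disregarded",
    "Precision",
    "Recall",
    "F1",
    "Accuracy",
    "PerfectMatchRatio",
)


def write_report(
    tables: Mapping[tuple[str, ConceptType], ConfusionTable],
    metrics: Mapping[tuple[str, ConceptType], MetricsRow],
    sink: Union[str, TextIO],
    perfect_match: Optional[Mapping[ConceptType, Optional[float]]] = None,
) -> None:
    """Write the per-scope confusion counts and metrics as a TSV.

    Rows are ordered by concept type (cell line, cell type, anatomical
    structure, untyped) then namespace (CLO, CL, UBERON, BTO); metric
    display is rounded half-up to 3 decimals; the perfect match ratio is
    shown on the first row of each concept block.  Output is
    deterministic: identical inputs yield identical bytes.
    """
    perfect_match = perfect_match or {}
    fh, close = _open(sink, "w")
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_HEADER)
        for concept in _CONCEPT_ORDER:
            first = True
            for ns in NAMESPACES:
                scope = (ns, concept)
                if scope not in tables:
                    continue
                t = tables[scope]
                m = metrics.get(scope)
                pmr = perfect_match.get(concept) if first else None
                writer.writerow(
                    [
                        concept.value,
                        ns,
                        t[ConfusionCell.TP_I],
                        t[ConfusionCell.TP_R],
                        t[ConfusionCell.TP_C],
                        t[ConfusionCell.FP_E],
                        t[ConfusionCell.FP_IC],
                        t[ConfusionCell.FN],
                        t[ConfusionCell.TN],
                        t.disregarded,
                        round3(m.precision) if m else "",
                        round3(m.recall) if m else "",
                        round3(m.f1) if m else "",
                        round3(m.accuracy) if m else "",
                        round3(pmr),
                    ]
                )
                first = False
    finally:
        if close:
            fh.close()


TALLIES_HEADER = (
    "Concept",
    "Ontology",
    "I",
    "R",
    "C",
    "E",
    "IC",
    "FN",
    "TN",
    "Disregarded",
)


def read_tallies_tsv(
    source: Union[str, TextIO]
) -> dict[tuple[str, ConceptType], ConfusionTable]:
    """Read pre-tallied confusion counts (worked-example fixtures)."""
    fh, close = _open(source)
    try:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.casefold() for h in header] != [
            h.casefold() for h in TALLIES_HEADER
        ]:
            raise SchemaError(f"bad tallies header: {header!r}")
        tables: dict[tuple[str, ConceptType], ConfusionTable] = {}
        for row in reader:
            if not row:
                continue
            concept = _CONCEPT_TOKENS[row[0].strip().upper()]
            ns = row[1].strip()
            i, r, c, e, ic, fn, tn, dis = (int(x) for x in row[2:10])
            tables[(ns, concept)] = ConfusionTable.from_counts(
                (ns, concept), i, r, c, e, ic, fn, tn, disregarded=dis
            )
        return tables
    finally:
        if close:
            fh.close()


def write_agreement_report(
    rows: Mapping[str, Mapping[str, Optional[float]]],
    sink: Union[str, TextIO],
) -> None:
    """Write per-ontology agreement statistics (kappa, p_o, p_e, soft ratio)."""
    fh, close = _open(sink, "w")
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["Ontology", "SoftAgreement", "CohensKappa", "p_o", "p_e"])
        for ns in NAMESPACES:
            if ns not in rows:
                continue
            r = rows[ns]
            writer.writerow(
                [
                    ns,
                    round3(r.get("soft_agreement")),
                    round3(r.get("kappa")),
                    round3(r.get("p_o")),
                    round3(r.get("p_e")),
                ]
            )
    finally:
        if close:
            fh.close()
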