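"""Relationship-aware evaluation of annotation proposals.

Each (label, ontology) proposal is classified against the gold standard
into a seven-cell confusion taxonomy:

* ``TP_I`` — proposed identifier identical to the reference;
* ``TP_R`` — not identical, but in a valid relationship with it (same
  entity under a different name, or a hypernym of the reference);
* ``TP_C`` — a valid identifier contributed where the gold standard has
  none;
* ``FP_E`` — a wrong or hallucinated identifier (model error);
* ``FP_IC`` — an invalid contribution in the absence of a reference;
* ``FN`` — no identifier proposed although the reference has one;
* ``TN`` — neither side has an identifier.

With TP = TP_I + TP_R + TP_C and FP = FP_E + FP_IC:

    precision = TP / (TP + FP)          recall = TP / (TP + FN)
    F1 = 2 TP / (2 TP + FP + FN)        accuracy = (TP + TN) / total

The *perfect match ratio* for a concept type is the fraction of its
labels with true-positive outcomes in BOTH priority ontologies.

Contributions (reference absent) are adjudicated automatically: a
proposal is valid when it resolves in its ontology and its inferred
identifiers are consistent with the label's gold values in the other
namespaces; a manual-override table can adjudicate any (label,
namespace, proposal) directly, taking precedence.
"""

from __future__ import annotations

import csv
import logging
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Optional, Sequence, TYPE_CHECKING

from .inference import (
    ConceptType,
    DEFAULT_PRIORITIES,
    GranularityError,
    PriorityMap,
    infer_identifiers,
)
from .ontology import OntologyGraph, TermId, is_ancestor, parse_term_id

if TYPE_CHECKING:  # pragma: no cover
    from .annotators import AnnotationResult
    from .io import BiosampleRecord

log = logging.getLogger(__name__)

NAMESPACES: tuple[str, ...] = ("CLO", "CL", "UBERON", "BTO")


class ConfusionCell(Enum):
    TP_I = "I"
    TP_R = "R"
    TP_C = "C"
    FP_E = "E"
    FP_IC = "IC"
    FN = "FN"
    TN = "TN"


TRUE_POSITIVE_CELLS = frozenset(
    {ConfusionCell.TP_I, ConfusionCell.TP_R, ConfusionCell.TP_C}
)
FALSE_POSITIVE_CELLS = frozenset({ConfusionCell.FP_E, ConfusionCell.FP_IC})


class Relationship(Enum):
    IDENTICAL = "identical"
    VALID = "valid"
    INVALID = "invalid"


class ReconciliationError(ValueError):
    """Annotated labels do not reconcile with the gold table."""


_PUNCT_RE = re.compile(r"[^\w\s]|_", flags=re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize_name(text: str) -> str:
    """Canonical form for class-name comparison.

    Casefolded, punctuation (including hyphens) removed without inserting
    spaces — so "meso-epithelial cell" and "mesoepithelial cell" coincide
    — and whitespace collapsed.
    """
    text = unicodedata.normalize("NFKC", text).casefold()
    text = _PUNCT_RE.sub("", text)
    return _WS_RE.sub(" ", text).strip()


@dataclass
class Overrides:
    """Manual adjudication of relationship validity.

    Keyed by (label, namespace, proposed identifier); verdict True marks
    the proposal VALID, False INVALID.  Mirrors a curator's review of
    non-identical proposals and of model contributions.
    """

    rules: dict[tuple[str, str, TermId], bool] = field(default_factory=dict)

    def lookup(
        self, label: Optional[str], namespace: str, proposed: TermId
    ) -> Optional[bool]:
        if label is None:
            return None
        return self.rules.get((label, namespace, proposed))

    def add(
        self, label: str, namespace: str, proposed: TermId, valid: bool,
    ) -> None:
        self.rules[(label, namespace, proposed)] = valid

    @classmethod
    def from_tsv(cls, source) -> "Overrides":
        """Read a TSV of (label, namespace, proposed id, VALID|INVALID, note)."""
        close = False
        if isinstance(source, str):
            source = open(source, newline="", encoding="utf-8")
            close = True
        try:
            rules: dict[tuple[str, str, TermId], bool] = {}
            for row in csv.reader(source, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                label, ns, pid, verdict = row[0], row[1], row[2], row[3]
                rules[(label, ns, parse_term_id(pid))] = (
                    verdict.strip().upper() == "VALID"
                )
            return cls(rules)
        finally:
            if close:
                source.close()

    def to_tsv(self, sink) -> None:
        writer = csv.writer(sink, delimiter="\t", lineterminator="\n")
        for (label, ns, pid), valid in sorted(
            self.rules.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
        ):
            writer.writerow(
                [label, ns, pid.render(), "VALID" if valid else "INVALID", ""]
            )


def relationship(
    proposed: TermId,
    reference: TermId,
    graph: OntologyGraph,
    overrides: Optional[Overrides] = None,
    label: Optional[str] = None,
) -> Relationship:
    """Relationship of a proposed identifier to the reference (same namespace).

    IDENTICAL for equal identifiers; VALID when an override says so, when
    the two terms share a normalized name or synonym (same entity,
    different name), or when the proposal is a strict ancestor — a
    hypernym — of the reference; INVALID otherwise, including proposals
    that are strict descendants (a finer claim than the reference
    supports) and unresolvable proposals (hallucinated identifiers).
    """
    if proposed.prefix != reference.prefix:
        raise ValueError(
            f"cross-namespace comparison: {proposed.render()} vs "
            f"{reference.render()}"
        )
    if proposed == reference:
        return Relationship.IDENTICAL
    if overrides is not None:
        verdict = overrides.lookup(label, proposed.prefix, proposed)
        if verdict is not None:
            return Relationship.VALID if verdict else Relationship.INVALID
    prop_term = graph.get(proposed)
    if prop_term is None or proposed.is_placeholder:
        log.debug(
            "unresolvable proposed identifier %s (hallucination)",
            proposed.render(),
        )
        return Relationship.INVALID
    ref_term = graph.get(reference)
    if ref_term is not None:
        prop_names = {normalize_name(s) for s in prop_term.labels()}
        ref_names = {normalize_name(s) for s in ref_term.labels()}
        if prop_names & ref_names - {""}:
            return Relationship.VALID
        if is_ancestor(graph, proposed, reference):
            return Relationship.VALID
    return Relationship.INVALID


def classify_outcome(
    proposed: Optional[TermId],
    reference: Optional[TermId],
    graph: OntologyGraph,
    overrides: Optional[Overrides] = None,
    label: Optional[str] = None,
    contribution_check: Optional[Callable[[TermId], bool]] = None,
) -> ConfusionCell:
    """Map one (proposal, reference) pair to its confusion cell.

    *contribution_check* adjudicates proposals made in the absence of a
    reference (see :func:`make_contribution_check`); overrides take
    precedence over it.  Without either, contributions count as invalid.
    """
    if proposed is not None and proposed.is_placeholder:
        proposed = None
    if reference is not None and reference.is_placeholder:
        reference = None

    if proposed is not None and reference is not None:
        rel = relationship(proposed, reference, graph, overrides, label)
        return {
            Relationship.IDENTICAL: ConfusionCell.TP_I,
            Relationship.VALID: ConfusionCell.TP_R,
            Relationship.INVALID: ConfusionCell.FP_E,
        }[rel]
    if proposed is not None:
        if overrides is not None:
            verdict = overrides.lookup(label, proposed.prefix, proposed)
            if verdict is not None:
                return ConfusionCell.TP_C if verdict else ConfusionCell.FP_IC
        if (
            contribution_check is not None
            and graph.get(proposed) is not None
            and contribution_check(proposed)
        ):
            return ConfusionCell.TP_C
        return ConfusionCell.FP_IC
    if reference is not None:
        return ConfusionCell.FN
    return ConfusionCell.TN


def make_contribution_check(
    record: "BiosampleRecord",
    graphs: Mapping[str, OntologyGraph],
    priorities: PriorityMap = DEFAULT_PRIORITIES,
) -> Callable[[TermId], bool]:
    """Automated adjudication of a contribution for one gold record.

    A contributed identifier is held valid when it resolves, its
    namespace is derivable for the label's concept type, and the
    identifiers inferred from it agree (identical or valid relationship)
    with the label's gold values in at least one other namespace, with no
    disagreement.  Untyped labels define no derivation order, so their
    contributions require a manual override.
    """

    def check(proposed: TermId) -> bool:
        if record.concept is ConceptType.NONE:
            return False
        try:
            inferred = infer_identifiers(
                graphs, proposed, record.concept, priorities
            )
        except GranularityError:
            return False
        corroborated = 0
        for ns, inf_id in inferred.items():
            if ns == proposed.prefix or inf_id is None:
                continue
            gold_id = record.gold.get(ns)
            if gold_id is None:
                continue
            rel = relationship(inf_id, gold_id, graphs[ns])
            if rel is Relationship.INVALID:
                return False
            corroborated += 1
        return corroborated > 0

    return check


@dataclass
class ConfusionTable:
    """Seven-cell counts for one (namespace, concept type) scope."""

    scope: tuple[str, ConceptType]
    counts: Counter = field(default_factory=Counter)
    disregarded: int = 0

    def add(self, cell: ConfusionCell, n: int = 1) -> None:
        self.counts[cell] += n

    def __getitem__(self, cell: ConfusionCell) -> int:
        return self.counts.get(cell, 0)

    @property
    def tp(self) -> int:
        return sum(self.counts.get(c, 0) for c in TRUE_POSITIVE_CELLS)

    @property
    def fp(self) -> int:
        return sum(self.counts.get(c, 0) for c in FALSE_POSITIVE_CELLS)

    @property
    def fn(self) -> int:
        return self.counts.get(ConfusionCell.FN, 0)

    @property
    def tn(self) -> int:
        return self.counts.get(ConfusionCell.TN, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_counts(
        cls,
        scope: tuple[str, ConceptType],
        i: int = 0,
        r: int = 0,
        c: int = 0,
        e: int = 0,
        ic: int = 0,
        fn: int = 0,
        tn: int = 0,
        disregarded: int = 0,
    ) -> "ConfusionTable":
        return cls(
            scope=scope,
            counts=Counter(
                {
                    ConfusionCell.TP_I: i,
                    ConfusionCell.TP_R: r,
                    ConfusionCell.TP_C: c,
                    ConfusionCell.FP_E: e,
                    ConfusionCell.FP_IC: ic,
                    ConfusionCell.FN: fn,
                    ConfusionCell.TN: tn,
                }
            ),
            disregarded=disregarded,
        )


@dataclass(frozen=True)
class MetricsRow:
    """Proportions computed from one confusion table; None for 0/0."""

    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    accuracy: Optional[float]
    perfect_match_ratio: Optional[float] = None


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def compute_metrics(table: ConfusionTable) -> MetricsRow:
    """Precision, recall, F1 and accuracy from aggregated TP/FP/FN/TN."""
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    return MetricsRow(
        precision=_ratio(tp, tp + fp),
        recall=_ratio(tp, tp + fn),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        accuracy=_ratio(tp + tn, tp + fp + fn + tn),
    )


def perfect_match_ratio(
    outcomes: Mapping[str, Mapping[str, ConfusionCell]],
    concept: ConceptType,
    priorities: PriorityMap = DEFAULT_PRIORITIES,
) -> float:
    """Fraction of labels with TP outcomes in both priority ontologies.

    *outcomes* maps each evaluated label of the concept type to its
    per-namespace confusion cells.  Untyped labels have no priority pair,
    so the ratio is undefined for them.
    """
    if concept is ConceptType.NONE:
        raise GranularityError(
            "perfect match ratio undefined for untyped labels"
        )
    first, second = priorities.priority[concept]
    if not outcomes:
        raise ValueError("no evaluated labels for perfect match ratio")
    hits = sum(
        1
        for cells in outcomes.values()
        if cells.get(first) in TRUE_POSITIVE_CELLS
        and cells.get(second) in TRUE_POSITIVE_CELLS
    )
    return hits / len(outcomes)


@dataclass
class EvaluationReport:
    """Stratified confusion tables, metrics, and per-label outcomes."""

    tables: dict[tuple[str, ConceptType], ConfusionTable]
    outcomes: dict[str, dict[str, ConfusionCell]]
    concepts: dict[str, ConceptType]
    priorities: PriorityMap = DEFAULT_PRIORITIES

    def metrics(self) -> dict[tuple[str, ConceptType], MetricsRow]:
        """Per-scope metrics; untyped scopes report precision only."""
        rows: dict[tuple[str, ConceptType], MetricsRow] = {}
        for scope, table in self.tables.items():
            row = compute_metrics(table)
            if scope[1] is ConceptType.NONE:
                row = MetricsRow(
                    precision=row.precision,
                    recall=None,
                    f1=None,
                    accuracy=None,
                )
            rows[scope] = row
        return rows

    def outcomes_for(
        self, concept: ConceptType
    ) -> dict[str, dict[str, ConfusionCell]]:
        return {
            label: cells
            for label, cells in self.outcomes.items()
            if self.concepts[label] is concept
        }

    def perfect_match_ratios(self) -> dict[ConceptType, Optional[float]]:
        out: dict[ConceptType, Optional[float]] = {}
        for concept in (
            ConceptType.CELL_LINE,
            ConceptType.CELL_TYPE,
            ConceptType.ANATOMICAL_STRUCTURE,
        ):
            scoped = self.outcomes_for(concept)
            out[concept] = (
                perfect_match_ratio(scoped, concept, self.priorities)
                if scoped
                else None
            )
        return out

    def disregarded(self, concept: ConceptType) -> int:
        for (ns, ct), table in self.tables.items():
            if ct is concept:
                return table.disregarded
        return 0


def stratify(
    results: Sequence["AnnotationResult"],
    gold: Mapping[str, "BiosampleRecord"],
    graphs: Mapping[str, OntologyGraph],
    overrides: Optional[Overrides] = None,
    priorities: PriorityMap = DEFAULT_PRIORITIES,
    namespaces: Iterable[str] = NAMESPACES,
) -> EvaluationReport:
    """Classify every result against *gold*, per (namespace, concept type).

    Format-failed results are routed to the scope's ``disregarded``
    counter and excluded from the cells.  Every annotated label must
    exist in the gold table.
    """
    missing = sorted({r.label for r in results} - set(gold))
    if missing:
        raise ReconciliationError(
            f"annotated labels missing from gold table: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    namespaces = tuple(namespaces)
    tables: dict[tuple[str, ConceptType], ConfusionTable] = {}
    outcomes: dict[str, dict[str, ConfusionCell]] = {}
    concepts: dict[str, ConceptType] = {}

    def table(ns: str, concept: ConceptType) -> ConfusionTable:
        key = (ns, concept)
        if key not in tables:
            tables[key] = ConfusionTable(scope=key)
        return tables[key]

    for result in results:
        record = gold[result.label]
        concepts[result.label] = record.concept
        if not result.format_ok:
            for ns in namespaces:
                table(ns, record.concept).disregarded += 1
            continue
        check = make_contribution_check(record, graphs, priorities)
        cells: dict[str, ConfusionCell] = {}
        for ns in namespaces:
            cell = classify_outcome(
                result.proposed.get(ns),
                record.gold.get(ns),
                graphs[ns],
                overrides=overrides,
                label=result.label,
                contribution_check=check,
            )
            table(ns, record.concept).add(cell)
            cells[ns] = cell
        outcomes[result.label] = cells

    log.info(
        "stratified %d results (%d disregarded) into %d scopes",
        len(results),
        sum(1 for r in results if not r.format_ok),
        len(tables),
    )
    return EvaluationReport(
        tables=tables, outcomes=outcomes, concepts=concepts,
        priorities=priorities,
    )
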