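"""Concept-type-aware identifier inference across ontologies.

A biosample label names a cell line, a cell type, or an anatomical
structure.  From an identifier at one granularity, identifiers in
coarser-or-equal ontologies can be derived through cross-ontology links
(a cell line implies its cell type and tissue of origin), but never the
reverse: a cell-type identifier does not determine which cell line — if
any — the sample came from.

The derivation order per concept type:

* cell line:            CLO -> CL -> UBERON -> BTO
* cell type:            CL -> UBERON -> BTO
* anatomical structure: UBERON -> BTO

CLO and BTO are the *priority* ontologies for cell lines (both carry
identifiers for specific lines), CL and BTO for cell types, UBERON and
BTO for anatomical structures; untyped labels treat all four as equal
and support no inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

from .ontology import OntologyGraph, TermId, cross_links

log = logging.getLogger(__name__)


class ConceptType(Enum):
    """Category of entity a biosample label denotes."""

    CELL_LINE = "CL"
    CELL_TYPE = "CT"
    ANATOMICAL_STRUCTURE = "A"
    NONE = "-"


class GranularityError(ValueError):
    """Namespace is not derivable for the given concept type."""


@dataclass(frozen=True)
class PriorityMap:
    """Priority pair and derivation order per concept type.

    ``priority`` gives the two ontologies whose joint true positives
    define a perfect match; ``derivable`` the fine-to-coarse namespaces
    inferable for that concept type.  Untyped labels rank all four
    namespaces equal and have no priority pair.
    """

    priority: Mapping[ConceptType, tuple[str, str]] = field(
        default_factory=lambda: {
            ConceptType.CELL_LINE: ("CLO", "BTO"),
            ConceptType.CELL_TYPE: ("CL", "BTO"),
            ConceptType.ANATOMICAL_STRUCTURE: ("UBERON", "BTO"),
        }
    )
    derivable: Mapping[ConceptType, tuple[str, ...]] = field(
        default_factory=lambda: {
            ConceptType.CELL_LINE: ("CLO", "CL", "UBERON", "BTO"),
            ConceptType.CELL_TYPE: ("CL", "UBERON", "BTO"),
            ConceptType.ANATOMICAL_STRUCTURE: ("UBERON", "BTO"),
            ConceptType.NONE: ("CLO", "CL", "UBERON", "BTO"),
        }
    )


DEFAULT_PRIORITIES = PriorityMap()


def granularity_rank(
    prefix: str,
    concept: ConceptType,
    priorities: PriorityMap = DEFAULT_PRIORITIES,
) -> int:
    """Position of *prefix* in the concept's derivation order (0 = finest).

    For untyped labels every known namespace ranks equal (0).
    """
    order = priorities.derivable[concept]
    if prefix not in order:
        raise GranularityError(
            f"namespace {prefix} is not derivable for {concept.name}"
        )
    if concept is ConceptType.NONE:
        return 0
    return order.index(prefix)


def infer_identifiers(
    graphs: Mapping[str, OntologyGraph],
    source: TermId,
    concept: ConceptType,
    priorities: PriorityMap = DEFAULT_PRIORITIES,
) -> dict[str, Optional[TermId]]:
    """Derive identifiers in coarser-or-equal namespaces from *source*.

    Returns one entry per namespace in the concept's derivation order:
    the source itself for its own namespace, the unique cross-link target
    for each coarser namespace, and ``None`` for namespaces finer than
    the source, for untyped labels, or when cross-link evidence is absent
    or ambiguous (multiple candidates yield ``None`` plus a logged
    diagnostic, never an arbitrary pick).

    When the source has no cross-link for a target namespace, the walk
    chains through already-inferred finer identifiers (cell line -> cell
    type -> anatomical structure), mirroring how a tissue is reached from
    a cell line via its cell type.
    """
    order = priorities.derivable[concept]
    if source.prefix not in order:
        raise GranularityError(
            f"source namespace {source.prefix} not derivable for {concept.name}"
        )
    graphs[source.prefix].require(source)

    out: dict[str, Optional[TermId]] = {ns: None for ns in order}
    out[source.prefix] = source
    if concept is ConceptType.NONE:
        return out

    source_rank = order.index(source.prefix)
    for rank, ns in enumerate(order):
        if rank <= source_rank or ns == source.prefix:
            continue
        anchors = [source] + [
            out[p] for p in order[source_rank + 1 : rank] if out[p] is not None
        ]
        candidates: set[TermId] = set()
        for anchor in anchors:
            candidates = cross_links(graphs, anchor, ns)
            if candidates:
                break
        if len(candidates) == 1:
            out[ns] = next(iter(candidates))
        elif len(candidates) > 1:
            log.info(
                "ambiguous cross-links from %s to %s: %s; leaving absent",
                source.render(),
                ns,
                sorted(c.render() for c in candidates),
            )
    return out
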