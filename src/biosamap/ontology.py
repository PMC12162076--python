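"""Ontology storage and queries.

Loads OBO-format ontology graphs (CLO, CL, UBERON, BTO in the default
profile), resolves identifiers to class names, and answers the hierarchy
and cross-ontology-link queries needed by the relationship validator and
the identifier-inference engine.

Identifiers follow the underscore CURIE dialect used throughout biosample
annotation data (``CLO_0001200``); the colon form ``CLO:0001200`` found in
OBO files is accepted on input and normalized on rendering.  An identifier
whose local part is all zeros (``CLO_0000000``) is a recognized
*placeholder* meaning "no identifier": it parses, but never resolves to a
term.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional

import networkx as nx
import obonet

#: Namespace tokens of the default ontology profile, finest-to-coarsest
#: for cell-line concepts.
DEFAULT_PREFIXES: tuple[str, ...] = ("CLO", "CL", "UBERON", "BTO")

#: Width of the zero-padded numeric local part of a CURIE.
LOCAL_WIDTH = 7

_CURIE_RE = re.compile(r"^([A-Za-z]+)[_:](\d+)$")
_SYNONYM_RE = re.compile(r'"(.*?)"')


class TermIdError(ValueError):
    """Malformed identifier text."""


class UnknownPrefixError(TermIdError):
    """Identifier uses a namespace prefix outside the configured profile."""


class OntologyLoadError(ValueError):
    """The OBO source cannot be turned into a valid ontology graph."""


class CycleError(OntologyLoadError):
    """is_a edges contain a cycle."""


class DanglingParentError(OntologyLoadError):
    """A term references an is_a parent absent from the file."""


class MissingTermError(KeyError):
    """A query referenced an identifier not present in the graph."""


@dataclass(frozen=True, order=True)
class TermId:
    """An ontology term identifier, e.g. ``TermId("CLO", "0001200")``."""

    prefix: str
    local: str

    def __post_init__(self) -> None:
        if not (self.local.isdigit() and len(self.local) == LOCAL_WIDTH):
            raise TermIdError(
                f"local part must be {LOCAL_WIDTH} digits, got {self.local!r}"
            )

    @property
    def is_placeholder(self) -> bool:
        """True for all-zero identifiers, which never denote a real term."""
        return set(self.local) == {"0"}

    def render(self) -> str:
        """Canonical underscore form, e.g. ``"CLO_0001200"``."""
        return f"{self.prefix}_{self.local}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def placeholder(prefix: str) -> TermId:
    """The all-zero placeholder identifier for *prefix*."""
    return TermId(prefix, "0" * LOCAL_WIDTH)


def parse_term_id(
    text: str, prefixes: Iterable[str] = DEFAULT_PREFIXES
) -> TermId:
    """Parse underscore- or colon-form CURIE text into a :class:`TermId`.

    Raises :class:`TermIdError` for malformed text and
    :class:`UnknownPrefixError` for a well-formed CURIE whose prefix is not
    in *prefixes*.
    """
    if not text:
        raise TermIdError("empty identifier text")
    m = _CURIE_RE.match(text.strip())
    if m is None:
        raise TermIdError(f"malformed identifier: {text!r}")
    prefix, local = m.group(1), m.group(2)
    if len(local) != LOCAL_WIDTH:
        raise TermIdError(
            f"identifier {text!r}: local part must be {LOCAL_WIDTH} digits"
        )
    if prefix not in set(prefixes):
        raise UnknownPrefixError(f"unknown ontology prefix in {text!r}")
    return TermId(prefix, local)


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology class: name, synonyms, is_a parents, cross-references."""

    id: TermId
    name: str
    synonyms: frozenset[str] = frozenset()
    parents: frozenset[TermId] = frozenset()
    xrefs: frozenset[TermId] = frozenset()
    obsolete: bool = False

    def labels(self) -> frozenset[str]:
        """Primary name plus synonyms."""
        return self.synonyms | {self.name}


@dataclass
class OntologyGraph:
    """One ontology's terms with validated is_a DAG structure."""

    prefix: str
    terms: dict[TermId, OntologyTerm]
    _remote_cache: dict[TermId, Optional[str]] = field(
        default_factory=dict, repr=False
    )

    def __contains__(self, term_id: TermId) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def get(self, term_id: TermId) -> Optional[OntologyTerm]:
        return self.terms.get(term_id)

    def require(self, term_id: TermId) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise MissingTermError(
                f"{term_id.render()} not in {self.prefix} graph"
            ) from None

    def parents(self, term_id: TermId) -> frozenset[TermId]:
        return self.require(term_id).parents

    def ancestors(self, term_id: TermId) -> set[TermId]:
        """All strict ancestors of *term_id* through is_a edges."""
        self.require(term_id)
        seen: set[TermId] = set()
        queue = deque(self.terms[term_id].parents)
        while queue:
            cur = queue.popleft()
            if cur in seen:
                continue
            seen.add(cur)
            queue.extend(self.terms[cur].parents)
        return seen

    def ancestor_levels(self, term_id: TermId) -> list[set[TermId]]:
        """Ancestors grouped by shortest is_a distance, nearest first."""
        self.require(term_id)
        levels: list[set[TermId]] = []
        seen: set[TermId] = {term_id}
        frontier = set(self.terms[term_id].parents) - seen
        while frontier:
            levels.append(frontier)
            seen |= frontier
            nxt: set[TermId] = set()
            for t in frontier:
                nxt |= self.terms[t].parents
            frontier = nxt - seen
        return levels


def load_ontology(
    source,
    prefix: str,
    known_prefixes: Iterable[str] = DEFAULT_PREFIXES,
) -> OntologyGraph:
    """Load one ontology from an OBO stream or path.

    Only ``[Term]`` stanzas whose id carries *prefix* are loaded; terms of
    other prefixes in the same file are ignored except as xref targets.
    is_a edges must form a DAG over loaded terms, and every referenced
    same-prefix parent must exist.
    """
    known = tuple(dict.fromkeys(list(known_prefixes) + [prefix]))
    raw = obonet.read_obo(source, ignore_obsolete=False)

    terms: dict[TermId, OntologyTerm] = {}
    for node, data in raw.nodes(data=True):
        if "name" not in data and not data.get("is_obsolete"):
            # node materialized only as an edge target; handled below
            continue
        try:
            tid = parse_term_id(node, known)
        except TermIdError:
            continue
        if tid.prefix != prefix:
            continue
        synonyms = frozenset(
            m.group(1)
            for s in data.get("synonym", ())
            for m in [_SYNONYM_RE.search(s)]
            if m
        )
        parents = []
        for p in data.get("is_a", ()):
            p = p.split("!")[0].strip()
            try:
                pid = parse_term_id(p, known)
            except TermIdError:
                continue
            if pid.prefix == prefix:
                parents.append(pid)
        xrefs = []
        for x in data.get("xref", ()):
            x = x.split('"')[0].strip()
            try:
                xid = parse_term_id(x, known)
            except TermIdError:
                continue
            if xid.prefix != prefix:
                xrefs.append(xid)
        terms[tid] = OntologyTerm(
            id=tid,
            name=data.get("name", ""),
            synonyms=synonyms,
            parents=frozenset(parents),
            xrefs=frozenset(xrefs),
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
        )

    for term in terms.values():
        for pid in term.parents:
            if pid not in terms:
                raise DanglingParentError(
                    f"{term.id.render()} lists parent {pid.render()} "
                    f"absent from the {prefix} source"
                )

    dag = nx.DiGraph(
        (t.id, p) for t in terms.values() for p in t.parents
    )
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        pretty = " -> ".join(e[0].render() for e in cycle)
        raise CycleError(f"is_a cycle in {prefix}: {pretty}")

    return OntologyGraph(prefix=prefix, terms=terms)


def dump_obo(graph: OntologyGraph, sink) -> None:
    """Write the graph back out as OBO [Term] stanzas (stable order)."""
    close = False
    if isinstance(sink, str):
        sink = open(sink, "w", encoding="utf-8")
        close = True
    try:
        sink.write("format-version: 1.2\n")
        sink.write(f"ontology: {graph.prefix.lower()}\n")
        for tid in sorted(graph.terms):
            term = graph.terms[tid]
            sink.write("\n[Term]\n")
            sink.write(f"id: {tid.prefix}:{tid.local}\n")
            sink.write(f"name: {term.name}\n")
            for syn in sorted(term.synonyms):
                sink.write(f'synonym: "{syn}" EXACT []\n')
            for pid in sorted(term.parents):
                sink.write(f"is_a: {pid.prefix}:{pid.local}\n")
            for xid in sorted(term.xrefs):
                sink.write(f"xref: {xid.prefix}:{xid.local}\n")
            if term.obsolete:
                sink.write("is_obsolete: true\n")
    finally:
        if close:
            sink.close()


def class_name(
    graph: OntologyGraph,
    term_id: TermId,
    remote: Optional[Callable[[TermId], Optional[str]]] = None,
) -> Optional[str]:
    """Resolve *term_id* to its class name, or ``None`` when unresolvable.

    Placeholder identifiers always resolve to ``None``.  When the term is
    not in the local graph and a *remote* lookup contract is supplied, it
    is consulted once and its answer cached on the graph.
    """
    if term_id.prefix != graph.prefix:
        raise ValueError(
            f"{term_id.render()} queried against {graph.prefix} graph"
        )
    if term_id.is_placeholder:
        return None
    term = graph.get(term_id)
    if term is not None:
        return term.name
    if remote is not None:
        if term_id not in graph._remote_cache:
            graph._remote_cache[term_id] = remote(term_id)
        return graph._remote_cache[term_id]
    return None


def is_ancestor(graph: OntologyGraph, a: TermId, b: TermId) -> bool:
    """True iff *a* is a strict ancestor (hypernym) of *b* via is_a edges."""
    graph.require(a)
    return a in graph.ancestors(b)


def cross_links(
    graphs: Mapping[str, OntologyGraph],
    term_id: TermId,
    target_prefix: str,
) -> set[TermId]:
    """Cross-ontology link targets of *term_id* in *target_prefix*.

    Returns the term's own xrefs with that prefix; when it has none, walks
    its is_a ancestors nearest-first and returns the union of xrefs at the
    first ancestor level that yields any.  Empty set when the whole
    ancestry is silent.
    """
    graph = graphs[term_id.prefix]
    term = graph.require(term_id)
    direct = {x for x in term.xrefs if x.prefix == target_prefix}
    if direct:
        return direct
    for level in graph.ancestor_levels(term_id):
        found: set[TermId] = set()
        for anc in level:
            found |= {
                x for x in graph.terms[anc].xrefs
                if x.prefix == target_prefix
            }
        if found:
            return found
    return set()
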