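"""Synthetic ontologies, gold tables, and simulated annotators.

Everything the pipeline consumes can be generated offline and
deterministically from a seed:

* four toy ontology graphs whose cross-ontology links follow the
  cell-line -> cell-type -> anatomy chain (plus links from all three
  into the tissue ontology), so identifier inference has the same shape
  it has over the real CLO/CL/UBERON/BTO;
* gold-standard biosample tables with the label pathologies real data
  shows — descriptive names, opaque alphanumeric codes, spelling
  variants of one entity sharing all identifiers, partially empty
  identifier columns;
* simulated annotator outputs whose per-namespace outcome rates are
  controlled by an :class:`ErrorProfile`, so evaluator estimates can be
  validated by parameter recovery against closed forms.

The simulator also emits a machine-written adjudication table
(:class:`~biosamap.evaluation.Overrides`) for the contribution outcomes
it samples, playing the role of the curator who manually checks whether
a contributed identifier is valid.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .annotators import AnnotationResult, render_proposals
from .evaluation import NAMESPACES, Overrides, normalize_name
from .inference import ConceptType, infer_identifiers
from .io import BiosampleRecord
from .ontology import LOCAL_WIDTH, OntologyGraph, OntologyTerm, TermId

log = logging.getLogger(__name__)

_MALFORMED_TEXT = "The most suitable identifiers for this sample appear to be:"


# ---------------------------------------------------------------------------
# Error profiles
# ---------------------------------------------------------------------------


def _check_simplex(probs: Sequence[float], what: str) -> None:
    if any(p < 0 or p > 1 for p in probs):
        raise ValueError(f"{what}: probabilities must lie in [0, 1]")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ValueError(f"{what}: probabilities must sum to 1")


@dataclass(frozen=True)
class PresentBranch:
    """Outcome distribution when the gold reference exists."""

    p_identical: float
    p_related: float
    p_wrong: float
    p_abstain: float

    def __post_init__(self) -> None:
        _check_simplex(self.as_tuple(), "reference-present branch")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.p_identical, self.p_related, self.p_wrong, self.p_abstain)


@dataclass(frozen=True)
class AbsentBranch:
    """Outcome distribution when the gold reference is absent."""

    p_valid: float
    p_invalid: float
    p_abstain: float

    def __post_init__(self) -> None:
        _check_simplex(self.as_tuple(), "reference-absent branch")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.p_valid, self.p_invalid, self.p_abstain)


@dataclass(frozen=True)
class ErrorProfile:
    """Per-namespace outcome probabilities for the annotator simulator.

    Expected confusion cells are linear in these rates: TP_I tracks
    ``p_identical``, TP_R ``p_related``, FP_E ``p_wrong``, FN the
    present-branch ``p_abstain``, TP_C ``p_valid``, FP_IC ``p_invalid``,
    TN the absent-branch ``p_abstain``.  ``p_malformed`` is the global
    probability that a whole output violates the format;
    ``p_hallucinate`` is the share of "wrong" proposals drawn as
    nonexistent identifiers.
    """

    present: Mapping[str, PresentBranch]
    absent: Mapping[str, AbsentBranch]
    p_malformed: float = 0.0
    p_hallucinate: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.p_malformed, self.p_hallucinate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("global probabilities must lie in [0, 1]")

    @classmethod
    def uniform(
        cls,
        present: tuple[float, float, float, float],
        absent: tuple[float, float, float],
        p_malformed: float = 0.0,
        p_hallucinate: float = 0.5,
        namespaces: Sequence[str] = NAMESPACES,
    ) -> "ErrorProfile":
        return cls(
            present={ns: PresentBranch(*present) for ns in namespaces},
            absent={ns: AbsentBranch(*absent) for ns in namespaces},
            p_malformed=p_malformed,
            p_hallucinate=p_hallucinate,
        )

    @classmethod
    def all_correct(cls) -> "ErrorProfile":
        """Degenerate profile: identical ids where gold exists, abstention
        where it does not — only TP_I and TN outcomes."""
        return cls.uniform((1, 0, 0, 0), (0, 0, 1))

    @classmethod
    def all_malformed(cls) -> "ErrorProfile":
        return cls.uniform((1, 0, 0, 0), (0, 0, 1), p_malformed=1.0)

    def expected_precision(self, ns: str, coverage: float) -> Optional[float]:
        """Closed-form precision implied by the rates at gold *coverage*."""
        pb, ab = self.present[ns], self.absent[ns]
        tp = coverage * (pb.p_identical + pb.p_related) + (1 - coverage) * ab.p_valid
        fp = coverage * pb.p_wrong + (1 - coverage) * ab.p_invalid
        return tp / (tp + fp) if tp + fp > 0 else None

    def expected_recall(self, ns: str, coverage: float) -> Optional[float]:
        pb, ab = self.present[ns], self.absent[ns]
        tp = coverage * (pb.p_identical + pb.p_related) + (1 - coverage) * ab.p_valid
        fn = coverage * pb.p_abstain
        return tp / (tp + fn) if tp + fn > 0 else None

    def to_yaml(self, sink) -> None:
        data = {
            "p_malformed": self.p_malformed,
            "p_hallucinate": self.p_hallucinate,
            "namespaces": {
                ns: {
                    "present": {
                        "identical": self.present[ns].p_identical,
                        "related": self.present[ns].p_related,
                        "wrong": self.present[ns].p_wrong,
                        "abstain": self.present[ns].p_abstain,
                    },
                    "absent": {
                        "valid": self.absent[ns].p_valid,
                        "invalid": self.absent[ns].p_invalid,
                        "abstain": self.absent[ns].p_abstain,
                    },
                }
                for ns in self.present
            },
        }
        close = False
        if isinstance(sink, str):
            sink = open(sink, "w", encoding="utf-8")
            close = True
        try:
            yaml.safe_dump(data, sink, sort_keys=True)
        finally:
            if close:
                sink.close()

    @classmethod
    def from_yaml(cls, source) -> "ErrorProfile":
        close = False
        if isinstance(source, str):
            source = open(source, encoding="utf-8")
            close = True
        try:
            data = yaml.safe_load(source)
        finally:
            if close:
                source.close()
        present = {}
        absent = {}
        for ns, branches in data["namespaces"].items():
            p = branches["present"]
            a = branches["absent"]
            present[ns] = PresentBranch(
                p["identical"], p["related"], p["wrong"], p["abstain"]
            )
            absent[ns] = AbsentBranch(a["valid"], a["invalid"], a["abstain"])
        return cls(
            present=present,
            absent=absent,
            p_malformed=data.get("p_malformed", 0.0),
            p_hallucinate=data.get("p_hallucinate", 0.5),
        )


# ---------------------------------------------------------------------------
# Ontology generation
# ---------------------------------------------------------------------------

_ORGANS = (
    "uterus breast lung liver kidney heart brain pancreas stomach skin "
    "colon spleen thymus bladder trachea prostate"
).split()
_ANAT_ADJ = (
    "dorsal ventral lateral medial proximal distal anterior posterior "
    "superior inferior left right"
).split()
_CELL_QUAL = (
    "uterine mammary pulmonary hepatic renal cardiac neural pancreatic "
    "gastric dermal colonic splenic basal luminal squamous ciliated"
).split()
_CELL_NOUNS = (
    "epithelial-cell fibroblast lymphocyte macrophage neuron hepatocyte "
    "keratinocyte myocyte osteoblast astrocyte monocyte melanocyte"
).split()

DEFAULT_SIZES: dict[str, int] = {"CLO": 60, "CL": 40, "UBERON": 30, "BTO": 80}


def _code(rng: np.random.Generator, lo: int = 4, hi: int = 7) -> str:
    """Opaque alphanumeric token, letters+digits, length 4-7."""
    n = int(rng.integers(lo, hi + 1))
    letters = string.ascii_uppercase
    digits = string.digits
    chars = [letters[rng.integers(len(letters))] for _ in range(2)]
    chars += [
        (letters + digits)[rng.integers(len(letters) + len(digits))]
        for _ in range(n - 2)
    ]
    if not any(c.isdigit() for c in chars):
        chars[-1] = digits[rng.integers(10)]
    return "".join(chars)


def _unique_name(base: str, used: set[str]) -> str:
    name = base
    k = 2
    while name in used:
        name = f"{base} {k}"
        k += 1
    used.add(name)
    return name


def _name_pool(prefix: str, size: int, rng: np.random.Generator) -> list[str]:
    used: set[str] = set()
    names: list[str] = []
    if prefix == "UBERON":
        names.append(_unique_name("anatomical structure", used))
        pool = list(_ORGANS) + [
            f"{a} {o}" for a in _ANAT_ADJ for o in _ORGANS
        ]
    elif prefix == "CL":
        names.append(_unique_name("cell", used))
        pool = [
            f"{q} {n.replace('-', ' ')}"
            for q in _CELL_QUAL
            for n in _CELL_NOUNS
        ]
    elif prefix == "CLO":
        names.append(_unique_name("cell line", used))
        pool = []
    else:  # BTO-style mixed scope
        names.append(_unique_name("tissue", used))
        pool = (
            [f"{o} tissue" for o in _ORGANS]
            + [
                f"{q} {n.replace('-', ' ')}"
                for q in _CELL_QUAL
                for n in _CELL_NOUNS
            ]
            + list(_ORGANS)
        )
    order = rng.permutation(len(pool)) if pool else []
    for idx in order:
        if len(names) >= size:
            break
        names.append(_unique_name(pool[int(idx)], used))
    while len(names) < size:
        names.append(_unique_name(f"{_code(rng)} cell", used))
    return names[:size]


def _synonym(name: str, rng: np.random.Generator) -> Optional[str]:
    words = name.split()
    long_words = [w for w in words if len(w) >= 6 and w.isalpha()]
    if not long_words:
        return None
    w = long_words[int(rng.integers(len(long_words)))]
    k = len(w) // 2
    return name.replace(w, f"{w[:k]}-{w[k:]}", 1)


def generate_ontologies(
    seed: int,
    sizes: Optional[Mapping[str, int]] = None,
    extra_parent_prob: float = 0.2,
    xref_dropout: float = 0.15,
    synonym_prob: float = 0.25,
) -> dict[str, OntologyGraph]:
    """Generate four rooted is_a DAGs with chained cross-ontology links.

    Every non-root CLO term links to a CL term and a BTO term; every
    non-root CL term links to a BTO term and (except for a *xref_dropout*
    fraction, which inherit through their parents) to a UBERON term;
    every non-root UBERON term links to a BTO term.  Roots link across so
    ancestor walks always terminate with a candidate.  Deterministic for
    a fixed seed.
    """
    sizes = dict(DEFAULT_SIZES if sizes is None else sizes)
    if any(v < 3 for v in sizes.values()):
        raise ValueError("each ontology needs at least 3 terms")
    rng = np.random.default_rng(seed)

    ids: dict[str, list[TermId]] = {}
    names: dict[str, list[str]] = {}
    parents: dict[str, list[frozenset[TermId]]] = {}
    build_order = [p for p in ("BTO", "UBERON", "CL", "CLO") if p in sizes]
    for prefix in build_order:
        n = sizes[prefix]
        ids[prefix] = [
            TermId(prefix, str(i + 1).zfill(LOCAL_WIDTH)) for i in range(n)
        ]
        names[prefix] = _name_pool(prefix, n, rng)
        plist: list[frozenset[TermId]] = [frozenset()]
        for i in range(1, n):
            ps = {ids[prefix][int(rng.integers(i))]}
            if i > 1 and rng.random() < extra_parent_prob:
                ps.add(ids[prefix][int(rng.integers(i))])
            plist.append(frozenset(ps))
        parents[prefix] = plist

    def pick(prefix: str, nonroot: bool = True) -> TermId:
        pool = ids[prefix][1:] if nonroot and len(ids[prefix]) > 1 else ids[prefix]
        return pool[int(rng.integers(len(pool)))]

    # BTO links are propagated down the CLO -> CL -> UBERON chain (each
    # term borrows the tissue link of its chain target) so that inference
    # from any granularity reaches the same BTO term.
    xrefs: dict[str, list[set[TermId]]] = {
        p: [set() for _ in ids[p]] for p in build_order
    }
    bto_of: dict[TermId, TermId] = {}
    if "BTO" in sizes:
        for i, tid in enumerate(ids.get("UBERON", [])):
            bto = ids["BTO"][0] if i == 0 else pick("BTO")
            xrefs["UBERON"][i].add(bto)
            bto_of[tid] = bto
    def inherited_targets(prefix: str, tid: TermId, target: str) -> set[TermId]:
        # nearest-ancestor-level walk over the xrefs assigned so far
        pos = {t: i for i, t in enumerate(ids[prefix])}
        seen = {tid}
        frontier = set(parents[prefix][pos[tid]])
        while frontier:
            hits: set[TermId] = set()
            for anc in frontier:
                hits |= {
                    x for x in xrefs[prefix][pos[anc]] if x.prefix == target
                }
            if hits:
                return hits
            seen |= frontier
            nxt: set[TermId] = set()
            for anc in frontier:
                nxt |= set(parents[prefix][pos[anc]])
            frontier = nxt - seen
        return set()

    if "CL" in sizes:
        for i, tid in enumerate(ids["CL"]):
            if "UBERON" in sizes:
                if i == 0:
                    xrefs["CL"][0].add(ids["UBERON"][0])
                    anatomy: Optional[TermId] = ids["UBERON"][0]
                else:
                    target = pick("UBERON")
                    if rng.random() >= xref_dropout:
                        xrefs["CL"][i].add(target)
                        anatomy = target
                    else:
                        # this term resolves its anatomy through inheritance
                        inherited = inherited_targets("CL", tid, "UBERON")
                        anatomy = (
                            next(iter(inherited))
                            if len(inherited) == 1
                            else None
                        )
                if "BTO" in sizes:
                    bto = bto_of[anatomy] if anatomy is not None else pick("BTO")
                    xrefs["CL"][i].add(bto)
                    bto_of[tid] = bto
            elif "BTO" in sizes:
                bto = ids["BTO"][0] if i == 0 else pick("BTO")
                xrefs["CL"][i].add(bto)
                bto_of[tid] = bto
    if "CLO" in sizes:
        for i, tid in enumerate(ids["CLO"]):
            if i == 0:
                if "BTO" in sizes:
                    xrefs["CLO"][0].add(ids["BTO"][0])
                continue
            if "CL" in sizes:
                target = pick("CL")
                xrefs["CLO"][i].add(target)
                if "BTO" in sizes:
                    xrefs["CLO"][i].add(bto_of[target])
            elif "BTO" in sizes:
                xrefs["CLO"][i].add(pick("BTO"))

    graphs: dict[str, OntologyGraph] = {}
    for prefix in build_order:
        terms = {}
        for i, tid in enumerate(ids[prefix]):
            syn = (
                _synonym(names[prefix][i], rng)
                if rng.random() < synonym_prob
                else None
            )
            terms[tid] = OntologyTerm(
                id=tid,
                name=names[prefix][i],
                synonyms=frozenset([syn] if syn else []),
                parents=parents[prefix][i],
                xrefs=frozenset(xrefs[prefix][i]),
            )
        graphs[prefix] = OntologyGraph(prefix=prefix, terms=terms)
    return graphs


# ---------------------------------------------------------------------------
# Gold-standard generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GoldSpec:
    """Shape of a generated gold-standard table.

    Default label counts per concept type follow the composition of the
    study dataset (3080 cell lines, 2258 cell types, 723 anatomical
    structures, 203 untyped; 6264 labels in total); tests and examples
    pass smaller counts explicitly.
    """

    counts: Mapping[ConceptType, int] = field(
        default_factory=lambda: {
            ConceptType.CELL_LINE: 3080,
            ConceptType.CELL_TYPE: 2258,
            ConceptType.ANATOMICAL_STRUCTURE: 723,
            ConceptType.NONE: 203,
        }
    )
    coded_fraction: float = 0.3
    variant_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    coverage: Mapping[str, float] = field(
        default_factory=lambda: {ns: 0.9 for ns in NAMESPACES}
    )

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("label counts must be non-negative")
        if not 0.0 <= self.coded_fraction <= 1.0:
            raise ValueError("coded_fraction must lie in [0, 1]")
        _check_simplex(list(self.variant_dist.values()), "variant distribution")
        if any(not 0.0 <= c <= 1.0 for c in self.coverage.values()):
            raise ValueError("coverage probabilities must lie in [0, 1]")


_SOURCE_NS = {
    ConceptType.CELL_LINE: "CLO",
    ConceptType.CELL_TYPE: "CL",
    ConceptType.ANATOMICAL_STRUCTURE: "UBERON",
}


def _variant(label: str, rng: np.random.Generator) -> str:
    """One seeded spelling/formatting mutation of a label."""
    ops = int(rng.integers(5))
    if ops == 0:
        return label.replace(" ", "_")
    if ops == 1:
        return label.lower() if label != label.lower() else label.upper()
    if ops == 2 and len(label) > 3:
        i = int(rng.integers(1, len(label) - 1))
        return label[:i] + label[i + 1 :]
    if ops == 3 and len(label) > 1:
        i = int(rng.integers(len(label)))
        return label[: i + 1] + label[i] + label[i + 1 :]
    suffix = "".join(
        string.ascii_lowercase[rng.integers(26)] for _ in range(3)
    )
    return f"{label}-{suffix}"


def generate_gold(
    graphs: Mapping[str, OntologyGraph],
    spec: GoldSpec,
    seed: int,
) -> list[BiosampleRecord]:
    """Generate a gold table whose identifiers respect the graphs' links.

    Each entity is a term drawn from its concept's source ontology; its
    gold identifiers are the inference closure of that term, thinned by
    the per-namespace coverage probability (dropout is per entity, so
    spelling variants of one entity share identical identifier columns).
    Labels mix descriptive names, opaque codes, and seeded misspellings,
    and are unique within the table.
    """
    rng = np.random.default_rng(seed)
    variant_ks = sorted(spec.variant_dist)
    variant_ps = [spec.variant_dist[k] for k in variant_ks]
    used_labels: set[str] = set()
    records: list[BiosampleRecord] = []

    for concept in (
        ConceptType.CELL_LINE,
        ConceptType.CELL_TYPE,
        ConceptType.ANATOMICAL_STRUCTURE,
        ConceptType.NONE,
    ):
        want = spec.counts.get(concept, 0)
        got = 0
        while got < want:
            if concept is ConceptType.NONE:
                ns = NAMESPACES[int(rng.integers(len(NAMESPACES)))]
            else:
                ns = _SOURCE_NS[concept]
            pool = sorted(graphs[ns].terms)[1:] or sorted(graphs[ns].terms)
            source = pool[int(rng.integers(len(pool)))]
            truth = infer_identifiers(graphs, source, concept)
            gold = {
                n: (
                    truth.get(n)
                    if truth.get(n) is not None
                    and rng.random() < spec.coverage.get(n, 1.0)
                    else None
                )
                for n in NAMESPACES
            }
            k = variant_ks[
                int(rng.choice(len(variant_ks), p=variant_ps))
            ]
            if rng.random() < spec.coded_fraction:
                base = _code(rng)
            else:
                base = graphs[ns].terms[source].name
            labels = [base]
            while len(labels) < k:
                labels.append(_variant(labels[-1], rng))
            for label in labels:
                if got >= want:
                    break
                final = label
                bump = 2
                while final in used_labels:
                    final = f"{label}_{bump}"
                    bump += 1
                used_labels.add(final)
                records.append(
                    BiosampleRecord(
                        label=final,
                        gold=gold,
                        concept=concept,
                        source_id=source,
                    )
                )
                got += 1
    return records


# ---------------------------------------------------------------------------
# Annotator simulation
# ---------------------------------------------------------------------------


def _hallucinated_id(graph: OntologyGraph, rng: np.random.Generator) -> TermId:
    for _ in range(1000):
        local = str(int(rng.integers(1, 10**LOCAL_WIDTH))).zfill(LOCAL_WIDTH)
        tid = TermId(graph.prefix, local)
        if tid not in graph:
            return tid
    raise RuntimeError("could not draw a nonexistent identifier")


def _wrong_id(
    graph: OntologyGraph,
    reference: Optional[TermId],
    rng: np.random.Generator,
    p_hallucinate: float,
) -> TermId:
    """An identifier guaranteed to be an invalid proposal for *reference*."""
    if rng.random() < p_hallucinate or len(graph) < 4:
        return _hallucinated_id(graph, rng)
    pool = sorted(graph.terms)
    ref_names: set[str] = set()
    banned: set[TermId] = set()
    if reference is not None and reference in graph:
        ref_term = graph.terms[reference]
        ref_names = {normalize_name(s) for s in ref_term.labels()}
        banned = graph.ancestors(reference) | {reference}
    for _ in range(100):
        cand = pool[int(rng.integers(len(pool)))]
        if cand in banned:
            continue
        if reference is not None and reference in graph.ancestors(cand):
            continue  # strict descendant is INVALID but keep it clearly wrong
        cand_names = {
            normalize_name(s) for s in graph.terms[cand].labels()
        }
        if cand_names & ref_names:
            continue
        return cand
    return _hallucinated_id(graph, rng)


def sample_annotation(
    record: BiosampleRecord,
    graphs: Mapping[str, OntologyGraph],
    profile: ErrorProfile,
    rng: np.random.Generator,
) -> tuple[Optional[dict[str, Optional[TermId]]], dict[str, tuple[TermId, bool]]]:
    """Sample one annotator output for *record* under *profile*.

    Returns ``(proposed, contribution_verdicts)``; ``proposed`` is None
    when the whole output is malformed.  ``contribution_verdicts`` maps
    namespaces where an identifier was contributed without a reference to
    ``(proposed_id, valid)`` — the simulator's ground-truth adjudication.
    """
    if rng.random() < profile.p_malformed:
        return None, {}
    truth: Optional[dict[str, Optional[TermId]]] = None
    if record.source_id is not None and record.concept is not ConceptType.NONE:
        try:
            truth = infer_identifiers(graphs, record.source_id, record.concept)
        except (KeyError, ValueError):
            truth = None

    proposed: dict[str, Optional[TermId]] = {}
    verdicts: dict[str, tuple[TermId, bool]] = {}
    for ns in NAMESPACES:
        graph = graphs.get(ns)
        ref = record.gold.get(ns)
        if ref is not None:
            branch = int(rng.choice(4, p=profile.present[ns].as_tuple()))
            if branch == 1:  # related: a strict ancestor (hypernym)
                ancestors = (
                    sorted(graph.ancestors(ref))
                    if graph is not None and ref in graph
                    else []
                )
                if ancestors:
                    proposed[ns] = ancestors[int(rng.integers(len(ancestors)))]
                    continue
                log.debug(
                    "no ancestor for %s; falling back to wrong", ref.render()
                )
                branch = 2
            if branch == 0:
                proposed[ns] = ref
            elif branch == 2:
                if graph is None:
                    proposed[ns] = None
                else:
                    proposed[ns] = _wrong_id(
                        graph, ref, rng, profile.p_hallucinate
                    )
            else:
                proposed[ns] = None
        else:
            branch = int(rng.choice(3, p=profile.absent[ns].as_tuple()))
            if branch == 2 or graph is None or len(graph) == 0:
                proposed[ns] = None
            else:
                if branch == 0:
                    cand = truth.get(ns) if truth else None
                    if cand is None:
                        pool = sorted(graph.terms)
                        cand = pool[int(rng.integers(len(pool)))]
                    valid = True
                else:
                    true_id = truth.get(ns) if truth else None
                    cand = _wrong_id(graph, None, rng, 0.0)
                    for _ in range(20):
                        if cand != true_id:
                            break
                        cand = _wrong_id(graph, None, rng, 0.0)
                    valid = False
                proposed[ns] = cand
                verdicts[ns] = (cand, valid)
    return proposed, verdicts


def simulate_annotator(
    gold: Sequence[BiosampleRecord],
    graphs: Mapping[str, OntologyGraph],
    profile: ErrorProfile,
    seed: int,
    annotator_id: str = "simulated",
) -> tuple[list[AnnotationResult], Overrides]:
    """Simulate one annotator over a gold table.

    Returns the annotation results and the simulator's adjudication of
    its contribution outcomes (the machine analogue of a curator's
    manual contribution check).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    results: list[AnnotationResult] = []
    overrides = Overrides()
    for record in gold:
        proposed, verdicts = sample_annotation(record, graphs, profile, rng)
        if proposed is None:
            results.append(
                AnnotationResult(
                    label=record.label,
                    proposed={},
                    format_ok=False,
                    raw_output=_MALFORMED_TEXT,
                    annotator_id=annotator_id,
                )
            )
            continue
        for ns, (cand, valid) in verdicts.items():
            overrides.add(record.label, ns, cand, valid)
        results.append(
            AnnotationResult(
                label=record.label,
                proposed=proposed,
                format_ok=True,
                raw_output=render_proposals(proposed),
                annotator_id=annotator_id,
            )
        )
    return results, overrides
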