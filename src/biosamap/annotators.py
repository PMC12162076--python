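"""Annotators: prompt pipeline, output parsing, lexical baseline, dataset prep.

Three ways to propose identifiers for a biosample label:

* the five-part prompt pipeline over a pluggable text-generation backend
  (contract: prompt string in, completion string out, synchronous);
* a deterministic mock backend driven by a gold table and an error
  profile, standing in for a remote LLM;
* a lexical baseline that ranks ontology class names and synonyms by
  TF-IDF cosine similarity with edit-distance tie-breaking, in the style
  of traditional term-mapping tools.

Also here: seeded dataset splitting and export of chat-format JSON-lines
fine-tuning datasets.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Optional, Sequence

import edlib
import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics.pairwise import linear_kernel

from .evaluation import NAMESPACES
from .ontology import (
    OntologyGraph,
    TermId,
    TermIdError,
    parse_term_id,
    placeholder,
)

log = logging.getLogger(__name__)


class PromptError(ValueError):
    """Prompt specification or input cannot be rendered."""


@dataclass(frozen=True)
class PromptSpec:
    """Five-component prompt: role, objectives, inputs, process, constraints.

    Rendering concatenates exactly these five sections in this order,
    each under a fixed header; the inputs section must carry a
    ``{label}`` placeholder for the label under annotation.
    """

    role_text: str
    objectives_text: str
    inputs_text: str
    process_refinements_text: str
    constraints_text: str


SECTION_HEADERS = (
    "### Role",
    "### Objectives",
    "### Inputs",
    "### Process refinements",
    "### Constraints",
)

#: Default prompt. The wording is this package's own reconstruction of the
#: five-component scheme (role / objectives / inputs / process refinements /
#: constraints) for expert ontology annotation.
DEFAULT_PROMPT_SPEC = PromptSpec(
    role_text=(
        "You are an expert ontology annotator for biological sample data."
    ),
    objectives_text=(
        "Find the most suitable identifier for the given biosample label in "
        "each of four ontologies: CLO (cell lines), CL (cell types), UBERON "
        "(anatomical structures), and BTO (tissues and enzyme sources). "
        "Labels denote cell lines, cell types, or anatomical structures."
    ),
    inputs_text='Label: "{label}"',
    process_refinements_text=(
        "Answer with a single list of four identifiers in the fixed order "
        "CLO, CL, UBERON, BTO, e.g. "
        "[CLO_0001200, CL_0002231, UBERON_0002367, BTO_0002999]. When no "
        "identifier applies in an ontology, use its all-zero placeholder, "
        "e.g. [CLO_0000000, CL_0000000, UBERON_0000000, BTO_0000000]."
    ),
    constraints_text=(
        "Output only the bracketed list, devoid of any introductory text, "
        "explanations, or conclusions."
    ),
)

#: Single-sentence instruction used for fine-tuned models, where task
#: context and output format are learned during training.
FINETUNE_INSTRUCTION = (
    "Annotate this biosample label with CLO, CL, UBERON and BTO identifiers:"
)

#: Fine-tuning hyperparameters recorded as export metadata (not acted on).
FINETUNE_HYPERPARAMETERS = {
    "n_epochs": 6,
    "batch_size": 3,
    "learning_rate_multiplier": 0.3,
}


def build_prompt(spec: PromptSpec, label: str) -> str:
    """Render the five-section prompt with *label* substituted. Deterministic."""
    if not label:
        raise PromptError("label must be non-empty")
    sections = (
        spec.role_text,
        spec.objectives_text,
        spec.inputs_text,
        spec.process_refinements_text,
        spec.constraints_text,
    )
    if any(not s or not s.strip() for s in sections):
        raise PromptError("all five prompt sections must be non-empty")
    if "{label}" not in spec.inputs_text:
        raise PromptError("inputs section must contain a {label} placeholder")
    rendered = []
    for header, body in zip(SECTION_HEADERS, sections):
        if header == SECTION_HEADERS[2]:
            body = body.replace("{label}", label)
        rendered.append(f"{header}\n{body}")
    return "\n\n".join(rendered)


@dataclass(frozen=True)
class AnnotationResult:
    """Per-label proposal set with format validity and provenance."""

    label: str
    proposed: Mapping[str, Optional[TermId]]
    format_ok: bool
    raw_output: str
    annotator_id: str


_OUTPUT_RE = re.compile(
    r"^\s*\[\s*([A-Za-z]+[_:]\d+)\s*,\s*([A-Za-z]+[_:]\d+)\s*,"
    r"\s*([A-Za-z]+[_:]\d+)\s*,\s*([A-Za-z]+[_:]\d+)\s*\]\s*$"
)


def parse_model_output(
    text: str, namespaces: Sequence[str] = NAMESPACES
) -> tuple[dict[str, Optional[TermId]], bool]:
    """Parse a bracketed four-identifier list in CLO, CL, UBERON, BTO order.

    Returns ``(proposed, format_ok)``.  Placeholder identifiers map to
    absent proposals with ``format_ok`` True; any other deviation (prose,
    wrong arity, wrong order, malformed identifiers) yields an empty
    proposal map with ``format_ok`` False — malformation is captured, not
    raised.
    """
    m = _OUTPUT_RE.match(text or "")
    if m is None:
        return {}, False
    proposed: dict[str, Optional[TermId]] = {}
    for ns, token in zip(namespaces, m.groups()):
        try:
            tid = parse_term_id(token, namespaces)
        except TermIdError:
            return {}, False
        if tid.prefix != ns:
            return {}, False
        proposed[ns] = None if tid.is_placeholder else tid
    return proposed, True


def render_proposals(
    proposed: Mapping[str, Optional[TermId]],
    namespaces: Sequence[str] = NAMESPACES,
) -> str:
    """Render a proposal map in the constrained output format.

    Absent proposals render as the namespace's all-zero placeholder;
    ``parse_model_output(render_proposals(p))`` reproduces ``p`` exactly.
    """
    parts = []
    for ns in namespaces:
        tid = proposed.get(ns)
        parts.append((tid or placeholder(ns)).render())
    return "[" + ", ".join(parts) + "]"


Backend = Callable[[str], str]


def annotate_labels(
    labels: Iterable[str],
    backend: Backend,
    annotator_id: str,
    prompt_spec: PromptSpec = DEFAULT_PROMPT_SPEC,
) -> list[AnnotationResult]:
    """Run the prompt pipeline over *labels* with a text-generation backend."""
    results = []
    for label in labels:
        raw = backend(build_prompt(prompt_spec, label))
        proposed, ok = parse_model_output(raw)
        results.append(
            AnnotationResult(
                label=label,
                proposed=proposed,
                format_ok=ok,
                raw_output=raw,
                annotator_id=annotator_id,
            )
        )
    n_bad = sum(1 for r in results if not r.format_ok)
    if n_bad:
        log.info("%d/%d outputs failed the format check", n_bad, len(results))
    return results


# ---------------------------------------------------------------------------
# Lexical baseline
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def lexical_tokens(text: str) -> list[str]:
    """Casefold, split on non-alphanumerics; add character 3-grams for
    tokens containing digits, so coded labels like "22Rv1" retain some
    signal for character-level matching."""
    tokens = [t for t in _TOKEN_RE.split(text.casefold()) if t]
    grams: list[str] = []
    for t in tokens:
        if any(ch.isdigit() for ch in t) and len(t) >= 3:
            grams.extend(t[i : i + 3] for i in range(len(t) - 2))
    return tokens + grams


@dataclass(frozen=True)
class LexicalMatch:
    term_id: TermId
    name: str
    score: float


@dataclass
class _NamespaceIndex:
    vectorizer: TfidfVectorizer
    matrix: "np.ndarray"
    entries: list[tuple[TermId, str]]  # (term, name-or-synonym document)


@dataclass
class LexicalIndex:
    """Per-namespace TF-IDF vector space over class names and synonyms.

    Every non-obsolete term contributes its primary name plus each
    synonym as separate documents; obsolete terms are excluded from the
    candidate index.
    """

    indexes: dict[str, Optional[_NamespaceIndex]]

    @classmethod
    def build(cls, graphs: Mapping[str, OntologyGraph]) -> "LexicalIndex":
        indexes: dict[str, Optional[_NamespaceIndex]] = {}
        for ns, graph in graphs.items():
            entries: list[tuple[TermId, str]] = []
            for tid in sorted(graph.terms):
                term = graph.terms[tid]
                if term.obsolete:
                    continue
                entries.append((tid, term.name))
                for syn in sorted(term.synonyms):
                    entries.append((tid, syn))
            if not entries:
                indexes[ns] = None
                continue
            vectorizer = TfidfVectorizer(analyzer=lexical_tokens)
            matrix = vectorizer.fit_transform(doc for _, doc in entries)
            indexes[ns] = _NamespaceIndex(vectorizer, matrix, entries)
        return cls(indexes)


def _norm_edit_distance(a: str, b: str) -> float:
    a, b = a.casefold(), b.casefold()
    if not a and not b:
        return 0.0
    return edlib.align(a, b)["editDistance"] / max(len(a), len(b))


def lexical_annotate(
    label: str,
    index: LexicalIndex,
    threshold: float = 0.5,
    tie_tolerance: float = 1e-9,
) -> dict[str, Optional[LexicalMatch]]:
    """Top TF-IDF cosine candidate per namespace, or absent below threshold.

    Ties within *tie_tolerance* of the best cosine are broken by lower
    normalized edit distance between the label and the candidate name,
    then by lexicographically smallest identifier.  Deterministic for a
    fixed index and configuration.
    """
    out: dict[str, Optional[LexicalMatch]] = {}
    for ns, nsi in index.indexes.items():
        if nsi is None:
            log.warning("empty lexical index for %s; returning absent", ns)
            out[ns] = None
            continue
        query = nsi.vectorizer.transform([label])
        sims = linear_kernel(query, nsi.matrix).ravel()
        best = float(sims.max()) if sims.size else 0.0
        if best < threshold or best <= 0.0:
            out[ns] = None
            continue
        tied = [
            (
                _norm_edit_distance(label, nsi.entries[i][1]),
                nsi.entries[i][0],
                nsi.entries[i][1],
                float(sims[i]),
            )
            for i in np.flatnonzero(sims >= best - tie_tolerance)
        ]
        dist, tid, name, score = min(tied, key=lambda t: (t[0], t[1]))
        out[ns] = LexicalMatch(term_id=tid, name=name, score=score)
    return out


def lexical_annotator(
    labels: Iterable[str],
    index: LexicalIndex,
    threshold: float = 0.5,
    annotator_id: str = "lexical-tfidf",
) -> list[AnnotationResult]:
    """Wrap :func:`lexical_annotate` into annotation results."""
    results = []
    for label in labels:
        matches = lexical_annotate(label, index, threshold)
        proposed = {
            ns: (m.term_id if m is not None else None)
            for ns, m in matches.items()
        }
        results.append(
            AnnotationResult(
                label=label,
                proposed=proposed,
                format_ok=True,
                raw_output=render_proposals(proposed),
                annotator_id=annotator_id,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Mock backend
# ---------------------------------------------------------------------------

_LABEL_IN_PROMPT_RE = re.compile(r'Label: "(.*)"')


def mock_backend(
    gold: Sequence,
    profile,
    seed: int,
    graphs: Optional[Mapping[str, OntologyGraph]] = None,
) -> Backend:
    """Deterministic text-generation backend standing in for a remote LLM.

    Given a prompt containing a known gold label, emits a bracketed list
    consistent with a per-namespace outcome sampled from *profile*
    (identical / related / wrong / placeholder, or a malformed whole
    output); unknown labels yield all placeholders.  *graphs* enable the
    "related" (ancestor) outcome; without them it degrades to "wrong".
    """
    from .synthetic import sample_annotation  # local to avoid import cycle

    records = {r.label: r for r in gold}
    rng = np.random.default_rng(seed)

    def backend(prompt: str) -> str:
        m = _LABEL_IN_PROMPT_RE.search(prompt)
        label = m.group(1) if m else None
        if label is None:
            for known in sorted(records, key=len, reverse=True):
                if known in prompt:
                    label = known
                    break
        if label is None or label not in records:
            return render_proposals({})
        proposed, _ = sample_annotation(
            records[label], graphs or {}, profile, rng
        )
        if proposed is None:
            return "I believe the identifiers for this sample are as follows."
        return render_proposals(proposed)

    return backend


# ---------------------------------------------------------------------------
# Dataset splitting and fine-tune export
# ---------------------------------------------------------------------------


def split_dataset(
    records: Sequence,
    fractions: tuple[float, float, float],
    seed: int,
) -> tuple[list, list, list]:
    """Seeded train/validation/test partition with floor-floor-remainder sizes.

    Train receives ``floor(f_train * N)`` records and validation
    ``floor(f_val * N)`` from a seeded uniform shuffle; test takes the
    remainder.  The union equals the input; the parts are disjoint.
    """
    if len(records) == 0:
        raise ValueError("cannot split an empty record table")
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0:
        raise ValueError("fractions must be positive")
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(records)
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(f_train * n))
    n_val = int(np.floor(f_val * n))
    shuffled = [records[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def export_finetune_dataset(
    records: Iterable,
    instruction: str = FINETUNE_INSTRUCTION,
    include_descriptions: bool = False,
) -> Iterator[dict]:
    """Yield chat-format training examples, one JSON object per record.

    The user message is a single-sentence instruction plus the label
    (plus its description when flagged); the assistant message is the
    bracketed four-identifier output with placeholders for absent gold
    values.  Records whose gold identifiers are all absent are skipped
    with a warning.
    """
    for record in records:
        if not any(v is not None for v in record.gold.values()):
            log.warning(
                "skipping %r: no gold identifier in any ontology", record.label
            )
            continue
        user = f"{instruction} {record.label}"
        description = getattr(record, "description", None)
        if include_descriptions and description:
            user = f"{user}\nDescription: {description}"
        yield {
            "messages": [
                {
                    "role": "system",
                    "content": DEFAULT_PROMPT_SPEC.role_text,
                },
                {"role": "user", "content": user},
                {
                    "role": "assistant",
                    "content": render_proposals(record.gold),
                },
            ]
        }


def write_finetune_jsonl(
    records: Sequence,
    path: str,
    instruction: str = FINETUNE_INSTRUCTION,
    include_descriptions: bool = False,
) -> dict:
    """Write the JSONL export plus a sidecar metadata file.

    The metadata records the fine-tuning hyperparameters (epochs, batch
    size, learning-rate multiplier) without acting on them, and the
    export configuration.  Returns the metadata dict.
    """
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for example in export_finetune_dataset(
            records, instruction, include_descriptions
        ):
            fh.write(json.dumps(example) + "\n")
            n += 1
    meta = {
        "n_examples": n,
        "include_descriptions": include_descriptions,
        "instruction": instruction,
        "hyperparameters": FINETUNE_HYPERPARAMETERS,
    }
    with open(path + ".meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
    return meta
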