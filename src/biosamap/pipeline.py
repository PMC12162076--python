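"""Pipeline orchestration: annotate -> evaluate -> (optionally) agree.

A :class:`RunConfig` names the ontology sources, the gold table, the
annotator (a stored annotations file, the seeded mock backend, or the
lexical baseline), optional manual overrides, and an output directory.
:func:`run_pipeline` executes the stages, logs counts at each one, and
writes the annotations, the stratified report, and the resolved
configuration (including the seed) alongside the outputs.  All
randomness flows from the one configured seed; per-stage seeds are
derived deterministically from it.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .agreement import TrigramEmbedder, cohens_kappa, soft_agreement
from .annotators import (
    AnnotationResult,
    LexicalIndex,
    annotate_labels,
    lexical_annotator,
    mock_backend,
)
from .evaluation import EvaluationReport, Overrides, stratify
from .io import (
    BiosampleRecord,
    read_annotations_tsv,
    read_biosamples_tsv,
    write_agreement_report,
    write_annotations_tsv,
    write_report,
)
from .ontology import OntologyGraph, class_name, load_ontology

log = logging.getLogger(__name__)


def derive_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage seed below 2**31, derived from the run seed."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    ontologies: Mapping[str, str]  # prefix -> OBO path
    gold_path: str
    out_dir: str
    seed: int = 0
    annotations_path: Optional[str] = None
    backend: Optional[str] = None  # "mock" | "lexical" when annotating
    profile_path: Optional[str] = None  # mock backend error profile (YAML)
    second_annotations_path: Optional[str] = None
    overrides_path: Optional[str] = None
    lexical_threshold: float = 0.5
    soft_threshold: float = 0.9

    def validate(self) -> None:
        for prefix, path in self.ontologies.items():
            if not os.path.exists(path):
                raise FileNotFoundError(f"ontology {prefix}: {path}")
        if not os.path.exists(self.gold_path):
            raise FileNotFoundError(f"gold table: {self.gold_path}")
        if self.annotations_path is None and self.backend not in (
            "mock",
            "lexical",
        ):
            raise ValueError(
                "either annotations_path or backend in {'mock', 'lexical'} "
                "is required"
            )


def load_graphs(ontologies: Mapping[str, str]) -> dict[str, OntologyGraph]:
    return {
        prefix: load_ontology(path, prefix)
        for prefix, path in ontologies.items()
    }


def agreement_between(
    results_a: Sequence[AnnotationResult],
    results_b: Sequence[AnnotationResult],
    graphs: Mapping[str, OntologyGraph],
    threshold: float = 0.9,
    embedder=None,
    unit: str = "class-name",
) -> dict[str, dict[str, Optional[float]]]:
    """Per-ontology agreement between two annotation tables.

    Cohen's kappa scores exact identifier matches (absence is an
    explicit category); soft agreement scores the cosine similarity of
    the comparison texts — the chosen identifiers' class names by
    default (falling back to the raw identifier when unresolvable), or
    the identifiers themselves with ``unit="identifier"``.
    """
    by_a = {r.label: r for r in results_a}
    by_b = {r.label: r for r in results_b}
    shared = sorted(set(by_a) & set(by_b))
    if not shared:
        raise ValueError("no shared labels between the two annotation tables")

    rows: dict[str, dict[str, Optional[float]]] = {}
    for ns, graph in graphs.items():
        id_pairs = []
        text_pairs = []
        for label in shared:
            pa = by_a[label].proposed.get(ns)
            pb = by_b[label].proposed.get(ns)
            id_pairs.append(
                (pa.render() if pa else None, pb.render() if pb else None)
            )
            if unit == "identifier":
                text_pairs.append(
                    (pa.render() if pa else None, pb.render() if pb else None)
                )
            else:
                text_pairs.append(
                    (
                        (class_name(graph, pa) or pa.render()) if pa else None,
                        (class_name(graph, pb) or pb.render()) if pb else None,
                    )
                )
        kappa = cohens_kappa(id_pairs)
        scorable = [p for p in text_pairs if p != (None, None)]
        soft = (
            soft_agreement(
                text_pairs, embedder or TrigramEmbedder(), threshold
            )
            if scorable
            else None
        )
        rows[ns] = {
            "kappa": kappa.kappa,
            "p_o": kappa.p_o,
            "p_e": kappa.p_e,
            "soft_agreement": soft.ratio if soft else None,
            "n": kappa.n,
        }
    return rows


def _annotate(
    config: RunConfig,
    gold: Sequence[BiosampleRecord],
    graphs: Mapping[str, OntologyGraph],
) -> list[AnnotationResult]:
    labels = [r.label for r in gold]
    if config.annotations_path:
        results = read_annotations_tsv(config.annotations_path)
        log.info("read %d stored annotations", len(results))
        return results
    if config.backend == "lexical":
        index = LexicalIndex.build(graphs)
        return lexical_annotator(labels, index, config.lexical_threshold)
    from .synthetic import ErrorProfile  # deferred: profiles live there

    profile = (
        ErrorProfile.from_yaml(config.profile_path)
        if config.profile_path
        else ErrorProfile.all_correct()
    )
    backend = mock_backend(gold, profile, derive_seed(config.seed, 1), graphs)
    return annotate_labels(labels, backend, annotator_id="mock")


def run_pipeline(config: RunConfig) -> EvaluationReport:
    """Execute annotate -> evaluate (-> agree) and write all artifacts.

    Raises on configuration errors before any work; poor metrics never
    fail the run.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)

    graphs = load_graphs(config.ontologies)
    log.info(
        "loaded %d ontologies: %s",
        len(graphs),
        {p: len(g) for p, g in graphs.items()},
    )
    gold = read_biosamples_tsv(config.gold_path)
    log.info("read %d gold records", len(gold))
    overrides = (
        Overrides.from_tsv(config.overrides_path)
        if config.overrides_path
        else None
    )

    results = _annotate(config, gold, graphs)
    n_bad = sum(1 for r in results if not r.format_ok)
    log.info("annotated %d labels; %d format failures", len(results), n_bad)
    write_annotations_tsv(
        results, os.path.join(config.out_dir, "annotations.tsv")
    )

    report = stratify(results, {r.label: r for r in gold}, graphs, overrides)
    log.info(
        "tallied %d cells; disregarded %d labels",
        sum(t.total for t in report.tables.values()),
        n_bad,
    )
    write_report(
        report.tables,
        report.metrics(),
        os.path.join(config.out_dir, "report.tsv"),
        report.perfect_match_ratios(),
    )

    if config.second_annotations_path:
        second = read_annotations_tsv(config.second_annotations_path)
        rows = agreement_between(
            results, second, graphs, threshold=config.soft_threshold
        )
        write_agreement_report(
            rows, os.path.join(config.out_dir, "agreement.tsv")
        )

    with open(
        os.path.join(config.out_dir, "run_config.yaml"), "w", encoding="utf-8"
    ) as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return report
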