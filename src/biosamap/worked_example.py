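"""Worked-example evaluation tallies of a fine-tuned LLM annotator.

The packaged fixture holds the seven-cell confusion tallies of a
fine-tuned LLM annotator evaluated against a human gold standard on a
1880-label biosample test set, stratified by concept type and ontology.
They serve as a concrete end-to-end check of the metric formulas and
report formatting: feeding them through :func:`compute_metrics` must
reproduce the published precision/recall/F1 values at 3-decimal
rounding, and the per-concept cell sums must be conserved across the
four ontologies.

Bookkeeping of the test set: 918 cell-line, 696 cell-type, 208
anatomical-structure and 58 untyped labels; 149 outputs failed the
constrained format and were disregarded (147 typed + 2 untyped),
leaving 804 / 673 / 198 evaluated labels per typed concept.
"""

from __future__ import annotations

from importlib import resources

from .evaluation import ConfusionTable
from .inference import ConceptType
from .io import read_tallies_tsv

#: Size of the worked-example test split and its composition.
TEST_SET_SIZE = 1880
TYPED_LABEL_COUNTS = {
    ConceptType.CELL_LINE: 918,
    ConceptType.CELL_TYPE: 696,
    ConceptType.ANATOMICAL_STRUCTURE: 208,
}
UNTYPED_LABELS = 58
FORMAT_FAILURES_TOTAL = 149

#: Full-dataset size and split fractions used to derive the test set.
DATASET_SIZE = 6264
SPLIT_FRACTIONS = (0.525, 0.175, 0.30)


def load_tallies() -> dict[tuple[str, ConceptType], ConfusionTable]:
    """Load the packaged worked-example confusion tallies."""
    ref = resources.files("biosamap.data") / "worked_example_tallies.tsv"
    with ref.open("r", encoding="utf-8") as fh:
        return read_tallies_tsv(fh)
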