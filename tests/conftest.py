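import io

import pytest
from hypothesis import settings

from biosamap.inference import ConceptType
from biosamap.ontology import load_ontology
from biosamap.synthetic import GoldSpec, generate_gold, generate_ontologies

settings.register_profile("suite", derandomize=True, max_examples=100)
settings.load_profile("suite")


CLO_OBO = """format-version: 1.2
ontology: clo

[Term]
id: CLO:0000001
name: cell line

[Term]
id: CLO:0001200
name: 22Rv1 cell
is_a: CLO:0000001
xref: CL:0002231
xref: UBERON:0002367
xref: BTO:0002999

[Term]
id: CLO:0000050
name: ambiguous line
is_a: CLO:0000001
xref: BTO:0002999
xref: BTO:0000001

[Term]
id: CLO:0000060
name: bare line
is_a: CLO:0001200

[Term]
id: CLO:0000070
name: retired line
is_a: CLO:0000001
is_obsolete: true
"""

CL_OBO = """format-version: 1.2
ontology: cl

[Term]
id: CL:0000001
name: cell

[Term]
id: CL:0002231
name: epithelial cell of prostate
is_a: CL:0000001
xref: UBERON:0002367
xref: BTO:0002999

[Term]
id: CL:0000066
name: epithelial cell
is_a: CL:0000001

[Term]
id: CL:0000077
name: mesothelial cell
synonym: "mesoepithelial cell" EXACT []
is_a: CL:0000066

[Term]
id: CL:0000076
name: meso-epithelial cell
is_a: CL:0000066

[Term]
id: CL:0002326
name: luminal epithelial cell of mammary gland
is_a: CL:0000066
xref: UBERON:0000310
"""

UBERON_OBO = """format-version: 1.2
ontology: uberon

[Term]
id: UBERON:0000001
name: anatomical structure

[Term]
id: UBERON:0000310
name: breast
is_a: UBERON:0000001

[Term]
id: UBERON:0008367
name: breast epithelium
is_a: UBERON:0000310

[Term]
id: UBERON:0002367
name: prostate gland
is_a: UBERON:0000001
xref: BTO:0002999
"""

BTO_OBO = """format-version: 1.2
ontology: bto

[Term]
id: BTO:0000001
name: tissues, cell types and enzyme sources

[Term]
id: BTO:0002999
name: 22RV1 cell
is_a: BTO:0000001

[Term]
id: BTO:0000214
name: mammary gland
is_a: BTO:0000001
"""


@pytest.fixture(scope="session")
def fixture_graphs():
    """Hand-written four-ontology fixture mirroring a prostate cell line
    (22Rv1) whose cross-links chain into cell type, anatomy and tissue."""
    return {
        "CLO": load_ontology(io.StringIO(CLO_OBO), "CLO"),
        "CL": load_ontology(io.StringIO(CL_OBO), "CL"),
        "UBERON": load_ontology(io.StringIO(UBERON_OBO), "UBERON"),
        "BTO": load_ontology(io.StringIO(BTO_OBO), "BTO"),
    }


@pytest.fixture(scope="session")
def gen_graphs():
    """Generated four-ontology fixture with chained cross-links."""
    return generate_ontologies(7)


@pytest.fixture(scope="session")
def small_gold(gen_graphs):
    spec = GoldSpec(
        counts={
            ConceptType.CELL_LINE: 60,
            ConceptType.CELL_TYPE: 40,
            ConceptType.ANATOMICAL_STRUCTURE: 15,
            ConceptType.NONE: 5,
        }
    )
    return generate_gold(gen_graphs, spec, 11)
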