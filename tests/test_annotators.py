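"""Prompt pipeline, output parsing, lexical baseline, splitting, export."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from biosamap.annotators import (
    DEFAULT_PROMPT_SPEC,
    FINETUNE_HYPERPARAMETERS,
    LexicalIndex,
    PromptError,
    PromptSpec,
    annotate_labels,
    build_prompt,
    export_finetune_dataset,
    lexical_annotate,
    lexical_tokens,
    mock_backend,
    parse_model_output,
    render_proposals,
    split_dataset,
    write_finetune_jsonl,
)
from biosamap.evaluation import NAMESPACES
from biosamap.inference import ConceptType
from biosamap.io import BiosampleRecord
from biosamap.ontology import OntologyGraph, OntologyTerm, TermId


class TestBuildPrompt:
    def test_five_sections_with_label_once(self):
        prompt = build_prompt(DEFAULT_PROMPT_SPEC, "22Rv1")
        for header in (
            "### Role",
            "### Objectives",
            "### Inputs",
            "### Process refinements",
            "### Constraints",
        ):
            assert header in prompt
        assert prompt.count("22Rv1") == 1
        inputs_section = prompt.split("### Inputs")[1].split("###")[0]
        assert "22Rv1" in inputs_section

    def test_deterministic(self):
        assert build_prompt(DEFAULT_PROMPT_SPEC, "A549") == build_prompt(
            DEFAULT_PROMPT_SPEC, "A549"
        )

    def test_empty_section_rejected(self):
        spec = PromptSpec(
            role_text="r",
            objectives_text="o",
            inputs_text="{label}",
            process_refinements_text="p",
            constraints_text="",
        )
        with pytest.raises(PromptError):
            build_prompt(spec, "x")

    def test_empty_label_rejected(self):
        with pytest.raises(PromptError):
            build_prompt(DEFAULT_PROMPT_SPEC, "")


ids = st.one_of(
    st.none(),
    st.integers(min_value=1, max_value=9999999),
)


@st.composite
def proposal_sets(draw):
    return {
        ns: (None if v is None else TermId(ns, f"{v:07d}"))
        for ns in NAMESPACES
        for v in [draw(ids)]
    }


class TestParseModelOutput:
    def test_full_row_parses(self):
        proposed, ok = parse_model_output(
            "[CLO_0001200, CL_0002231, UBERON_0002367, BTO_0002999]"
        )
        assert ok
        assert proposed == {
            "CLO": TermId("CLO", "0001200"),
            "CL": TermId("CL", "0002231"),
            "UBERON": TermId("UBERON", "0002367"),
            "BTO": TermId("BTO", "0002999"),
        }

    def test_placeholders_mean_absent_but_well_formed(self):
        proposed, ok = parse_model_output(
            "[CLO_0000000, CL_0000000, UBERON_0000000, BTO_0000000]"
        )
        assert ok
        assert all(v is None for v in proposed.values())

    @pytest.mark.parametrize(
        "text",
        [
            "The identifiers are CLO_0001200, CL_0002231...",
            "[CLO_0001200, CL_0002231, UBERON_0002367]",
            "[CL_0002231, CLO_0001200, UBERON_0002367, BTO_0002999]",
            "[CLO_12, CL_0002231, UBERON_0002367, BTO_0002999]",
            "",
        ],
    )
    def test_malformation_is_captured_not_raised(self, text):
        proposed, ok = parse_model_output(text)
        assert not ok
        assert proposed == {}

    @given(proposal_sets())
    def test_render_parse_round_trip(self, proposals):
        parsed, ok = parse_model_output(render_proposals(proposals))
        assert ok
        assert parsed == proposals


@pytest.fixture(scope="module")
def two_doc_index():
    terms = {
        TermId("UBERON", "0000001"): OntologyTerm(
            TermId("UBERON", "0000001"), "uterus"
        ),
        TermId("UBERON", "0000002"): OntologyTerm(
            TermId("UBERON", "0000002"), "breast epithelium"
        ),
    }
    return LexicalIndex.build({"UBERON": OntologyGraph("UBERON", terms)})


class TestLexicalAnnotate:

    def test_exact_name_match_scores_one(self, two_doc_index):
        got = lexical_annotate("uterus", two_doc_index)["UBERON"]
        assert got.term_id == TermId("UBERON", "0000001")
        assert got.score == pytest.approx(1.0)

    def test_two_document_fixture_matches_hand_computation(self, two_doc_index):
        """TF-IDF with smoothed idf and l2 norm over {"uterus",
        "breast epithelium"}: the query "uterus epithelium" splits its mass
        evenly, so cosine with "uterus" is 1/sqrt(2) and with "breast
        epithelium" is 1/2; the oracle below recomputes this from scratch."""
        docs = ["uterus", "breast epithelium"]
        query = "uterus epithelium"
        vocab = sorted({t for d in docs for t in lexical_tokens(d)})
        n = len(docs)
        df = {
            t: sum(t in lexical_tokens(d) for d in docs) for t in vocab
        }
        idf = {t: math.log((1 + n) / (1 + df[t])) + 1 for t in vocab}

        def vec(text):
            counts = {t: lexical_tokens(text).count(t) for t in vocab}
            raw = np.array([counts[t] * idf[t] for t in vocab], float)
            norm = np.linalg.norm(raw)
            return raw / norm if norm else raw

        sims = [float(np.dot(vec(query), vec(d))) for d in docs]
        assert sims[0] == pytest.approx(1 / np.sqrt(2))
        assert sims[1] == pytest.approx(0.5)
        got = lexical_annotate(query, two_doc_index)["UBERON"]
        assert got.term_id == TermId("UBERON", "0000001")
        assert got.score == pytest.approx(max(sims))

    def test_no_shared_signal_is_absent(self, two_doc_index):
        assert lexical_annotate("zzzzqq", two_doc_index)["UBERON"] is None

    def test_scores_match_bruteforce_on_generated_index(self, gen_graphs):
        """Top-candidate scores equal an independent brute-force TF-IDF /
        cosine computation on a small (<= 20 term) index."""
        small = {}
        for ns, graph in gen_graphs.items():
            keep = dict(sorted(graph.terms.items())[:15])
            keep = {
                tid: OntologyTerm(tid, t.name, t.synonyms)
                for tid, t in keep.items()
            }
            small[ns] = OntologyGraph(ns, keep)
        index = LexicalIndex.build(small)

        def brute_best(label, ns):
            entries = []
            for tid in sorted(small[ns].terms):
                term = small[ns].terms[tid]
                entries.append((tid, term.name))
                for syn in sorted(term.synonyms):
                    entries.append((tid, syn))
            docs = [doc for _, doc in entries]
            n = len(docs)
            vocab = sorted({t for d in docs for t in lexical_tokens(d)})
            df = {
                t: sum(t in set(lexical_tokens(d)) for d in docs)
                for t in vocab
            }
            idf = {
                t: math.log((1 + n) / (1 + df[t])) + 1 for t in vocab
            }

            def vec(text):
                toks = lexical_tokens(text)
                raw = np.array(
                    [toks.count(t) * idf[t] for t in vocab], float
                )
                norm = np.linalg.norm(raw)
                return raw / norm if norm else raw

            q = vec(label)
            return max(
                (float(np.dot(q, vec(d))) for d in docs), default=0.0
            )

        rng = np.random.default_rng(3)
        names = [
            t.name for g in small.values() for t in g.terms.values()
        ]
        queries = [names[i] for i in rng.integers(0, len(names), size=8)]
        for label in queries:
            got = lexical_annotate(label, index, threshold=0.0)
            for ns in NAMESPACES:
                best = brute_best(label, ns)
                if got[ns] is None:
                    assert best == pytest.approx(0.0, abs=1e-12)
                else:
                    assert got[ns].score == pytest.approx(best)


def _record(label, gold, concept=ConceptType.CELL_LINE):
    return BiosampleRecord(label=label, gold=gold, concept=concept)


class TestMockBackend:
    def _gold(self, gen_graphs, n=30, seed=21):
        from biosamap.synthetic import GoldSpec, generate_gold

        return generate_gold(
            gen_graphs,
            GoldSpec(
                counts={ConceptType.CELL_LINE: n},
                coverage={ns: 1.0 for ns in NAMESPACES},
            ),
            seed,
        )

    def test_all_correct_profile_reproduces_gold(self, gen_graphs):
        from biosamap.synthetic import ErrorProfile

        gold = self._gold(gen_graphs)
        backend = mock_backend(
            gold, ErrorProfile.all_correct(), 1, gen_graphs
        )
        results = annotate_labels(
            [r.label for r in gold], backend, "mock"
        )
        for record, result in zip(gold, results):
            assert result.format_ok
            assert dict(result.proposed) == dict(record.gold)

    def test_all_malformed_profile_fails_every_parse(self, gen_graphs):
        from biosamap.synthetic import ErrorProfile

        gold = self._gold(gen_graphs)
        backend = mock_backend(
            gold, ErrorProfile.all_malformed(), 1, gen_graphs
        )
        results = annotate_labels([r.label for r in gold], backend, "mock")
        assert all(not r.format_ok for r in results)

    def test_unknown_label_yields_placeholders(self, gen_graphs):
        from biosamap.synthetic import ErrorProfile

        backend = mock_backend(
            self._gold(gen_graphs), ErrorProfile.all_correct(), 1, gen_graphs
        )
        results = annotate_labels(["no-such-label"], backend, "mock")
        assert results[0].format_ok
        assert all(v is None for v in results[0].proposed.values())

    def test_correct_rate_within_binomial_band(self, gen_graphs):
        """p(identical) = 0.6 per namespace: the fraction of proposals that
        reproduce gold lies in the binomial 99% interval."""
        from biosamap.synthetic import ErrorProfile

        gold = self._gold(gen_graphs, n=100, seed=22)
        profile = ErrorProfile.uniform((0.6, 0.0, 0.4, 0.0), (0.0, 0.0, 1.0))
        backend = mock_backend(gold, profile, 77, gen_graphs)
        results = annotate_labels([r.label for r in gold], backend, "mock")
        trials = hits = 0
        for record, result in zip(gold, results):
            for ns in NAMESPACES:
                if record.gold.get(ns) is None:
                    continue
                trials += 1
                hits += result.proposed.get(ns) == record.gold[ns]
        lo, hi = stats.binom.interval(0.99, trials, 0.6)
        assert lo <= hits <= hi


class TestSplitDataset:
    def test_study_sized_split(self):
        records = list(range(6264))
        train, val, test = split_dataset(records, (0.525, 0.175, 0.30), 0)
        assert (len(train), len(val), len(test)) == (3288, 1096, 1880)

    def test_exact_division(self):
        train, val, test = split_dataset(list(range(10)), (0.5, 0.2, 0.3), 1)
        assert (len(train), len(val), len(test)) == (5, 2, 3)

    def test_partition_properties(self):
        records = list(range(101))
        train, val, test = split_dataset(records, (0.525, 0.175, 0.30), 3)
        assert sorted(train + val + test) == records
        assert not (set(train) & set(val))
        assert not (set(train) & set(test))
        assert not (set(val) & set(test))

    def test_same_seed_same_partition(self):
        records = list(range(50))
        assert split_dataset(records, (0.5, 0.25, 0.25), 9) == split_dataset(
            records, (0.5, 0.25, 0.25), 9
        )

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            split_dataset([], (0.5, 0.2, 0.3), 0)
        with pytest.raises(ValueError):
            split_dataset([1], (0.5, 0.2, 0.2), 0)


class TestFinetuneExport:
    def test_full_row_renders_assistant_message(self):
        rec = _record(
            "22Rv1",
            {
                "CLO": TermId("CLO", "0001200"),
                "CL": TermId("CL", "0002231"),
                "UBERON": TermId("UBERON", "0002367"),
                "BTO": TermId("BTO", "0002999"),
            },
        )
        (example,) = export_finetune_dataset([rec])
        assert (
            example["messages"][2]["content"]
            == "[CLO_0001200, CL_0002231, UBERON_0002367, BTO_0002999]"
        )
        assert "22Rv1" in example["messages"][1]["content"]

    def test_absent_gold_renders_placeholder(self):
        rec = _record(
            "226LDM_normal_breast_luminal_cells",
            {
                "CLO": None,
                "CL": TermId("CL", "0002326"),
                "UBERON": TermId("UBERON", "0000310"),
                "BTO": None,
            },
        )
        (example,) = export_finetune_dataset([rec])
        assert (
            example["messages"][2]["content"]
            == "[CLO_0000000, CL_0002326, UBERON_0000310, BTO_0000000]"
        )

    def test_all_absent_record_skipped_and_empty_stream(self):
        rec = _record("opaque", {ns: None for ns in NAMESPACES})
        assert list(export_finetune_dataset([rec])) == []
        assert list(export_finetune_dataset([])) == []

    def test_description_flag_and_metadata(self, tmp_path):
        rec = _record(
            "22Rv1",
            {"CLO": TermId("CLO", "0001200"), "CL": None, "UBERON": None,
             "BTO": None},
        )
        rec = BiosampleRecord(
            label=rec.label, gold=rec.gold, concept=rec.concept,
            description="prostate carcinoma line",
        )
        out = tmp_path / "train.jsonl"
        meta = write_finetune_jsonl([rec], str(out), include_descriptions=True)
        assert meta["hyperparameters"] == FINETUNE_HYPERPARAMETERS
        assert meta["n_examples"] == 1
        lines = out.read_text().splitlines()
        example = json.loads(lines[0])
        assert "prostate carcinoma line" in example["messages"][1]["content"]
        sidecar = json.loads((tmp_path / "train.jsonl.meta.json").read_text())
        assert sidecar["hyperparameters"]["n_epochs"] == 6
        assert sidecar["hyperparameters"]["batch_size"] == 3
        assert sidecar["hyperparameters"]["learning_rate_multiplier"] == 0.3
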