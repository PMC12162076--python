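# Methods

This note documents the models and procedures `biosamap` implements, the
parameters that matter, the synthetic-data generator's assumptions, and
the design choices made where the design was genuinely open. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Setting and identifiers

A *biosample label* is a free-text name (a descriptive phrase or an
opaque alphanumeric code) to be linked to at most one identifier in each
of four ontologies: CLO (cell lines), CL (cell types), UBERON (anatomy),
BTO (tissues and enzyme sources). Identifiers are CURIEs with a
7-digit, zero-padded local part. The canonical rendering is the
underscore form (`CLO_0001200`), matching how annotation data and
constrained model outputs print them; the colon form used inside OBO
files is accepted on input. The all-zero identifier per namespace
(`CLO_0000000`) is a *placeholder*: it parses — constrained generators
emit it to mean "no identifier" — but never resolves to a term.

Ontologies are loaded from OBO flat files (via `obonet`) into
per-namespace graphs holding names, synonyms, `is_a` parents and
cross-namespace `xref`s. Loading validates that `is_a` edges form a DAG
and that every referenced same-prefix parent exists; terms of other
namespaces in the same file are ignored except as xref targets.
Obsolete terms load (they may appear as gold values in legacy data) but
are excluded from annotation candidate indexes. Class-name resolution
is local; a caller may supply a remote lookup contract
(`TermId -> name`), whose answers are cached, but nothing in the package
requires one — the toolkit runs entirely offline.

## Identifier inference

Each typed label has a fine-to-coarse derivation order:

* cell line: CLO → CL → UBERON → BTO (priority pair CLO+BTO)
* cell type: CL → UBERON → BTO (priority pair CL+BTO)
* anatomical structure: UBERON → BTO (priority pair UBERON+BTO)
* untyped: all four namespaces rank equal; no inference is defined.

From a source identifier, identifiers at coarser-or-equal ranks are
derived; finer ranks are never inferred (a cell type does not determine
a cell line). Cross-link candidates for a target namespace are gathered
in three stages, stopping at the first that yields any:

1. the source term's own xrefs;
2. xrefs inherited from its `is_a` ancestors, walked nearest-level
   first, taking the union within the first non-silent level;
3. chaining through already-inferred finer identifiers (a tissue is
   reached from a cell line via its cell type when the cell-line term
   has no direct tissue link).

Exactly one candidate is accepted. Ambiguous evidence (two or more
candidates) yields an absent result plus a logged diagnostic, never an
arbitrary pick: inference is meant to produce *the* identifier, and
non-unique evidence is insufficient. Inherited and chained derivations
are ordinary results; sparse direct xref coverage is the norm in real
ontologies.

## Confusion taxonomy and adjudication

Each (label, namespace) pair lands in one of seven cells: TP_I, TP_R,
TP_C, FP_E, FP_IC, FN, TN (see README for definitions). The
relationship test behind TP_R accepts, in order: a manual override; a
shared normalized name or synonym (same entity, different name);
a strict `is_a` ancestor of the reference (hypernym). A strict
*descendant* is invalid — mirroring the inference granularity rule,
a finer claim than the reference is unsupported. A proposal that does
not resolve in its ontology is a hallucination and invalid. Name
normalization casefolds, strips punctuation without inserting spaces
(so a hyphenated spelling equals its fused form) and collapses
whitespace.

Contributions (proposals where the gold standard has no identifier) are
adjudicated in two ways. A manual-override table —
TSV of (label, namespace, proposed id, VALID|INVALID, note) — always
takes precedence; it is the mechanism for curator judgment. Absent an
override, an automatic check holds a contribution valid when it
resolves, its namespace is derivable for the label's concept type, and
the identifiers inferred *from the contribution* agree with the label's
gold values in at least one other namespace with no disagreement.
Untyped labels define no derivation order, so their contributions
require an override; without one they count as invalid — a conservative
default.

Format-failed outputs are retained in annotation files with
`format_ok = false`, routed to a per-scope *disregarded* counter, and
excluded from the cells; their count is a result in its own right.

Metrics per (namespace, concept-type) scope use aggregated
TP = I + R + C and FP = E + IC. Ratios with zero denominators are
reported absent, not zero. For untyped labels only precision is
reported: priority ontologies — which recall and the perfect match
ratio lean on — are undefined there. The perfect match ratio counts
labels whose outcomes in *both* priority namespaces are true positives
of any origin, over the evaluated (non-disregarded) labels of the
concept type; the disregarded count is reported alongside so the
including-failures denominator can be formed by the reader.

Report display rounds half-up to three decimals; internal values stay
full precision.

## Annotators

**Prompt pipeline.** Prompts have five mandatory sections — role,
objectives, inputs, process refinements, constraints — concatenated
under fixed headers, with the label substituted into the inputs section.
The default wording is this package's own reconstruction of that scheme
for expert ontology annotation; callers supply their own `PromptSpec`
to change it. The backend contract is a synchronous
`prompt string -> completion string` callable, keeping remote LLMs,
local models and the mock interchangeable. Output parsing accepts
exactly one bracketed list of four identifiers in CLO, CL, UBERON, BTO
order (whitespace-tolerant; placeholders mean absent); anything else is
captured as a format failure, never raised.

**Lexical baseline.** A TF-IDF vector space (scikit-learn, smoothed idf,
l2 norm) is built per namespace over every non-obsolete term's name and
each synonym as separate documents. Tokenization casefolds and splits
on non-alphanumerics, adding character 3-grams for tokens containing
digits so coded labels like `22Rv1` retain some signal — pure term
matching is known to fail on such labels. The top candidate by cosine
similarity is returned when it reaches the acceptance threshold
(default 0.5 cosine — a conservative default, configurable; no
canonical value exists for this corpus). Ties within 1e-9 of the best
cosine break by lower normalized edit distance (edlib) between label
and candidate text, then by lexicographically smallest identifier, for
full determinism.

**Mock backend.** Deterministically samples outputs for known gold
labels under an error profile (below), emitting the constrained format
or, with the profile's malformation probability, prose that fails it.
Unknown labels yield all placeholders.

**Dataset utilities.** `split_dataset` partitions with
floor(f·N) / floor(f·N) / remainder sizes over a seeded uniform
shuffle; at the defaults (52.5 / 17.5 / 30) a 6264-record table splits
3288 / 1096 / 1880. The fine-tune exporter writes chat-format JSONL
(system / user / assistant) with a single-sentence instruction, the
bracketed gold output (placeholders for absent values), and an optional
description line; a sidecar metadata file records the fine-tuning
hyperparameters (6 epochs, batch size 3, learning-rate multiplier 0.3)
as configuration provenance without acting on them. Records with no
gold identifier anywhere are skipped with a warning — they carry no
training signal in this format.

## Inter-annotator agreement

Cohen's kappa is computed per ontology on exact identifier matches,
κ = (p_o − p_e)/(1 − p_e), with p_e from the two raters' marginal
distributions and "no identifier" as an explicit category; when both
raters use one identical category (p_e = 1) kappa is undefined and
reported absent. Soft agreement is the fraction of pairs whose
comparison texts exceed a cosine-similarity threshold, default 0.9 with
a strictly-greater comparison. The comparison unit is the chosen
identifiers' class names (falling back to the raw identifier when
unresolvable) — the package's reading of "the textual labels assigned
by each annotator"; an identifier-string mode is provided as the
alternative reading. Pairs where both sides are absent are skipped;
one-sided absence counts as a non-match in the denominator. The
embedder is a pluggable contract (callable `text -> vector`, optional
`fit(texts)`, an `embedder_id` for provenance). The in-repo embedders —
character-trigram term frequency and exact-match indicator — are
deterministic and need no network or model download; a
sentence-transformer model satisfies the same contract where available.

## Synthetic data

**Ontology generator.** Each namespace gets a rooted random `is_a` DAG
(each term one parent among earlier terms, a second with probability
0.2) with names drawn from small anatomical/cell-type vocabularies —
organs, positional adjectives, cell-type nouns — and code-plus-"cell"
names for cell lines; about a quarter of terms get a hyphen-variant
synonym to exercise name normalization. Cross-links follow the
inference chain: CLO terms link to a CL term, CL terms to a UBERON term
(15% instead inherit their anatomy through ancestors, exercising the
inherited-xref path), UBERON terms to a BTO term; roots link across so
ancestor walks terminate. BTO links are propagated *down* the chain —
each term borrows the tissue link of its chain target — so that
inference from any granularity reaches the same BTO term; without this
coherence the generated gold could not satisfy the invariant that
re-inferring from the finest gold identifier reproduces the coarser
columns. Default sizes are 60/40/30/80 terms for CLO/CL/UBERON/BTO —
small enough for exhaustive oracles, large enough for non-trivial
hierarchies.

**Gold generator.** Entities are terms drawn from the concept's source
ontology (CLO for cell lines, CL for cell types, UBERON for anatomical
structures; any namespace for untyped labels); gold identifiers are the
entity's inference closure, thinned per namespace by a coverage
probability (default 0.9), with dropout applied per entity so spelling
variants share identical identifier columns. Labels mix the term's
descriptive name and opaque alphanumeric codes (fraction 0.3 by
default), with 1–3 variants per entity (probabilities 0.7/0.2/0.1)
produced by seeded mutations — underscore/case changes, dropped or
doubled characters, random suffixes. Default label counts per concept
type follow the composition of the study dataset (3080 cell lines, 2258
cell types, 723 anatomical structures, 203 untyped); tests and the
acceptance script pass smaller counts explicitly as their problem
sizes. What the generator does *not* emulate: the linguistic
distribution of real ontology names, multi-species anatomy, or
token-level LLM behavior — so passing tests validate the evaluator's
bookkeeping and estimators, not any claim about real annotator quality.

**Annotator simulator.** An `ErrorProfile` gives, per namespace, the
outcome distribution conditional on the reference being present
(identical / related / wrong / abstain) or absent (valid contribution /
invalid contribution / abstain), plus a global malformation probability
and the share of "wrong" proposals drawn as nonexistent identifiers
(default 0.5, exercising the hallucination path). "Related" draws a
strict ancestor — the one automatically-validated relation; a root
reference with no ancestor falls back to "wrong" with a diagnostic.
"Wrong" existing terms are resampled until they are neither ancestors
nor descendants of the reference and share no normalized name with it,
so the branch lands in FP_E by construction. Valid contributions
propose the entity's true (pre-dropout) identifier; invalid ones a
guaranteed-unrelated term. The simulator emits its contribution
verdicts as an overrides table — the machine analogue of the curator's
manual contribution check — so that evaluating with those overrides
makes expected confusion cells exactly linear in the profile rates:
with coverage c,

    E[precision] = [c(p_id + p_rel) + (1−c) p_valid] /
                   [c(p_id + p_rel + p_wrong) + (1−c)(p_valid + p_invalid)]
    E[recall]    = [c(p_id + p_rel) + (1−c) p_valid] /
                   [c(p_id + p_rel) + (1−c) p_valid + c·p_abstain]

Parameter-recovery tests run 2000 simulated cell-line labels at
coverage 0.85 and check the evaluator's precision and recall per
namespace against these closed forms within three binomial standard
errors, conditioning on the realized coverage.

## Determinism and numerical choices

All randomness flows from explicit integer seeds through NumPy
generators; pipeline stages derive child seeds from the one run seed via
`SeedSequence`, kept below 2^31. Identical seeds give identical
ontologies, gold tables, simulations and byte-identical reports.
Undefined ratios (0/0) are absent values, never zeros. Kappa at
p_e = 1 is absent. Cosine similarity rejects zero vectors and
dimension mismatches rather than guessing. Report rounding is half-up
at three decimals.

## Limitations

* Inference relies on xref quality; it reports ambiguity rather than
  resolving it, and never overwrites gold values that disagree with
  ontology xrefs — both sides are kept visible.
* The automatic contribution check needs corroborating gold values in
  other namespaces; sparse gold rows push valid contributions into
  FP_IC unless a curator override says otherwise.
* Only `is_a` reachability is used; no OWL reasoning, no
  cross-species or developmental mappings.
* Agreement statistics cover exactly two raters; no weighted kappa or
  confidence intervals.
* One identifier per (label, ontology): multi-label or probabilistic
  mappings are out of scope.
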