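# Methods

## Problem setting

Phenotype concept normalization maps a textual mention to the identifier
of an ontology concept. The package treats the Human Phenotype Ontology
(HPO) as the target vocabulary: each concept has an id `HP:` + 7 digits,
one preferred name, zero or more synonyms, and optional cross-references
(xrefs) into other vocabularies such as SNOMED-CT, which may carry that
vocabulary's own surface term. Normalizers are compared on six query
categories of increasing difficulty: exact training names, synonyms held
out of training, single-character typos, multi-character typos, SNOMED-CT
xref terms, and colloquial laymen's terms.

## Vocabulary ingestion

`parse_obo` delegates stanza parsing to `obonet` and then applies the
ingestion rules: obsolete stanzas are dropped (they have no valid
normalization target), stanzas whose id lacks the `HP:` prefix are skipped
with a logged count, synonym surface strings are the quoted portion of the
`synonym:` line with **all scope tags ingested uniformly** (EXACT, BROAD,
NARROW, RELATED — the evaluation design does not distinguish them),
synonyms are deduplicated case-sensitively, and a synonym identical to the
preferred name is removed (HPO releases list the name among the synonyms
for some concepts; names and synonyms are counted as distinct terms).
Because real annotation pipelines sometimes distribute SNOMED-CT synonym
lists separately from the OBO xref field, both paths are supported: xref
surface terms via `extract_xref_terms`, and a sideloaded two-column TSV via
`load_term_tsv`.

No ontology graph reasoning is performed: the `is_a` hierarchy is not
traversed, and identifiers are treated as opaque labels except for the
digit-suffix diagnostic described below.

## Synthetic vocabularies

`generate_fixture` emulates the structural features of an HPO release that
the pipeline depends on: sequential `HP:` ids, one multi-word name and 0–8
synonyms per concept, and (at a configurable rate) one SNOMED-style xref
with a hyphenated surface term. Names and synonyms are 2–5-token phrases
drawn from a 64-word pool of phenotype-flavored vocabulary, sampled
without replacement within a phrase and kept **globally unique as sorted
token multisets** — no surface term is a permutation of another — so exact
lookup has a unique answer and token-based retrieval is nontrivial (terms
share tokens heavily without being equal). Generation is a pure function
of its arguments: fixed seeds give byte-identical OBO serializations.

What the fixture deliberately does not emulate: real HPO term length and
morphology (Latin/Greek compounds), the ontology's hierarchical id
structure, polysemous abbreviations, and the long-tailed synonym-count
distribution (the real vocabulary averages ~2.7 synonyms per concept;
fixture defaults span 0–4 uniformly). Passing tests on fixtures therefore
validate the machinery and its contracts — splits, determinism, retrieval
semantics, scoring — not absolute accuracy figures on the real ontology,
which additionally depend on the analyzer and the release used.

## Corpus generation

One template renders every training sentence:

    The Human Phenotype Ontology term {term} is identified by the HPO ID {id}

Sentences are rendered **without a trailing period**, so the identifier is
the final token span and the evaluation prompt is simply the sentence
truncated after `HPO ID ` — the completion target is the bare id.
Multi-template generation is intentionally absent by default: adding
sentence variants increases training cost with little benefit for this
task, and one template keeps records trivially invertible (every sentence
parses back to its (term, id) pair; this is enforced by property tests).

The NAME+SYN split takes, per concept with n synonyms, a seeded uniform
sample of ⌊n/2⌋ synonyms into training and holds out the remaining ⌈n/2⌉.
Floor was chosen for the odd case so the held-out (evaluation) share is
never smaller than the training share; sampling rather than "first half"
avoids ordering bias from the source file. Typo augmentation emits one
sentence per input sentence with the term replaced by a simple typo; the
augmented corpus is produced separately so a training schedule can either
concatenate it with or substitute it for the clean corpus during the extra
typo epochs.

## Typo model

Both generators substitute letters with QWERTY-adjacent letters, preserve
case and never touch non-letters (spaces, digits, punctuation). The
adjacency table is built from the three letter rows with the physical
half-key stagger, giving diagonal neighbors: `i → {u,o,j,k}`,
`m → {n,j,k}`, `u ~ y`, `v ~ b`. Simple typos alter exactly one uniformly
chosen letter position. Complex typos alter
`k = min(3, max(1, round(0.2·L)))` distinct positions, where `L` counts
letters only and rounding is half-up; the floor at 1 guarantees every
complex typo changes something and the cap at 3 bounds the damage on long
terms. Insertions, deletions and transpositions are out of scope — the
typo model is substitution-only by design.

## BM25 baseline

Every (name, id) and (synonym, id) pair is indexed as its own entry, so
synonyms compete as separate candidates rather than being concatenated
into one document per concept. The analyzer lowercases and splits on runs
of non-alphanumerics, with no stemming or stopword removal (hyphen
stripping is therefore a no-op at the token level, which is tested).
Candidates are filtered by token semantics — AND requires every query
token in the entry, OR at least one — and ranked by Okapi BM25 with
`k1 = 1.2`, `b = 0.75` (standard Lucene-style defaults; both are
configurable) and the non-negative IDF variant
`ln(1 + (N − df + 0.5)/(df + 0.5))`. Ties break by higher score, then
lexicographically smallest concept id, making retrieval fully
deterministic. An exhaustive brute-force scorer in the test suite serves
as the independent oracle for small indexes.

Fuzzy or character-n-gram retrieval is deliberately excluded: the point of
the baseline is the behavior of plain token retrieval under perturbation,
in particular the AND/OR asymmetry — one mistyped token empties the AND
candidate set while OR degrades gracefully.

## Completion-model adapter and the desk-scale model

Any object with `complete(prompt) -> str` is a normalizer after wrapping:
the prompt template (default: the training sentence truncated after
`HPO ID `) is rendered, a greedy continuation of at most 16 characters is
requested (an HPO id plus slack), and the first `HP:` + 7-digit substring
is extracted, case-normalized. Greedy decoding is required for
deterministic evaluation. Hallucinated but well-formed ids are extracted
and then scored as incorrect; continuations without any id count as
missing predictions.

`FinetuneConfig` carries the full-scale fine-tuning recipe — 100 epochs,
30 extra typo epochs, LoRA rank 32, batch size 128 — as configuration.
Transformer fine-tuning itself is out of scope here (it requires GPU
infrastructure and a base LLM); the LoRA fields are inert for desk-scale
models. The exact set of weight matrices a LoRA adapter would update is a
deployment choice and is not modeled.

`TinyCharLM` is the in-repo trainable model: a character-level MLP over an
80-character context window (embedding 16, hidden 192, tanh, softmax over
~70 characters; 261k parameters) trained with Adam (lr 3e-3) on
next-character prediction over full sentences. The window is sized so the
discriminating part of the term is still in view while the identifier
digits are generated (the template suffix plus id spans ~40 characters).
Its role is to exercise the complete train → memorize → evaluate loop in
seconds on one CPU, including the prompt-brittleness effect: near-perfect
greedy recall on the training template, collapse on a structurally
different prompt. It makes no claim of generalizing to unseen synonyms
the way a fine-tuned billion-parameter transformer does.

## Evaluation protocol

Accuracy is exact string equality of the predicted and gold identifiers;
a missing prediction (no candidate, no extractable id, or a normalizer
exception) counts as incorrect. Typo queries are generated from preferred
names only. Laymen's terms are read from a TSV with gold ids validated
against the vocabulary (unknown rows dropped with a logged count); live
generation by an external chat model is out of scope for a reproducible
surface. BM25 is evaluated on all six categories even though training
names and held-out synonyms are trivially present in its index —
self-retrieval there should be near-perfect and those rows are not
comparable to fine-tuned-model numbers, which is why per-row metadata
records the normalizer identity.

Wrong predictions that are well-formed ids carry a diagnostic: the length
of the differing digit suffix (1 = off by the last digit). Hierarchically
close concepts often share id prefixes, so fine-tuned models' near-misses
cluster at suffix length 1–2; the diagnostic is reported for error
analysis and never as partial credit.

## Problem sizes and numerical choices

The acceptance script runs the whole pipeline at 500 concepts (vs the real
ontology's ~17k), 0–4 synonyms per concept, 30% xref rate, and trains the
desk-scale model on a 20-concept NAME corpus for the full 100 epochs;
these sizes make the end-to-end run complete in well under a minute on one
CPU while leaving every qualitative effect (OR ≫ AND under typos, AND ≈ 0
on multi-token typos, memorization, prompt brittleness) clearly visible.
All randomness flows through seeded `numpy` generators; corpora, fixtures
and reports are byte-reproducible for fixed seeds. Known limitations are
as stated above: fixture realism, substitution-only typos, no graph
reasoning, and desk-scale-only training.
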