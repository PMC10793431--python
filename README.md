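# phenonorm

Concept normalization maps a free-text phenotype mention — "hearing loss",
"Bascular dilatation", "Kidney - Abnormal" — to the identifier of a
standardized concept in the Human Phenotype Ontology (HPO), e.g.
`HP:0000365` for *Hearing impairment*. Standardized phenotype identifiers
are what downstream rare-disease tooling (disease ranking, phenotype-driven
variant prioritization) actually consumes, yet clinical narratives mention
phenotypes with typos, synonyms, cross-vocabulary terms and colloquialisms
that defeat exact dictionary lookup.

`phenonorm` is a toolkit for building and evaluating normalizers under
exactly those conditions. It provides:

- **Ontology I/O** — load OBO vocabularies (`parse_obo`, via `obonet`),
  extract SNOMED-CT cross-reference surface terms as test queries, and
  generate deterministic synthetic HPO-style vocabularies so everything
  runs without a download.
- **Fine-tuning corpus generation** — every training sentence instantiates
  one template, `The Human Phenotype Ontology term {term} is identified by
  the HPO ID {id}`. The NAME corpus uses preferred names only; NAME+SYN
  adds a seeded random half (⌊n/2⌋) of each concept's synonyms and holds
  the rest out; a typo-augmented copy supports extra typo-training epochs.
- **Perturbation** — simple typos (exactly one letter replaced by a
  QWERTY-adjacent key, e.g. `i → {u,o,j,k}`), complex typos (20% of
  letters, at least 1, at most 3), and hyphen stripping.
- **BM25 baseline** — every name and synonym indexed as its own entry,
  Okapi BM25 ranking (`k1=1.2`, `b=0.75`, IDF `ln(1+(N−df+0.5)/(df+0.5))`)
  under **AND** (all query tokens must match) or **OR** (any token)
  candidate semantics, top-1 id returned.
- **Completion-model adapter** — prompt/completion training records, HPO-id
  extraction from generated text, a wrapper turning any completion model
  into a normalizer, and a ~0.3M-parameter character-level model
  (`TinyCharLM`) that exercises the fine-tune → memorize → evaluate loop on
  one CPU. The full-scale recipe (LoRA rank 32, batch 128, 100 epochs, +30
  typo epochs) is carried as `FinetuneConfig`.
- **Evaluation harness** — six query categories (training names, held-out
  synonyms, simple/complex typos, SNOMED-CT xref terms, laymen's terms),
  exact-match accuracy with missing predictions scored as wrong, per-query
  outcomes with a digit-suffix near-miss diagnostic, and TSV/aligned-text
  reports.

## Worked example

```sh
python examples/04_bm25_normalization.py
```

prints

```
indexed 284 surface terms for 100 concepts
query exact name 'Rigidity decreased':
  AND: HP:0000001 (gold HP:0000001)
  OR: HP:0000001 (gold HP:0000001)
query with one typo 'Rigidity decreqsed':
  AND: None
  OR: HP:0000001
```

The exact name resolves under both modes. One mistyped character removes
the token `decreqsed` from every posting list, so conjunctive (AND)
retrieval has an empty candidate set and returns nothing, while OR still
ranks the correct entry through the unaltered token — the central
robustness asymmetry between the two retrieval modes. The desk-scale
fine-tuning example shows the complementary effect for completion models:

```sh
python examples/05_toy_finetune_loop.py
```

```
model parameters: 261,209
mean NLL/char: epoch 1 = 3.086, epoch 100 = 0.0328
training-template accuracy: 100.0%
alternate-prompt accuracy:  0.0%
```

After 100 epochs the character model reproduces every training identifier
under greedy decoding, but accuracy collapses when the evaluation prompt
(`HPO ID of {term} is`) departs from the training sentence structure —
the model learned the template, not a prompt-independent mapping.

The remaining examples cover vocabulary/fixture handling, corpus
construction with the half-synonym hold-out, typo generation, and the full
six-category report. A `phenonorm` CLI wraps the same functions
(`phenonorm make-fixture`, `build-corpus`, `perturb`, `index`, `normalize`,
`evaluate`, `finetune`, `complete`); see `phenonorm --help`.

Laymen's terms are consumed from a two-column TSV (`term`, `gold_id`)
rather than generated live by an external chat model, keeping evaluation
reproducible and offline.

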