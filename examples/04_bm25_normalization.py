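"""Normalize query terms with the BM25 dictionary-lookup baseline.

Every name and synonym is indexed as its own entry; a query is tokenized
and candidates are filtered under AND (all tokens must match) or OR (any
token) semantics before Okapi BM25 ranking.  The single most informative
behavior: one mistyped token empties the AND candidate set, while OR still
recovers the concept through the remaining tokens.
"""

from phenonorm import RetrievalMode, build_index, generate_fixture, normalize
from phenonorm.perturb import simple_typo

vocab = generate_fixture(100, (1, 3), 0.0, seed=11)
index = build_index(vocab)
print(f"indexed {index.n_entries} surface terms for {len(vocab)} concepts")

concept = vocab.concepts[0]
print(f"query exact name {concept.name!r}:")
for mode in RetrievalMode:
    print(f"  {mode.value}: {normalize(index, concept.name, mode)} (gold {concept.id})")

typo = simple_typo(concept.name, seed=3)
print(f"query with one typo {typo!r}:")
for mode in RetrievalMode:
    print(f"  {mode.value}: {normalize(index, typo, mode)}")
# AND usually prints None here: the mistyped token occurs in no entry, so
# conjunctive retrieval has no candidates; OR still ranks the right entry.
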