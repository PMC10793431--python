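"""Generate a synthetic HPO-style vocabulary and round-trip it through OBO.

Real runs would load an HPO release (hp.obo) with `parse_obo`; the fixture
generator emulates its structure — HP:NNNNNNN ids, one preferred name,
0-8 synonyms, optional hyphenated SNOMED-CT cross-references — so every
example here is self-contained and deterministic.
"""

from phenonorm import generate_fixture, parse_obo, write_obo
from phenonorm.ontology import extract_xref_terms

vocab = generate_fixture(n_concepts=10, synonyms_per_concept=(2, 4), xref_rate=0.5, seed=7)
print(f"{len(vocab)} concepts, {vocab.n_synonyms} synonyms, source={vocab.source}")
first = vocab.concepts[0]
print(f"first concept: {first.id}  {first.name!r}  synonyms={first.synonyms}")

reparsed = parse_obo(write_obo(vocab))
print("OBO round-trip preserves every concept:", [c.id for c in reparsed] == [c.id for c in vocab])

xrefs = extract_xref_terms(vocab, "SNOMEDCT_US")
print(f"{len(xrefs)} SNOMED-CT xref surface terms, e.g. {xrefs[0].term!r} -> {xrefs[0].gold_id}")
# The xref terms are hyphenated like real SNOMED-CT synonyms; they become
# the XREF evaluation category with the owning concept's id as gold label.
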