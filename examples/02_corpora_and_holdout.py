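"""Build fine-tuning corpora with the half-synonym hold-out split.

The NAME corpus pairs each concept's preferred name with its id in one
template sentence.  The NAME+SYN corpus adds a seeded random half of each
concept's synonyms (floor(n/2)); the other half is held out to test
generalization to terms never seen during fine-tuning.
"""

from phenonorm import generate_fixture
from phenonorm.corpus import build_name_corpus, build_name_syn_corpus, build_typo_corpus

vocab = generate_fixture(10, (3, 3), 0.0, seed=4)

name = build_name_corpus(vocab)
print(f"NAME corpus: {len(name.sentences)} sentences (one per concept)")
print("example sentence:", name.sentences[0].text)

syn = build_name_syn_corpus(vocab, seed=1)
print(f"NAME+SYN corpus: {len(syn.sentences)} sentences, {len(syn.held_out)} held-out synonyms")
# 10 concepts x 3 synonyms: 1 synonym trains per concept (floor(3/2)),
# 2 are held out -> 20 sentences total, 20 held out.

typo = build_typo_corpus(syn, seed=2)
print("typo-augmented copy, first term:", repr(syn.sentences[0].term), "->", repr(typo.sentences[0].term))
# Each typo sentence differs from its source term by exactly one
# keyboard-adjacent character; it drives the extra typo-training epochs.
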